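"""Patient-specific preictal interval detection.

The interictal reference is a 2 h stretch of windows ending 6 h before
seizure onset.  Per channel, the ten windowed features over that stretch
define a multivariate Gaussian reference (mean mu, ridge-regularized
covariance S); every later window is scored by its Mahalanobis distance

    d = sqrt((p - mu)^T S^-1 (p - mu))

and L99 is the 99th percentile of the training windows' own distances, so
by construction about 1% of baseline windows exceed it.  A preictal
interval is a window span [t1, tL] that

* starts and ends on supra-threshold windows,
* lasts at least 15 min, and
* has median distance d50 > L99.

d50 uses the lower-median order statistic, under which "d50 > L99" is
exactly equivalent to "strictly more than half the windows exceed L99".
Among qualifying spans the detector maximizes the *excess* (count above
minus count below L99; the max-sum span of +/-1 labels), which pins the
detected edges to the anomalous block instead of letting isolated spurious
supra-threshold windows far outside it stretch the span; ties go to the
longer, then the later span.  The reported record-level interval comes from
the channel with the largest d50 / L99 ratio among per-channel detections.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CoverageError, DataError, ParameterError
from .features import WindowedFeatures

DEFAULT_INTERICTAL_DURATION_H = 2.0
DEFAULT_GAP_H = 6.0
DEFAULT_PERCENTILE = 99.0
DEFAULT_RIDGE = 1e-6
DEFAULT_MIN_DURATION_MIN = 15.0
MIN_TRAIN_WINDOWS = 100
_COND_LIMIT = 1e10


@dataclass
class InterictalModel:
    """Per-channel interictal feature distribution and distance threshold."""

    channel_labels: list[str]
    mu: np.ndarray          # (n_channels, 10)
    cov: np.ndarray         # (n_channels, 10, 10)
    cov_inv: np.ndarray     # (n_channels, 10, 10)
    l99: np.ndarray         # (n_channels,)
    n_train: np.ndarray     # (n_channels,)
    span_s: tuple[float, float]
    percentile: float = DEFAULT_PERCENTILE

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class DistanceSeries:
    """Mahalanobis distance of every window from the interictal model.

    ``d[w, c]`` is the distance of window ``w`` on channel ``c``; masked
    windows carry NaN.
    """

    times: np.ndarray       # window starts, seconds
    d: np.ndarray           # (n_windows, n_channels)
    channel_labels: list[str]
    window_s: float
    hop_s: float

    def to_dataframe(self):
        import pandas as pd

        frames = [
            pd.DataFrame({"time_s": self.times, "channel": label,
                          "d": self.d[:, c]})
            for c, label in enumerate(self.channel_labels)
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class PreictalInterval:
    """A detected preictal interval [t1, tL] on its provenance channel."""

    t1_s: float
    tL_s: float
    d50: float
    channel: str

    @property
    def duration_min(self) -> float:
        return (self.tL_s - self.t1_s) / 60.0


def lower_median(values: np.ndarray) -> float:
    """Median as the lower order statistic (index floor((n-1)/2))."""
    return float(np.quantile(np.asarray(values, float), 0.5, method="lower"))


def regularize_covariance(cov: np.ndarray, ridge: float = DEFAULT_RIDGE,
                          feature_scale: float = 1.0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Add an escalating ridge to the diagonal until the covariance is
    invertible with condition number below 1e10.

    Band powers are linearly constrained (their sum is bounded by 1) and
    entropy/mobility are strongly correlated, so the raw sample covariance
    is routinely near-singular.  The ridge is ``lam * trace(S) / dim`` with
    lam escalated x10 from its starting value; the trace term is floored at
    ``(1e-7 * feature_scale)^2`` so a degenerate (constant-feature) sample,
    whose covariance is pure rounding noise, still yields ~zero distances.
    """
    dim = cov.shape[0]
    scale = max(np.trace(cov) / dim, (1e-7 * feature_scale) ** 2)
    lam = ridge
    for _ in range(40):
        reg = cov + lam * scale * np.eye(dim)
        try:
            cond = np.linalg.cond(reg)
            if np.isfinite(cond) and cond < _COND_LIMIT:
                return reg, np.linalg.inv(reg)
        except np.linalg.LinAlgError:
            pass
        lam *= 10.0
    raise DataError("covariance could not be regularized to positive definite")


def fit_interictal_model(feat: WindowedFeatures, onset_s: float,
                         interictal_duration_h: float = DEFAULT_INTERICTAL_DURATION_H,
                         gap_h: float = DEFAULT_GAP_H,
                         percentile: float = DEFAULT_PERCENTILE,
                         ridge: float = DEFAULT_RIDGE,
                         min_train: int = MIN_TRAIN_WINDOWS) -> InterictalModel:
    """Fit the per-channel interictal distribution and its L99 threshold.

    The training stretch is ``[onset - gap - duration, onset - gap]``; the
    recording must cover it, and each channel needs at least ``min_train``
    unmasked windows.  L99 is the ``percentile`` (linear interpolation) of
    the training windows' own distances.
    """
    if interictal_duration_h <= 0 or gap_h < 0:
        raise ParameterError("interictal duration must be positive, gap nonnegative")
    t0 = onset_s - (gap_h + interictal_duration_h) * 3600.0
    t1 = onset_s - gap_h * 3600.0
    if t0 < feat.window_start_s[0] - 1e-9:
        raise CoverageError(
            f"interictal interval starts at {t0:.0f}s, before the first window")
    if t1 > feat.window_start_s[-1] + feat.window_s + 1e-9:
        raise CoverageError(
            f"interictal interval ends at {t1:.0f}s, after the last window")
    sel = feat.window_slice(t0, t1)
    n_ch = feat.n_channels
    dim = len(feat.feature_names)
    mu = np.empty((n_ch, dim))
    cov = np.empty((n_ch, dim, dim))
    cov_inv = np.empty((n_ch, dim, dim))
    l99 = np.empty(n_ch)
    n_train = np.empty(n_ch, dtype=int)
    for c in range(n_ch):
        ok = sel & feat.mask[:, c]
        x = feat.values[ok, c, :]
        n_train[c] = x.shape[0]
        if n_train[c] < min_train:
            raise DataError(
                f"channel {feat.channel_labels[c]}: only {n_train[c]} usable "
                f"training windows (< {min_train})")
        mu[c] = x.mean(axis=0)
        cov_c = np.cov(x, rowvar=False)
        feature_scale = 1.0 + float(np.sqrt(np.mean(mu[c] ** 2)))
        cov[c], cov_inv[c] = regularize_covariance(cov_c, ridge, feature_scale)
        diff = x - mu[c]
        d_train = np.sqrt(np.maximum(
            np.einsum("ij,jk,ik->i", diff, cov_inv[c], diff), 0.0))
        l99[c] = np.percentile(d_train, percentile)
    return InterictalModel(list(feat.channel_labels), mu, cov, cov_inv, l99,
                           n_train, (t0, t1), percentile)


def mahalanobis_series(feat: WindowedFeatures, model: InterictalModel,
                       t_start_s: float, t_end_s: float) -> DistanceSeries:
    """Distance of every window with start in ``[t_start_s, t_end_s - window]``
    from the per-channel interictal distribution.  Masked windows stay NaN."""
    if t_end_s <= t_start_s:
        raise ParameterError("need t_end > t_start")
    if list(feat.channel_labels) != list(model.channel_labels):
        raise ParameterError("feature and model channel sets differ")
    sel = feat.window_slice(t_start_s, t_end_s)
    if not np.any(sel):
        raise ParameterError("requested span contains no complete windows")
    times = feat.window_start_s[sel]
    d = np.full((times.size, feat.n_channels), np.nan)
    for c in range(feat.n_channels):
        ok = feat.mask[sel, c]
        x = feat.values[sel, c, :][ok]
        diff = x - model.mu[c]
        q = np.einsum("ij,jk,ik->i", diff, model.cov_inv[c], diff)
        d[ok, c] = np.sqrt(np.maximum(q, 0.0))
    return DistanceSeries(times, d, list(feat.channel_labels),
                          feat.window_s, feat.hop_s)


def _best_span(d: np.ndarray, threshold: float, hop_s: float, window_s: float,
               min_duration_s: float) -> tuple[int, int] | None:
    """Maximum-excess span of a single channel's distance series.

    Labels windows +1 (above threshold) / -1 (below; NaN counts below) and
    finds the span [i, j] that maximizes the label sum subject to:
    endpoints above, span duration >= min_duration_s.  A positive sum is the
    strict-majority (equivalently lower-median) criterion.  Ties prefer the
    longer span, then the later start.  Returns window indices or None.
    """
    above = np.greater(d, threshold, where=np.isfinite(d),
                       out=np.zeros(d.shape, dtype=bool))
    n = above.size
    # minimal index gap so that (j - i) * hop + window >= min duration
    min_gap = max(int(np.ceil((min_duration_s - window_s) / hop_s - 1e-9)), 0)
    labels = np.where(above, 1, -1)
    prefix = np.concatenate([[0], np.cumsum(labels)])
    best = None  # (sum, length, start_index, end_index)
    min_p = np.inf
    min_i = -1
    for j in range(min_gap, n):
        i_new = j - min_gap
        if above[i_new] and prefix[i_new] < min_p:
            min_p = prefix[i_new]
            min_i = i_new
        if not above[j] or min_i < 0:
            continue
        s = prefix[j + 1] - min_p
        if s < 1:
            continue
        cand = (s, j - min_i, min_i, j)
        if best is None or (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]):
            best = cand
    if best is None:
        return None
    return best[2], best[3]


def detect_preictal_per_channel(ds: DistanceSeries, model: InterictalModel,
                                min_duration_min: float = DEFAULT_MIN_DURATION_MIN,
                                ) -> dict[str, PreictalInterval | None]:
    """Run interval detection independently on every channel."""
    if ds.d.size == 0:
        raise ParameterError("empty distance series")
    out: dict[str, PreictalInterval | None] = {}
    for c, label in enumerate(ds.channel_labels):
        span = _best_span(ds.d[:, c], model.l99[c], ds.hop_s, ds.window_s,
                          min_duration_min * 60.0)
        if span is None:
            out[label] = None
            continue
        i, j = span
        seg = np.nan_to_num(ds.d[i:j + 1, c], nan=0.0)
        d50 = lower_median(seg)
        interval = PreictalInterval(
            t1_s=float(ds.times[i]),
            tL_s=float(ds.times[j] + ds.window_s),
            d50=d50, channel=label)
        # both defining criteria hold by construction; assert on every output
        assert interval.tL_s - interval.t1_s >= min_duration_min * 60.0 - 1e-6
        assert d50 > model.l99[c]
        out[label] = interval
    return out


def detect_preictal(ds: DistanceSeries, model: InterictalModel,
                    min_duration_min: float = DEFAULT_MIN_DURATION_MIN,
                    ) -> PreictalInterval | None:
    """Record-level preictal interval, or None when no channel qualifies.

    Detection runs per channel; the reported interval is the one whose
    provenance channel maximizes d50 / L99 among detected channels.
    """
    per_channel = detect_preictal_per_channel(ds, model, min_duration_min)
    best: PreictalInterval | None = None
    best_ratio = -np.inf
    for label, interval in per_channel.items():
        if interval is None:
            continue
        ratio = interval.d50 / model.l99[model.channel_index(label)]
        if ratio > best_ratio:
            best, best_ratio = interval, ratio
    return best
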