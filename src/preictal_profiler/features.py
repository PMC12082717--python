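"""The ten windowed EEG features.

Each channel of a band-passed recording is summarized over 6 s windows with
a 3 s hop by ten descriptors widely used in quantitative EEG:

* **spectral entropy** -- Shannon entropy (bits) of the one-sided power
  spectrum normalized to a probability distribution, DC excluded;
* **Hjorth mobility / complexity** -- variance ratios of the signal and its
  first difference; mobility tracks mean frequency, complexity is minimal
  (1) for a pure sinusoid;
* **Higuchi fractal dimension** -- least-squares slope of log curve length
  versus log(1/k) over subsampled strides k = 1..k_max; 1 for a smooth
  ramp, 2 for white noise;
* **five relative band powers** -- fraction of one-sided spectral energy in
  the delta (0.5-4), theta (4-8), alpha (8-13), beta (13-30) and gamma
  (30-48 Hz) bands, relative to the total energy inside the analysis band
  (the 0.5-75 Hz filter passband, clipped to Nyquist).  Band edges are
  half-open ``[f1, f2)`` so shared edges are not double-counted and the
  five fractions sum to at most 1;
* **DFA exponent** -- slope of log RMS detrended fluctuation versus log
  scale of the mean-centered cumulative sum; 0.5 for white noise, 1.5 for
  a random walk.

All ten are invariant to positive amplitude rescaling of the window.  The
module exposes per-window reference operations plus a vectorized
:func:`extract_features` that computes every window of every channel at
once; the two paths agree exactly and the tests hold them to it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .errors import DegenerateWindowError, ParameterError
from .recording import Recording

FEATURE_NAMES = (
    "spectral_entropy", "hjorth_mobility", "hjorth_complexity", "higuchi_fd",
    "delta_power", "theta_power", "alpha_power", "beta_power", "gamma_power",
    "dfa",
)

BANDS_HZ = {
    "delta": (0.4, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 48.0),
}

DEFAULT_WINDOW_S = 6.0
DEFAULT_HOP_S = 3.0
DEFAULT_K_MAX = 8
DEFAULT_DFA_MIN_SCALE = 16
DEFAULT_DFA_N_SCALES = 10
DEFAULT_TOTAL_BAND_HZ = (0.5, 75.0)


# ---------------------------------------------------------------------------
# per-window operations


def _validate_window(window: np.ndarray) -> np.ndarray:
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("window must be a 1-D vector of length >= 2")
    return x


def _one_sided_power(x: np.ndarray) -> np.ndarray:
    """One-sided periodogram |rfft|^2 with the DC bin removed."""
    return np.abs(np.fft.rfft(x))[1:] ** 2


def spectral_entropy(window: np.ndarray, fs: float | None = None) -> float:
    """Shannon entropy (bits) of the normalized one-sided power spectrum."""
    x = _validate_window(window)
    s = _one_sided_power(x)
    total = s.sum()
    if not total > 0:
        raise DegenerateWindowError("constant window has no spectral power")
    p = s / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def hjorth_mobility(window: np.ndarray) -> float:
    """sqrt(var(first difference) / var(window)); ~ mean digital frequency."""
    x = _validate_window(window)
    v = x.var()
    if not v > 0:
        raise DegenerateWindowError("zero-variance window")
    return float(np.sqrt(np.diff(x).var() / v))


def hjorth_complexity(window: np.ndarray) -> float:
    """mobility(diff(window)) / mobility(window); 1 for a pure sinusoid."""
    x = _validate_window(window)
    d = np.diff(x)
    if not (x.var() > 0 and d.var() > 0):
        raise DegenerateWindowError("zero-variance window or difference")
    return float(hjorth_mobility(d) / hjorth_mobility(x))


def higuchi_fd(window: np.ndarray, k_max: int = DEFAULT_K_MAX) -> float:
    """Higuchi fractal dimension: slope of log L(k) vs log(1/k), k=1..k_max.

    For stride k and offset m (1-based), the normalized curve length is
    ``L_m(k) = (N-1) / (floor((N-m)/k) * k^2) * sum |x(m+ik) - x(m+(i-1)k)|``
    and L(k) averages L_m(k) over the k offsets.
    """
    x = _validate_window(window)
    if int(k_max) != k_max or k_max < 2:
        raise ParameterError(f"k_max must be an integer >= 2, got {k_max}")
    k_max = int(k_max)
    n = x.size
    if n <= k_max:
        raise ParameterError("window shorter than k_max")
    log_inv_k, log_l = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(1, k + 1):
            idx = np.arange(m - 1, n, k)  # x(m), x(m+k), ... (0-based)
            n_i = idx.size - 1
            if n_i < 1:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            lengths.append(dist * (n - 1) / (n_i * k * k))
        l_k = np.mean(lengths)
        if not l_k > 0:
            raise DegenerateWindowError("flat window: zero curve length")
        log_inv_k.append(np.log(1.0 / k))
        log_l.append(np.log(l_k))
    slope = np.polyfit(log_inv_k, log_l, 1)[0]
    return float(slope)


def band_power(window: np.ndarray, fs: float, f1: float, f2: float,
               total_band: tuple[float, float] = DEFAULT_TOTAL_BAND_HZ) -> float:
    """Fraction of one-sided spectral energy in ``[f1, f2)`` relative to the
    analysis band (default 0.5-75 Hz, clipped to Nyquist), DC excluded."""
    x = _validate_window(window)
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if not 0 <= f1 < f2:
        raise ParameterError(f"need 0 <= f1 < f2, got [{f1}, {f2}]")
    if f2 > fs / 2 and f1 >= fs / 2:
        raise ParameterError(f"band [{f1}, {f2}] lies beyond Nyquist {fs / 2}")
    s = _one_sided_power(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)[1:]
    lo, hi = total_band
    denom_mask = (freqs >= lo) & (freqs < hi)
    denom = s[denom_mask].sum()
    if not denom > 0:
        raise DegenerateWindowError("no spectral power in the analysis band")
    num = s[(freqs >= f1) & (freqs < f2) & denom_mask].sum()
    return float(num / denom)


def dfa_scales(n_samples: int, min_scale: int = DEFAULT_DFA_MIN_SCALE,
               n_scales: int = DEFAULT_DFA_N_SCALES) -> np.ndarray:
    """Default DFA scales: distinct integers log-spaced between ``min_scale``
    and ``n_samples // 4``."""
    max_scale = n_samples // 4
    if max_scale <= min_scale:
        raise ParameterError(
            f"window of {n_samples} samples too short for DFA scales from {min_scale}")
    scales = np.unique(np.rint(np.geomspace(min_scale, max_scale, n_scales))
                       .astype(int))
    return scales


def dfa(window: np.ndarray, scales: np.ndarray | None = None) -> float:
    """DFA scaling exponent: slope of log F(n) versus log n.

    The window is integrated (mean-centered cumulative sum), cut into
    consecutive non-overlapping segments of length n, each segment is
    linearly detrended, and F(n) is the RMS over segments of the per-segment
    RMS deviation from the local trend.
    """
    x = _validate_window(window)
    if scales is None:
        scales = dfa_scales(x.size)
    scales = np.asarray(scales, dtype=int)
    if scales.size < 4 or np.unique(scales).size < 4:
        raise ParameterError("DFA needs at least 4 distinct scales")
    if scales.min() < 4 or scales.max() > x.size // 4:
        raise ParameterError("DFA scales must lie in [4, window length / 4]")
    z = np.cumsum(x - x.mean())
    log_n, log_f = [], []
    for n in np.unique(scales):
        m = z.size // n
        seg = z[: m * n].reshape(m, n)
        t = np.arange(n, dtype=np.float64)
        tc = t - t.mean()
        denom = (tc * tc).sum()
        y = seg - seg.mean(axis=1, keepdims=True)
        b = (y * tc).sum(axis=1) / denom
        rss = np.maximum((y * y).sum(axis=1) - b * b * denom, 0.0)
        f_n = np.sqrt(rss.mean() / n)
        if not f_n > 0:
            raise DegenerateWindowError("flat window: zero fluctuation")
        log_n.append(np.log(n))
        log_f.append(np.log(f_n))
    return float(np.polyfit(log_n, log_f, 1)[0])


# ---------------------------------------------------------------------------
# windowed extraction


@dataclass
class WindowedFeatures:
    """windows x channels x 10 feature tensor with window timestamps.

    ``values[w, c, :]`` holds the ten features (order :data:`FEATURE_NAMES`)
    of channel ``c`` over the window starting at ``window_start_s[w]``.
    Degenerate (flat) windows are masked: ``mask[w, c]`` is False and the
    corresponding values are NaN.
    """

    values: np.ndarray
    window_start_s: np.ndarray
    channel_labels: list[str]
    fs: float
    window_s: float = DEFAULT_WINDOW_S
    hop_s: float = DEFAULT_HOP_S
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.all(np.isfinite(self.values), axis=2)
        starts = np.asarray(self.window_start_s)
        if starts.size > 1 and not np.allclose(np.diff(starts), self.hop_s):
            raise ParameterError("window starts must increase by the hop")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def window_slice(self, t_start_s: float, t_end_s: float) -> np.ndarray:
        """Boolean selector of windows fully inside ``[t_start_s, t_end_s]``."""
        starts = self.window_start_s
        return (starts >= t_start_s - 1e-9) & (starts + self.window_s <= t_end_s + 1e-9)

    def to_dataframe(self) -> pd.DataFrame:
        """Flat windows x (channels*10) frame with ``channel:feature`` columns."""
        cols = {}
        for c, label in enumerate(self.channel_labels):
            for f, name in enumerate(self.feature_names):
                cols[f"{label}:{name}"] = self.values[:, c, f]
        df = pd.DataFrame(cols)
        df.insert(0, "window_start_s", self.window_start_s)
        return df


def _window_starts(n_samples: int, fs: float, window_s: float, hop_s: float
                   ) -> tuple[np.ndarray, int, int]:
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if win < 2 or hop < 1:
        raise ParameterError("window and hop must span at least 2 and 1 samples")
    if n_samples < win:
        raise ParameterError("recording shorter than one window")
    n_win = (n_samples - win) // hop + 1
    starts = np.arange(n_win) * hop
    return starts, win, hop


def _batch_spectral(frames: np.ndarray, fs: float,
                    total_band: tuple[float, float]) -> tuple[np.ndarray, ...]:
    """Entropy and the five band fractions for a frames x samples matrix."""
    s = np.abs(np.fft.rfft(frames, axis=1))[:, 1:] ** 2
    freqs = np.fft.rfftfreq(frames.shape[1], 1.0 / fs)[1:]
    total = s.sum(axis=1)
    ok = total > 0
    p = np.divide(s, total[:, None], out=np.zeros_like(s), where=ok[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = np.where(ok, -plogp.sum(axis=1), np.nan)

    lo, hi = total_band
    denom_mask = (freqs >= lo) & (freqs < hi)
    denom = s[:, denom_mask].sum(axis=1)
    bands = []
    for f1, f2 in BANDS_HZ.values():
        m = denom_mask & (freqs >= f1) & (freqs < f2)
        frac = np.divide(s[:, m].sum(axis=1), denom,
                         out=np.full(frames.shape[0], np.nan), where=denom > 0)
        bands.append(frac)
    return entropy, bands


def _batch_hjorth(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v0 = frames.var(axis=1)
    d1 = np.diff(frames, axis=1)
    v1 = d1.var(axis=1)
    v2 = np.diff(d1, axis=1).var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.sqrt(v1 / v0)
        comp = np.sqrt(v2 / v1) / mob
    mob[~(v0 > 0)] = np.nan
    comp[~((v0 > 0) & (v1 > 0))] = np.nan
    return mob, comp


def _shared_slope(log_y: np.ndarray, log_x: np.ndarray) -> np.ndarray:
    """Per-frame least-squares slope with a design shared by all frames."""
    xc = log_x - log_x.mean()
    bad = ~np.all(np.isfinite(log_y), axis=1)
    log_y = np.where(bad[:, None], 0.0, log_y)
    slope = (log_y @ xc) / (xc * xc).sum()
    slope[bad] = np.nan
    return slope


def _higuchi_lengths_numpy(frames: np.ndarray, k_max: int) -> np.ndarray:
    n_frames, n = frames.shape
    lk = np.empty((n_frames, k_max))
    for k in range(1, k_max + 1):
        # |x[j+k] - x[j]| summed over the residue class j = m-1 (mod k)
        # equals the curve-length sum for offset m, so one lag-k difference
        # serves all k offsets
        d = np.abs(frames[:, k:] - frames[:, :-k])
        n_pad = (-d.shape[1]) % k
        if n_pad:
            d = np.pad(d, [(0, 0), (0, n_pad)])
        per_residue = d.reshape(n_frames, -1, k).sum(axis=1)  # (frames, k)
        n_i = (n - np.arange(1, k + 1)) // k
        valid = n_i >= 1
        lm = per_residue[:, valid] * (n - 1) / (n_i[valid] * k * k)
        lk[:, k - 1] = lm.mean(axis=1)
    return lk


def _batch_higuchi(frames: np.ndarray, k_max: int) -> np.ndarray:
    if int(k_max) != k_max or k_max < 2:
        raise ParameterError(f"k_max must be an integer >= 2, got {k_max}")
    k_max = int(k_max)
    if frames.shape[1] <= k_max:
        raise ParameterError("window shorter than k_max")
    if _kernels.HAVE_NUMBA:
        lk = _kernels.higuchi_lengths(frames, k_max)
    else:
        lk = _higuchi_lengths_numpy(frames, k_max)
    with np.errstate(divide="ignore"):
        log_l = np.log(lk)
    return _shared_slope(log_l, np.log(1.0 / np.arange(1, k_max + 1)))


def _dfa_fluctuations_numpy(frames: np.ndarray, scales: np.ndarray
                            ) -> np.ndarray:
    z = np.cumsum(frames - frames.mean(axis=1, keepdims=True), axis=1)
    f_n = np.empty((frames.shape[0], scales.size))
    for j, n in enumerate(scales):
        m = z.shape[1] // n
        seg = z[:, : m * n].reshape(z.shape[0], m, n)
        t = np.arange(n, dtype=np.float64)
        tc = t - t.mean()
        denom = (tc * tc).sum()
        y = seg - seg.mean(axis=2, keepdims=True)
        b = (y @ tc) / denom
        rss = np.maximum(np.einsum("fmn,fmn->fm", y, y) - b * b * denom, 0.0)
        f_n[:, j] = np.sqrt(rss.mean(axis=1) / n)
    return f_n


def _batch_dfa(frames: np.ndarray, scales: np.ndarray) -> np.ndarray:
    scales = np.unique(np.asarray(scales, dtype=np.int64))
    if _kernels.HAVE_NUMBA:
        f_n = _kernels.dfa_fluctuations(frames, scales)
    else:
        f_n = _dfa_fluctuations_numpy(frames, scales)
    with np.errstate(divide="ignore"):
        log_f = np.log(f_n)
    return _shared_slope(log_f, np.log(scales))


def extract_features(rec: Recording, window_s: float = DEFAULT_WINDOW_S,
                     hop_s: float = DEFAULT_HOP_S, k_max: int = DEFAULT_K_MAX,
                     dfa_min_scale: int = DEFAULT_DFA_MIN_SCALE,
                     dfa_n_scales: int = DEFAULT_DFA_N_SCALES,
                     total_band: tuple[float, float] = DEFAULT_TOTAL_BAND_HZ,
                     ) -> WindowedFeatures:
    """Compute all ten features for every window of every channel.

    The window count is ``floor((duration - window) / hop) + 1``.  Flat
    (zero-variance) windows yield a masked row instead of an error.  Every
    value equals the corresponding per-window operation applied to the same
    samples; the batch path exists purely for speed.
    """
    starts, win, hop = _window_starts(rec.n_samples, rec.fs, window_s, hop_s)
    fs = rec.fs
    total_band = (total_band[0], min(total_band[1], fs / 2 + 1e-9))
    scales = dfa_scales(win, dfa_min_scale, dfa_n_scales)
    n_win = starts.size
    values = np.empty((n_win, rec.n_channels, len(FEATURE_NAMES)))
    for c in range(rec.n_channels):
        x = rec.signal[c]
        frames = np.ascontiguousarray(
            np.lib.stride_tricks.sliding_window_view(x, win)[::hop])
        entropy, bands = _batch_spectral(frames, fs, total_band)
        mob, comp = _batch_hjorth(frames)
        hfd = _batch_higuchi(frames, k_max)
        dfa_exp = _batch_dfa(frames, scales)
        values[:, c, 0] = entropy
        values[:, c, 1] = mob
        values[:, c, 2] = comp
        values[:, c, 3] = hfd
        for b, frac in enumerate(bands):
            values[:, c, 4 + b] = frac
        values[:, c, 9] = dfa_exp
    # a window degenerate for any feature is masked for the whole row
    bad = ~np.all(np.isfinite(values), axis=2)
    values[bad] = np.nan
    return WindowedFeatures(values=values, window_start_s=starts / fs,
                            channel_labels=list(rec.channel_labels), fs=fs,
                            window_s=win / fs, hop_s=hop / fs)
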