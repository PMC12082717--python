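"""Channel selection and feature importance.

Once a preictal interval is fixed, each channel is scored by how well a
logistic regression on its ten features separates preictal windows
(positive class) from interictal windows: the model is fit on a seeded 80%
split and evaluated by the F1 score (harmonic mean of precision and recall)
on the held-out 20%.  Channels whose F1 strictly exceeds the 75th
percentile of the F1 distribution are selected as carrying preictal
activity.  Feature importance comes from the channel with the maximal F1:
the absolute logistic weight of each standardized feature orders the ten
features, and the top three are reported.

Features are z-scored with interictal-interval statistics before any fit so
the weight magnitudes are comparable across features.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import train_test_split

from .detection import PreictalInterval
from .errors import FitError, LabelingError, ParameterError
from .features import WindowedFeatures

DEFAULT_TEST_FRACTION = 0.2
DEFAULT_QUANTILE = 0.75
DEFAULT_C = 1.0
DEFAULT_MAX_ITER = 1000


@dataclass(frozen=True)
class ChannelScore:
    """Held-out separability of one channel (preictal = positive class)."""

    channel: str
    f1: float
    precision: float
    recall: float


@dataclass(frozen=True)
class FeatureRanking:
    """All ten features of one channel ordered by |logistic weight|."""

    channel: str
    entries: tuple[tuple[str, float], ...]  # (feature name, |coefficient|)

    @property
    def top3(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries[:3])


def build_dataset(feat: WindowedFeatures, channel: str,
                  preictal: PreictalInterval,
                  interictal_span: tuple[float, float]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Standardized features and 0/1 labels for one channel.

    Positive rows are unmasked windows inside the record-level preictal
    interval, negative rows those inside the interictal span; z-scoring
    uses interictal mean/SD (zero SDs left unscaled).
    """
    c = feat.channel_labels.index(channel)
    pos = feat.window_slice(preictal.t1_s, preictal.tL_s) & feat.mask[:, c]
    neg = feat.window_slice(*interictal_span) & feat.mask[:, c]
    if not (pos.any() and neg.any()):
        raise LabelingError(
            f"channel {channel}: one of the classes has no usable windows")
    x_neg = feat.values[neg, c, :]
    x_pos = feat.values[pos, c, :]
    mean = x_neg.mean(axis=0)
    sd = x_neg.std(axis=0)
    sd[sd == 0] = 1.0
    x = np.vstack([(x_neg - mean) / sd, (x_pos - mean) / sd])
    y = np.concatenate([np.zeros(len(x_neg), int), np.ones(len(x_pos), int)])
    return x, y


def _fit_split(x: np.ndarray, y: np.ndarray, seed: int, test_fraction: float,
               C: float, max_iter: int):
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, random_state=seed, stratify=y)
    model = LogisticRegression(C=C, max_iter=max_iter, random_state=seed)
    model.fit(x_tr, y_tr)
    if not np.all(np.isfinite(model.coef_)):
        raise FitError("logistic fit produced non-finite coefficients")
    return model, x_te, y_te


def score_channel(feat: WindowedFeatures, channel: str,
                  preictal: PreictalInterval,
                  interictal_span: tuple[float, float], seed: int = 0,
                  test_fraction: float = DEFAULT_TEST_FRACTION,
                  C: float = DEFAULT_C,
                  max_iter: int = DEFAULT_MAX_ITER) -> ChannelScore:
    """F1/precision/recall of one channel on the held-out 20% split."""
    x, y = build_dataset(feat, channel, preictal, interictal_span)
    if len(np.unique(y)) < 2:
        raise LabelingError(f"channel {channel}: single-class data")
    model, x_te, y_te = _fit_split(x, y, seed, test_fraction, C, max_iter)
    y_hat = model.predict(x_te)
    return ChannelScore(
        channel=channel,
        f1=float(f1_score(y_te, y_hat, zero_division=0)),
        precision=float(precision_score(y_te, y_hat, zero_division=0)),
        recall=float(recall_score(y_te, y_hat, zero_division=0)),
    )


def select_channels(scores: list[ChannelScore],
                    quantile: float = DEFAULT_QUANTILE) -> list[str]:
    """Channels whose F1 strictly exceeds the ``quantile`` (default 75th
    percentile, linear interpolation) of the F1 distribution, sorted by
    descending F1.  Ties at the threshold are excluded; with fewer than 4
    scored channels the percentile is meaningless and an error is raised."""
    if len(scores) < 4:
        raise ParameterError(f"need >= 4 scored channels, got {len(scores)}")
    f1s = np.array([s.f1 for s in scores])
    threshold = float(np.quantile(f1s, quantile))
    chosen = [s for s in scores if s.f1 > threshold]
    chosen.sort(key=lambda s: -s.f1)
    return [s.channel for s in chosen]


def rank_features(feat: WindowedFeatures, best_channel: str,
                  preictal: PreictalInterval,
                  interictal_span: tuple[float, float], seed: int = 0,
                  test_fraction: float = DEFAULT_TEST_FRACTION,
                  C: float = DEFAULT_C,
                  max_iter: int = DEFAULT_MAX_ITER) -> FeatureRanking:
    """Rank the ten features of the best channel by |logistic weight|.

    Refits the same seeded 80% split used by :func:`score_channel`, so the
    coefficients are those of the channel-scoring model itself.
    """
    x, y = build_dataset(feat, best_channel, preictal, interictal_span)
    model, _, _ = _fit_split(x, y, seed, test_fraction, C, max_iter)
    coefs = np.abs(model.coef_[0])
    order = np.argsort(-coefs, kind="stable")
    entries = tuple((feat.feature_names[i], float(coefs[i])) for i in order)
    return FeatureRanking(channel=best_channel, entries=entries)
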