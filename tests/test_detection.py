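"""Interictal model fitting, Mahalanobis distances, and interval detection."""
from __future__ import annotations

import numpy as np
import pytest

import oracles
from preictal_profiler import detection as D
from preictal_profiler.errors import CoverageError, DataError, ParameterError
from preictal_profiler.features import WindowedFeatures

HOP = 3.0
WIN = 6.0


def make_features(values, t0=0.0):
    """values: (n_windows, n_channels, 10) -> WindowedFeatures at 3 s hop."""
    values = np.asarray(values, float)
    starts = t0 + HOP * np.arange(values.shape[0])
    labels = [f"C{i}" for i in range(values.shape[1])]
    return WindowedFeatures(values=values, window_start_s=starts,
                            channel_labels=labels, fs=128.0,
                            window_s=WIN, hop_s=HOP)


def gaussian_features(rng, n_windows, n_channels=1, mu=None, cov=None):
    mu = np.zeros(10) if mu is None else mu
    cov = np.eye(10) if cov is None else cov
    vals = rng.multivariate_normal(mu, cov, size=(n_windows, n_channels))
    return make_features(vals)


def make_series(d, hop_s=HOP, window_s=WIN, labels=("C0",)):
    d = np.asarray(d, float)
    if d.ndim == 1:
        d = d[:, None]
    times = hop_s * np.arange(d.shape[0])
    return D.DistanceSeries(times, d, list(labels), window_s, hop_s)


def make_model(l99, labels=("C0",)):
    n = len(labels)
    return D.InterictalModel(list(labels), np.zeros((n, 10)),
                             np.tile(np.eye(10), (n, 1, 1)),
                             np.tile(np.eye(10), (n, 1, 1)),
                             np.full(n, float(l99)), np.full(n, 2400),
                             (0.0, 7200.0))


# ---------------------------------------------------------------------------
# model fitting


def _onset_after(n_windows: int) -> float:
    """Onset such that the 2 h interictal span covers all n windows."""
    return (n_windows - 1) * HOP + WIN + 6 * 3600.0


def _fit(feat, onset_s, **kwargs):
    return D.fit_interictal_model(feat, onset_s, **kwargs)


def test_identical_training_vectors_regularized_to_valid_model(rng):
    vals = np.tile(rng.standard_normal(10), (2500, 1, 1))
    model = _fit(make_features(vals), onset_s=_onset_after(2500))
    assert np.all(np.isfinite(model.cov_inv))
    # all training points coincide, so their distances and L99 are ~0
    # negligible against the O(5) thresholds of non-degenerate data
    assert model.l99[0] == pytest.approx(0.0, abs=1e-2)
    ident = model.cov[0] @ model.cov_inv[0]
    np.testing.assert_allclose(ident, np.eye(10), atol=1e-6)


def test_gaussian_mean_recovered_within_3_se(rng):
    mu = rng.normal(size=10)
    a = rng.standard_normal((10, 10))
    cov = a @ a.T / 10 + 0.5 * np.eye(10)
    n = 2400
    feat = gaussian_features(rng, n, mu=mu, cov=cov)
    model = _fit(feat, onset_s=_onset_after(n))
    se = np.sqrt(np.diag(cov) / n)
    assert np.all(np.abs(model.mu[0] - mu) < 3.5 * se)
    # a 2 h span holds one window fewer than n at a 3 s hop (6 s windows)
    assert model.n_train[0] == n - 1


def test_interictal_interval_beyond_record_is_coverage_error(rng):
    feat = gaussian_features(rng, 200)  # starts at t=0, far too short
    with pytest.raises(CoverageError):
        D.fit_interictal_model(feat, onset_s=200 * HOP + 6 * 3600.0,
                               interictal_duration_h=2.0)


def test_too_few_training_windows_is_data_error(rng):
    # cover the span with a 60 s hop grid -> only ~120 windows in 2 h
    vals = rng.standard_normal((500, 1, 10))
    feat = WindowedFeatures(values=vals, window_start_s=60.0 * np.arange(500),
                            channel_labels=["C0"], fs=128.0,
                            window_s=WIN, hop_s=60.0)
    with pytest.raises(DataError):
        D.fit_interictal_model(feat, onset_s=499 * 60.0 + WIN + 6 * 3600.0,
                               min_train=2000)


def test_l99_is_99th_percentile_of_training_distances(rng):
    n = 2400
    feat = gaussian_features(rng, n)
    model = _fit(feat, onset_s=_onset_after(n))
    in_span = feat.window_slice(*model.span_s)
    diff = feat.values[in_span, 0, :] - model.mu[0]
    d = np.sqrt(np.einsum("ij,jk,ik->i", diff, model.cov_inv[0], diff))
    assert model.l99[0] == pytest.approx(np.percentile(d, 99), rel=1e-9)


# ---------------------------------------------------------------------------
# Mahalanobis distances


def test_distance_zero_at_the_mean_and_euclidean_under_identity(rng):
    n = 2400
    feat = gaussian_features(rng, n)
    model = _fit(feat, onset_s=_onset_after(n))
    model.mu[0] = feat.values[5, 0, :]
    model.cov_inv[0] = np.eye(10)
    ds = D.mahalanobis_series(feat, model, 0.0, n * HOP + WIN)
    assert ds.d[5, 0] == pytest.approx(0.0, abs=1e-12)
    expected = np.linalg.norm(feat.values[7, 0, :] - model.mu[0])
    assert ds.d[7, 0] == pytest.approx(expected, rel=1e-12)


def test_distance_matches_direct_solve_oracle(rng):
    n = 1200
    mu = rng.normal(size=10)
    a = rng.standard_normal((10, 10))
    cov = a @ a.T + 0.1 * np.eye(10)
    feat = gaussian_features(rng, n, mu=mu, cov=cov)
    model = make_model(1.0)
    model.mu[0] = mu
    model.cov[0] = cov
    model.cov_inv[0] = np.linalg.inv(cov)
    ds = D.mahalanobis_series(feat, model, 0.0, n * HOP + WIN)
    for w in [0, 17, 311, n - 1]:
        p = feat.values[w, 0, :]
        oracle = np.sqrt((p - mu) @ np.linalg.solve(cov, p - mu))
        assert ds.d[w, 0] == pytest.approx(oracle, rel=1e-10)


def test_masked_windows_propagate_as_nan(rng):
    n = 1200
    feat = gaussian_features(rng, n)
    feat.values[10, 0, :] = np.nan
    feat.mask[10, 0] = False
    model = make_model(1.0)
    ds = D.mahalanobis_series(feat, model, 0.0, n * HOP + WIN)
    assert np.isnan(ds.d[10, 0]) and np.isfinite(ds.d[11, 0])


# ---------------------------------------------------------------------------
# interval detection


def block_series(n=2400, block=(1000, 1400), lo=1.0, hi=10.0):
    d = np.full(n, lo)
    d[block[0]: block[1]] = hi
    return make_series(d)


def test_all_subthreshold_yields_none():
    assert D.detect_preictal(make_series(np.ones(2400)), make_model(5.0)) is None


def test_clean_20min_block_detected_exactly():
    ds = block_series()  # 400 windows * 3 s hop = 20 min above threshold
    model = make_model(5.0)
    interval = D.detect_preictal(ds, model)
    assert interval is not None
    assert abs(interval.t1_s - 1000 * HOP) <= HOP
    assert abs(interval.tL_s - (1399 * HOP + WIN)) <= HOP
    assert interval.d50 == pytest.approx(10.0)


def test_10min_block_below_minimum_duration_yields_none():
    ds = block_series(block=(1000, 1200))  # 10 min
    assert D.detect_preictal(ds, make_model(5.0)) is None
    # the same block clears a 10 min threshold
    assert D.detect_preictal(ds, make_model(5.0), min_duration_min=9.0) is not None


def test_empty_series_is_parameter_error():
    ds = make_series(np.ones(0))
    with pytest.raises(ParameterError):
        D.detect_preictal(ds, make_model(5.0))


def test_detected_interval_never_shorter_than_minimum(rng):
    for _ in range(20):
        d = np.where(rng.random(2400) < 0.05, 10.0, 1.0)
        interval = D.detect_preictal(make_series(d), make_model(5.0))
        if interval is not None:
            assert interval.tL_s - interval.t1_s >= 15 * 60.0


def test_monotone_transform_of_distances_leaves_interval_unchanged(rng):
    d = np.where(rng.random(2400) < 0.2, 1.0, 0.0) * rng.uniform(5, 20, 2400) \
        + rng.uniform(0, 3, 2400)
    d[800:1300] += 10.0
    base = D.detect_preictal(make_series(d), make_model(4.0))
    squashed = D.detect_preictal(make_series(np.log1p(d)), make_model(np.log1p(4.0)))
    assert base is not None and squashed is not None
    assert squashed.t1_s == base.t1_s and squashed.tL_s == base.tL_s


def test_lower_median_criterion_equals_strict_majority(rng):
    threshold = 5.0
    for _ in range(200):
        n = rng.integers(2, 40)
        seg = rng.uniform(0, 10, n)
        majority = (seg > threshold).sum() > n / 2
        assert (D.lower_median(seg) > threshold) == majority


def test_record_level_interval_comes_from_strongest_channel():
    d = np.ones((2400, 2))
    d[1000:1400, 0] = 8.0   # d50/L99 = 1.6
    d[1000:1400, 1] = 30.0  # d50/L99 = 6
    ds = make_series(d, labels=("C0", "C1"))
    interval = D.detect_preictal(ds, make_model(5.0, labels=("C0", "C1")))
    assert interval.channel == "C1"
    per_channel = D.detect_preictal_per_channel(
        ds, make_model(5.0, labels=("C0", "C1")))
    assert per_channel["C0"] is not None and per_channel["C1"] is not None


def test_detection_matches_exhaustive_oracle_on_noisy_block(rng):
    """A 30 min span with ~60% supra-threshold windows embedded in noise is
    resolved identically by the fast scan and the brute-force search."""
    for seed in range(5):
        r = np.random.default_rng(seed)
        d = r.uniform(0, 4.9, 160)
        span = slice(40, 101)  # 61 windows at a 30 s hop
        hot = r.random(61) < 0.6
        d[span][hot] = r.uniform(5.5, 12, hot.sum())
        ds = make_series(d, hop_s=30.0, window_s=60.0)
        model = make_model(5.0)
        interval = D.detect_preictal(ds, model)
        expected = oracles.exhaustive_interval_search(
            d, 5.0, 30.0, 60.0, 15 * 60.0)
        if expected is None:
            assert interval is None
        else:
            i, j = expected
            assert interval is not None
            assert interval.t1_s == pytest.approx(30.0 * i)
            assert interval.tL_s == pytest.approx(30.0 * j + 60.0)
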