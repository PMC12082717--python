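"""Windowed feature operations: closed forms, oracles, and invariances."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st


from preictal_profiler import features as F
from preictal_profiler.errors import DegenerateWindowError, ParameterError
from preictal_profiler.recording import Recording

FS = 256.0
WIN = int(6 * FS)
TOTAL_BAND = (0.5, 75.0)


def sine(freq, n=WIN, fs=FS, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


# ---------------------------------------------------------------------------
# closed-form limits


def test_entropy_single_tone_is_zero_bits():
    assert F.spectral_entropy(sine(10.0)) < 1e-6


def test_entropy_two_equal_tones_is_one_bit():
    window = sine(10.0) + sine(20.0)
    assert F.spectral_entropy(window) == pytest.approx(1.0, abs=1e-6)


def test_entropy_white_noise_near_log2_bins(rng):
    n_bins = WIN // 2
    values = [F.spectral_entropy(rng.standard_normal(WIN)) for _ in range(100)]
    assert abs(np.mean(values) - np.log2(n_bins)) < 1.0


@pytest.mark.parametrize("freq", [4.0, 10.0, 32.0])
def test_mobility_sinusoid_closed_form(freq):
    omega = 2 * np.pi * freq / FS
    assert F.hjorth_mobility(sine(freq)) == pytest.approx(
        2 * np.sin(omega / 2), abs=1e-3)


def test_mobility_white_noise_sqrt2(rng):
    values = [F.hjorth_mobility(rng.standard_normal(WIN)) for _ in range(50)]
    assert np.mean(values) == pytest.approx(np.sqrt(2), abs=0.02)


def test_complexity_pure_sine_is_minimal():
    assert F.hjorth_complexity(sine(10.0)) == pytest.approx(1.0, abs=1e-2)


def test_higuchi_linear_ramp_dimension_one():
    assert F.higuchi_fd(np.arange(WIN, dtype=float)) == pytest.approx(1.0, abs=0.05)


def test_higuchi_white_noise_dimension_two(rng):
    values = [F.higuchi_fd(rng.standard_normal(WIN)) for _ in range(30)]
    assert np.mean(values) == pytest.approx(2.0, abs=0.1)


def test_dfa_white_noise_half(rng):
    values = [F.dfa(rng.standard_normal(WIN)) for _ in range(30)]
    assert np.mean(values) == pytest.approx(0.5, abs=0.1)


def test_dfa_random_walk_three_halves(rng):
    values = [F.dfa(np.cumsum(rng.standard_normal(WIN))) for _ in range(30)]
    assert np.mean(values) == pytest.approx(1.5, abs=0.15)


def test_band_power_tone_lands_in_alpha():
    window = sine(10.0)
    fractions = {name: F.band_power(window, FS, f1, f2, TOTAL_BAND)
                 for name, (f1, f2) in F.BANDS_HZ.items()}
    assert fractions["alpha"] == pytest.approx(1.0, abs=1e-6)
    for name in ("delta", "theta", "beta", "gamma"):
        assert fractions[name] < 1e-6


def test_band_power_white_noise_proportional_to_bandwidth(rng):
    lo, hi = TOTAL_BAND
    means = {name: np.mean([
        F.band_power(rng.standard_normal(WIN), FS, f1, f2, TOTAL_BAND)
        for _ in range(100)]) for name, (f1, f2) in F.BANDS_HZ.items()}
    for name, (f1, f2) in F.BANDS_HZ.items():
        expected = (min(f2, hi) - max(f1, lo)) / (hi - lo)
        assert means[name] == pytest.approx(expected, abs=0.01)


# ---------------------------------------------------------------------------
# error handling


def test_degenerate_windows_raise():
    flat = np.zeros(WIN)
    for op in (F.spectral_entropy, F.hjorth_mobility, F.hjorth_complexity,
               F.dfa):
        with pytest.raises(DegenerateWindowError):
            op(flat)


@pytest.mark.parametrize("k_max", [1, 0, 1.5])
def test_higuchi_k_max_validation(k_max):
    with pytest.raises(ParameterError):
        F.higuchi_fd(np.arange(100, dtype=float), k_max=k_max)


def test_dfa_scale_validation(rng):
    x = rng.standard_normal(WIN)
    with pytest.raises(ParameterError):
        F.dfa(x, scales=[64])  # a single scale cannot define a slope
    with pytest.raises(ParameterError):
        F.dfa(x, scales=[16, 32, 64, WIN])  # max scale beyond length/4


def test_band_power_validation(rng):
    x = rng.standard_normal(WIN)
    with pytest.raises(ParameterError):
        F.band_power(x, FS, 13.0, 8.0, TOTAL_BAND)


# ---------------------------------------------------------------------------
# properties


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=1e-4, max_value=1e4),
       seed=st.integers(min_value=0, max_value=2**16))
def test_amplitude_scale_invariance(scale, seed):
    """All ten features are invariant to positive amplitude rescaling."""
    x = np.random.default_rng(seed).standard_normal(512)
    for op in (F.spectral_entropy, F.hjorth_mobility, F.hjorth_complexity,
               lambda w: F.higuchi_fd(w, 6),
               lambda w: F.band_power(w, FS, 8.0, 13.0, TOTAL_BAND),
               lambda w: F.dfa(w, [8, 16, 32, 64, 128])):
        assert op(scale * x) == pytest.approx(op(x), rel=1e-8)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(f1=st.floats(min_value=1.0, max_value=30.0),
       widen=st.floats(min_value=0.5, max_value=20.0),
       seed=st.integers(min_value=0, max_value=2**16))
def test_band_fraction_monotone_in_bandwidth(f1, widen, seed):
    x = np.random.default_rng(seed).standard_normal(512)
    narrow = F.band_power(x, FS, f1, f1 + 2.0, TOTAL_BAND)
    wide = F.band_power(x, FS, max(f1 - widen, 0.0), f1 + 2.0 + widen, TOTAL_BAND)
    assert wide >= narrow - 1e-12


def test_band_fractions_sum_below_one(rng):
    x = rng.standard_normal(WIN)
    total = sum(F.band_power(x, FS, f1, f2, TOTAL_BAND)
                for f1, f2 in F.BANDS_HZ.values())
    assert 0.0 < total <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# windowed extraction


def _toy_recording(rng, n_channels=2, duration_s=60.0, fs=FS):
    signal = rng.standard_normal((n_channels, int(duration_s * fs)))
    labels = ["Fp1", "Fp2", "F7"][:n_channels]
    return Recording(labels, fs, signal, np.full(n_channels, 1e6))


def test_window_count_and_feature_order(rng):
    feat = F.extract_features(_toy_recording(rng), total_band=TOTAL_BAND)
    assert feat.n_windows == (60 - 6) // 3 + 1 == 19
    assert feat.feature_names == F.FEATURE_NAMES
    assert feat.values.shape == (19, 2, 10)
    assert np.allclose(np.diff(feat.window_start_s), 3.0)


def test_every_windowed_value_matches_per_window_operation(rng):
    """Slicing oracle: batch extraction equals the single-window operations
    applied to the raw samples of each window (no off-by-one in hops)."""
    rec = _toy_recording(rng, n_channels=2, duration_s=45.0)
    feat = F.extract_features(rec, total_band=TOTAL_BAND)
    win = int(feat.window_s * rec.fs)
    hop = int(feat.hop_s * rec.fs)
    scales = F.dfa_scales(win)
    for w in range(feat.n_windows):
        for c in range(rec.n_channels):
            x = rec.signal[c, w * hop: w * hop + win]
            expected = np.array(
                [F.spectral_entropy(x), F.hjorth_mobility(x),
                 F.hjorth_complexity(x), F.higuchi_fd(x, 8)]
                + [F.band_power(x, rec.fs, f1, f2, TOTAL_BAND)
                   for f1, f2 in F.BANDS_HZ.values()]
                + [F.dfa(x, scales)])
            np.testing.assert_allclose(feat.values[w, c], expected, rtol=1e-8)


def test_degenerate_window_masked_not_fatal(rng):
    rec = _toy_recording(rng, n_channels=1, duration_s=60.0)
    rec.signal[0, 20 * int(FS): 30 * int(FS)] = 0.0  # 10 s of dead signal
    feat = F.extract_features(rec, total_band=TOTAL_BAND)
    dead = ~feat.mask[:, 0]
    assert dead.any() and not dead.all()
    assert np.isnan(feat.values[dead, 0, :]).all()
    assert np.isfinite(feat.values[feat.mask[:, 0], 0, :]).all()


def test_dataframe_export_columns(rng):
    feat = F.extract_features(_toy_recording(rng), total_band=TOTAL_BAND)
    df = feat.to_dataframe()
    assert "Fp1:spectral_entropy" in df.columns
    assert df.shape == (19, 1 + 2 * 10)
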