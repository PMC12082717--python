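"""Shared fixtures and scaled-down study configurations.

Full-length runs in the suite use 8.2 h single- to four-channel recordings
sampled at 128 Hz with a 0.5-60 Hz analysis band; every method parameter
(6 s / 3 s windows, 2 h interictal ending 6 h before onset, 99th
percentile, 15 min minimum interval) is at its standard value.
"""
from __future__ import annotations

import numpy as np
import pytest

import preictal_profiler as pp
from preictal_profiler.synthetic import AnomalySpec, SyntheticSpec

SCALED_FS = 128.0
SCALED_HIGH_HZ = 60.0  # below the 64 Hz Nyquist of the scaled rate
SCALED_BAND = (0.5, SCALED_HIGH_HZ)
ONSET_S = 8.05 * 3600.0


def scaled_spec(seed: int, n_channels: int = 1, channels=("Fp1",),
                mechanism: str = "spectral_tilt", duration_min: float = 40.0,
                start_min: float = 60.0, effect_size: float = 4.0,
                anomaly: bool = True) -> SyntheticSpec:
    anom = AnomalySpec(start_min_before_onset=start_min,
                       duration_min=duration_min, channels=tuple(channels),
                       mechanism=mechanism,
                       effect_size=effect_size) if anomaly else None
    return SyntheticSpec(n_channels=n_channels, fs=SCALED_FS, duration_h=8.2,
                         seizure_onset_h=8.05, anomaly=anom, seed=seed)


def scaled_config() -> dict:
    return pp.load_config(overrides={"filter": {"high_hz": SCALED_HIGH_HZ}})


def detect_run(spec: SyntheticSpec) -> dict:
    """Generate -> filter -> features -> model -> distances -> interval."""
    rec, truth = pp.generate_recording(spec)
    filt = pp.bandpass(rec, high_hz=SCALED_HIGH_HZ)
    feat = pp.extract_features(filt, total_band=SCALED_BAND)
    onset = spec.seizure_onset_h * 3600.0
    model = pp.fit_interictal_model(feat, onset)
    ds = pp.mahalanobis_series(feat, model, onset - 6 * 3600.0, onset)
    interval = pp.detect_preictal(ds, model)
    return {"rec": rec, "truth": truth, "feat": feat, "model": model,
            "ds": ds, "interval": interval, "onset_s": onset}


@pytest.fixture(scope="session")
def tilt_run() -> dict:
    """One anomalous scaled run shared by read-only assertions."""
    return detect_run(scaled_spec(seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    # fresh, fixed-seed generator per test: outcomes don't depend on order
    return np.random.default_rng(1234)
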