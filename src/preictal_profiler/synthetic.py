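"""Synthetic multi-channel EEG with a known injected preictal interval.

The baseline is stationary Gaussian colored noise per channel: a 1/f^beta
amplitude spectrum restricted to the 0.5-75 Hz analysis band, with
per-band gain factors and an optional alpha-range spectral peak, scaled to
a realistic scalp-EEG RMS (~30 uV, within +/-100 uV).  Channels are
independent realizations of the same spectrum, so the ten windowed
features are strictly stationary outside the anomaly.

The anomaly is a contiguous interval before seizure onset during which the
*generator parameters* of a listed subset of channels switch; the feature
shift is therefore emergent, not injected in feature space:

* ``spectral_tilt`` tilts the internal spectrum of every band above delta
  upward and sharpens it into a band-limited rhythm near the band's upper
  edge while preserving every band's total power — a rhythmization that moves
  spectral entropy (down) and Hjorth mobility (up) far more than the band
  fractions, so those two surface as the most important features;
* ``band_shift`` moves spectral power from the alpha band into the theta
  band;
* ``entropy_drop`` concentrates power in a narrow alpha-range peak,
  lowering spectral entropy.

``effect_size`` scales the parameter change in units calibrated so that a
value of about 4 drives the large majority of in-anomaly windows past the
interictal L99 threshold; 0 reproduces the baseline parameters exactly.
Everything is deterministic given the spec's seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import _edf
from .eeg_io import write_annotations
from .errors import ParameterError
from .recording import MONTAGE_1020, Recording, SeizureEvent

MECHANISMS = ("spectral_tilt", "band_shift", "entropy_drop")
SEARCH_SPAN_H = 6.0  # anomaly must lie inside the pre-onset search span

#: Features each mechanism is expected to move most (emergent check targets).
EXPECTED_DOMINANT_FEATURES = {
    "spectral_tilt": ("spectral_entropy", "hjorth_mobility"),
    "band_shift": ("theta_power", "alpha_power"),
    "entropy_drop": ("spectral_entropy", "alpha_power"),
}

_BAND_EDGES = (
    ("delta", 0.5, 4.0), ("theta", 4.0, 8.0), ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0), ("gamma", 30.0, 48.0), ("high", 48.0, 75.0),
)

# effect_size -> generator-parameter scalings (chosen once; see docs/methods)
_RHYTHM_WEIGHT_PER_UNIT = 0.2  # within-band rhythmization weight per unit
_RHYTHM_POSITION = 0.8         # rhythm center, as a fraction of its band
_RHYTHM_REL_WIDTH = 0.05       # rhythm width relative to band width
_SHIFT_PER_UNIT = 0.6          # relative band-gain change per unit
_PEAK_POWER_PER_UNIT = 1.0     # narrowband peak power per unit, x broadband


@dataclass
class NoiseModel:
    """Second-order spectral description of the baseline EEG noise.

    PSD(f) = gain(f) / (1 + (f/knee)^slope) inside the analysis band, with
    a mild Gaussian alpha bump; the low-frequency knee reproduces the
    shoulder real scalp spectra show below a few Hz.
    """

    slope: float = 1.5                       # 1/f^slope exponent
    knee_hz: float = 2.0                     # low-frequency shoulder
    band_gains: dict = field(default_factory=dict)  # per-band PSD gain
    alpha_peak_gain: float = 2.0             # physiological alpha bump
    rms_uv: float = 30.0
    peak: tuple[float, float, float] | None = None  # (f0, width, rel power)
    band_rhythm: tuple[float, float, float] | None = None  # (pos, width, w)

    def psd(self, freqs: np.ndarray, band_limits: tuple[float, float]
            ) -> np.ndarray:
        lo, hi = band_limits
        base = 1.0 / (1.0 + (freqs / self.knee_hz) ** self.slope)
        psd = np.where((freqs >= lo) & (freqs < hi), base, 0.0)
        for band, f1, f2 in _BAND_EDGES:
            gain = self.band_gains.get(band, 1.0)
            if gain != 1.0:
                psd = np.where((freqs >= f1) & (freqs < f2), psd * gain, psd)
        if self.alpha_peak_gain != 1.0:
            psd = psd * (1 + (self.alpha_peak_gain - 1)
                         * np.exp(-0.5 * ((freqs - 10.0) / 1.5) ** 2))
        if self.band_rhythm is not None:
            # concentrate each band's power into a narrow rhythm near the
            # band's upper edge, preserving every band total exactly; the
            # delta band keeps its shape so the slow (DFA-visible) dynamics
            # stay baseline-like
            pos, rel_width, weight = self.band_rhythm
            out = psd.copy()
            for band, f1, f2 in _BAND_EDGES:
                if band == "delta":
                    continue
                f2c = min(f2, hi)
                if f2c <= f1:
                    continue
                m = (freqs >= f1) & (freqs < f2c)
                total = psd[m].sum()
                if total <= 0:
                    continue
                center = f1 + pos * (f2c - f1)
                sigma = max(rel_width * (f2c - f1), 0.25)
                bump = np.exp(-0.5 * ((freqs[m] - center) / sigma) ** 2)
                out[m] = (1 - weight) * psd[m] + weight * total * bump / bump.sum()
            psd = out
        if self.peak is not None:
            f0, width, rel = self.peak
            bump = np.exp(-0.5 * ((freqs - f0) / width) ** 2)
            bump = np.where((freqs >= lo) & (freqs < hi), bump, 0.0)
            total = psd.sum()
            if bump.sum() > 0 and total > 0:
                psd = psd + rel * total * bump / bump.sum()
        return psd


@dataclass
class AnomalySpec:
    """Where, how long, on which channels, and by which mechanism."""

    start_min_before_onset: float = 60.0
    duration_min: float = 40.0
    channels: tuple[str, ...] = ("O1", "O2", "Pz")
    mechanism: str = "spectral_tilt"
    effect_size: float = 4.0


@dataclass
class SyntheticSpec:
    """Full description of one synthetic recording."""

    n_channels: int = 19
    fs: float = 256.0
    duration_h: float = 9.0
    seizure_onset_h: float = 8.5
    anomaly: AnomalySpec | None = field(default_factory=AnomalySpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    @property
    def channel_labels(self) -> list[str]:
        return list(MONTAGE_1020[: self.n_channels])

    def validate(self) -> None:
        if not 1 <= self.n_channels <= len(MONTAGE_1020):
            raise ParameterError(
                f"n_channels must be in [1, {len(MONTAGE_1020)}]")
        if self.fs <= 0 or abs(self.fs - round(self.fs)) > 1e-9:
            raise ParameterError("fs must be a positive integer rate")
        if self.seizure_onset_h < 8.0:
            raise ParameterError(
                "onset must be >= 8 h into the record (inclusion rule)")
        if self.duration_h < self.seizure_onset_h:
            raise ParameterError("record must extend to the seizure onset")
        if self.anomaly is not None:
            a = self.anomaly
            if a.mechanism not in MECHANISMS:
                raise ParameterError(f"unknown mechanism {a.mechanism!r}")
            if a.effect_size < 0:
                raise ParameterError("effect_size must be >= 0")
            if not 0 < a.duration_min <= a.start_min_before_onset:
                raise ParameterError(
                    "anomaly must end at or before onset (duration <= start)")
            if a.start_min_before_onset > SEARCH_SPAN_H * 60:
                raise ParameterError(
                    f"anomaly must start within {SEARCH_SPAN_H} h of onset")
            missing = set(a.channels) - set(self.channel_labels)
            if not a.channels or missing:
                raise ParameterError(
                    f"anomaly channels invalid or absent: {sorted(missing)}")

    def without_anomaly(self) -> "SyntheticSpec":
        return replace(self, anomaly=None)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        anomaly = payload.pop("anomaly", "default")
        noise = payload.pop("noise", None)
        spec = cls(**payload)
        if anomaly is None:
            spec = replace(spec, anomaly=None)
        elif anomaly != "default":
            if "channels" in anomaly:
                anomaly["channels"] = tuple(anomaly["channels"])
            spec = replace(spec, anomaly=AnomalySpec(**anomaly))
        if noise is not None:
            if "peak" in noise and noise["peak"] is not None:
                noise["peak"] = tuple(noise["peak"])
            spec = replace(spec, noise=NoiseModel(**noise))
        spec.validate()
        return spec


@dataclass(frozen=True)
class GroundTruth:
    """What was injected: interval bounds, channels and mechanism."""

    t1_s: float
    tL_s: float
    channels: tuple[str, ...]
    mechanism: str
    effect_size: float
    expected_dominant_features: tuple[str, ...]

    def to_json(self) -> dict:
        return {
            "t1_s": self.t1_s, "tL_s": self.tL_s,
            "channels": list(self.channels), "mechanism": self.mechanism,
            "effect_size": self.effect_size,
            "expected_dominant_features": list(self.expected_dominant_features),
        }


def anomalous_noise_model(noise: NoiseModel, mechanism: str,
                          effect_size: float) -> NoiseModel:
    """Baseline noise model with the mechanism's parameter switch applied."""
    if mechanism == "spectral_tilt":
        weight = min(_RHYTHM_WEIGHT_PER_UNIT * effect_size, 0.95)
        if weight == 0:
            return replace(noise)
        return replace(noise, band_rhythm=(_RHYTHM_POSITION, _RHYTHM_REL_WIDTH,
                                           weight))
    if mechanism == "band_shift":
        factor = 1.0 + _SHIFT_PER_UNIT * effect_size
        gains = dict(noise.band_gains)
        gains["theta"] = gains.get("theta", 1.0) * factor
        gains["alpha"] = gains.get("alpha", 1.0) / factor
        return replace(noise, band_gains=gains)
    if mechanism == "entropy_drop":
        if effect_size == 0:
            return replace(noise)
        return replace(noise, peak=(10.0, 0.5, _PEAK_POWER_PER_UNIT * effect_size))
    raise ParameterError(f"unknown mechanism {mechanism!r}")


def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   noise: NoiseModel) -> np.ndarray:
    """One stationary Gaussian realization with the model's spectrum.

    Generated at the next FFT-friendly length and truncated (truncation of
    a stationary process is stationary).
    """
    from scipy.fft import next_fast_len

    m = next_fast_len(n, real=True)
    freqs = np.fft.rfftfreq(m, 1.0 / fs)
    amp = np.sqrt(noise.psd(freqs, (0.5, min(75.0, fs / 2))))
    spec = amp * (rng.standard_normal(freqs.size)
                  + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    if m % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, m)[:n]
    sd = x.std()
    return x * (noise.rms_uv / sd) if sd > 0 else x


def generate_recording(spec: SyntheticSpec
                       ) -> tuple[Recording, GroundTruth | None]:
    """Generate one synthetic recording and its ground truth.

    The baseline of every channel is one long stationary realization; on
    the anomaly channels the samples of the anomaly interval are replaced
    by a realization of the mechanism-switched noise model (same RMS), with
    a 1 s cosine crossfade at both edges.  Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = float(spec.fs)
    n = int(round(spec.duration_h * 3600 * fs))
    labels = spec.channel_labels
    signal = np.empty((len(labels), n))
    for c in range(len(labels)):
        signal[c] = _colored_noise(rng, n, fs, spec.noise)

    truth = None
    if spec.anomaly is not None:
        a = spec.anomaly
        onset_s = spec.seizure_onset_h * 3600.0
        t1 = onset_s - a.start_min_before_onset * 60.0
        tl = t1 + a.duration_min * 60.0
        i0, i1 = int(round(t1 * fs)), int(round(tl * fs))
        fade = int(fs)  # 1 s cosine crossfade at each edge
        alt = anomalous_noise_model(spec.noise, a.mechanism, a.effect_size)
        ramp_up = 0.5 * (1 - np.cos(np.pi * np.arange(fade) / fade))
        for label in a.channels:
            c = labels.index(label)
            seg = _colored_noise(rng, i1 - i0, fs, alt)
            blend = np.ones(i1 - i0)
            blend[:fade] = ramp_up
            blend[-fade:] = ramp_up[::-1]
            signal[c, i0:i1] = blend * seg + (1 - blend) * signal[c, i0:i1]
        truth = GroundTruth(
            t1_s=t1, tL_s=tl, channels=tuple(a.channels),
            mechanism=a.mechanism, effect_size=a.effect_size,
            expected_dominant_features=EXPECTED_DOMINANT_FEATURES[a.mechanism])

    meta = {
        "patient_id": f"SYN{spec.seed:04d}",
        "record_id": f"SYN{spec.seed:04d}-r1",
        "synthetic": True,
        "seizure_onset_s": spec.seizure_onset_h * 3600.0,
    }
    rec = Recording(labels, fs, signal,
                    np.full(len(labels), 10.0 * spec.noise.rms_uv), meta)
    return rec, truth


def generate_null_recording(spec: SyntheticSpec) -> Recording:
    """Anomaly-free recording under the same spec (same seed layout)."""
    rec, _ = generate_recording(spec.without_anomaly())
    return rec


def synthetic_events(spec: SyntheticSpec) -> list[SeizureEvent]:
    onset = spec.seizure_onset_h * 3600.0
    offset = min(onset + 60.0, spec.duration_h * 3600.0)
    return [SeizureEvent(onset, offset, "1")]


def write_synthetic_dataset(spec: SyntheticSpec, out_dir: str | Path
                            ) -> dict[str, Path]:
    """Write EDF + sidecar annotations JSON + ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec, truth = generate_recording(spec)
    record_id = rec.meta["record_id"]
    paths = {
        "edf": out / f"{record_id}.edf",
        "annotations": out / f"{record_id}.annotations.json",
        "truth": out / f"{record_id}.truth.json",
    }
    _edf.write_edf(paths["edf"], rec)
    write_annotations(paths["annotations"], record_id, synthetic_events(spec))
    paths["truth"].write_text(json.dumps(
        truth.to_json() if truth else None, indent=2))
    return paths
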