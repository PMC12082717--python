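"""Core in-memory containers: a multi-channel EEG recording and its seizure
annotations.

Amplitudes are kept in microvolts throughout; times are seconds from the
start of the record.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Scalp electrode names of the international 10-20 system, in the order the
#: synthetic generator assigns them.  The first 19 are the classical montage;
#: Fpz/Oz extend it to the 21-electrode layout common in clinical EEG.
MONTAGE_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2", "Fpz", "Oz",
)

_MONTAGE_LOWER = {m.lower() for m in MONTAGE_1020} | {"a1", "a2", "t1", "t2",
                                                      "t7", "t8", "p7", "p8",
                                                      "f9", "f10", "ft9", "ft10"}


def is_eeg_label(label: str) -> bool:
    """10-20 label filter used when loading clinical EDF files.

    Accepts explicit ``EEG ...`` labels and bare electrode names (optionally
    carrying a reference suffix such as ``Fp1-Ref``); rejects polygraphy
    channels (ECG, EMG, SpO2, markers, ...).
    """
    name = label.strip()
    low = name.lower()
    if low.startswith("eeg"):
        name = name[3:].strip(" -_")
        low = name.lower()
        if not name:
            return True
    # drop a reference suffix: "Fp1-Ref", "O2-A1"
    base = low.split("-")[0].split(" ")[0]
    return base in _MONTAGE_LOWER


@dataclass
class Recording:
    """A multi-channel scalp EEG recording.

    Attributes
    ----------
    channel_labels : list of str
        10-20 electrode names, unique, one per signal row.
    fs : float
        Sampling rate in Hz (identical for all channels).
    signal : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    transducer_max : ndarray, shape (n_channels,)
        Physical maximum of each channel's transducer in microvolts, read
        from the EDF physical-maximum header field.
    meta : dict
        Free-form provenance (patient/record identifiers, onset info).
    """

    channel_labels: list[str]
    fs: float
    signal: np.ndarray
    transducer_max: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.transducer_max = np.asarray(self.transducer_max, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 2:
            raise ParameterError("signal must be a channels x samples matrix")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ParameterError("one label per signal row required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ParameterError("channel labels must be unique")
        if self.transducer_max.shape != (self.signal.shape[0],):
            raise ParameterError("one transducer maximum per channel required")
        if not np.all(np.isfinite(self.signal)):
            raise ParameterError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError as exc:
            raise ParameterError(f"no channel named {label!r}") from exc


@dataclass(frozen=True)
class SeizureEvent:
    """A single annotated seizure: onset/offset in seconds from record start."""

    onset_s: float
    offset_s: float
    seizure_id: str = ""

    def validate(self, record_duration_s: float | None = None) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise ParameterError(
                f"need 0 <= onset < offset, got [{self.onset_s}, {self.offset_s}]"
            )
        if record_duration_s is not None and self.offset_s > record_duration_s + 1e-9:
            raise ParameterError("seizure offset lies beyond the end of the record")
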