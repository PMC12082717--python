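"""Reading EDF recordings and seizure annotations, record-quality and
seizure-selection rules, and report writing.

Records are excluded when more than 10% of their samples (pooled over all
channels) exceed the transducer's physical maximum, and seizures are only
analyzed when at least 8 h of signal precedes onset; within a cluster of
seizures less than 12 h apart only the first is analyzed.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf
from .errors import ContentError, FormatError, PipelineError
from .recording import Recording, SeizureEvent, is_eeg_label

MIN_PRE_SEIZURE_S = 8 * 3600.0
CLUSTER_GAP_S = 12 * 3600.0
NOISY_FRACTION = 0.10

REPORT_COLUMNS = [
    "patient_id", "seizure_id", "detected",
    "preictal_start_min_before_onset", "preictal_duration_min",
    "channels_selected", "top3_features", "provenance_channel",
    "d50", "l99", "error_stage", "error",
]


def read_recording(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording`.

    Non-EEG polygraphy channels (ECG, EMG, SpO2, ...) are dropped by label;
    the native sampling rate is preserved; amplitudes are converted to
    microvolts.  Per-channel transducer maxima come from the EDF
    physical-maximum header field.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    header = _edf.peek_header(path)  # validates EDF structure cheaply
    try:
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except PipelineError:
        raise
    except Exception as exc:  # mne raises bare ValueError/OSError on bad files
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc

    keep = [i for i, name in enumerate(raw.ch_names) if is_eeg_label(name)]
    if not keep:
        raise ContentError(f"{path}: no EEG channels after label filtering")
    labels = [raw.ch_names[i].strip() for i in keep]
    signal = raw.get_data(picks=keep) * 1e6  # MNE loads EEG in volts

    phys_max = dict(zip((l.strip() for l in header["labels"]), header["physical_max"]))
    transducer_max = np.array(
        [abs(phys_max.get(raw.ch_names[i].strip(), np.inf)) for i in keep]
    )
    meta = {
        "path": str(path),
        "record_id": path.stem,
        "patient_id": path.stem.split("-")[0],
    }
    return Recording(labels, float(raw.info["sfreq"]), signal, transducer_max, meta)


def flag_noisy(rec: Recording) -> bool:
    """True iff strictly more than 10% of samples, pooled over the whole
    channels x samples array, exceed the channel's transducer maximum in
    absolute value."""
    exceed = np.abs(rec.signal) > rec.transducer_max[:, None]
    return bool(exceed.mean() > NOISY_FRACTION)


def select_seizures(events: list[SeizureEvent],
                    record_duration_s: float) -> list[SeizureEvent]:
    """Apply the inclusion and cluster rules to onset-sorted seizure events.

    A seizure is retained iff (a) at least 8 h of recording precedes its
    onset and (b) it is the first retained event or starts at least 12 h
    after the previously retained one (greedy left-to-right, so only the
    first seizure of each cluster survives).
    """
    retained: list[SeizureEvent] = []
    for ev in sorted(events, key=lambda e: e.onset_s):
        ev.validate(record_duration_s)
        if ev.onset_s < MIN_PRE_SEIZURE_S:
            continue
        if retained and ev.onset_s - retained[-1].onset_s < CLUSTER_GAP_S:
            continue
        retained.append(ev)
    return retained


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> tuple[str, list[SeizureEvent]]:
    """Read the sidecar annotation JSON:
    ``{"record_id": str, "seizures": [{"onset_s": f, "offset_s": f}]}``."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except OSError as exc:
        raise FormatError(f"{path}: cannot read annotations ({exc})") from exc
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid annotation JSON ({exc})") from exc
    try:
        events = [
            SeizureEvent(float(s["onset_s"]), float(s["offset_s"]),
                         str(s.get("seizure_id", i + 1)))
            for i, s in enumerate(payload["seizures"])
        ]
        record_id = str(payload["record_id"])
    except (KeyError, TypeError) as exc:
        raise ContentError(f"{path}: annotation schema mismatch ({exc})") from exc
    return record_id, events


def write_annotations(path: str | Path, record_id: str,
                      events: list[SeizureEvent]) -> None:
    payload = {
        "record_id": record_id,
        "seizures": [
            {"onset_s": e.onset_s, "offset_s": e.offset_s, "seizure_id": e.seizure_id}
            for e in events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


_SIENA_TIME = re.compile(r"(\d{1,2})[.:](\d{2})[.:](\d{2})")


def _parse_siena_time(line: str) -> float:
    m = _SIENA_TIME.search(line.split(":", 1)[1])
    if m is None:
        raise FormatError(f"cannot parse time of day in {line!r}")
    h, mi, s = (int(g) for g in m.groups())
    return h * 3600.0 + mi * 60.0 + s


def read_siena_annotations(path: str | Path) -> dict[str, list[SeizureEvent]]:
    """Adapter for the Siena Scalp EEG Database ``Seizures-list-PNxx.txt``
    files.  Returns ``{edf file name: [SeizureEvent, ...]}`` with onsets in
    seconds from the start of the corresponding registration (times of day
    that wrap past midnight are unwrapped)."""
    text = Path(path).read_text(errors="replace")
    out: dict[str, list[SeizureEvent]] = {}
    current: str | None = None
    reg_start: float | None = None
    onset: float | None = None
    for line in text.splitlines():
        low = line.lower().strip()
        if low.startswith("file name"):
            current = line.split(":", 1)[1].strip()
            out.setdefault(current, [])
            reg_start = None
        elif low.startswith("registration start time"):
            reg_start = _parse_siena_time(line)
        elif low.startswith("seizure start time") and current and reg_start is not None:
            onset = _parse_siena_time(line) - reg_start
            if onset < 0:
                onset += 24 * 3600.0
        elif low.startswith("seizure end time") and current and onset is not None:
            offset = _parse_siena_time(line) - reg_start
            if offset < 0:
                offset += 24 * 3600.0
            out[current].append(
                SeizureEvent(onset, offset, f"{len(out[current]) + 1}"))
            onset = None
    if not out:
        raise ContentError(f"{path}: no 'File name' entries found")
    return out


# ---------------------------------------------------------------------------
# reports


@dataclass
class AnalysisReport:
    """Per-seizure result rows plus cohort summary statistics."""

    rows: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def add_row(self, row: dict) -> None:
        if row.get("detected"):
            dur = row.get("preictal_duration_min")
            if dur is None or dur < 15.0 - 1e-9:
                raise PipelineError(
                    f"detected interval shorter than 15 min in report row: {row}")
        self.rows.append({c: row.get(c) for c in REPORT_COLUMNS})

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=REPORT_COLUMNS)
        for col in ("channels_selected", "top3_features"):
            df[col] = df[col].map(
                lambda v: ";".join(v) if isinstance(v, (list, tuple)) else v)
        return df

    def summarize(self) -> dict:
        """Cohort summary: counts plus mean +/- SD of start and duration."""
        det = [r for r in self.rows if r.get("detected")]
        starts = np.array([r["preictal_start_min_before_onset"] for r in det], float)
        durs = np.array([r["preictal_duration_min"] for r in det], float)
        self.summary = {
            "n_seizures": len(self.rows),
            "n_detected": len(det),
            "start_min_mean": float(starts.mean()) if det else None,
            "start_min_sd": float(starts.std(ddof=1)) if len(det) > 1 else None,
            "duration_min_mean": float(durs.mean()) if det else None,
            "duration_min_sd": float(durs.std(ddof=1)) if len(det) > 1 else None,
        }
        return self.summary


def write_report(report: AnalysisReport, path: str | Path) -> None:
    """Emit ``<path>.json`` and ``<path>.csv`` with one row per seizure.

    Undetected seizures carry ``detected = False`` and null interval fields;
    an empty report still yields a valid header-only CSV.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    df = report.to_dataframe()
    try:
        df.to_csv(base.with_suffix(".csv"), index=False)
        payload = {"rows": report.rows, "summary": report.summarize()}
        base.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    except OSError as exc:
        raise FormatError(f"{base}: cannot write report ({exc})") from exc
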