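"""Per-seizure and batch orchestration of the full analysis.

Stages, in order: band-pass filter -> windowed feature extraction ->
interictal model fit -> Mahalanobis distance over the 6 h pre-onset search
span -> preictal interval detection -> per-channel F1 scoring -> channel
selection -> feature importance (top 3).  Each stage failure is recorded in
the report row with its stage name; a batch run isolates failures per
record.
"""
from __future__ import annotations

import logging
import time
from pathlib import Path

import yaml

from . import detection, eeg_io, features, localization, preprocessing
from .errors import ConfigError, PipelineError
from .recording import Recording, SeizureEvent

log = logging.getLogger("preictal_profiler")


def run_seizure(rec: Recording, event: SeizureEvent, config: dict,
                diagnostics_dir: str | Path | None = None) -> dict:
    """Analyze one seizure of one recording; returns a report row dict.

    The row always carries patient/seizure identity; on a stage error the
    ``error_stage``/``error`` fields name the failing stage and the run can
    continue with other seizures.
    """
    row = {
        "patient_id": rec.meta.get("patient_id", "?"),
        "seizure_id": event.seizure_id or "1",
        "detected": False,
    }
    onset = event.onset_s
    stage = "bandpass"
    t_start = time.monotonic()
    try:
        filtered = preprocessing.bandpass(
            rec, config["filter"]["low_hz"], config["filter"]["high_hz"],
            config["filter"]["transition_hz"])
        log.info("stage bandpass done in %.1fs", time.monotonic() - t_start)

        stage = "extract_features"
        feat = features.extract_features(
            filtered, window_s=config["window_s"], hop_s=config["hop_s"],
            k_max=config["hfd"]["k_max"],
            dfa_min_scale=config["dfa"]["min_scale"],
            dfa_n_scales=config["dfa"]["n_scales"],
            total_band=(config["filter"]["low_hz"], config["filter"]["high_hz"]))

        stage = "fit_interictal_model"
        model = detection.fit_interictal_model(
            feat, onset,
            interictal_duration_h=config["interictal"]["duration_h"],
            gap_h=config["interictal"]["gap_h"],
            percentile=config["detect"]["percentile"],
            ridge=config["detect"]["ridge"])

        stage = "mahalanobis_series"
        search_start = onset - config["interictal"]["gap_h"] * 3600.0
        ds = detection.mahalanobis_series(feat, model, search_start, onset)
        if diagnostics_dir is not None:
            out = Path(diagnostics_dir)
            out.mkdir(parents=True, exist_ok=True)
            ds.to_dataframe().to_csv(
                out / f"{row['patient_id']}-{row['seizure_id']}-distances.csv",
                index=False)

        stage = "detect_preictal"
        interval = detection.detect_preictal(
            ds, model, config["detect"]["min_duration_min"])
        if interval is None:
            log.info("seizure %s: no preictal interval detected",
                     row["seizure_id"])
            return row

        row.update(
            detected=True,
            preictal_start_min_before_onset=(onset - interval.t1_s) / 60.0,
            preictal_duration_min=interval.duration_min,
            provenance_channel=interval.channel,
            d50=interval.d50,
            l99=float(model.l99[model.channel_index(interval.channel)]),
        )

        stage = "score_channels"
        seed = config["select"]["seed"]
        scores = [
            localization.score_channel(
                feat, label, interval, model.span_s, seed=seed,
                test_fraction=config["select"]["test_fraction"],
                C=config["logreg"]["C"], max_iter=config["logreg"]["max_iter"])
            for label in feat.channel_labels
        ]

        stage = "select_channels"
        # the quantile rule needs >= 4 channels; below that, and when every
        # F1 ties (nothing strictly above the quantile), fall back to the
        # single best channel
        selected = (localization.select_channels(scores,
                                                 config["select"]["quantile"])
                    if len(scores) >= 4 else [])
        best = max(scores, key=lambda s: s.f1).channel
        if not selected:
            selected = [best]
        row["channels_selected"] = selected

        stage = "rank_features"
        ranking = localization.rank_features(
            feat, best, interval, model.span_s, seed=seed,
            test_fraction=config["select"]["test_fraction"],
            C=config["logreg"]["C"], max_iter=config["logreg"]["max_iter"])
        row["top3_features"] = list(ranking.top3)
        log.info("seizure %s analyzed in %.1fs", row["seizure_id"],
                 time.monotonic() - t_start)
    except PipelineError as exc:
        log.warning("seizure %s failed at stage %s: %s", row["seizure_id"],
                    stage, exc)
        row.update(detected=False, error_stage=stage, error=str(exc))
    return row


def load_manifest(path: str | Path) -> list[dict]:
    try:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    except OSError as exc:
        raise ConfigError(f"{path}: cannot read manifest ({exc})") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid manifest YAML ({exc})") from exc
    records = payload.get("records", payload if isinstance(payload, list) else None)
    if not isinstance(records, list):
        raise ConfigError(f"{path}: manifest must contain a 'records' list")
    for entry in records:
        if "edf" not in entry or "annotations" not in entry:
            raise ConfigError(
                f"{path}: each manifest entry needs 'edf' and 'annotations'")
    return records


def run_record(edf_path: str | Path, annotations_path: str | Path,
               config: dict, report: eeg_io.AnalysisReport,
               diagnostics_dir: str | Path | None = None) -> None:
    """Read, quality-check and analyze all retained seizures of one record."""
    if annotations_path is None:
        raise ConfigError(f"{edf_path}: no annotations provided")
    rec = eeg_io.read_recording(edf_path)
    _, events = eeg_io.read_annotations(annotations_path)
    if eeg_io.flag_noisy(rec):
        log.warning("%s: flagged noisy (>10%% of samples beyond transducer max)",
                    edf_path)
        report.add_row({
            "patient_id": rec.meta.get("patient_id", "?"), "seizure_id": None,
            "detected": False, "error_stage": "flag_noisy",
            "error": "record excluded: noisy",
        })
        return
    retained = eeg_io.select_seizures(events, rec.duration_s)
    for event in retained:
        report.add_row(run_seizure(rec, event, config, diagnostics_dir))


def run_batch(manifest: list[dict] | str | Path, config: dict,
              diagnostics_dir: str | Path | None = None
              ) -> eeg_io.AnalysisReport:
    """Run every record of a manifest, isolating per-record failures."""
    if not isinstance(manifest, list):
        manifest = load_manifest(manifest)
    report = eeg_io.AnalysisReport()
    for entry in manifest:
        try:
            run_record(entry["edf"], entry.get("annotations"), config, report,
                       diagnostics_dir)
        except PipelineError as exc:
            log.error("record %s failed: %s", entry.get("edf"), exc)
            report.add_row({
                "patient_id": Path(str(entry.get("edf"))).stem,
                "seizure_id": None, "detected": False,
                "error_stage": "read", "error": str(exc),
            })
    report.summarize()
    return report
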