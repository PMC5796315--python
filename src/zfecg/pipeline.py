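"""Batch and streaming analysis pipelines tying the stages together.

``analyze_record`` mirrors the batch ("read from file") flow: filter ->
fiducials -> interval features & HRV -> rule diagnosis -> summary.
``monitor_record`` replays a record through the streaming ("measure live")
flow: the trailing window is filtered and diagnosed on every hop, and each
emitted frame carries the OR of the per-interval flags inside the window,
matching how a live front panel displays a diagnosis for the data currently
on screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .anomalies import (
    FLAG_NAMES,
    AnomalyCriteria,
    AnomalyReport,
    build_summary,
    diagnose,
)
from .denoise import FilterConfig, filter_pipeline
from .fiducials import FiducialConfig, NoBeatsError, detect_r_peaks, extract_fiducials
from .hrv import compute_hrv, interval_features
from .io import ECGRecord, SummaryDocument

__all__ = ["PipelineConfig", "BatchResult", "analyze_record", "monitor_record"]


@dataclass(frozen=True)
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    fiducial: FiducialConfig = field(default_factory=FiducialConfig)
    criteria: AnomalyCriteria = field(default_factory=AnomalyCriteria)
    window_seconds: float = 10.0
    hop_seconds: float = 1.0
    isoelectric: float | None = None

    def __post_init__(self) -> None:
        if self.window_seconds <= 0 or self.hop_seconds <= 0:
            raise ValueError("window and hop must be positive")


@dataclass
class BatchResult:
    record: ECGRecord
    filtered: ECGRecord
    r_peaks: np.ndarray
    fiducials: list
    features: pd.DataFrame
    hrv: dict
    reports: list[AnomalyReport]
    summary: SummaryDocument


def analyze_record(
    record: ECGRecord, config: PipelineConfig = PipelineConfig()
) -> BatchResult:
    """Run the full batch chain on one record.

    Raises :class:`zfecg.fiducials.NoBeatsError` if no R peaks are found.
    """
    filtered = filter_pipeline(record, config.filter)
    r_peaks = detect_r_peaks(filtered, config.fiducial)
    if r_peaks.size < 2:
        raise NoBeatsError("fewer than two beats detected; no R-R interval to analyze")
    fids = extract_fiducials(filtered, r_peaks, config.fiducial)
    features = interval_features(filtered, fids, config.isoelectric)
    hrv = compute_hrv(r_peaks, filtered.fs).to_dict()
    reports = diagnose(features, config.criteria, fs=filtered.fs)
    summary = build_summary(
        reports,
        hrv=hrv,
        config={
            "filter": vars(config.filter).copy(),
            "fiducial": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in vars(config.fiducial).items()
            },
            "criteria": vars(config.criteria).copy(),
        },
    )
    return BatchResult(
        record=record,
        filtered=filtered,
        r_peaks=r_peaks,
        fiducials=fids,
        features=features,
        hrv=hrv,
        reports=reports,
        summary=summary,
    )


def monitor_record(
    record: ECGRecord, config: PipelineConfig = PipelineConfig()
) -> Iterator[dict]:
    """Replay a record through the streaming flow, yielding one frame per hop.

    Each frame covers exactly the trailing ``window_seconds`` ending at its
    ``t_end``; its flags are the OR over the R-R intervals inside the
    window. Frames emitted before a full window has accumulated are marked
    ``warming_up`` and carry no diagnosis.
    """
    fs = record.fs
    win = int(round(config.window_seconds * fs))
    hop = int(round(config.hop_seconds * fs))
    n = len(record)
    for end in range(hop, n + 1, hop):
        start = end - win
        if start < 0:
            yield {
                "t_start": record.t0,
                "t_end": record.t0 + end / fs,
                "warming_up": True,
                "flags": {},
                "normal_rhythm": None,
            }
            continue
        window = ECGRecord(
            samples=record.samples[start:end].copy(),
            fs=fs,
            channel_id=record.channel_id,
            t0=record.t0 + start / fs,
        )
        frame = {
            "t_start": window.t0,
            "t_end": window.t0 + config.window_seconds,
            "warming_up": False,
        }
        try:
            result = analyze_record(window, config)
        except (NoBeatsError, ValueError) as exc:
            frame.update({"flags": {}, "normal_rhythm": None, "error": str(exc)})
            yield frame
            continue
        flags = {
            name: any(getattr(rep, name) is True for rep in result.reports)
            for name in FLAG_NAMES
        }
        frame.update(
            {
                "flags": flags,
                "normal_rhythm": not any(flags.values()),
                "mean_bpm": result.hrv["mean_bpm"],
                "n_intervals": len(result.reports),
            }
        )
        yield frame
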