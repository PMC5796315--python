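"""Rule-based per-interval diagnosis of zebrafish ECG anomalies.

Criteria (defaults calibrated for zebrafish, all configurable):

* sinus bradycardia — instantaneous rate 60/RR below 90 BPM,
* sinus tachycardia — instantaneous rate above 150 BPM,
* sinus arrhythmia — max-min RR spread over the trailing window of up to
  10 beats greater than 0.16 s,
* sinus arrest — consecutive-P interval greater than twice the reference
  R-R (median RR of the trailing window),
* ST elevation / depression — mean ST-segment deviation from the
  isoelectric line beyond +/- 0.1 mV (no zebrafish reference values exist;
  these are working defaults).

"Normal Rhythm" is true exactly when no anomaly flag is set. AV block is
deliberately not rule-diagnosed (its signature — orphaned P waves — is
handled by the classification path); the missing-QRS beats still surface
here through the arrest and bradycardia rules on the merged intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SummaryDocument

__all__ = [
    "AnomalyCriteria",
    "AnomalyReport",
    "FLAG_NAMES",
    "diagnose",
    "summarize",
    "reports_to_frame",
]

#: Flag attribute -> report display name (Table-1 style vocabulary).
FLAG_NAMES = {
    "bradycardia": "Bradycardia",
    "tachycardia": "Tachycardia",
    "sinus_arrhythmia": "Arrhythmia",
    "sinus_arrest": "Sinus Arrest",
    "st_elevation": "ST Elevation",
    "st_depression": "ST Depression",
}


@dataclass(frozen=True)
class AnomalyCriteria:
    brady_bpm: float = 90.0
    tachy_bpm: float = 150.0
    arrhythmia_spread_s: float = 0.16
    arrhythmia_window: int = 10
    arrest_factor: float = 2.0
    st_elev_mv: float = 0.1
    st_dep_mv: float = 0.1

    def __post_init__(self) -> None:
        if not self.brady_bpm < self.tachy_bpm:
            raise ValueError("brady_bpm must be below tachy_bpm")
        if not self.arrest_factor > 1:
            raise ValueError("arrest_factor must exceed 1")
        if min(self.arrhythmia_spread_s, self.st_elev_mv, self.st_dep_mv) <= 0:
            raise ValueError("thresholds must be positive")
        if self.arrhythmia_window < 2:
            raise ValueError("arrhythmia_window must be >= 2")


@dataclass
class AnomalyReport:
    """Boolean diagnosis of one R-R interval.

    ``sinus_arrest`` is ``None`` when it could not be evaluated (no
    preceding P wave); the reason is recorded in ``notes``.
    """

    interval_index: int
    bradycardia: bool = False
    tachycardia: bool = False
    sinus_arrhythmia: bool = False
    sinus_arrest: bool | None = False
    st_elevation: bool = False
    st_depression: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def flags(self) -> dict[str, bool | None]:
        return {name: getattr(self, name) for name in FLAG_NAMES}

    @property
    def active(self) -> frozenset[str]:
        """Names of flags that are definitely True."""
        return frozenset(k for k, v in self.flags.items() if v is True)

    @property
    def normal_rhythm(self) -> bool:
        return not self.active


def diagnose(
    features: pd.DataFrame,
    criteria: AnomalyCriteria = AnomalyCriteria(),
    fs: float = 1000.0,
) -> list[AnomalyReport]:
    """Apply the criteria to a per-interval feature table.

    ``features`` must carry ``rr_s`` and, for the arrest / ST rules,
    ``p_idx`` and ``st_mean_dev_mv`` (as produced by
    :func:`zfecg.hrv.interval_features`); absent columns disable the
    corresponding rule rather than failing.
    """
    if features.empty:
        raise ValueError("feature table is empty")
    rr = features["rr_s"].to_numpy(dtype=float)
    p_idx = (
        features["p_idx"].to_numpy(dtype=float)
        if "p_idx" in features
        else np.full(rr.size, np.nan)
    )
    st_dev = (
        features["st_mean_dev_mv"].to_numpy(dtype=float)
        if "st_mean_dev_mv" in features
        else np.full(rr.size, np.nan)
    )
    idx = (
        features["interval_index"].to_numpy(dtype=int)
        if "interval_index" in features
        else np.arange(1, rr.size + 1)
    )

    reports: list[AnomalyReport] = []
    for i in range(rr.size):
        rep = AnomalyReport(interval_index=int(idx[i]))
        bpm = 60.0 / rr[i]
        rep.bradycardia = bool(bpm < criteria.brady_bpm)
        rep.tachycardia = bool(bpm > criteria.tachy_bpm)

        window = rr[max(0, i - criteria.arrhythmia_window + 1) : i + 1]
        if window.size >= 2:
            rep.sinus_arrhythmia = bool(
                window.max() - window.min() > criteria.arrhythmia_spread_s
            )

        if i == 0 or np.isnan(p_idx[i]) or np.isnan(p_idx[i - 1]):
            rep.sinus_arrest = None
            rep.notes.append("sinus arrest not evaluable: no preceding P wave")
        else:
            pp = (p_idx[i] - p_idx[i - 1]) / fs
            reference_rr = float(np.median(window))
            rep.sinus_arrest = bool(pp > criteria.arrest_factor * reference_rr)

        if not np.isnan(st_dev[i]):
            rep.st_elevation = bool(st_dev[i] > criteria.st_elev_mv)
            rep.st_depression = bool(st_dev[i] < -criteria.st_dep_mv)
        reports.append(rep)
    return reports


def summarize(reports: list[AnomalyReport]) -> list[dict]:
    """Collapse per-interval reports into Table-1-style summary rows.

    Maximal runs of consecutive intervals with an identical set of active
    flags become one row ``{"intervals": "a-b", "anomalies": [...]}``;
    anomaly-free runs are omitted. Anomaly names follow the display
    vocabulary in canonical order.
    """
    rows: list[dict] = []
    run_start = run_end = None
    run_flags: frozenset[str] = frozenset()

    def _flush() -> None:
        if run_start is not None and run_flags:
            text = f"{run_start}-{run_end}" if run_end != run_start else str(run_start)
            rows.append(
                {
                    "intervals": text,
                    "anomalies": [FLAG_NAMES[k] for k in FLAG_NAMES if k in run_flags],
                }
            )

    for rep in sorted(reports, key=lambda r: r.interval_index):
        if run_start is not None and rep.active == run_flags and rep.interval_index == run_end + 1:
            run_end = rep.interval_index
        else:
            _flush()
            run_start = run_end = rep.interval_index
            run_flags = rep.active
    _flush()
    return rows


def build_summary(
    reports: list[AnomalyReport],
    hrv: dict | None = None,
    config: dict | None = None,
) -> SummaryDocument:
    """Assemble the JSON summary document from reports and the HRV block."""
    return SummaryDocument(
        anomaly_rows=summarize(reports),
        hrv=dict(hrv or {}),
        config=dict(config or {}),
    )


def reports_to_frame(reports: list[AnomalyReport]) -> pd.DataFrame:
    """Per-interval CSV-ready table of boolean flags plus normal-rhythm."""
    rows = []
    for rep in reports:
        row = {"interval_index": rep.interval_index}
        row.update(rep.flags)
        row["normal_rhythm"] = rep.normal_rhythm
        rows.append(row)
    return pd.DataFrame(rows)
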