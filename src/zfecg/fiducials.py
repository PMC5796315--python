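"""R-peak detection and windowed P/Q/S/T localization.

R waves are local maxima above a threshold of 50 % of the maximum amplitude
of the analysis window (the whole record in batch mode; the trailing
display window in streaming mode), with a refractory spacing that collapses
near-coincident detections to the larger peak. Each R-R interval bounded by
consecutive R peaks (R1, R2) is then divided into fixed search windows:

* Q: minimum in the 50 ms before R1,
* S: minimum in the 50 ms after R1,
* T: highest peak 15-55 % of the interval after R1,
* P: highest peak 65-95 % of the interval after R1 (the P wave of the
  following beat, which in zebrafish falls late in the interval).

Window endpoints are inclusive, ties break toward the earlier sample, and
windows that would leave the record are clamped and flagged. A prominence
score (peak amplitude minus window median) accompanies P and T so that
degenerate detections — e.g. the P-only beats of an AV-block record, whose
"T" is just baseline — can be recognized downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ECGRecord

__all__ = [
    "FiducialConfig",
    "BeatFiducials",
    "NoBeatsError",
    "detect_r_peaks",
    "extract_fiducials",
    "fiducials_to_frame",
]


class NoBeatsError(ValueError):
    """Raised when no peak crosses the detection threshold."""


@dataclass(frozen=True)
class FiducialConfig:
    """Windowing parameters (defaults follow the zebrafish protocol)."""

    r_threshold_frac: float = 0.50      # fraction of max amplitude
    qs_window: float = 0.050            # s before/after R for Q and S
    t_window: tuple[float, float] = (0.15, 0.55)   # fractions of R-R
    p_window: tuple[float, float] = (0.65, 0.95)   # fractions of R-R
    refractory: float = 0.150           # s, minimum R-R spacing
    prominence_min: float = 0.02        # mV, low-prominence flag threshold

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold_frac < 1:
            raise ValueError("r_threshold_frac must lie in (0, 1)")
        for lo, hi in (self.t_window, self.p_window):
            if not 0 <= lo < hi <= 1:
                raise ValueError("window fractions must satisfy 0 <= lo < hi <= 1")
        if self.t_window[1] > self.p_window[0]:
            raise ValueError("T and P windows must not overlap")
        if self.qs_window <= 0 or self.refractory <= 0:
            raise ValueError("qs_window and refractory must be positive")


@dataclass
class BeatFiducials:
    """Fiducial indices and amplitudes for one R-R interval (1-based index)."""

    interval_index: int
    r1_idx: int
    r2_idx: int
    q_idx: int
    s_idx: int
    t_idx: int
    p_idx: int
    r1_amp: float
    r2_amp: float
    q_amp: float
    s_amp: float
    t_amp: float
    p_amp: float
    t_prominence: float = np.nan
    p_prominence: float = np.nan
    t_low_prominence: bool = False
    p_low_prominence: bool = False
    clamped: bool = False

    @property
    def rr_samples(self) -> int:
        return self.r2_idx - self.r1_idx


def detect_r_peaks(
    record: ECGRecord, cfg: FiducialConfig = FiducialConfig()
) -> np.ndarray:
    """Indices of R peaks: local maxima above the relative threshold.

    Raises :class:`NoBeatsError` when nothing crosses the threshold.
    """
    x = record.samples
    if x.size < 3:
        raise NoBeatsError("record too short for peak detection")
    threshold = cfg.r_threshold_frac * float(np.max(x))
    if np.max(x) <= 0:
        raise NoBeatsError("no beats detected")
    distance = max(1, int(round(cfg.refractory * record.fs)))
    peaks, _ = sps.find_peaks(x, height=threshold, distance=distance)
    if peaks.size == 0:
        raise NoBeatsError("no beats detected")
    return peaks


def _argext(x: np.ndarray, lo: int, hi: int, mode: str) -> tuple[int, bool]:
    """Arg max/min on the inclusive index window [lo, hi], clamped to x."""
    n = x.size
    clamped = lo < 0 or hi > n - 1
    lo_c, hi_c = max(0, lo), min(n - 1, hi)
    seg = x[lo_c : hi_c + 1]
    off = int(np.argmax(seg)) if mode == "max" else int(np.argmin(seg))
    return lo_c + off, clamped


def extract_fiducials(
    record: ECGRecord,
    r_peaks: np.ndarray,
    cfg: FiducialConfig = FiducialConfig(),
) -> list[BeatFiducials]:
    """Locate P, Q, S, T in every R-R interval; one entry per interval.

    Requires at least two R peaks; the last R starts no interval. The
    extractor always returns a peak per window (as the windowing algorithm
    does); prominence flags mark detections that are indistinguishable from
    baseline.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 2:
        raise ValueError("need at least two R peaks to form an R-R interval")
    x = record.samples
    fs = record.fs
    qs = int(round(cfg.qs_window * fs))
    out: list[BeatFiducials] = []
    for i, (r1, r2) in enumerate(zip(r_peaks[:-1], r_peaks[1:]), start=1):
        rr = int(r2 - r1)
        q_idx, c1 = _argext(x, r1 - qs, r1 - 1, "min")
        s_idx, c2 = _argext(x, r1 + 1, r1 + qs, "min")
        t_lo = r1 + int(round(cfg.t_window[0] * rr))
        t_hi = r1 + int(round(cfg.t_window[1] * rr))
        t_idx, c3 = _argext(x, t_lo, t_hi, "max")
        p_lo = r1 + int(round(cfg.p_window[0] * rr))
        p_hi = r1 + int(round(cfg.p_window[1] * rr))
        p_idx, c4 = _argext(x, p_lo, p_hi, "max")
        t_prom = float(x[t_idx] - np.median(x[max(0, t_lo) : min(x.size, t_hi + 1)]))
        p_prom = float(x[p_idx] - np.median(x[max(0, p_lo) : min(x.size, p_hi + 1)]))
        out.append(
            BeatFiducials(
                interval_index=i,
                r1_idx=int(r1),
                r2_idx=int(r2),
                q_idx=q_idx,
                s_idx=s_idx,
                t_idx=t_idx,
                p_idx=p_idx,
                r1_amp=float(x[r1]),
                r2_amp=float(x[r2]),
                q_amp=float(x[q_idx]),
                s_amp=float(x[s_idx]),
                t_amp=float(x[t_idx]),
                p_amp=float(x[p_idx]),
                t_prominence=t_prom,
                p_prominence=p_prom,
                t_low_prominence=t_prom < cfg.prominence_min,
                p_low_prominence=p_prom < cfg.prominence_min,
                clamped=c1 or c2 or c3 or c4,
            )
        )
    return out


def fiducials_to_frame(fiducials: list[BeatFiducials]) -> pd.DataFrame:
    """Annotation table: one row per (interval, wave) with index and amplitude."""
    rows = []
    for fid in fiducials:
        for wave, idx, amp in (
            ("P", fid.p_idx, fid.p_amp),
            ("Q", fid.q_idx, fid.q_amp),
            ("R", fid.r1_idx, fid.r1_amp),
            ("S", fid.s_idx, fid.s_amp),
            ("T", fid.t_idx, fid.t_amp),
        ):
            rows.append(
                {
                    "interval_index": fid.interval_index,
                    "wave": wave,
                    "sample_index": idx,
                    "amplitude_mV": amp,
                }
            )
    return pd.DataFrame(rows, columns=["interval_index", "wave", "sample_index", "amplitude_mV"])
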