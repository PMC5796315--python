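"""Per-interval timing/amplitude features and heart-rate-variability summary.

Interval conventions within an R-R interval bounded by (R1, R2), where Q
and S flank R1 and P is detected late in the interval (it belongs to the
next beat):

====  =======================================
RR    R2 - R1
QR    R1 - Q          (Q precedes R1)
RS    S - R1
ST    T - S
RT    T - R1
TP    P - T
PQ    Q' - P          (Q' = Q of the next interval)
PR    R2 - P
====  =======================================

All are reported in seconds (index differences divided by fs). The only
amplitude feature is the signed difference amplitude(R1) - amplitude(T).

ST-segment statistics split the samples strictly between S and T by the
isoelectric line (default: median of the same interval's T-to-P segment,
the conventional baseline) into values above and below, and report count,
mean and population standard deviation per side; samples exactly on the
line count as above.

The HRV block reports, over all R-R intervals: mean and SD of the
instantaneous rate (BPM = 60/RR), mean and SD of RR, the root mean square
of successive RR differences (RMSSD), the number of adjacent RR pairs
differing by more than 50 ms (NN50), and that count as a percentage of all
adjacent pairs (pNN50). Sample (N-1) SDs are used for the HRV block,
population SDs for the ST statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import ECGRecord
from .fiducials import BeatFiducials

__all__ = [
    "STStats",
    "HRVSummary",
    "compute_intervals",
    "st_segment_stats",
    "interval_features",
    "compute_hrv",
]


@dataclass(frozen=True)
class STStats:
    """Above/below-isoelectric statistics of one ST segment (mV)."""

    isoelectric: float
    count_above: int
    mean_above: float
    sd_above: float
    count_below: int
    mean_below: float
    sd_below: float

    @property
    def mean_deviation(self) -> float:
        """Mean of all ST-segment samples minus the isoelectric value."""
        total = self.count_above + self.count_below
        if total == 0:
            return float("nan")
        s = 0.0
        if self.count_above:
            s += self.count_above * self.mean_above
        if self.count_below:
            s += self.count_below * self.mean_below
        return s / total - self.isoelectric


@dataclass(frozen=True)
class HRVSummary:
    """Time-domain HRV metrics over a sequence of R-R intervals."""

    mean_bpm: float
    sd_bpm: float
    mean_rr_s: float
    sd_rr_s: float
    rmssd_s: float
    nn50: int
    pnn50_pct: float
    n_intervals: int

    def to_dict(self) -> dict:
        return asdict(self)


def compute_intervals(
    fiducials: list[BeatFiducials], fs: float
) -> pd.DataFrame:
    """Timing features per R-R interval (one row per interval, in seconds).

    A missing fiducial propagates as NaN in the affected columns; the PQ
    interval of the final interval is NaN because it needs the next
    interval's Q wave.
    """
    rows = []
    for i, fid in enumerate(fiducials):
        q_next = fiducials[i + 1].q_idx if i + 1 < len(fiducials) else np.nan
        rows.append(
            {
                "interval_index": fid.interval_index,
                "r1_idx": fid.r1_idx,
                "r2_idx": fid.r2_idx,
                "p_idx": fid.p_idx,
                "q_idx": fid.q_idx,
                "s_idx": fid.s_idx,
                "t_idx": fid.t_idx,
                "rr_s": (fid.r2_idx - fid.r1_idx) / fs,
                "qr_s": (fid.r1_idx - fid.q_idx) / fs,
                "rs_s": (fid.s_idx - fid.r1_idx) / fs,
                "st_s": (fid.t_idx - fid.s_idx) / fs,
                "rt_s": (fid.t_idx - fid.r1_idx) / fs,
                "tp_s": (fid.p_idx - fid.t_idx) / fs,
                "pq_s": (q_next - fid.p_idx) / fs,
                "pr_s": (fid.r2_idx - fid.p_idx) / fs,
                "rt_amp_mv": fid.r1_amp - fid.t_amp,
            }
        )
    return pd.DataFrame(rows)


def st_segment_stats(
    record: ECGRecord,
    fid: BeatFiducials,
    isoelectric: float | None = None,
) -> STStats:
    """Above/below-isoelectric statistics of the samples strictly between S and T.

    ``isoelectric=None`` uses the median of the interval's own T-to-P
    segment. Samples exactly on the line count as above; an empty side
    yields count 0 with NaN mean/SD. SDs are population (N-denominator).
    """
    x = record.samples
    if isoelectric is None:
        tp = x[fid.t_idx : fid.p_idx + 1]
        isoelectric = float(np.median(tp)) if tp.size else 0.0
    seg = x[fid.s_idx + 1 : fid.t_idx]
    above = seg[seg >= isoelectric]
    below = seg[seg < isoelectric]

    def _stats(side: np.ndarray) -> tuple[int, float, float]:
        if side.size == 0:
            return 0, float("nan"), float("nan")
        return side.size, float(np.mean(side)), float(np.std(side, ddof=0))

    ca, ma, sa = _stats(above)
    cb, mb, sb = _stats(below)
    return STStats(
        isoelectric=float(isoelectric),
        count_above=ca,
        mean_above=ma,
        sd_above=sa,
        count_below=cb,
        mean_below=mb,
        sd_below=sb,
    )


def interval_features(
    record: ECGRecord,
    fiducials: list[BeatFiducials],
    isoelectric: float | None = None,
) -> pd.DataFrame:
    """Combined per-interval feature table: timings plus ST-segment statistics."""
    df = compute_intervals(fiducials, record.fs)
    st_rows = []
    for fid in fiducials:
        st = st_segment_stats(record, fid, isoelectric)
        st_rows.append(
            {
                "iso_mv": st.isoelectric,
                "st_count_above": st.count_above,
                "st_mean_above": st.mean_above,
                "st_sd_above": st.sd_above,
                "st_count_below": st.count_below,
                "st_mean_below": st.mean_below,
                "st_sd_below": st.sd_below,
                "st_mean_dev_mv": st.mean_deviation,
            }
        )
    return pd.concat([df, pd.DataFrame(st_rows)], axis=1)


def compute_hrv(r_peaks: np.ndarray, fs: float) -> HRVSummary:
    """HRV summary from R-peak sample indices.

    Needs >= 2 peaks for the RR statistics; with exactly two, the successive-
    difference metrics (RMSSD, pNN50) are NaN and NN50 is 0.
    """
    r = np.asarray(r_peaks, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two R peaks for RR statistics")
    rr = np.diff(r) / fs
    bpm = 60.0 / rr
    drr = np.diff(rr)
    nn50 = int(np.sum(np.abs(drr) > 0.050))
    if drr.size:
        rmssd = float(np.sqrt(np.mean(drr**2)))
        pnn50 = 100.0 * nn50 / drr.size
    else:
        rmssd = float("nan")
        pnn50 = float("nan")
    return HRVSummary(
        mean_bpm=float(np.mean(bpm)),
        sd_bpm=float(np.std(bpm, ddof=1)) if bpm.size > 1 else float("nan"),
        mean_rr_s=float(np.mean(rr)),
        sd_rr_s=float(np.std(rr, ddof=1)) if rr.size > 1 else float("nan"),
        rmssd_s=rmssd,
        nn50=nn50,
        pnn50_pct=pnn50,
        n_intervals=int(rr.size),
    )
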