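"""Synthetic zebrafish ECG generation with ground-truth annotations.

Every downstream stage (denoising, fiducial extraction, HRV, rule-based
diagnosis, classification) is exercised against records produced here, since
no recorded zebrafish ECG data are publicly deposited. A beat is modelled as
five Gaussian bumps (P, Q, R, S, T; Q and S negative), the standard
surrogate for ECG morphology when only peak locations and amplitudes matter.
Within one R-R interval the wave order matches adult zebrafish ECG: the R
peak is followed by S, the T wave around a third of the interval, and the P
wave of the *next* beat late in the interval (65-95 %), which is why the
windowed extractor searches for P there.

Noise terms emulate the dominant contaminants of tank recordings:
low-frequency baseline wander, 60 Hz mains pickup, broadband white noise,
and periodic gill-motion artifact bursts (damped oscillations recurring at
the 2-4 Hz gill beat rate).

Anomaly injection covers atrioventricular block (AVB: QRS/T of every k-th
beat dropped, P retained), sinus arrest (SA: whole beats deleted leaving a
pause with P-P exceeding twice the reference R-R), ST elevation (STE:
constant offset between S and T), bradycardia/tachycardia (mean rate below
90 / above 150 BPM) and sinus arrhythmia (R-R spread over 10 beats above
0.16 s). Ground truth records every true fiducial index, dropped-beat flag,
pause extent and ST offset, so parameter recovery is directly testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import ECGRecord

__all__ = [
    "Wave",
    "NoiseParams",
    "AnomalyParams",
    "SyntheticSpec",
    "GroundTruth",
    "beat_template",
    "generate",
    "inject_anomaly",
    "segment_dataset",
    "match_fiducials",
    "awake_spec",
    "anesthetized_spec",
]

WAVE_ORDER = ("P", "Q", "R", "S", "T")

ANOMALY_KINDS = (
    "none",
    "AVB",
    "SA",
    "STE",
    "bradycardia",
    "tachycardia",
    "sinus_arrhythmia",
)


@dataclass(frozen=True)
class Wave:
    """One Gaussian wave: ``amplitude * exp(-((t - c)/width)^2 / 2)``.

    ``offset`` is the wave centre as a fraction of the R-R interval from the
    start of the beat; ``width`` is the Gaussian sigma in seconds, so the
    time integral of an isolated wave is ``amplitude * width * sqrt(2*pi)``.
    """

    amplitude: float  # mV
    width: float      # s (Gaussian sigma)
    offset: float     # fraction of R-R from beat start

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("wave width must be positive")
        if not 0 <= self.offset < 1:
            raise ValueError("wave offset must lie in [0, 1)")


def default_waves() -> dict[str, Wave]:
    """Default zebrafish-like morphology (R normalized to 1 mV).

    Zebrafish P and T amplitudes are not standardized; these defaults keep P
    and T well below the 50 % R-peak detection threshold while remaining the
    clear extrema of their search windows.
    """
    return {
        "P": Wave(amplitude=0.12, width=0.018, offset=0.10),
        "Q": Wave(amplitude=-0.15, width=0.006, offset=0.26),
        "R": Wave(amplitude=1.00, width=0.006, offset=0.30),
        "S": Wave(amplitude=-0.20, width=0.006, offset=0.34),
        "T": Wave(amplitude=0.25, width=0.030, offset=0.65),
    }


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise model for tank recordings (all amplitudes in mV)."""

    baseline_amp: float = 0.15     # baseline wander amplitude
    baseline_freq: float = 0.25    # Hz
    mains_amp: float = 0.02        # 60 Hz hum surviving the hardware notch
    mains_freq: float = 60.0
    white_sd: float = 0.02         # broadband sensor noise SD
    gill_amp: float = 0.0          # gill-motion burst amplitude (0 = off)
    gill_rate: float = 3.0         # bursts per second (gill beat rate, 2-4 Hz)
    gill_carrier: float = 12.0     # intra-burst oscillation frequency, Hz
    gill_decay: float = 0.06       # burst decay time constant, s

    @classmethod
    def none(cls) -> "NoiseParams":
        """Noise-free configuration (parameter-recovery oracles)."""
        return cls(baseline_amp=0.0, mains_amp=0.0, white_sd=0.0, gill_amp=0.0)


@dataclass(frozen=True)
class AnomalyParams:
    """Anomaly pattern to inject; defaults satisfy each defining inequality.

    kind
        One of ``none, AVB, SA, STE, bradycardia, tachycardia,
        sinus_arrhythmia``.
    drop_every
        AVB: every ``drop_every``-th beat loses its QRS and T (P retained).
    pause_beats
        SA: number of consecutive whole beats deleted; the resulting P-P gap
        is ``(pause_beats + 1)`` R-R intervals, so >= 2 guarantees a P-P
        interval strictly greater than twice the reference R-R.
    st_offset
        STE: constant offset (mV) added between S and T of every beat. The
        default keeps the elevated plateau below half the R amplitude so the
        R detection threshold is not crossed.
    target_bpm
        Brady-/tachycardia: mean heart rate to impose (< 90 / > 150).
    rr_spread
        Sinus arrhythmia: R-R alternates base -/+ ``rr_spread / 2`` so the
        max-min spread over any window of >= 2 beats equals ``rr_spread``
        (> 0.16 s to satisfy the diagnostic criterion).
    """

    kind: str = "none"
    drop_every: int = 2
    pause_beats: int = 2
    st_offset: float = 0.15
    target_bpm: float | None = None
    rr_spread: float = 0.20

    def __post_init__(self) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        if self.kind == "AVB" and self.drop_every < 2:
            raise ValueError("AVB requires drop_every >= 2")
        if self.kind == "SA" and self.pause_beats < 2:
            raise ValueError(
                "SA requires pause_beats >= 2 to make P-P strictly exceed 2 R-R"
            )
        if self.kind == "STE" and not self.st_offset > 0:
            raise ValueError("STE requires a positive st_offset")
        if self.kind == "bradycardia":
            bpm = self.target_bpm if self.target_bpm is not None else 60.0
            if not bpm < 90:
                raise ValueError("bradycardia requires target_bpm < 90")
        if self.kind == "tachycardia":
            bpm = self.target_bpm if self.target_bpm is not None else 180.0
            if not bpm > 150:
                raise ValueError("tachycardia requires target_bpm > 150")
        if self.kind == "sinus_arrhythmia" and not self.rr_spread > 0.16:
            raise ValueError("sinus arrhythmia requires rr_spread > 0.16 s")

    @property
    def effective_bpm(self) -> float | None:
        if self.kind == "bradycardia":
            return self.target_bpm if self.target_bpm is not None else 60.0
        if self.kind == "tachycardia":
            return self.target_bpm if self.target_bpm is not None else 180.0
        return None


@dataclass(frozen=True)
class SyntheticSpec:
    """Full specification of one synthetic record; the seed fixes the output."""

    fs: float = 1000.0
    duration: float = 10.0
    heart_rate: float = 120.0          # BPM mean
    rr_jitter_sd: float = 0.005        # s, Gaussian beat-to-beat jitter
    waves: Mapping[str, Wave] = field(default_factory=default_waves)
    noise: NoiseParams = field(default_factory=NoiseParams)
    anomaly: AnomalyParams = field(default_factory=AnomalyParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.heart_rate > 0:
            raise ValueError("heart_rate must be positive")
        if self.rr_jitter_sd < 0:
            raise ValueError("rr_jitter_sd must be non-negative")
        missing = set(WAVE_ORDER) - set(self.waves)
        if missing:
            raise ValueError(f"waves missing {sorted(missing)}")
        if self.duration < 60.0 / self.effective_heart_rate:
            raise ValueError("duration too short for one beat")

    @property
    def effective_heart_rate(self) -> float:
        bpm = self.anomaly.effective_bpm
        return bpm if bpm is not None else self.heart_rate

    def to_yaml(self, path: str | Path) -> Path:
        d = {
            "fs": self.fs,
            "duration": self.duration,
            "heart_rate": self.heart_rate,
            "rr_jitter_sd": self.rr_jitter_sd,
            "seed": self.seed,
            "waves": {
                k: {"amplitude": w.amplitude, "width": w.width, "offset": w.offset}
                for k, w in self.waves.items()
            },
            "noise": vars(self.noise).copy(),
            "anomaly": vars(self.anomaly).copy(),
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        d = yaml.safe_load(Path(path).read_text())
        waves = {k: Wave(**w) for k, w in d.pop("waves", {}).items()} or default_waves()
        noise = NoiseParams(**d.pop("noise", {}))
        anomaly = AnomalyParams(**d.pop("anomaly", {}))
        return cls(waves=waves, noise=noise, anomaly=anomaly, **d)


def awake_spec(**overrides) -> SyntheticSpec:
    """Awake-like spec: intrinsic rates around 200 BPM are typical."""
    overrides.setdefault("heart_rate", 200.0)
    return SyntheticSpec(**overrides)


def anesthetized_spec(**overrides) -> SyntheticSpec:
    """Anesthetized-like spec: ~100 BPM under tricaine."""
    overrides.setdefault("heart_rate", 100.0)
    return SyntheticSpec(**overrides)


@dataclass
class GroundTruth:
    """True fiducials and anomaly bookkeeping for a generated record.

    ``beats`` has one row per scheduled beat: columns ``beat`` (0-based),
    ``p_idx``, ``q_idx``, ``r_idx``, ``s_idx``, ``t_idx`` (sample indices;
    NaN where the wave was dropped) and ``dropped`` (AVB flag).
    """

    beats: pd.DataFrame
    pause: tuple[int, int] | None = None   # sample range deleted by SA
    st_offset: float = 0.0                 # mV added between S and T (STE)
    spec: SyntheticSpec | None = None

    @property
    def r_indices(self) -> np.ndarray:
        """True R sample indices of non-dropped beats, strictly increasing."""
        r = self.beats.loc[~self.beats["dropped"], "r_idx"].to_numpy(dtype=float)
        return r[~np.isnan(r)].astype(int)

    @property
    def p_indices(self) -> np.ndarray:
        p = self.beats["p_idx"].to_numpy(dtype=float)
        return p[~np.isnan(p)].astype(int)

    def to_annotation_frame(self) -> pd.DataFrame:
        """Long-form annotation table (beat, wave, sample_index)."""
        rows = []
        for _, row in self.beats.iterrows():
            for wave in WAVE_ORDER:
                idx = row[f"{wave.lower()}_idx"]
                if not np.isnan(idx):
                    rows.append({"beat": int(row["beat"]), "wave": wave,
                                 "sample_index": int(idx)})
        return pd.DataFrame(rows, columns=["beat", "wave", "sample_index"])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_annotation_frame().to_csv(path, index=False)
        return path


def _check_wave_separation(waves: Mapping[str, Wave], rr: float) -> None:
    # Degenerate when two wave centres fall within one sigma of the wider
    # wave: their peaks are then no longer distinct extrema.
    centers = [(waves[w].offset * rr, waves[w].width, w) for w in WAVE_ORDER]
    for (c1, w1, n1), (c2, w2, n2) in zip(centers, centers[1:]):
        if c2 - c1 < max(w1, w2):
            raise ValueError(f"overlapping wave windows: {n1} and {n2} at rr={rr}")


def beat_template(waves: Mapping[str, Wave], rr: float, fs: float) -> np.ndarray:
    """Render one beat of length ``round(rr * fs)`` samples.

    P precedes the QRS complex, which precedes T; with the default
    morphology the R peak is the global maximum of the beat.
    """
    n = int(round(rr * fs))
    if n < 1:
        raise ValueError("rr too short for the sampling rate")
    _check_wave_separation(waves, rr)
    t = np.arange(n) / fs
    beat = np.zeros(n)
    for name in WAVE_ORDER:
        w = waves[name]
        c = w.offset * rr
        beat += w.amplitude * np.exp(-0.5 * ((t - c) / w.width) ** 2)
    return beat


def _build_rr_series(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    base = 60.0 / spec.effective_heart_rate
    n_max = int(math.ceil(spec.duration / base)) + 2
    rr = np.full(n_max, base)
    if spec.anomaly.kind == "sinus_arrhythmia":
        half = spec.anomaly.rr_spread / 2.0
        rr += np.where(np.arange(n_max) % 2 == 0, -half, half)
    if spec.rr_jitter_sd > 0:
        rr = rr + rng.normal(0.0, spec.rr_jitter_sd, size=n_max)
    rr = np.maximum(rr, 0.5 * base)
    return rr


def generate(spec: SyntheticSpec) -> tuple[ECGRecord, GroundTruth]:
    """Generate one record plus its ground truth, reproducibly from the seed.

    The R-peak times are scheduled first (the jittered/modulated R-R series
    is exactly the series of R-to-R gaps, which is what the rate- and
    variability-based rules operate on); every other wave is then placed at
    its fractional offset within the actual R-R interval it occupies: S and
    T follow their own R, while the P and Q of each beat fall late in the
    preceding interval. The configured anomaly edits the beat schedule or
    waveform, and additive noise is superimposed last, so the clean wave
    geometry in the ground truth is exact.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration * fs))
    rr_series = _build_rr_series(spec, rng)
    waves = spec.waves
    r_off = waves["R"].offset
    # Fractional placements within an R-R interval of length L:
    #   S at R + d_s * L, T at R + d_t * L (same beat),
    #   P at R + d_p * L, Q at R + d_q * L (next beat, late in the interval).
    d_s = waves["S"].offset - r_off
    d_t = waves["T"].offset - r_off
    d_p = 1.0 - (r_off - waves["P"].offset)
    d_q = 1.0 - (r_off - waves["Q"].offset)
    if not (0 < d_s < d_t < d_p < d_q < 1):
        raise ValueError("wave offsets do not respect the R-S-T-P-Q interval order")

    # R schedule: first R sits r_off of one interval in; each beat must leave
    # room for its own T wave before the record ends.
    r_times: list[float] = []
    gaps: list[float] = []
    t = r_off * rr_series[0]
    for gap in rr_series:
        if t + d_t * gap > spec.duration + 1e-12:
            break
        r_times.append(t)
        gaps.append(gap)
        t += gap
    if not r_times:
        raise ValueError("duration too short for one beat")
    n_beats = len(r_times)

    dropped = np.zeros(n_beats, dtype=bool)
    deleted = np.zeros(n_beats, dtype=bool)
    if spec.anomaly.kind == "AVB":
        dropped[(np.arange(n_beats) + 1) % spec.anomaly.drop_every == 0] = True
    pause: tuple[int, int] | None = None
    if spec.anomaly.kind == "SA":
        k = spec.anomaly.pause_beats
        j = max(1, (n_beats - k) // 2)
        if j + k >= n_beats:
            raise ValueError("record too short for the requested sinus-arrest pause")
        deleted[j : j + k] = True
        pause = (int(round(r_times[j - 1] * fs)), int(round(r_times[j + k] * fs)))

    # Wave centres in seconds per beat; P/Q of beat k live in interval k-1.
    centers = np.full((n_beats, len(WAVE_ORDER)), np.nan)
    for k in range(n_beats):
        _check_wave_separation(waves, gaps[k])
        r_k = r_times[k]
        centers[k, WAVE_ORDER.index("R")] = r_k
        centers[k, WAVE_ORDER.index("S")] = r_k + d_s * gaps[k]
        centers[k, WAVE_ORDER.index("T")] = r_k + d_t * gaps[k]
        if k == 0:
            prev_r, prev_gap = r_times[0] - gaps[0], gaps[0]
        else:
            prev_r, prev_gap = r_times[k - 1], gaps[k - 1]
        centers[k, WAVE_ORDER.index("P")] = prev_r + d_p * prev_gap
        centers[k, WAVE_ORDER.index("Q")] = prev_r + d_q * prev_gap

    signal = np.zeros(n)
    tgrid = np.arange(n) / fs
    rows = []
    st_offset = spec.anomaly.st_offset if spec.anomaly.kind == "STE" else 0.0
    for k in range(n_beats):
        if deleted[k]:
            rows.append({"beat": k, **{f"{w.lower()}_idx": np.nan for w in WAVE_ORDER},
                         "dropped": False, "deleted": True})
            continue
        idxs: dict[str, float] = {}
        for wi, name in enumerate(WAVE_ORDER):
            if dropped[k] and name != "P":
                idxs[f"{name.lower()}_idx"] = np.nan
                continue
            w = waves[name]
            c = centers[k, wi]
            ci = int(round(c * fs))
            if ci < 0 or ci >= n:
                idxs[f"{name.lower()}_idx"] = np.nan
                continue
            lo = max(0, int((c - 6 * w.width) * fs))
            hi = min(n, int((c + 6 * w.width) * fs) + 1)
            signal[lo:hi] += w.amplitude * np.exp(
                -0.5 * ((tgrid[lo:hi] - c) / w.width) ** 2
            )
            idxs[f"{name.lower()}_idx"] = float(ci)
        if st_offset and not dropped[k]:
            s_i, t_i = idxs.get("s_idx"), idxs.get("t_idx")
            if s_i is not None and t_i is not None and not (np.isnan(s_i) or np.isnan(t_i)):
                signal[int(s_i) + 1 : int(t_i)] += st_offset
        rows.append({"beat": k, **idxs, "dropped": bool(dropped[k]), "deleted": False})

    noise = np.zeros(n)
    np_ = spec.noise
    if np_.baseline_amp:
        phase = rng.uniform(0, 2 * np.pi)
        noise += np_.baseline_amp * np.sin(2 * np.pi * np_.baseline_freq * tgrid + phase)
    if np_.mains_amp:
        phase = rng.uniform(0, 2 * np.pi)
        noise += np_.mains_amp * np.sin(2 * np.pi * np_.mains_freq * tgrid + phase)
    if np_.gill_amp:
        t0 = rng.uniform(0, 1.0 / np_.gill_rate)
        tb = t0
        while tb < spec.duration:
            lo = int(tb * fs)
            hi = min(n, lo + int(6 * np_.gill_decay * fs))
            if hi > lo:
                tt = tgrid[lo:hi] - tb
                noise[lo:hi] += (
                    np_.gill_amp
                    * np.exp(-tt / np_.gill_decay)
                    * np.sin(2 * np.pi * np_.gill_carrier * tt)
                )
            tb += 1.0 / np_.gill_rate
    if np_.white_sd:
        noise += rng.normal(0.0, np_.white_sd, size=n)

    beats = pd.DataFrame(rows)
    record = ECGRecord(
        samples=signal + noise,
        fs=fs,
        channel_id="synthetic",
        meta={"generator": "zfecg.synth", "seed": spec.seed,
              "anomaly": spec.anomaly.kind, "heart_rate": spec.effective_heart_rate},
    )
    truth = GroundTruth(beats=beats, pause=pause, st_offset=st_offset, spec=spec)
    return record, truth


def inject_anomaly(
    record: ECGRecord,
    truth: GroundTruth,
    anomaly: str,
    params: Mapping | None = None,
) -> tuple[ECGRecord, GroundTruth]:
    """Return the same scheduled recording with ``anomaly`` applied.

    Regenerates from the spec embedded in ``truth`` with the anomaly set and
    the same seed, so beat timing and noise draws match the input record
    wherever the anomaly leaves them untouched. Raises ``ValueError`` when
    the parameters cannot satisfy the anomaly's defining inequality.
    """
    if truth.spec is None:
        raise ValueError("ground truth carries no generator spec")
    ap = AnomalyParams(kind=anomaly, **dict(params or {}))
    return generate(replace(truth.spec, anomaly=ap))


def match_fiducials(truth: GroundTruth, fiducials, fs: float) -> pd.DataFrame:
    """Per-interval timing errors (ms) of extracted fiducials vs ground truth.

    Each extracted interval is matched to the truth beat whose R index is
    nearest its first R peak. Within the interval bounded by true beats
    (k, k+1): Q, S, T belong to beat k and P is the P wave of beat k+1.
    """
    tb = truth.beats[~truth.beats["deleted"] & ~truth.beats["dropped"]]
    true_r = tb["r_idx"].to_numpy(dtype=float)
    rows = []
    for fid in fiducials:
        k = int(np.argmin(np.abs(true_r - fid.r1_idx)))
        beat_k = tb.iloc[k]
        nxt = truth.beats[truth.beats["beat"] > beat_k["beat"]]
        nxt = nxt[~nxt["p_idx"].isna()]
        p_true = nxt.iloc[0]["p_idx"] if len(nxt) else np.nan
        ms = 1000.0 / fs
        rows.append({
            "interval_index": fid.interval_index,
            "r_err_ms": (fid.r1_idx - beat_k["r_idx"]) * ms,
            "q_err_ms": (fid.q_idx - beat_k["q_idx"]) * ms,
            "s_err_ms": (fid.s_idx - beat_k["s_idx"]) * ms,
            "t_err_ms": (fid.t_idx - beat_k["t_idx"]) * ms,
            "p_err_ms": (fid.p_idx - p_true) * ms if not np.isnan(p_true) else np.nan,
        })
    return pd.DataFrame(rows)


def segment_dataset(
    classes: tuple[str, ...] = ("AVB", "SA", "STE"),
    n_per_class: int = 60,
    seed: int = 0,
    fs: float = 1000.0,
    duration: float = 3.0,
    heart_rate: float = 92.0,
    segment_samples: int = 3000,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Labeled segment dataset mirroring the classification experiment.

    Each segment holds roughly 4-5 beats (~3000 samples at 1000 Hz). Classes
    are the mutant-line phenotypes (AVB, SA, STE); add ``"none"`` for a
    control class. Segments within a class share the generator defaults and
    differ by beat-timing jitter and noise draw, so classes are separable by
    construction. Returns (segments, labels) with labels as class-name
    strings in the order given.
    """
    rng = np.random.default_rng(seed)
    segments: list[np.ndarray] = []
    labels: list[str] = []
    noise = NoiseParams(baseline_amp=0.03, mains_amp=0.01, white_sd=0.02, gill_amp=0.0)
    for cls in classes:
        for _ in range(n_per_class):
            spec = SyntheticSpec(
                fs=fs,
                duration=duration,
                heart_rate=heart_rate,
                rr_jitter_sd=0.005,
                noise=noise,
                anomaly=AnomalyParams(kind=cls),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec, _ = generate(spec)
            segments.append(rec.samples[:segment_samples].copy())
            labels.append(cls)
    return segments, np.asarray(labels)
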