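"""Reading and writing ECG records and analysis artifacts.

The on-disk record format is plain comma-delimited text, one column per
channel, with the acquisition metadata (sampling rate, channel label, gain,
start offset) embedded as commented YAML header lines::

    # fs: 1000.0
    # channel_id: ch0
    # gain: 1.0
    # t0: 0.0
    # units: mV
    ch0
    0.012345
    ...

A full batch analysis saves exactly four artifacts: the raw record, the
filtered record, the per-beat feature table, and a JSON summary document
listing the diagnosed anomalies per R-R interval range alongside the
heart-rate-variability block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ECGRecord",
    "SummaryDocument",
    "read_record",
    "write_record",
    "write_outputs",
]

#: Fixed vocabulary of anomaly names used in summary documents (Table-1 style).
ANOMALY_NAMES = (
    "Bradycardia",
    "Tachycardia",
    "Arrhythmia",
    "Sinus Arrest",
    "ST Elevation",
    "ST Depression",
)


@dataclass
class ECGRecord:
    """A uniformly sampled single-channel ECG trace in millivolts.

    Parameters
    ----------
    samples
        Amplitude samples in mV.
    fs
        Sampling rate in Hz (zebrafish acquisitions digitize at 1000 Hz).
    channel_id
        Label of the acquisition channel.
    t0
        Start-time offset of the first sample in seconds.
    meta
        Free-form provenance (generator spec, gain, source file, ...).
    """

    samples: np.ndarray
    fs: float = 1000.0
    channel_id: str = "ch0"
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("ECGRecord requires a 1-D sample array with length >= 1")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (t0-offset)."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, **meta: Any) -> "ECGRecord":
        """Copy of this record with new samples (used by filtering stages)."""
        out = replace(self, samples=np.asarray(samples, dtype=float))
        out.meta = {**self.meta, **meta}
        return out


@dataclass
class SummaryDocument:
    """Summary of a batch analysis: per-interval anomaly table plus HRV block.

    ``anomaly_rows`` lists maximal runs of consecutive 1-based R-R intervals
    sharing an identical anomaly set, e.g. ``{"intervals": "1-2",
    "anomalies": ["Bradycardia"]}``; runs with no anomaly are omitted.
    """

    anomaly_rows: list[dict] = field(default_factory=list)
    hrv: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        last_end = 0
        for row in self.anomaly_rows:
            start, end = _parse_range(row["intervals"])
            if start <= last_end:
                raise ValueError("summary interval ranges must be disjoint and ascending")
            last_end = end
            for name in row["anomalies"]:
                if name not in ANOMALY_NAMES:
                    raise ValueError(f"unknown anomaly name: {name!r}")

    def to_dict(self) -> dict:
        return {
            "anomaly_table": self.anomaly_rows,
            "hrv": self.hrv,
            "config": self.config,
        }

    def to_json(self, **kwargs: Any) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SummaryDocument":
        return cls(
            anomaly_rows=list(d.get("anomaly_table", [])),
            hrv=dict(d.get("hrv", {})),
            config=dict(d.get("config", {})),
        )


def _parse_range(text: str) -> tuple[int, int]:
    parts = text.split("-")
    if len(parts) == 1:
        a = b = int(parts[0])
    else:
        a, b = int(parts[0]), int(parts[1])
    if a < 1 or b < a:
        raise ValueError(f"bad interval range {text!r}")
    return a, b


def _read_header_meta(path: Path) -> dict:
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                lines.append(line.lstrip("#"))
            else:
                break
    if not lines:
        return {}
    meta = yaml.safe_load("".join(lines))
    return meta if isinstance(meta, dict) else {}


def read_record(
    path: str | Path,
    fs: float | None = None,
    channel: int | str = 0,
    gain: float | None = None,
) -> ECGRecord:
    """Read one channel of a delimited-text ECG file as an :class:`ECGRecord`.

    Parameters
    ----------
    path
        CSV file, one column per channel, optional header row, optional
        commented YAML metadata lines.
    fs
        Sampling rate override in Hz. Required when the file carries no
        ``fs`` metadata.
    channel
        Column index (0-based) or column name.
    gain
        Acquisition gain divided out of the stored values to obtain mV
        (hardware chains may store amplified counts). Defaults to the file's
        ``gain`` metadata, else 1.

    Raises
    ------
    FileNotFoundError, ValueError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    meta = _read_header_meta(path)

    # Header row detection: a first non-comment line with any non-numeric
    # token is treated as column names.
    header: int | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            for tok in line.strip().split(","):
                try:
                    float(tok)
                except ValueError:
                    header = 0
            break
    df = pd.read_csv(path, comment="#", header=header)
    if df.empty:
        raise ValueError(f"no samples in {path}")

    if isinstance(channel, str):
        if channel not in df.columns:
            raise ValueError(f"channel {channel!r} not in {list(df.columns)}")
        col = df[channel]
        channel_id = channel
    else:
        if not 0 <= channel < df.shape[1]:
            raise ValueError(f"channel index {channel} out of range (file has {df.shape[1]})")
        col = df.iloc[:, channel]
        channel_id = str(df.columns[channel]) if header == 0 else f"ch{channel}"

    samples = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    if np.isnan(samples).any():
        raise ValueError(f"non-numeric rows in {path}")

    fs_eff = fs if fs is not None else meta.get("fs")
    if fs_eff is None:
        raise ValueError("sampling rate not given and absent from file metadata")
    gain_eff = gain if gain is not None else float(meta.get("gain", 1.0))
    if gain_eff != 1.0:
        samples = samples / gain_eff
    return ECGRecord(
        samples=samples,
        fs=float(fs_eff),
        channel_id=meta.get("channel_id", channel_id),
        t0=float(meta.get("t0", 0.0)),
        meta={k: v for k, v in meta.items() if k not in {"fs", "channel_id", "t0"}},
    )


def write_record(record: ECGRecord, path: str | Path, float_fmt: str = "%.6f") -> Path:
    """Write a record as CSV with commented YAML metadata header.

    Values are written with 6 decimal places, so a read/write round trip
    reproduces the samples to 1e-6 mV.
    """
    path = Path(path)
    header = {
        "fs": float(record.fs),
        "channel_id": record.channel_id,
        "t0": float(record.t0),
        "units": "mV",
    }
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(f"{record.channel_id}\n")
        for v in record.samples:
            fh.write((float_fmt % v) + "\n")
    return path


def write_outputs(
    record: ECGRecord,
    filtered: ECGRecord,
    features: pd.DataFrame,
    summary: SummaryDocument,
    out_dir: str | Path,
    stem: str = "ecg",
) -> dict[str, Path]:
    """Save the four batch-analysis artifacts to ``out_dir``.

    Exactly four files are written: raw record, filtered record, per-beat
    feature table, and the JSON summary document. Output bytes are
    deterministic for fixed inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "raw": out_dir / f"{stem}_raw.csv",
        "filtered": out_dir / f"{stem}_filtered.csv",
        "features": out_dir / f"{stem}_beats.csv",
        "summary": out_dir / f"{stem}_summary.json",
    }
    write_record(record, paths["raw"])
    write_record(filtered, paths["filtered"])
    features.to_csv(paths["features"], index=False, float_format="%.6f")
    paths["summary"].write_text(summary.to_json() + "\n")
    return paths
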