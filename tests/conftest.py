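"""Shared fixtures: synthetic records with ground truth, quiet-sample masks."""

from __future__ import annotations

import numpy as np
import pytest

from zfecg import synth


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 10 s record at 120 BPM with ground truth."""
    spec = synth.SyntheticSpec(noise=synth.NoiseParams.none(), seed=42)
    return synth.generate(spec)


@pytest.fixture(scope="session")
def noisy_record():
    """Default-noise 10 s record at 120 BPM with ground truth."""
    return synth.generate(synth.SyntheticSpec(seed=42))


def quiet_mask(record, truth, edge_s: float = 0.5) -> np.ndarray:
    """Boolean mask of baseline samples away from all waves and record edges."""
    fs = record.fs
    mask = np.ones(len(record), dtype=bool)
    edge = int(edge_s * fs)
    if edge:
        mask[:edge] = False
        mask[-edge:] = False
    pads = {"p_idx": 0.08, "q_idx": 0.04, "r_idx": 0.04, "s_idx": 0.04, "t_idx": 0.12}
    for _, beat in truth.beats.iterrows():
        for col, pad in pads.items():
            idx = beat[col]
            if not np.isnan(idx):
                lo = max(0, int(idx - pad * fs))
                mask[lo : int(idx + pad * fs)] = False
    return mask
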