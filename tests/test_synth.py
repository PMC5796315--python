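"""Generator oracles: beat morphology, schedules, anomaly injection, determinism."""

import math

import numpy as np
import pytest

from zfecg import synth
from zfecg.synth import (
    AnomalyParams,
    NoiseParams,
    SyntheticSpec,
    Wave,
    beat_template,
    default_waves,
    generate,
    inject_anomaly,
)


class TestBeatTemplate:
    def test_zero_amplitudes_give_zero_beat(self):
        waves = {k: Wave(0.0, w.width, w.offset) for k, w in default_waves().items()}
        beat = beat_template(waves, rr=0.5, fs=1000.0)
        assert beat.shape == (500,)
        np.testing.assert_array_equal(beat, 0.0)

    def test_argmax_is_r_offset_sample(self):
        waves = default_waves()
        beat = beat_template(waves, rr=0.5, fs=1000.0)
        assert np.argmax(beat) == round(waves["R"].offset * 0.5 * 1000)

    def test_wave_order_p_qrs_t(self):
        waves = default_waves()
        assert waves["P"].offset < waves["Q"].offset < waves["R"].offset
        assert waves["R"].offset < waves["S"].offset < waves["T"].offset

    def test_isolated_gaussian_integral_closed_form(self):
        # Only a P wave; its time integral must equal amplitude*width*sqrt(2*pi).
        waves = default_waves()
        lone = {k: Wave(w.amplitude if k == "P" else 0.0, w.width, w.offset)
                for k, w in waves.items()}
        fs = 10000.0
        beat = beat_template(lone, rr=1.0, fs=fs)
        integral = beat.sum() / fs
        expected = waves["P"].amplitude * waves["P"].width * math.sqrt(2 * math.pi)
        assert integral == pytest.approx(expected, rel=0.01)

    def test_overlapping_waves_raise(self):
        waves = default_waves()
        waves["Q"] = Wave(-0.2, 0.006, waves["R"].offset)  # Q on top of R
        with pytest.raises(ValueError, match="overlap"):
            beat_template(waves, rr=0.5, fs=1000.0)


class TestGenerate:
    def test_beat_count_matches_rate(self):
        spec = SyntheticSpec(duration=10.0, heart_rate=120.0, rr_jitter_sd=0.0,
                             noise=NoiseParams.none())
        _, truth = generate(spec)
        assert abs(len(truth.r_indices) - 20) <= 1

    def test_seed_reproducibility_bitwise(self):
        spec = SyntheticSpec(seed=7)
        rec1, truth1 = generate(spec)
        rec2, truth2 = generate(spec)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)
        assert truth1.beats.equals(truth2.beats)

    def test_different_seeds_differ(self):
        a, _ = generate(SyntheticSpec(seed=1))
        b, _ = generate(SyntheticSpec(seed=2))
        assert not np.array_equal(a.samples, b.samples)

    def test_truth_indices_strictly_increasing_and_in_bounds(self):
        rec, truth = generate(SyntheticSpec(seed=3))
        r = truth.r_indices
        assert np.all(np.diff(r) > 0)
        for col in ["p_idx", "q_idx", "r_idx", "s_idx", "t_idx"]:
            vals = truth.beats[col].dropna()
            assert ((vals >= 0) & (vals < len(rec))).all()

    def test_every_intact_beat_has_five_fiducials(self):
        _, truth = generate(SyntheticSpec(seed=3))
        intact = truth.beats[~truth.beats["dropped"] & ~truth.beats["deleted"]]
        assert not intact[["p_idx", "q_idx", "r_idx", "s_idx", "t_idx"]].isna().any().any()

    def test_too_short_duration_raises(self):
        with pytest.raises(ValueError, match="duration"):
            SyntheticSpec(duration=0.1, heart_rate=60.0)

    def test_scheduled_gaps_equal_detected_rr(self):
        # R-to-R sample gaps must match the jittered schedule, not a smoothed
        # version of it: the variability rules read these gaps directly.
        spec = SyntheticSpec(duration=10.0, rr_jitter_sd=0.02,
                             noise=NoiseParams.none(), seed=11)
        _, truth = generate(spec)
        gaps = np.diff(truth.r_indices) / spec.fs
        assert gaps.std() > 0.01  # jitter survives in the R schedule

    def test_yaml_round_trip(self, tmp_path):
        spec = SyntheticSpec(heart_rate=150.0, anomaly=AnomalyParams(kind="STE"), seed=9)
        path = spec.to_yaml(tmp_path / "spec.yaml")
        back = SyntheticSpec.from_yaml(path)
        assert back == spec
        rec1, _ = generate(spec)
        rec2, _ = generate(back)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)


class TestAnomalyInjection:
    def test_avb_2to1_keeps_all_p_drops_half_qrs(self):
        spec = SyntheticSpec(duration=10.0, heart_rate=120.0, rr_jitter_sd=0.0,
                             noise=NoiseParams.none(),
                             anomaly=AnomalyParams(kind="AVB", drop_every=2))
        _, truth = generate(spec)
        n_beats = len(truth.beats)
        assert n_beats == 20
        assert truth.beats["p_idx"].notna().sum() == 20
        assert len(truth.r_indices) == 10

    def test_sa_pause_exceeds_twice_rr_in_p_and_r(self):
        spec = SyntheticSpec(duration=10.0, heart_rate=120.0, rr_jitter_sd=0.0,
                             noise=NoiseParams.none(), anomaly=AnomalyParams(kind="SA"))
        _, truth = generate(spec)
        rr = 0.5
        pp = np.diff(truth.p_indices) / spec.fs
        assert pp.max() > 2 * rr
        assert truth.pause is not None

    def test_ste_offset_raises_st_segment_only(self):
        base = SyntheticSpec(duration=5.0, rr_jitter_sd=0.0, noise=NoiseParams.none())
        clean, _ = generate(base)
        spec = SyntheticSpec(duration=5.0, rr_jitter_sd=0.0, noise=NoiseParams.none(),
                             anomaly=AnomalyParams(kind="STE", st_offset=0.3))
        rec, truth = generate(spec)
        beat = truth.beats.iloc[0]
        mid = int((beat["s_idx"] + beat["t_idx"]) // 2)
        assert rec.samples[mid] - clean.samples[mid] == pytest.approx(0.3, abs=1e-9)
        before_s = int(beat["s_idx"]) - 40
        assert rec.samples[before_s] == pytest.approx(clean.samples[before_s], abs=1e-9)

    @pytest.mark.parametrize(
        "kind,check",
        [
            ("bradycardia", lambda gaps: 60.0 / gaps.mean() < 90),
            ("tachycardia", lambda gaps: 60.0 / gaps.mean() > 150),
        ],
    )
    def test_rate_anomalies_hit_their_band(self, kind, check):
        spec = SyntheticSpec(duration=10.0, noise=NoiseParams.none(),
                             anomaly=AnomalyParams(kind=kind), seed=1)
        _, truth = generate(spec)
        gaps = np.diff(truth.r_indices) / spec.fs
        assert check(gaps)

    def test_sinus_arrhythmia_spread_exceeds_criterion(self):
        spec = SyntheticSpec(duration=10.0, rr_jitter_sd=0.0, noise=NoiseParams.none(),
                             anomaly=AnomalyParams(kind="sinus_arrhythmia"))
        _, truth = generate(spec)
        gaps = np.diff(truth.r_indices) / spec.fs
        for i in range(len(gaps) - 9):
            window = gaps[i : i + 10]
            assert window.max() - window.min() > 0.16

    def test_inject_anomaly_regenerates_from_truth_spec(self):
        rec, truth = generate(SyntheticSpec(duration=10.0, seed=4,
                                            noise=NoiseParams.none()))
        rec2, truth2 = inject_anomaly(rec, truth, "AVB", {"drop_every": 2})
        assert truth2.beats["dropped"].sum() == len(truth.beats) // 2
        # non-dropped beats keep identical wave geometry
        keep = truth2.beats[~truth2.beats["dropped"]]
        orig = truth.beats[truth.beats["beat"].isin(keep["beat"])]
        np.testing.assert_array_equal(keep["r_idx"].to_numpy(), orig["r_idx"].to_numpy())

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "AVB", "drop_every": 1},
            {"kind": "SA", "pause_beats": 1},
            {"kind": "STE", "st_offset": 0.0},
            {"kind": "bradycardia", "target_bpm": 95},
            {"kind": "tachycardia", "target_bpm": 140},
            {"kind": "sinus_arrhythmia", "rr_spread": 0.1},
            {"kind": "hiccup"},
        ],
    )
    def test_unsatisfiable_or_unknown_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            AnomalyParams(**kwargs)


class TestSegmentDataset:
    def test_shapes_labels_and_determinism(self):
        segs, labels = synth.segment_dataset(n_per_class=3, seed=5)
        assert len(segs) == 9
        assert sorted(set(labels)) == ["AVB", "SA", "STE"]
        segs2, labels2 = synth.segment_dataset(n_per_class=3, seed=5)
        np.testing.assert_array_equal(labels, labels2)
        for a, b in zip(segs, segs2):
            np.testing.assert_array_equal(a, b)

    def test_segments_hold_about_four_to_five_beats(self):
        segs, labels = synth.segment_dataset(classes=("none",), n_per_class=2, seed=0)
        from zfecg.fiducials import detect_r_peaks
        from zfecg.io import ECGRecord

        for seg in segs:
            peaks = detect_r_peaks(ECGRecord(seg, fs=1000.0))
            assert 3 <= len(peaks) <= 6
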