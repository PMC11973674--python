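"""Peak-to-peak features, segment aggregation, normalization
conventions and pipeline trajectory recovery."""
import numpy as np
import pytest

from coiegm.features import (
    FeatureSeries,
    build_feature_series,
    feature_table,
    normalize_series,
    peak_to_peak,
    segment_feature,
)
from coiegm.pipeline import PipelineConfig
from coiegm.segmentation import BeatWindow, Segment
from coiegm.synthetic import (
    GROUP_DEFAULTS,
    GeneratorConfig,
    coi_trajectory,
    generate_lesion_recording,
    hf_survival_trajectory,
)
from conftest import run_record


class TestPeakToPeak:
    @pytest.mark.parametrize(
        "window, expected",
        [([1.0, -2.0, 3.0], 5.0), ([4.0, 4.0, 4.0], 0.0), ([-1.0], 0.0)],
    )
    def test_examples(self, window, expected):
        assert peak_to_peak(window) == expected

    def test_full_cycle_sine(self):
        t = np.arange(1000) / 1000.0
        assert peak_to_peak(3.0 * np.sin(2 * np.pi * t)) == pytest.approx(6.0, rel=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            peak_to_peak([])


def _segment_from_pps(pps, contaminated=None):
    contaminated = contaminated or [False] * len(pps)
    signal = np.zeros(10000)
    windows = []
    for i, (pp, bad) in enumerate(zip(pps, contaminated)):
        start = 500 + 1000 * i
        signal[start] = pp  # window PP = pp (rest of window is 0)
        windows.append(BeatWindow(start + 200, start, 150, contaminated=bad))
    seg = Segment(0, 0, 10000, 50.0, 55.0, beat_windows=windows)
    return seg, signal


class TestSegmentFeature:
    def test_median_over_beats(self):
        seg, sig = _segment_from_pps([1.0, 2.0, 3.0])
        assert segment_feature(seg, sig) == 2.0

    def test_single_beat(self):
        seg, sig = _segment_from_pps([1.7])
        assert segment_feature(seg, sig) == pytest.approx(1.7)

    def test_contaminated_beats_skipped(self):
        seg, sig = _segment_from_pps([1.0, 2.0, 100.0], [False, False, True])
        assert segment_feature(seg, sig) == 1.5

    def test_all_contaminated_rejected(self):
        seg, sig = _segment_from_pps([1.0, 2.0], [True, True])
        with pytest.raises(ValueError, match="no usable beats"):
            segment_feature(seg, sig)


class TestBuildFeatureSeries:
    def test_grid_structure(self, noisy_pfa_record):
        record, truth = noisy_pfa_record
        series, _ = run_record(record, truth)
        for band, s in series.items():
            assert np.sum(s.times_rel_s < 0) == 2  # exactly two pre-ablation points
            assert np.all(np.diff(s.times_rel_s) > 0)
        # unipolar series starts at the +30 s segment (center 35 s)
        lf_post = series["unipolar_LF"].times_rel_s
        assert lf_post[lf_post > 0][0] == pytest.approx(35.0)
        # bipolar series has every post segment
        hf_post = series["bipolar_HF"].times_rel_s
        assert hf_post[hf_post > 0][0] == pytest.approx(5.0)

    def test_hf_drops_at_ablation(self, noisy_pfa_record):
        record, truth = noisy_pfa_record
        series, _ = run_record(record, truth)
        hf = series["bipolar_HF"]
        first_post = np.nonzero((hf.times_rel_s > 0) & hf.valid_mask)[0][0]
        assert hf.normalized[first_post] < 0.35

    def test_sham_series_flat(self):
        cfg = GeneratorConfig(duration_post_s=60.0)
        record, truth = generate_lesion_recording(cfg, ("SHAM", "none"), seed=12)
        series, _ = run_record(record, truth)
        for band in ("bipolar_HF", "unipolar_LF"):
            s = series[band]
            vals = s.normalized[s.valid_mask]
            assert np.all(np.abs(vals - 1.0) < 0.1)

    def test_insufficient_preablation_rejected(self):
        cfg = GeneratorConfig(duration_pre_s=15.0, duration_post_s=40.0)
        record, truth = generate_lesion_recording(cfg, ("PFA", "T+"), seed=1)
        with pytest.raises((ValueError, RuntimeError), match="pre-ablation"):
            run_record(record, truth)


class TestNormalization:
    def _series(self, times, values):
        return FeatureSeries(
            lesion_id="lesion-000", channel_band="unipolar_LF",
            times_rel_s=np.asarray(times), values_mV=np.asarray(values),
            valid_mask=np.ones(len(times), dtype=bool),
        )

    def test_post30s_reference_is_one(self):
        s = normalize_series(self._series([-15, -5, 35, 45], [1.0, 1.1, 2.0, 1.5]), "post30s")
        assert s.normalized[2] == 1.0
        assert s.normalized[3] == 0.75

    def test_preablation_last_vs_first(self):
        raw = self._series([-15, -5, 35], [2.0, 4.0, 2.0])
        assert normalize_series(raw, "preablation", "last").normalized[1] == 1.0
        assert normalize_series(raw, "preablation", "first").normalized[0] == 1.0

    def test_flat_series_normalizes_to_one(self):
        s = normalize_series(self._series([-15, -5, 35], [2.0, 2.0, 2.0]), "preablation")
        np.testing.assert_allclose(s.normalized, 1.0)

    def test_scale_invariance(self):
        a = normalize_series(self._series([-15, -5, 35], [1.0, 2.0, 3.0]), "post30s")
        b = normalize_series(self._series([-15, -5, 35], [2.0, 4.0, 6.0]), "post30s")
        np.testing.assert_allclose(a.normalized, b.normalized)

    def test_missing_reference_rejected(self):
        s = self._series([35.0, 45.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="pre-ablation"):
            normalize_series(s, "preablation")
        zero_ref = self._series([-5.0, 35.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="positive"):
            normalize_series(zero_ref, "preablation")


class TestTrajectoryRecovery:
    def test_noise_free_pipeline_matches_generator(self, clean_pfa_record):
        record, truth = clean_pfa_record
        series, _ = run_record(record, truth)
        coi, hf_params = GROUP_DEFAULTS[truth.group_label]

        hf = series["bipolar_HF"]
        m = hf.valid_mask
        expected = hf_survival_trajectory(hf.times_rel_s[m], hf_params)
        assert np.max(np.abs(hf.normalized[m] - expected) / expected) < 0.1

        lf = series["unipolar_LF"]
        m = lf.valid_mask
        t_ref = lf.times_rel_s[m & (lf.times_rel_s > 0)][0]
        expected = coi_trajectory(lf.times_rel_s[m], coi) / coi_trajectory(t_ref, coi)
        assert np.max(np.abs(lf.normalized[m] - expected) / expected) < 0.1


def test_feature_table_schema(noisy_pfa_record):
    record, truth = noisy_pfa_record
    series, _ = run_record(record, truth)
    table = feature_table(series.values())
    assert set(table.columns) == {
        "lesion_id", "animal_id", "modality", "transmural",
        "channel_band", "t_rel_s", "value_mV", "normalized", "valid",
    }
    assert set(table["channel_band"].unique()) == {
        "bipolar_raw", "unipolar_raw", "bipolar_HF", "unipolar_LF",
    }
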