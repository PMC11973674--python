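"""Atrial windows, segment tiling, contamination flags, exclusion rules."""
import numpy as np
import pytest

from coiegm.core import SignalRecord
from coiegm.segmentation import (
    BeatWindow,
    ContaminationCriteria,
    Segment,
    apply_exclusion_rules,
    extract_atrial_windows,
    flag_contaminated_beats,
    segment_record,
    segment_table,
)
from coiegm.synthetic import ArtifactSpec, GeneratorConfig, generate_lesion_recording, inject_artifacts


def _zeros_record(n, abl, fs=1000.0):
    z = np.zeros(n)
    return SignalRecord(fs=fs, ecg=z, bipolar=z.copy(), unipolar=z.copy(), ablation_index=abl)


class TestAtrialWindows:
    def test_window_arithmetic(self):
        (w,) = extract_atrial_windows([1000], 1000.0, 10000)
        assert (w.start, w.stop, w.length) == (800, 950, 150)
        assert w.in_bounds

    def test_out_of_bounds_flagged(self):
        (w,) = extract_atrial_windows([100], 1000.0, 10000)
        assert not w.in_bounds

    def test_empty_and_unsorted(self):
        assert extract_atrial_windows([], 1000.0, 1000) == []
        with pytest.raises(ValueError):
            extract_atrial_windows([500, 400], 1000.0, 1000)


class TestSegmentGrid:
    def test_tiling_counts_default_durations(self):
        record = _zeros_record(630000, 30000)
        segs = segment_record(record, [])
        assert len(segs) == 63
        assert sum(s.is_pre for s in segs) == 3
        # tiling: contiguous, disjoint, covers the record
        assert segs[0].start == 0 and segs[-1].stop == record.n_samples
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.stop == b.start

    def test_boundary_anchored_at_ablation(self):
        record = _zeros_record(65000, 25000)
        segs = segment_record(record, [])
        assert any(s.start == 25000 for s in segs)
        first = segs[0]
        assert first.start == 0 and first.stop == 5000  # clipped partial segment

    def test_beat_on_boundary_goes_to_later_segment(self):
        record = _zeros_record(50000, 20000)
        windows = extract_atrial_windows([20000], 1000.0, record.n_samples)
        segs = segment_record(record, windows)
        holder = [s for s in segs if s.n_beats][0]
        assert holder.start == 20000

    def test_no_beats_gives_empty_segments(self):
        segs = segment_record(_zeros_record(40000, 20000), [])
        assert all(s.n_beats == 0 for s in segs)


class TestContamination:
    def test_clean_record_mostly_uncontaminated(self):
        cfg = GeneratorConfig(duration_post_s=120.0)
        record, truth = generate_lesion_recording(cfg, ("RFA", "T+"), seed=6)
        windows = extract_atrial_windows(truth.r_peak_indices, record.fs, record.n_samples)
        flagged = flag_contaminated_beats(record, windows)
        frac = np.mean([w.contaminated for w in flagged if w.in_bounds])
        assert frac < 0.05

    def test_saturation_interval_flags_unipolar_only(self, noisy_pfa_record):
        record, truth = noisy_pfa_record
        windows = extract_atrial_windows(truth.r_peak_indices, record.fs, record.n_samples)
        flagged = flag_contaminated_beats(
            record,
            windows,
            ContaminationCriteria(saturation_interval=truth.saturation_interval),
        )
        a, b = truth.saturation_interval
        inside = [w for w in flagged if w.start < b and w.stop > a]
        assert inside and all(w.is_contaminated("unipolar") for w in inside)
        # the bipolar channel stays usable through the saturation window
        assert not any(w.is_contaminated("bipolar") for w in inside)

    def test_amplitude_outlier_flagged(self):
        record, truth = generate_lesion_recording(
            GeneratorConfig(duration_post_s=40.0), ("RFA", "T+"), seed=8
        )
        record = record.copy()
        # low-gain channel, then one deflection far beyond 8x the
        # running median PP (yet below the rail)
        record.bipolar *= 0.1
        a = truth.beat_atrial_indices[10]
        record.bipolar[a - 20 : a + 20] += np.linspace(0.0, 5.0, 40)
        windows = extract_atrial_windows(truth.r_peak_indices, record.fs, record.n_samples)
        flagged = flag_contaminated_beats(record, windows)
        assert flagged[10].is_contaminated("bipolar")

    def test_injected_transients_recalled(self):
        cfg = GeneratorConfig(duration_post_s=120.0)
        record, truth = generate_lesion_recording(cfg, ("RFA", "T+"), seed=4)
        spec = ArtifactSpec(rate=0.1)
        corrupted, bad_idx = inject_artifacts(record, truth, spec, seed=5)
        windows = extract_atrial_windows(truth.r_peak_indices, record.fs, record.n_samples)
        flagged = flag_contaminated_beats(corrupted, windows)
        recalled = np.mean([flagged[i].contaminated for i in bad_idx])
        assert recalled >= 0.9


def _segment_with_beats(n_beats, n_bad, t_start_rel_s=50.0):
    windows = [
        BeatWindow(r_peak_index=1000 * i, start=1000 * i - 200, length=150,
                   contaminated=i < n_bad)
        for i in range(n_beats)
    ]
    return Segment(
        index=0, start=0, stop=10000,
        t_start_rel_s=t_start_rel_s, t_center_rel_s=t_start_rel_s + 5.0,
        beat_windows=windows,
        contaminated_fraction=n_bad / n_beats if n_beats else 0.0,
    )


class TestExclusionRules:
    def test_exactly_twenty_percent_retained(self):
        (seg,) = apply_exclusion_rules([_segment_with_beats(10, 2)])
        assert seg.valid_bipolar and seg.valid_unipolar

    def test_thirty_percent_excluded(self):
        (seg,) = apply_exclusion_rules([_segment_with_beats(10, 3)])
        assert not seg.valid_bipolar and not seg.valid_unipolar

    def test_zero_beats_invalid(self):
        (seg,) = apply_exclusion_rules([_segment_with_beats(0, 0)])
        assert not seg.valid_bipolar

    def test_unipolar_blanked_first_30s(self):
        for t0, expect in [(0.0, False), (10.0, False), (20.0, False), (30.0, True), (-10.0, True)]:
            (seg,) = apply_exclusion_rules([_segment_with_beats(10, 0, t_start_rel_s=t0)], "PFA")
            assert seg.valid_unipolar is expect
            assert seg.valid_bipolar  # bipolar unaffected by blanking

    def test_sham_not_blanked(self):
        (seg,) = apply_exclusion_rules([_segment_with_beats(10, 0, t_start_rel_s=0.0)], "SHAM")
        assert seg.valid_unipolar

    def test_exclusion_monotone_in_contamination(self):
        # adding contaminated beats can only invalidate, never re-validate
        prev_valid = True
        for n_bad in range(0, 11):
            (seg,) = apply_exclusion_rules([_segment_with_beats(10, n_bad)])
            assert prev_valid or not seg.valid_bipolar
            prev_valid = seg.valid_bipolar


def test_segment_table_schema():
    table = segment_table([_segment_with_beats(5, 1)], lesion_id="lesion-042")
    assert list(table.columns) == [
        "lesion_id", "segment_index", "t_center_rel_s", "n_beats",
        "contaminated_fraction", "valid_bipolar", "valid_unipolar",
    ]
    assert table.iloc[0]["contaminated_fraction"] == pytest.approx(0.2)
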