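"""Generator: closed-form trajectories, determinism, saturation,
spectral separation of the beat templates, cohort structure, artifacts."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coiegm.synthetic import (
    ArtifactSpec,
    COIParams,
    CohortConfig,
    GROUP_DEFAULTS,
    GeneratorConfig,
    HFSurvivalParams,
    biphasic_template,
    coi_plateau_template,
    coi_trajectory,
    generate_cohort,
    generate_lesion_recording,
    hf_survival_trajectory,
    inject_artifacts,
)


class TestCOITrajectory:
    @pytest.mark.parametrize(
        "t, params, expected",
        [
            (30.0, COIParams(jump=1.73, floor=0.8, tau_decay_s=120.0), 1.73),
            (1e9, COIParams(jump=1.73, floor=0.8, tau_decay_s=120.0), 0.8),
            # floor + (jump - floor)/e at t = 30 + tau
            (150.0, COIParams(jump=1.73, floor=0.8, tau_decay_s=120.0), 0.8 + 0.93 / math.e),
            (-5.0, COIParams(baseline_level=1.0), 1.0),
        ],
    )
    def test_closed_form(self, t, params, expected):
        assert coi_trajectory(t, params) == pytest.approx(expected, rel=1e-12)

    def test_saturation_window_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            coi_trajectory(10.0, COIParams())

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            coi_trajectory(float("nan"), COIParams())
        with pytest.raises(ValueError):
            coi_trajectory(60.0, COIParams(jump=float("inf")))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            coi_trajectory(60.0, COIParams(jump=0.5, floor=0.8))
        with pytest.raises(ValueError):
            coi_trajectory(60.0, COIParams(tau_decay_s=0.0))

    @given(
        jump=st.floats(0.0, 5.0),
        floor_frac=st.floats(0.0, 1.0),
        tau=st.floats(1.0, 500.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_monotone_and_bounded(self, jump, floor_frac, tau):
        p = COIParams(jump=jump, floor=jump * floor_frac, tau_decay_s=tau)
        t = np.linspace(30.0, 1200.0, 200)
        y = coi_trajectory(t, p)
        assert np.all(np.diff(y) <= 1e-12)
        assert np.all(y <= p.jump + 1e-12) and np.all(y >= p.floor - 1e-12)


class TestHFTrajectory:
    @pytest.mark.parametrize(
        "t, params, expected",
        [
            (0.0, HFSurvivalParams(drop=0.2, recovery_plateau=0.6, tau_recover_s=70.0), 0.2),
            (500.0, HFSurvivalParams(drop=0.2, recovery_plateau=0.2), 0.2),
            # plateau - (plateau - drop)/e at t = tau
            (70.0, HFSurvivalParams(0.2, 0.6, 70.0), 0.6 - 0.4 / math.e),
            (-1.0, HFSurvivalParams(), 1.0),
        ],
    )
    def test_closed_form(self, t, params, expected):
        assert hf_survival_trajectory(t, params) == pytest.approx(expected, rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            hf_survival_trajectory(0.0, HFSurvivalParams(drop=0.7, recovery_plateau=0.3))

    @given(
        drop=st.floats(0.0, 1.0),
        plateau_frac=st.floats(0.0, 1.0),
        tau=st.floats(1.0, 500.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_monotone_and_bounded(self, drop, plateau_frac, tau):
        plateau = drop + (1.0 - drop) * plateau_frac
        p = HFSurvivalParams(drop=drop, recovery_plateau=plateau, tau_recover_s=tau)
        t = np.linspace(0.0, 1200.0, 200)
        y = hf_survival_trajectory(t, p)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(y >= drop - 1e-12) and np.all(y <= plateau + 1e-12)


class TestLesionRecording:
    def test_determinism(self):
        cfg = GeneratorConfig(duration_post_s=40.0)
        a, _ = generate_lesion_recording(cfg, ("PFA", "T+"), seed=3)
        b, _ = generate_lesion_recording(cfg, ("PFA", "T+"), seed=3)
        for ch in ("ecg", "bipolar", "unipolar"):
            assert np.array_equal(a.channel(ch), b.channel(ch))

    def test_pfa_unipolar_saturated_at_rail(self, noisy_pfa_record):
        record, truth = noisy_pfa_record
        a, b = truth.saturation_interval
        assert b - a == round(30.0 * record.fs)
        assert np.all(record.unipolar[a:b] == 10.0)

    def test_rfa_and_sham_not_saturated(self):
        cfg = GeneratorConfig(duration_post_s=40.0)
        for group in (("RFA", "T+"), ("SHAM", "none")):
            _, truth = generate_lesion_recording(cfg, group, seed=1)
            assert truth.saturation_interval is None

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            generate_lesion_recording(GeneratorConfig(), ("CRYO", "T+"), seed=0)

    def test_r_peaks_strictly_increasing(self, noisy_pfa_record):
        _, truth = noisy_pfa_record
        assert np.all(np.diff(truth.r_peak_indices) > 0)

    def test_atrial_deflection_leads_r_peak(self, noisy_pfa_record):
        record, truth = noisy_pfa_record
        lead_ms = (truth.r_peak_indices - truth.beat_atrial_indices) * 1000.0 / record.fs
        assert np.all((lead_ms >= 50.0) & (lead_ms <= 200.0))


class TestSpectralSeparation:
    @staticmethod
    def _band_fraction(template, fs, lo, hi, nfft=8192):
        pad = np.zeros(nfft)
        pad[: len(template)] = template
        energy = np.abs(np.fft.rfft(pad)) ** 2
        f = np.fft.rfftfreq(nfft, 1.0 / fs)
        return energy[(f >= lo) & (f <= hi)].sum() / energy.sum()

    def test_bipolar_spike_is_high_frequency(self):
        tmpl = biphasic_template(1000.0, 1.5, 4.0)
        assert self._band_fraction(tmpl, 1000.0, 63.0, 500.0) >= 0.8

    def test_coi_plateau_is_low_frequency(self):
        tmpl = coi_plateau_template(1000.0, 1.5, 100.0)
        assert self._band_fraction(tmpl, 1000.0, 1.0, 16.0) >= 0.8


class TestCohort:
    def test_default_cohort_size_and_animals(self):
        cohort = generate_cohort(
            CohortConfig(generator=GeneratorConfig(duration_post_s=31.0)), seed=1
        )
        assert len(cohort) == 38
        assert len({m.animal_id for _, _, m in cohort}) == 5
        assert sum(m.modality == "PFA" for _, _, m in cohort) == 21
        assert sum(m.modality == "RFA" for _, _, m in cohort) == 17

    def test_empty_cohort(self):
        cfg = CohortConfig(n_pfa=0, n_rfa=0, n_sham=0, pfa_transmural=0, rfa_transmural=0)
        assert generate_cohort(cfg, seed=0) == []

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(n_pfa=-1), seed=0)
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(n_pfa=2, pfa_transmural=5), seed=0)

    def test_labels_reproducible(self):
        cfg = CohortConfig(
            n_pfa=4, n_rfa=2, pfa_transmural=2, rfa_transmural=1,
            generator=GeneratorConfig(duration_post_s=31.0),
        )
        a = [(m.lesion_id, m.modality, m.transmural) for _, _, m in generate_cohort(cfg, seed=9)]
        b = [(m.lesion_id, m.modality, m.transmural) for _, _, m in generate_cohort(cfg, seed=9)]
        assert a == b


class TestArtifacts:
    def test_zero_rate_is_identity(self, noisy_pfa_record):
        record, truth = noisy_pfa_record
        out, idx = inject_artifacts(record, truth, ArtifactSpec(rate=0.0), seed=1)
        assert idx.size == 0
        assert np.array_equal(out.bipolar, record.bipolar)

    def test_corrupted_count_matches_rate(self, noisy_pfa_record):
        record, truth = noisy_pfa_record
        n = len(truth.beat_atrial_indices)
        out, idx = inject_artifacts(record, truth, ArtifactSpec(rate=0.3), seed=1)
        assert len(idx) == round(0.3 * n)
        assert not np.array_equal(out.bipolar, record.bipolar)

    def test_full_rate_flags_every_beat(self, noisy_pfa_record):
        record, truth = noisy_pfa_record
        _, idx = inject_artifacts(record, truth, ArtifactSpec(rate=1.0), seed=1)
        assert len(idx) == len(truth.beat_atrial_indices)
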