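"""Synthetic ECG + iEGM generator with ground truth.

The porcine recordings that motivate this package are not publicly
deposited, so every downstream stage is validated against simulated
signals whose post-ablation dynamics are prescribed in closed form.

The signal model is deliberately phenomenological, not biophysical:

* Every heartbeat places a QRS complex on the ECG channel, a narrow
  biphasic deflection on the bipolar iEGM (energy concentrated above
  63 Hz) and a wider deflection followed by a 100-ms current-of-injury
  (COI) plateau on the unipolar iEGM (COI energy concentrated in
  1-16 Hz).
* After ablation the bipolar deflection amplitude follows
  :func:`hf_survival_trajectory` and the COI plateau follows
  :func:`coi_trajectory`, with per-group parameters that reproduce the
  characteristic differences between pulsed-field ablation (PFA),
  radiofrequency ablation (RFA) and sham catheter placement, and
  between transmural (T+) and nontransmural (T-) lesions.
* PFA energy saturates the unipolar amplifier: the channel is clamped
  at the rail for 30 s after delivery.
* Optional movement/contact artifacts corrupt individual beats and are
  reported as ground truth for the exclusion-rule tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import LesionMeta, SignalRecord

__all__ = [
    "COIParams",
    "HFSurvivalParams",
    "PulseSpec",
    "ArtifactSpec",
    "GeneratorConfig",
    "CohortConfig",
    "GroundTruth",
    "GROUP_DEFAULTS",
    "coi_trajectory",
    "hf_survival_trajectory",
    "generate_lesion_recording",
    "generate_cohort",
    "inject_artifacts",
    "biphasic_template",
    "coi_plateau_template",
    "qrs_template",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class COIParams:
    """Current-of-injury level on the unipolar channel, as a dimensionless
    multiple of the pre-ablation COI plateau amplitude.

    ``baseline_level`` is the contact-injury COI present before ablation;
    ``jump`` is the level at the first valid reading 30 s post-ablation;
    recovery decays exponentially with time constant ``tau_decay_s``
    towards ``floor`` (which may sit below baseline: most lesions end the
    observation period with less COI than before treatment).
    """

    baseline_level: float = 1.0
    jump: float = 1.73
    tau_decay_s: float = 150.0
    floor: float = 0.7

    def validate(self) -> None:
        vals = (self.baseline_level, self.jump, self.tau_decay_s, self.floor)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite COI parameters: {self}")
        if not self.jump >= self.floor >= 0:
            raise ValueError(f"COI parameters require jump >= floor >= 0: {self}")
        if self.tau_decay_s <= 0:
            raise ValueError(f"tau_decay_s must be positive: {self}")


@dataclass(frozen=True)
class HFSurvivalParams:
    """Surviving fraction of the pre-ablation bipolar deflection amplitude.

    The amplitude drops to ``drop`` immediately after ablation and relaxes
    exponentially (time constant ``tau_recover_s``) towards
    ``recovery_plateau``.  Groups without electrical recovery have
    ``recovery_plateau == drop``.
    """

    drop: float = 0.2
    recovery_plateau: float = 0.2
    tau_recover_s: float = 70.0

    def validate(self) -> None:
        vals = (self.drop, self.recovery_plateau, self.tau_recover_s)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite HF parameters: {self}")
        if not 0 <= self.drop <= self.recovery_plateau <= 1:
            raise ValueError(
                f"HF parameters require 0 <= drop <= recovery_plateau <= 1: {self}"
            )
        if self.tau_recover_s <= 0:
            raise ValueError(f"tau_recover_s must be positive: {self}")


@dataclass(frozen=True)
class PulseSpec:
    """Amplitude/width of a biphasic deflection template."""

    amplitude_mV: float
    width_ms: float


@dataclass(frozen=True)
class ArtifactSpec:
    """Movement/contact artifact model: a fraction ``rate`` of beats is
    corrupted by a large low-frequency transient.  The default amplitude
    exceeds the +-10 mV amplifier rail, so corrupted beats clip -- as
    real movement and contact-loss artifacts typically do."""

    rate: float = 0.0
    transient_amplitude_mV: float = 12.0
    transient_width_ms: float = 300.0


# Per-group dynamics.  PFA shows the +73% COI jump with
# transmurality-dependent recovery (faster for T-); RFA shows no initial
# COI increase; bipolar amplitude drops to ~20% for transmural lesions and
# recovers towards ~60% only for nontransmural PFA; nontransmural RFA
# drops only to ~60% and stays flat; SHAM is identity dynamics.
GROUP_DEFAULTS: dict[tuple[str, str], tuple[COIParams, HFSurvivalParams]] = {
    ("PFA", "T+"): (
        COIParams(baseline_level=1.0, jump=1.73, tau_decay_s=150.0, floor=0.7),
        HFSurvivalParams(drop=0.2, recovery_plateau=0.2, tau_recover_s=70.0),
    ),
    ("PFA", "T-"): (
        COIParams(baseline_level=1.0, jump=1.73, tau_decay_s=45.0, floor=0.5),
        HFSurvivalParams(drop=0.2, recovery_plateau=0.6, tau_recover_s=70.0),
    ),
    ("RFA", "T+"): (
        COIParams(baseline_level=1.0, jump=1.0, tau_decay_s=100.0, floor=0.8),
        HFSurvivalParams(drop=0.2, recovery_plateau=0.2, tau_recover_s=70.0),
    ),
    ("RFA", "T-"): (
        COIParams(baseline_level=1.0, jump=1.0, tau_decay_s=100.0, floor=0.8),
        HFSurvivalParams(drop=0.6, recovery_plateau=0.6, tau_recover_s=70.0),
    ),
    ("SHAM", "none"): (
        COIParams(baseline_level=1.0, jump=1.0, tau_decay_s=60.0, floor=1.0),
        HFSurvivalParams(drop=1.0, recovery_plateau=1.0, tau_recover_s=60.0),
    ),
}

#: First sample after PFA at which the unipolar channel is valid again.
UNIPOLAR_BLANKING_S = 30.0


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated lesion recording.

    Defaults emulate a swine atrial recording: 80 beats/min with +-3% RR
    jitter, 30 s of pre-ablation baseline and 10 min of follow-up at
    1 kHz.  The atrial deflection leads the R peak by ``atrial_offset_ms``
    so that it falls inside the 150-ms atrial analysis window
    [-200, -50] ms used downstream.  The bipolar deflection is much
    narrower than the unipolar one, which separates their spectral
    content (HF vs LF) by construction.
    """

    heart_rate_bpm: float = 80.0
    duration_pre_s: float = 30.0
    duration_post_s: float = 600.0
    fs: float = 1000.0
    qrs_amplitude_mV: float = 1.0
    atrial_offset_ms: float = 120.0
    bipolar_spike: PulseSpec = field(default_factory=lambda: PulseSpec(1.5, 4.0))
    unipolar_deflection: PulseSpec = field(default_factory=lambda: PulseSpec(0.2, 30.0))
    coi_amplitude_mV: float = 1.5
    coi_plateau_ms: float = 100.0
    coi_params: COIParams | None = None
    hf_params: HFSurvivalParams | None = None
    noise_sd_mV: float = 0.02
    rr_jitter_frac: float = 0.03
    saturation_rail_mV: float = 10.0
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_pre_s <= 0 or self.duration_post_s <= 0:
            raise ValueError("durations must be positive")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart rate must be positive")
        if not 50.0 <= self.atrial_offset_ms <= 200.0:
            raise ValueError(
                "atrial_offset_ms must place the atrial deflection inside "
                "[-200, -50] ms relative to the R peak"
            )
        if not self.bipolar_spike.width_ms < self.unipolar_deflection.width_ms:
            raise ValueError(
                "bipolar spike must be narrower than the unipolar deflection "
                "(HF vs LF separation by construction)"
            )
        if self.noise_sd_mV < 0 or self.saturation_rail_mV <= 0:
            raise ValueError("noise_sd_mV must be >= 0 and rail positive")


@dataclass
class GroundTruth:
    """Generator-side truth used to score downstream stages."""

    r_peak_indices: np.ndarray
    beat_atrial_indices: np.ndarray
    contaminated_beat_indices: np.ndarray
    saturation_interval: tuple[int, int] | None
    group_label: tuple[str, str]


@dataclass
class CohortConfig:
    """Cohort composition.  Defaults mirror the study scale: 38 lesions
    (21 PFA / 17 RFA) across 5 animals.  The PFA transmural split (15/6)
    and RFA split (8/9) follow the dose-titration outcome; both are
    configurable because per-group sizes are not uniquely pinned down."""

    n_pfa: int = 21
    n_rfa: int = 17
    n_sham: int = 0
    pfa_transmural: int = 15
    rfa_transmural: int = 8
    n_animals: int = 5
    animal_gain_sd: float = 0.2
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------


def _as_valid_times(t_rel_s) -> tuple[np.ndarray, bool]:
    t = np.asarray(t_rel_s, dtype=float)
    scalar = t.ndim == 0
    if not np.all(np.isfinite(t)):
        raise ValueError("t_rel_s contains non-finite values")
    return np.atleast_1d(t), scalar


def coi_trajectory(t_rel_s, p: COIParams):
    """COI level multiplier at ``t_rel_s`` seconds relative to ablation.

    Defined for pre-ablation times (returns ``baseline_level``) and from
    the first valid unipolar reading 30 s post-ablation onward, where it
    decays exponentially from ``jump`` towards ``floor``.  Times in
    [0, 30) s fall inside the amplifier-saturation blanking window and
    are rejected.
    """
    p.validate()
    t, scalar = _as_valid_times(t_rel_s)
    if np.any((t >= 0) & (t < UNIPOLAR_BLANKING_S)):
        raise ValueError(
            "COI is undefined in [0, 30) s post-ablation "
            "(unipolar amplifier saturation window)"
        )
    decay = p.floor + (p.jump - p.floor) * np.exp(
        -(np.maximum(t, UNIPOLAR_BLANKING_S) - UNIPOLAR_BLANKING_S) / p.tau_decay_s
    )
    out = np.where(t < 0, p.baseline_level, decay)
    return float(out[0]) if scalar else out


def hf_survival_trajectory(t_rel_s, p: HFSurvivalParams):
    """Surviving fraction of the bipolar deflection amplitude.

    1.0 before ablation; from t=0 it relaxes from ``drop`` towards
    ``recovery_plateau`` with time constant ``tau_recover_s`` (the
    bipolar channel is not blocked by amplifier saturation).
    """
    p.validate()
    t, scalar = _as_valid_times(t_rel_s)
    rec = p.recovery_plateau - (p.recovery_plateau - p.drop) * np.exp(
        -np.maximum(t, 0.0) / p.tau_recover_s
    )
    out = np.where(t < 0, 1.0, rec)
    return float(out[0]) if scalar else out


def _coi_multiplier(t_rel_s: float, p: COIParams) -> float:
    """Generator-internal COI level, extended through the blanking window
    at the ``jump`` level (continuous at 30 s).  On PFA records those
    samples are overwritten by the saturation rail anyway."""
    if t_rel_s < 0:
        return p.baseline_level
    if t_rel_s < UNIPOLAR_BLANKING_S:
        return p.jump
    return float(coi_trajectory(t_rel_s, p))


# --------------------------------------------------------------------------
# beat templates
# --------------------------------------------------------------------------


def _ricker(t: np.ndarray, a: float) -> np.ndarray:
    return (1.0 - (t / a) ** 2) * np.exp(-(t**2) / (2 * a**2))


def qrs_template(fs: float, amplitude_mV: float, width_ms: float = 60.0) -> np.ndarray:
    """Mexican-hat QRS complex; ``width_ms`` is the full tri-phasic span."""
    a = width_ms / 6.0 / 1000.0
    t = np.arange(-3 * a, 3 * a + 0.5 / fs, 1.0 / fs)
    return amplitude_mV * _ricker(t, a)


def biphasic_template(fs: float, amplitude_mV: float, width_ms: float) -> np.ndarray:
    """Derivative-of-Gaussian biphasic deflection.

    ``width_ms`` is the nominal full duration; the Gaussian sigma is a
    quarter of it, so the positive and negative lobes peak ``width/4``
    apart and the pulse decays within +-width/2.
    """
    sd = width_ms / 4.0 / 1000.0
    t = np.arange(-4 * sd, 4 * sd + 0.5 / fs, 1.0 / fs)
    g = -(t / sd) * np.exp(-(t**2) / (2 * sd**2))
    return amplitude_mV * g / np.exp(-0.5)


def coi_plateau_template(fs: float, amplitude_mV: float, plateau_ms: float = 100.0) -> np.ndarray:
    """Raised-cosine (Hann) COI plateau following the atrial deflection."""
    n = max(3, int(round(plateau_ms * fs / 1000.0)))
    return amplitude_mV * np.hanning(n)


def _gaussian(fs: float, amplitude_mV: float, sd_ms: float) -> np.ndarray:
    sd = sd_ms / 1000.0
    t = np.arange(-4 * sd, 4 * sd + 0.5 / fs, 1.0 / fs)
    return amplitude_mV * np.exp(-(t**2) / (2 * sd**2))


def _add_at(signal_arr: np.ndarray, template: np.ndarray, center: int) -> None:
    half = len(template) // 2
    a = center - half
    b = a + len(template)
    ta, tb = 0, len(template)
    if a < 0:
        ta, a = -a, 0
    if b > len(signal_arr):
        tb -= b - len(signal_arr)
        b = len(signal_arr)
    if tb > ta:
        signal_arr[a:b] += template[ta:tb]


def _add_from(signal_arr: np.ndarray, template: np.ndarray, start: int) -> None:
    _add_at(signal_arr, template, start + len(template) // 2)


# --------------------------------------------------------------------------
# record generation
# --------------------------------------------------------------------------


def _beat_times(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    rr = 60.0 / cfg.heart_rate_bpm
    total = cfg.duration_pre_s + cfg.duration_post_s
    times = []
    t = max(0.4, 0.5 * rr)
    while t < total - 0.4:
        times.append(t)
        t += rr * (1.0 + cfg.rr_jitter_frac * rng.uniform(-1.0, 1.0))
    return np.asarray(times)


def _corrupt_beats(
    bipolar: np.ndarray,
    unipolar: np.ndarray,
    atrial_idx: np.ndarray,
    spec: ArtifactSpec,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add large low-frequency transients to a deterministic count of
    beats (``round(rate * n_beats)``); returns corrupted beat indices."""
    n = len(atrial_idx)
    n_bad = int(round(spec.rate * n))
    if n_bad == 0:
        return np.array([], dtype=int)
    chosen = np.sort(rng.choice(n, size=min(n_bad, n), replace=False))
    tmpl = spec.transient_amplitude_mV * np.hanning(
        max(3, int(round(spec.transient_width_ms * fs / 1000.0)))
    )
    for b in chosen:
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        _add_at(bipolar, sign * tmpl, int(atrial_idx[b]))
        _add_at(unipolar, sign * tmpl, int(atrial_idx[b]))
    return chosen


def generate_lesion_recording(
    cfg: GeneratorConfig,
    group: tuple[str, str] = ("PFA", "T+"),
    seed: int | None = None,
    amplitude_gain: float = 1.0,
    lesion_id: str = "lesion-000",
    animal_id: str = "animal-0",
) -> tuple[SignalRecord, GroundTruth]:
    """Simulate one lesion recording with ground truth.

    Deterministic for a fixed ``(cfg, group, seed)``.  ``amplitude_gain``
    is the per-animal multiplicative amplitude factor (random intercept
    in the cohort model); it scales the deterministic signal content but
    not the amplifier noise.
    """
    cfg.validate()
    group = (group[0], group[1])
    if group not in GROUP_DEFAULTS:
        raise ValueError(f"unknown group label {group!r}; expected one of {sorted(GROUP_DEFAULTS)}")
    coi = cfg.coi_params if cfg.coi_params is not None else GROUP_DEFAULTS[group][0]
    hf = cfg.hf_params if cfg.hf_params is not None else GROUP_DEFAULTS[group][1]
    coi.validate()
    hf.validate()

    fs = cfg.fs
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    n_pre = int(round(cfg.duration_pre_s * fs))
    n_post = int(round(cfg.duration_post_s * fs))
    n = n_pre + n_post
    abl = n_pre

    times = _beat_times(cfg, rng)
    r_idx = np.round(times * fs).astype(int)
    atrial_idx = r_idx - int(round(cfg.atrial_offset_ms * fs / 1000.0))

    if cfg.noise_sd_mV > 0:
        ecg = rng.normal(0.0, cfg.noise_sd_mV, n)
        bip = rng.normal(0.0, cfg.noise_sd_mV, n)
        uni = rng.normal(0.0, cfg.noise_sd_mV, n)
    else:
        ecg = np.zeros(n)
        bip = np.zeros(n)
        uni = np.zeros(n)

    qrs = qrs_template(fs, cfg.qrs_amplitude_mV * amplitude_gain)
    twave = _gaussian(fs, 0.25 * cfg.qrs_amplitude_mV * amplitude_gain, 40.0)
    pwave = _gaussian(fs, 0.08 * cfg.qrs_amplitude_mV * amplitude_gain, 12.0)
    spike = biphasic_template(fs, cfg.bipolar_spike.amplitude_mV * amplitude_gain, cfg.bipolar_spike.width_ms)
    defl = biphasic_template(
        fs, cfg.unipolar_deflection.amplitude_mV * amplitude_gain, cfg.unipolar_deflection.width_ms
    )
    plateau = coi_plateau_template(fs, cfg.coi_amplitude_mV * amplitude_gain, cfg.coi_plateau_ms)
    plateau_start_off = int(round(cfg.unipolar_deflection.width_ms / 2.0 * fs / 1000.0))
    t_off = int(round(0.28 * fs))  # T wave 280 ms after R

    for r, a in zip(r_idx, atrial_idx):
        t_rel = (a - abl) / fs
        _add_at(ecg, qrs, r)
        _add_at(ecg, twave, r + t_off)
        _add_at(ecg, pwave, a)
        _add_at(bip, hf_survival_trajectory(t_rel, hf) * spike, a)
        _add_at(uni, defl, a)
        _add_from(uni, _coi_multiplier(t_rel, coi) * plateau, a + plateau_start_off)

    contaminated = _corrupt_beats(bip, uni, atrial_idx, cfg.artifact_spec, fs, rng)

    rail = cfg.saturation_rail_mV
    np.clip(bip, -rail, rail, out=bip)
    np.clip(uni, -rail, rail, out=uni)

    saturation: tuple[int, int] | None = None
    if group[0] == "PFA":
        sat_stop = min(n, abl + int(round(UNIPOLAR_BLANKING_S * fs)))
        uni[abl:sat_stop] = rail
        saturation = (abl, sat_stop)

    record = SignalRecord(
        fs=fs,
        ecg=ecg,
        bipolar=bip,
        unipolar=uni,
        ablation_index=abl,
        lesion_id=lesion_id,
        animal_id=animal_id,
        modality=group[0],
        transmural=group[1],
    )
    truth = GroundTruth(
        r_peak_indices=r_idx,
        beat_atrial_indices=atrial_idx,
        contaminated_beat_indices=contaminated,
        saturation_interval=saturation,
        group_label=group,
    )
    return record, truth


def inject_artifacts(
    record: SignalRecord,
    ground_truth: GroundTruth,
    spec: ArtifactSpec,
    seed: int = 0,
) -> tuple[SignalRecord, np.ndarray]:
    """Corrupt a deterministic fraction of beats in an existing record.

    Returns a modified copy and the corrupted beat indices (positions in
    ``ground_truth.beat_atrial_indices``), to serve as ground truth for
    the artifact-exclusion tests.
    """
    out = record.copy()
    rng = np.random.default_rng(seed)
    idx = _corrupt_beats(
        out.bipolar, out.unipolar, ground_truth.beat_atrial_indices, spec, record.fs, rng
    )
    rail = 10.0  # amplifier rail, mV
    np.clip(out.bipolar, -rail, rail, out=out.bipolar)
    np.clip(out.unipolar, -rail, rail, out=out.unipolar)
    return out, idx


def generate_cohort(
    cohort_cfg: CohortConfig | None = None,
    seed: int = 0,
) -> list[tuple[SignalRecord, GroundTruth, LesionMeta]]:
    """Simulate a cohort of lesions across animals.

    Per-lesion seeds are derived from the master seed; animal ids are
    assigned round-robin and each animal receives one multiplicative
    log-normal amplitude factor (sd ``animal_gain_sd`` on the log scale),
    the true random intercept that the mixed-effects analysis should
    recover.
    """
    cfg = cohort_cfg if cohort_cfg is not None else CohortConfig()
    for name in ("n_pfa", "n_rfa", "n_sham", "n_animals"):
        if getattr(cfg, name) < 0 or (name == "n_animals" and cfg.n_animals == 0):
            raise ValueError(f"{name} must be non-negative (n_animals positive)")
    if not 0 <= cfg.pfa_transmural <= cfg.n_pfa:
        raise ValueError("pfa_transmural must be within [0, n_pfa]")
    if not 0 <= cfg.rfa_transmural <= cfg.n_rfa:
        raise ValueError("rfa_transmural must be within [0, n_rfa]")

    groups: list[tuple[str, str]] = (
        [("PFA", "T+")] * cfg.pfa_transmural
        + [("PFA", "T-")] * (cfg.n_pfa - cfg.pfa_transmural)
        + [("RFA", "T+")] * cfg.rfa_transmural
        + [("RFA", "T-")] * (cfg.n_rfa - cfg.rfa_transmural)
        + [("SHAM", "none")] * cfg.n_sham
    )
    if not groups:
        return []

    ss = np.random.SeedSequence(seed)
    gain_rng = np.random.default_rng(ss.spawn(1)[0])
    gains = np.exp(gain_rng.normal(0.0, cfg.animal_gain_sd, cfg.n_animals))
    lesion_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(groups))]

    out = []
    for i, (group, lseed) in enumerate(zip(groups, lesion_seeds)):
        animal = i % cfg.n_animals
        meta = LesionMeta(
            lesion_id=f"lesion-{i:03d}",
            animal_id=f"animal-{animal}",
            modality=group[0],
            transmural=group[1],
            seed=lseed,
            amplitude_gain=float(gains[animal]),
        )
        record, truth = generate_lesion_recording(
            cfg.generator,
            group=group,
            seed=lseed,
            amplitude_gain=meta.amplitude_gain,
            lesion_id=meta.lesion_id,
            animal_id=meta.animal_id,
        )
        out.append((record, truth, meta))
    return out
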