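"""Core containers for multichannel ablation recordings."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Channel roles carried by every record, in storage order.
CHANNELS = ("ecg", "bipolar", "unipolar")

MODALITIES = ("PFA", "RFA", "SHAM")
TRANSMURAL_LABELS = ("T+", "T-", "none")


@dataclass
class SignalRecord:
    """One catheter-stable recording around a single ablation delivery.

    Channels are sampled synchronously at ``fs`` Hz and expressed in mV:
    a surface ECG lead used for QRS gating, a bipolar iEGM from the
    catheter tip electrode pair (local, high-frequency activity), and a
    unipolar iEGM referenced to a distant electrode -- the channel that
    carries the slow current-of-injury (COI) baseline shift.

    ``ablation_index`` is the sample at which ablation energy was
    delivered; all derived time axes are expressed in seconds relative
    to that instant.
    """

    fs: float
    ecg: np.ndarray
    bipolar: np.ndarray
    unipolar: np.ndarray
    ablation_index: int
    lesion_id: str = "lesion-000"
    animal_id: str = "animal-0"
    modality: str = "PFA"
    transmural: str = "none"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.bipolar = np.asarray(self.bipolar, dtype=float)
        self.unipolar = np.asarray(self.unipolar, dtype=float)
        lengths = {len(self.ecg), len(self.bipolar), len(self.unipolar)}
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {sorted(lengths)}")
        if not 0 <= self.ablation_index <= self.n_samples:
            raise ValueError(
                f"ablation_index {self.ablation_index} outside record "
                f"of {self.n_samples} samples"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.transmural not in TRANSMURAL_LABELS:
            raise ValueError(f"unknown transmurality label {self.transmural!r}")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    def time_rel_s(self) -> np.ndarray:
        """Sample times in seconds relative to the ablation instant."""
        return (np.arange(self.n_samples) - self.ablation_index) / self.fs

    def copy(self) -> "SignalRecord":
        return replace(
            self,
            ecg=self.ecg.copy(),
            bipolar=self.bipolar.copy(),
            unipolar=self.unipolar.copy(),
        )


@dataclass
class LesionMeta:
    """Per-lesion cohort metadata (manifest row)."""

    lesion_id: str
    animal_id: str
    modality: str
    transmural: str
    seed: int = 0
    amplitude_gain: float = 1.0
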