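"""Daubechies-6 multiresolution analysis and sub-band reconstruction.

A decimated DWT (``pywt.wavedec``) splits each signal into detail levels
D1..Dn plus the final approximation An; the reconstruction of a single
level with every other coefficient array zeroed gives that level's
contribution to the signal, and the contributions sum back to the input
(additive MRA, perfect reconstruction).  At fs = 1 kHz the nominal
dyadic band of detail level k is (fs/2^(k+1), fs/2^k), so levels 1-3
jointly span 62.5-500 Hz (the "63-500 Hz" high-frequency range that
carries the sharp bipolar depolarization component) and levels 6-9 span
~0.98-15.6 Hz (the "1-16 Hz" low-frequency range that carries the
unipolar current-of-injury shift).  The approximation below ~1 Hz is
deliberately excluded from the LF preset.

Boundary handling uses symmetric (half-sample) extension to limit edge
artifacts on 10-s analysis blocks.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pywt

__all__ = [
    "DEFAULT_WAVELET",
    "DEFAULT_LEVELS",
    "HF_PRESET",
    "LF_PRESET",
    "MRADecomposition",
    "band_edges",
    "mra_decompose",
    "reconstruct_band",
]

DEFAULT_WAVELET = "db6"
DEFAULT_LEVELS = 9
#: Detail levels whose union spans 62.5-500 Hz at fs=1 kHz.
HF_PRESET = (1, 2, 3)
#: Detail levels whose union spans ~0.98-15.6 Hz at fs=1 kHz.
LF_PRESET = (6, 7, 8, 9)


def band_edges(fs: float, level: int) -> tuple[float, float]:
    """Nominal dyadic frequency band (f_lo, f_hi) of detail level ``level``."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if level < 1:
        raise ValueError("level must be >= 1")
    return fs / 2 ** (level + 1), fs / 2**level


@dataclass
class MRADecomposition:
    """Additive MRA of one channel: ``details[k-1]`` is the full-length
    reconstruction of detail level k; ``approximation`` is the final
    low-pass remainder.  Their sum reproduces the input."""

    wavelet: str
    n_levels: int
    details: list[np.ndarray]
    approximation: np.ndarray
    fs: float | None = None

    def detail(self, level: int) -> np.ndarray:
        if not 1 <= level <= self.n_levels:
            raise ValueError(f"detail level {level} outside 1..{self.n_levels}")
        return self.details[level - 1]

    def reconstruct_all(self) -> np.ndarray:
        return sum(self.details) + self.approximation


def mra_decompose(
    x,
    fs: float | None = None,
    wavelet: str = DEFAULT_WAVELET,
    n_levels: int = DEFAULT_LEVELS,
    mode: str = "symmetric",
) -> MRADecomposition:
    """Decompose ``x`` into ``n_levels`` detail reconstructions plus the
    approximation.  Raises ``ValueError`` when the signal is too short to
    support the requested depth with the chosen wavelet."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(len(x), w.dec_len)
    if n_levels < 1 or n_levels > max_level:
        raise ValueError(
            f"signal of {len(x)} samples supports at most {max_level} "
            f"{wavelet} levels; requested {n_levels}"
        )
    coeffs = pywt.wavedec(x, w, mode=mode, level=n_levels)
    n = len(x)
    components = []
    for i in range(len(coeffs)):
        masked = [c if j == i else np.zeros_like(c) for j, c in enumerate(coeffs)]
        components.append(pywt.waverec(masked, w, mode=mode)[:n])
    # wavedec order is [An, Dn, ..., D1]; store details as [D1, ..., Dn]
    return MRADecomposition(
        wavelet=wavelet,
        n_levels=n_levels,
        details=components[1:][::-1],
        approximation=components[0],
        fs=fs,
    )


def reconstruct_band(
    mra: MRADecomposition,
    levels: Iterable[int],
    include_approximation: bool = False,
) -> np.ndarray:
    """Pointwise sum of the selected detail reconstructions.

    ``levels=HF_PRESET`` yields the 63-500 Hz content and
    ``levels=LF_PRESET`` the 1-16 Hz content at fs=1 kHz.  An empty
    selection returns zeros.
    """
    out = np.zeros_like(mra.approximation)
    for level in levels:
        out = out + mra.detail(level)
    if include_approximation:
        out = out + mra.approximation
    return out
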