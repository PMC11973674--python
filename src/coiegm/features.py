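"""Peak-to-peak sub-band features on the 10-s segment grid.

For every segment and channel band, the per-beat peak-to-peak (PP)
amplitude is measured inside the 150-ms atrial window on the
band-reconstructed signal, and the segment value is the median PP over
uncontaminated, in-bounds beats.  Two normalization conventions are
supported: division by a pre-ablation reference (used for the bipolar
high-frequency content) and division by the first valid post-ablation
value at +30 s (used for the unipolar low-frequency content, whose
earliest valid reading follows the amplifier-saturation window).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import SignalRecord
from .mra import DEFAULT_LEVELS, DEFAULT_WAVELET, HF_PRESET, LF_PRESET, mra_decompose, reconstruct_band
from .segmentation import Segment

__all__ = [
    "CHANNEL_BANDS",
    "FeatureSeries",
    "peak_to_peak",
    "segment_feature",
    "build_feature_series",
    "normalize_series",
    "feature_table",
]

CHANNEL_BANDS = ("bipolar_raw", "unipolar_raw", "bipolar_HF", "unipolar_LF")


@dataclass
class FeatureSeries:
    """Per-lesion time series of segment PP values for one channel band.

    ``times_rel_s`` are segment centers in seconds relative to ablation
    (two pre-ablation points, then one point per 10-s segment);
    ``valid_mask`` marks usable points; excluded segments remain in the
    grid as gaps, never as zeros.
    """

    lesion_id: str
    channel_band: str
    times_rel_s: np.ndarray
    values_mV: np.ndarray
    valid_mask: np.ndarray
    normalized: np.ndarray | None = None
    normalization_mode: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_rel_s = np.asarray(self.times_rel_s, dtype=float)
        self.values_mV = np.asarray(self.values_mV, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if np.any(np.diff(self.times_rel_s) <= 0):
            raise ValueError("times_rel_s must be strictly increasing")


def peak_to_peak(window_samples) -> float:
    """max - min of the window; non-negative by construction."""
    w = np.asarray(window_samples, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return float(np.max(w) - np.min(w))


def segment_feature(
    segment: Segment,
    band_signal: np.ndarray,
    signal_offset: int = 0,
    channel: str | None = None,
) -> float:
    """Median per-beat PP over uncontaminated, in-bounds beats.

    ``band_signal`` is indexed in record coordinates shifted by
    ``signal_offset`` (the start of the slice that was decomposed).
    ``channel`` selects the per-channel contamination verdict when one
    was recorded.  Raises ``ValueError`` when no usable beat remains.
    """
    pps = []
    for w in segment.beat_windows:
        if w.is_contaminated(channel) or not w.in_bounds:
            continue
        a = w.start - signal_offset
        b = a + w.length
        if a < 0 or b > len(band_signal):
            continue
        pps.append(peak_to_peak(band_signal[a:b]))
    if not pps:
        raise ValueError(f"segment {segment.index}: no usable beats")
    return float(np.median(pps))


def _band_signal(
    record: SignalRecord,
    segment: Segment,
    channel: str,
    levels: tuple[int, ...] | None,
    wavelet: str,
    n_levels: int,
    pad_samples: int,
) -> tuple[np.ndarray, int]:
    x = record.channel(channel)
    if levels is None:
        return x, 0
    # pad on the left so atrial windows of beats near the segment start
    # (whose window reaches into the previous segment) stay in-slice
    a = max(0, segment.start - pad_samples)
    sl = x[a : segment.stop]
    m = mra_decompose(sl, fs=record.fs, wavelet=wavelet, n_levels=n_levels)
    return reconstruct_band(m, levels), a


def build_feature_series(
    record: SignalRecord,
    segments: Sequence[Segment],
    bands: Iterable[str] = CHANNEL_BANDS,
    hf_levels: tuple[int, ...] = HF_PRESET,
    lf_levels: tuple[int, ...] = LF_PRESET,
    wavelet: str = DEFAULT_WAVELET,
    n_levels: int = DEFAULT_LEVELS,
    pad_s: float = 0.25,
) -> dict[str, FeatureSeries]:
    """One FeatureSeries per requested channel band.

    The pre-ablation grid has exactly two points (the last two complete
    pre-ablation segments); the post-ablation grid holds every post
    segment for bipolar bands and starts at the +30 s segment for
    unipolar bands.  Requires at least 20 s of pre-ablation recording.
    """
    band_spec = {
        "bipolar_raw": ("bipolar", None),
        "unipolar_raw": ("unipolar", None),
        "bipolar_HF": ("bipolar", tuple(hf_levels)),
        "unipolar_LF": ("unipolar", tuple(lf_levels)),
    }
    seg_len = int(round(10.0 * record.fs))
    pre = [s for s in segments if s.is_pre and s.stop - s.start == seg_len]
    post = [s for s in segments if not s.is_pre]
    if len(pre) < 2:
        raise ValueError(
            "need at least 20 s of pre-ablation recording "
            "(two complete pre-ablation segments)"
        )
    pre = sorted(pre, key=lambda s: s.t_center_rel_s)[-2:]
    post = sorted(post, key=lambda s: s.t_center_rel_s)
    pad = int(round(pad_s * record.fs))

    meta = {
        "animal_id": record.animal_id,
        "modality": record.modality,
        "transmural": record.transmural,
    }
    out: dict[str, FeatureSeries] = {}
    for band in bands:
        if band not in band_spec:
            raise KeyError(f"unknown channel band {band!r}")
        channel, levels = band_spec[band]
        grid = pre + post
        if channel == "unipolar":
            # the unipolar series starts at the first segment allowed by
            # the 30-s validity rule; earlier post segments are dropped
            grid = pre + [
                s for s in post if s.valid_unipolar or s.t_start_rel_s >= 30.0
            ]
        times, values, valid = [], [], []
        for seg in grid:
            ok = seg.valid_bipolar if channel == "bipolar" else seg.valid_unipolar
            value = np.nan
            if ok:
                try:
                    sig, offset = _band_signal(
                        record, seg, channel, levels, wavelet, n_levels, pad
                    )
                    value = segment_feature(seg, sig, offset, channel=channel)
                except ValueError:
                    ok = False
            times.append(seg.t_center_rel_s)
            values.append(value)
            valid.append(bool(ok and np.isfinite(value)))
        out[band] = FeatureSeries(
            lesion_id=record.lesion_id,
            channel_band=band,
            times_rel_s=np.asarray(times),
            values_mV=np.asarray(values),
            valid_mask=np.asarray(valid),
            meta=dict(meta),
        )
    return out


def normalize_series(
    series: FeatureSeries,
    mode: str,
    pre_reference: str = "last",
) -> FeatureSeries:
    """Return a copy with the ``normalized`` values filled in.

    ``mode="preablation"`` divides by a pre-ablation segment value
    (``pre_reference`` selects "last", closest to treatment -- the
    default -- or "first"); ``mode="post30s"`` divides by the first
    valid post-ablation value.  The normalized series equals exactly 1
    at the reference time.  A missing or non-positive reference makes
    the series unusable and raises ``ValueError``.
    """
    if mode == "none":
        return replace(series, normalized=None, normalization_mode="none")
    t = series.times_rel_s
    v = series.values_mV
    usable = series.valid_mask & np.isfinite(v)
    if mode == "preablation":
        idx = np.nonzero(usable & (t < 0))[0]
        if idx.size == 0:
            raise ValueError(f"{series.lesion_id}/{series.channel_band}: no valid pre-ablation reference")
        ref_i = idx[-1] if pre_reference == "last" else idx[0]
    elif mode == "post30s":
        idx = np.nonzero(usable & (t > 0))[0]
        if idx.size == 0:
            raise ValueError(f"{series.lesion_id}/{series.channel_band}: no valid post-ablation reference")
        ref_i = idx[0]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    ref = v[ref_i]
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(
            f"{series.lesion_id}/{series.channel_band}: normalization reference "
            f"must be positive, got {ref}"
        )
    return replace(series, normalized=v / ref, normalization_mode=mode)


def feature_table(series_list: Iterable[FeatureSeries]) -> pd.DataFrame:
    """Long-format table: one row per (lesion, band, timepoint)."""
    rows = []
    for s in series_list:
        norm = s.normalized if s.normalized is not None else np.full_like(s.values_mV, np.nan)
        for t, v, nv, ok in zip(s.times_rel_s, s.values_mV, norm, s.valid_mask):
            rows.append(
                {
                    "lesion_id": s.lesion_id,
                    "animal_id": s.meta.get("animal_id", ""),
                    "modality": s.meta.get("modality", ""),
                    "transmural": s.meta.get("transmural", ""),
                    "channel_band": s.channel_band,
                    "t_rel_s": t,
                    "value_mV": v,
                    "normalized": nv,
                    "valid": bool(ok),
                }
            )
    return pd.DataFrame(rows)
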