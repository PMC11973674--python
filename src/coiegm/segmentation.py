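"""Per-beat atrial windows, 10-second segments and exclusion rules.

The atrial analysis interval is the 150 ms window starting 200 ms before
each detected R peak, i.e. [R-200 ms, R-50 ms): it brackets the atrial
deflection while excluding the ventricular complex.  Records are tiled
into non-overlapping 10-s segments with one boundary pinned to the
ablation instant; a segment is dropped when more than 20% of its beats
are contaminated (exactly 20% is retained), and unipolar values are
invalid until 30 s post-ablation because PFA transiently saturates the
unipolar amplifier.

Sample indexing is 0-based with half-open intervals; a beat exactly on a
segment boundary belongs to the later segment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SignalRecord
from .synthetic import UNIPOLAR_BLANKING_S

__all__ = [
    "ATRIAL_WINDOW_PRE_MS",
    "ATRIAL_WINDOW_LEN_MS",
    "SEGMENT_LEN_S",
    "CONTAMINATION_MAX_FRACTION",
    "BeatWindow",
    "Segment",
    "ContaminationCriteria",
    "extract_atrial_windows",
    "flag_contaminated_beats",
    "segment_record",
    "apply_exclusion_rules",
    "segment_table",
]

ATRIAL_WINDOW_PRE_MS = 200.0
ATRIAL_WINDOW_LEN_MS = 150.0
SEGMENT_LEN_S = 10.0
#: Strictly more than this fraction of contaminated beats excludes a segment.
CONTAMINATION_MAX_FRACTION = 0.20


@dataclass
class BeatWindow:
    """Atrial analysis interval [start, start+length) for one heartbeat.

    ``contaminated`` is the union flag over analyzed channels;
    ``contaminated_by`` holds the per-channel verdicts (a beat whose
    unipolar window sits in the post-PFA saturation interval is still
    usable on the bipolar channel).
    """

    r_peak_index: int
    start: int
    length: int
    contaminated: bool = False
    in_bounds: bool = True
    contaminated_by: dict = field(default_factory=dict)

    @property
    def stop(self) -> int:
        return self.start + self.length

    def is_contaminated(self, channel: str | None = None) -> bool:
        if channel is None or channel not in self.contaminated_by:
            return self.contaminated
        return self.contaminated_by[channel]


@dataclass
class Segment:
    """One 10-s analysis block aligned to the ablation instant."""

    index: int
    start: int
    stop: int
    t_start_rel_s: float
    t_center_rel_s: float
    beat_windows: list[BeatWindow] = field(default_factory=list)
    contaminated_fraction: float = 0.0
    valid_bipolar: bool = True
    valid_unipolar: bool = True

    @property
    def n_beats(self) -> int:
        return len(self.beat_windows)

    @property
    def is_pre(self) -> bool:
        return self.t_start_rel_s < 0 and self.t_center_rel_s < 0


def extract_atrial_windows(
    r_peaks: Sequence[int], fs: float, record_length: int
) -> list[BeatWindow]:
    """One window per R peak; windows reaching outside the record are
    marked ``in_bounds=False`` and later excluded from features."""
    offset = int(round(ATRIAL_WINDOW_PRE_MS * fs / 1000.0))
    length = int(round(ATRIAL_WINDOW_LEN_MS * fs / 1000.0))
    r_arr = np.asarray(r_peaks, dtype=int)
    if r_arr.size and np.any(np.diff(r_arr) <= 0):
        raise ValueError("r_peaks must be strictly increasing")
    windows = []
    for r in r_arr:
        start = int(r) - offset
        windows.append(
            BeatWindow(
                r_peak_index=int(r),
                start=start,
                length=length,
                in_bounds=start >= 0 and start + length <= record_length,
            )
        )
    return windows


@dataclass(frozen=True)
class ContaminationCriteria:
    """Automatic stand-in for the visual artifact screen.

    A beat is contaminated when, on any analyzed channel inside its
    window, a sample touches the amplifier rail, the per-beat
    peak-to-peak exceeds ``outlier_factor`` times a running median of
    per-beat peak-to-peak values (centered window of ``rolling_beats``
    beats), or the window overlaps a declared saturation interval.
    """

    channels: tuple[str, ...] = ("bipolar", "unipolar")
    rail_mV: float = 10.0
    rail_tol_mV: float = 1e-9
    outlier_factor: float = 8.0
    rolling_beats: int = 21
    saturation_interval: tuple[int, int] | None = None


def flag_contaminated_beats(
    record: SignalRecord,
    windows: Sequence[BeatWindow],
    criteria: ContaminationCriteria = ContaminationCriteria(),
) -> list[BeatWindow]:
    """Return copies of ``windows`` with the ``contaminated`` flag set."""
    out = [replace(w, contaminated_by=dict(w.contaminated_by)) for w in windows]
    if not out:
        return out

    sat = criteria.saturation_interval
    for name in criteria.channels:
        x = record.channel(name)
        flags = np.zeros(len(out), dtype=bool)
        pp = np.full(len(out), np.nan)
        for i, w in enumerate(out):
            # amplifier saturation is a unipolar-channel phenomenon
            if sat is not None and name == "unipolar" and w.start < sat[1] and w.stop > sat[0]:
                flags[i] = True
            if not w.in_bounds:
                continue
            seg = x[w.start : w.stop]
            if np.max(np.abs(seg)) >= criteria.rail_mV - criteria.rail_tol_mV:
                flags[i] = True
            pp[i] = np.ptp(seg)
        ref = (
            pd.Series(pp)
            .rolling(criteria.rolling_beats, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        with np.errstate(invalid="ignore"):
            flags |= pp > criteria.outlier_factor * ref
        for w, f in zip(out, flags):
            w.contaminated_by[name] = bool(f)

    for w in out:
        w.contaminated = any(w.contaminated_by.values())
    return out


def segment_record(
    record: SignalRecord,
    windows: Sequence[BeatWindow],
    ablation_index: int | None = None,
) -> list[Segment]:
    """Tile the record into non-overlapping 10-s segments.

    The grid is anchored so one boundary coincides with the ablation
    instant; partial segments at the record edges are kept (they simply
    hold fewer beats).  Beats are assigned to the segment containing
    their R peak; a beat exactly on a boundary goes to the later segment.
    """
    abl = record.ablation_index if ablation_index is None else ablation_index
    fs = record.fs
    n = record.n_samples
    seg_len = int(round(SEGMENT_LEN_S * fs))
    first = abl - seg_len * math.ceil(abl / seg_len)

    segments: list[Segment] = []
    idx = 0
    for start in range(first, n, seg_len):
        a, b = max(start, 0), min(start + seg_len, n)
        if b <= a:
            continue
        beats = [
            replace(w, contaminated_by=dict(w.contaminated_by))
            for w in windows
            if a <= w.r_peak_index < b
        ]
        frac = (
            sum(w.contaminated for w in beats) / len(beats) if beats else 0.0
        )
        segments.append(
            Segment(
                index=idx,
                start=a,
                stop=b,
                t_start_rel_s=(a - abl) / fs,
                t_center_rel_s=((a + b) / 2.0 - abl) / fs,
                beat_windows=beats,
                contaminated_fraction=frac,
            )
        )
        idx += 1
    return segments


def apply_exclusion_rules(
    segments: Sequence[Segment],
    modality: str = "PFA",
    unipolar_blanking_s: float = UNIPOLAR_BLANKING_S,
) -> list[Segment]:
    """Set per-segment validity flags.

    A segment is invalid on a channel when it holds no beats or when
    strictly more than 20% of its beats are contaminated on that channel
    (the union flag is used for beats without per-channel verdicts).
    For PFA and RFA, unipolar validity additionally requires the segment
    to start at or after ablation + 30 s (or before ablation):
    post-ablation unipolar readings earlier than that fall in the
    amplifier-saturation window.
    """
    out = []
    for s in segments:
        seg = replace(
            s,
            beat_windows=[
                replace(w, contaminated_by=dict(w.contaminated_by)) for w in s.beat_windows
            ],
        )
        if seg.n_beats == 0:
            seg.valid_bipolar = False
            seg.valid_unipolar = False
        else:
            for channel, attr in (("bipolar", "valid_bipolar"), ("unipolar", "valid_unipolar")):
                frac = sum(w.is_contaminated(channel) for w in seg.beat_windows) / seg.n_beats
                setattr(seg, attr, frac <= CONTAMINATION_MAX_FRACTION)
        if modality in ("PFA", "RFA") and 0 <= seg.t_start_rel_s < unipolar_blanking_s:
            seg.valid_unipolar = False
        out.append(seg)
    return out


def segment_table(segments: Sequence[Segment], lesion_id: str = "") -> pd.DataFrame:
    """Long-format summary of the segmentation (one row per segment)."""
    return pd.DataFrame(
        {
            "lesion_id": lesion_id,
            "segment_index": [s.index for s in segments],
            "t_center_rel_s": [s.t_center_rel_s for s in segments],
            "n_beats": [s.n_beats for s in segments],
            "contaminated_fraction": [s.contaminated_fraction for s in segments],
            "valid_bipolar": [s.valid_bipolar for s in segments],
            "valid_unipolar": [s.valid_unipolar for s in segments],
        }
    )
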