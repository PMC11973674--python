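"""Slope-threshold QRS detection on the ECG channel.

The detector follows the So-Chan scheme: a five-point weighted slope
operator, an adaptive threshold proportional to a running mean of recent
per-beat maximum slopes, and a refractory period.  The ECG is prefiltered
with a zero-phase 10-Hz high-pass and the first 50 samples are zeroed so
a record that starts mid-QRS cannot poison the threshold initialization.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["QRSDetectorParams", "prefilter_ecg", "slope_signal", "detect_qrs", "evaluate_detection"]


@dataclass(frozen=True)
class QRSDetectorParams:
    """Detector tuning.  ``slope_filter_parameter / threshold_divisor``
    scales the running mean of recent per-beat maximum slopes into the
    detection threshold (the classic default is 4/16 = 1/4)."""

    hp_cutoff_hz: float = 10.0
    zeroed_leading_samples: int = 50
    slope_filter_parameter: float = 4.0
    threshold_divisor: float = 16.0
    refractory_ms: float = 200.0
    init_window_s: float = 2.0
    search_window_ms: float = 100.0
    slope_smooth_ms: float = 8.0
    history: int = 8

    def validate(self, fs: float) -> None:
        if min(
            self.hp_cutoff_hz,
            self.slope_filter_parameter,
            self.threshold_divisor,
            self.refractory_ms,
            self.init_window_s,
            self.search_window_ms,
        ) <= 0 or self.zeroed_leading_samples < 0:
            raise ValueError(f"QRS detector parameters must be positive: {self}")
        if round(self.refractory_ms * fs / 1000.0) < 1:
            raise ValueError("refractory period shorter than one sample")


def prefilter_ecg(x, fs: float, params: QRSDetectorParams = QRSDetectorParams()) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass, then zero the first
    ``zeroed_leading_samples`` samples.  Output length equals input length."""
    params.validate(fs)
    x = np.asarray(x, dtype=float)
    if fs <= 2 * params.hp_cutoff_hz:
        raise ValueError(f"fs={fs} too low for a {params.hp_cutoff_hz} Hz high-pass")
    if len(x) <= params.zeroed_leading_samples:
        raise ValueError("record shorter than the zeroed leading interval")
    sos = sps.butter(4, params.hp_cutoff_hz, btype="highpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    y[: params.zeroed_leading_samples] = 0.0
    return y


def slope_signal(x: np.ndarray, fs: float | None = None, smooth_ms: float = 0.0) -> np.ndarray:
    """Five-point weighted slope s(n) = -2x(n-2) - x(n-1) + x(n+1) + 2x(n+2).

    At 1 kHz the raw operator spans only 4 ms and amplifies wideband
    noise; ``smooth_ms > 0`` applies a centered moving average of that
    duration, which preserves the sustained QRS upstroke slope while
    suppressing sample-to-sample noise.
    """
    x = np.asarray(x, dtype=float)
    s = np.zeros_like(x)
    if len(x) >= 5:
        s[2:-2] = -2 * x[:-4] - x[1:-3] + x[3:-1] + 2 * x[4:]
    if smooth_ms > 0 and fs is not None:
        win = max(1, int(round(smooth_ms * fs / 1000.0)))
        if win > 1:
            s = np.convolve(s, np.ones(win) / win, mode="same")
    return s


def _next_exceed(s: np.ndarray, start: int, threshold: float, chunk: int = 8192) -> int | None:
    i = start
    n = len(s)
    while i < n:
        hits = np.nonzero(s[i : i + chunk] > threshold)[0]
        if hits.size:
            return i + int(hits[0])
        i += chunk
    return None


def detect_qrs(
    x_filtered,
    fs: float,
    params: QRSDetectorParams = QRSDetectorParams(),
) -> np.ndarray:
    """Detect R peaks on a prefiltered ECG.

    Each slope-threshold crossing opens a ``search_window_ms`` window; the
    R peak is the maximum absolute filtered amplitude inside it (earliest
    sample on ties, as returned by argmax).  The threshold is
    ``slope_filter_parameter / threshold_divisor`` times a running
    median of the most recent per-beat maximum slopes, seeded from the
    first ``init_window_s`` seconds; the median (rather than a mean)
    keeps an isolated low-slope false detection from dragging the
    threshold down and cascading into double detections.  Detections are
    strictly increasing and at least one refractory period apart.
    """
    params.validate(fs)
    x = np.asarray(x_filtered, dtype=float)
    init_n = int(round(params.init_window_s * fs))
    if len(x) < init_n:
        raise ValueError(
            f"record of {len(x)} samples shorter than the "
            f"{params.init_window_s} s initialization window"
        )
    s = slope_signal(x, fs=fs, smooth_ms=params.slope_smooth_ms)
    refractory = max(1, int(round(params.refractory_ms * fs / 1000.0)))
    win = max(1, int(round(params.search_window_ms * fs / 1000.0)))
    scale = params.slope_filter_parameter / params.threshold_divisor

    recent: deque[float] = deque([max(float(s[:init_n].max()), 0.0)], maxlen=params.history)
    peaks: list[int] = []
    i = 0
    n = len(x)
    while i < n:
        threshold = scale * float(np.median(recent))
        j = _next_exceed(s, i, threshold)
        if j is None:
            break
        stop = min(j + win, n)
        r = j + int(np.argmax(np.abs(x[j:stop])))
        peaks.append(r)
        recent.append(float(s[j:stop].max()))
        i = max(r, j) + refractory
    return np.asarray(peaks, dtype=int)


def evaluate_detection(
    detected: np.ndarray,
    reference: np.ndarray,
    fs: float,
    tolerance_ms: float = 50.0,
) -> tuple[float, float]:
    """Greedy one-to-one matching of detections against reference peaks.

    Returns ``(sensitivity, positive_predictive_value)``; both are 1.0
    for empty reference and empty detections.
    """
    detected = np.sort(np.asarray(detected, dtype=int))
    reference = np.sort(np.asarray(reference, dtype=int))
    tol = tolerance_ms * fs / 1000.0
    if len(reference) == 0:
        return 1.0, (1.0 if len(detected) == 0 else 0.0)
    if len(detected) == 0:
        return 0.0, 1.0
    used = np.zeros(len(detected), dtype=bool)
    tp = 0
    for ref in reference:
        k = int(np.argmin(np.abs(detected - ref)))
        if not used[k] and abs(detected[k] - ref) <= tol:
            used[k] = True
            tp += 1
    return tp / len(reference), tp / len(detected)
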