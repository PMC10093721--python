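"""Preprocessing of PPG records: baseline removal, low-pass filtering,
windowed segmentation, and paired SBP/DBP reference extraction from the
arterial-pressure channel.

The stage order is fixed: median-filter baseline correction, zero-phase
Butterworth low-pass at 5 Hz, fixed-length windowing, then per-window
reference extraction by arterial-beat peak detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .signal_io import WaveformRecord

__all__ = [
    "Segment",
    "PreprocessConfig",
    "remove_baseline",
    "lowpass",
    "segment_signal",
    "extract_bp_refs",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class Segment:
    """One fixed-length analysis window of preprocessed PPG.

    ``sbp_ref``/``dbp_ref`` (mmHg) are absent (None) in inference-only mode.
    Sample coordinates are 0-based; the window covers ``[start_index,
    start_index + len(x))`` in the source record.
    """

    x: np.ndarray
    start_index: int
    fs: float
    sbp_ref: float | None = None
    dbp_ref: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if len(self.x) < 2:
            raise ValueError("segment must have at least 2 samples")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("segment contains non-finite samples")
        if (
            self.sbp_ref is not None
            and self.dbp_ref is not None
            and not self.sbp_ref > self.dbp_ref
        ):
            raise ValueError(
                f"sbp_ref ({self.sbp_ref}) must exceed dbp_ref ({self.dbp_ref})"
            )


@dataclass(frozen=True)
class PreprocessConfig:
    """Pipeline settings (defaults follow common PPG practice).

    Two median windows implement two-pass baseline estimation: the short
    pass flattens individual pulses, the long pass smooths the remaining
    steps into a drift estimate that is subtracted from the signal.
    """

    baseline_window1_s: float = 0.6
    baseline_window2_s: float = 1.2
    baseline_smooth_hz: float = 0.5
    lowpass_cutoff_hz: float = 5.0
    lowpass_order: int = 4
    segment_window_s: float = 8.0
    segment_overlap: float = 0.0
    peaks_min_distance_s: float = 0.33
    peaks_percentile: float = 60.0

    def with_(self, **kwargs) -> "PreprocessConfig":
        return replace(self, **kwargs)


def _odd_window(window_s: float, fs: float) -> int:
    w = int(round(window_s * fs))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def remove_baseline(
    x,
    fs: float,
    window_s: float = 0.6,
    window2_s: float | None = 1.2,
    smooth_hz: float | None = 0.5,
) -> np.ndarray:
    """Subtract a median-filter baseline-wander estimate.

    The raw estimate is a two-pass running median (``medfilt(x, w1)`` then
    ``medfilt(·, w2)``), whose sub-second windows track sub-0.5 Hz drift
    while flattening individual cardiac pulses. Because the raw median of
    an oscillatory pulse train still carries intra-beat ripple, the
    estimate is band-limited to the wander band with a zero-phase
    Butterworth low-pass at ``smooth_hz`` (baseline wander is by definition
    the sub-0.5 Hz component) before subtraction; this makes the correction
    idempotent on already-clean signals. Pass ``smooth_hz=None`` for the
    raw median estimate.
    """
    x = np.asarray(x, dtype=np.float64)
    if window_s * fs < 3:
        raise ValueError(f"median window {window_s} s spans <3 samples at {fs} Hz")
    w1 = _odd_window(window_s, fs)
    if w1 > len(x):
        raise ValueError(
            f"median window ({w1} samples) longer than signal ({len(x)})"
        )
    baseline = sps.medfilt(x, w1)
    if window2_s is not None:
        w2 = _odd_window(window2_s, fs)
        if w2 > len(x):
            raise ValueError(
                f"second median window ({w2} samples) longer than signal ({len(x)})"
            )
        baseline = sps.medfilt(baseline, w2)
    if smooth_hz is not None and 0 < smooth_hz < fs / 2:
        sos = sps.butter(4, smooth_hz, btype="low", fs=fs, output="sos")
        baseline = sps.sosfiltfilt(sos, baseline)
    return x - baseline


def lowpass(x, fs: float, cutoff_hz: float = 5.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    Zero-phase filtering preserves pulse timing, which the slope-based
    features depend on. Effective attenuation is twice the single-pass
    filter's (the response is squared).
    """
    x = np.asarray(x, dtype=np.float64)
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz outside (0, Nyquist={fs / 2} Hz)"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def segment_signal(
    x, fs: float, window_s: float = 8.0, overlap_frac: float = 0.0
) -> list[Segment]:
    """Fixed-length, left-aligned windows; the trailing partial is dropped.

    With ``N`` samples, window length ``L`` and step ``L·(1−overlap)``, the
    number of segments is ``floor((N − L)/step) + 1`` (0 if N < L).
    """
    x = np.asarray(x, dtype=np.float64)
    L = int(round(window_s * fs))
    if L < 16:
        raise ValueError(f"window of {window_s} s spans {L} < 16 samples at {fs} Hz")
    if not 0 <= overlap_frac < 1:
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    step = max(1, int(round(L * (1 - overlap_frac))))
    segments = []
    for start in range(0, len(x) - L + 1, step):
        segments.append(Segment(x[start : start + L], start_index=start, fs=fs))
    return segments


def _beat_extrema(abp: np.ndarray, fs: float, min_distance_s: float,
                  percentile: float):
    """Systolic peak indices/heights and the per-beat (pre-upstroke) minima.

    Peaks are local maxima above the given amplitude percentile with a
    refractory distance; each detected beat's diastolic value is the
    minimum over the inter-peak interval preceding its peak.
    """
    distance = max(1, int(round(min_distance_s * fs)))
    height = np.percentile(abp, percentile)
    peaks, _ = sps.find_peaks(abp, distance=distance, height=height)
    minima = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        minima.append(float(np.min(abp[a + 1 : b + 1])))
    return peaks, abp[peaks].astype(float), np.array(minima)


def extract_bp_refs(
    abp,
    fs: float,
    segments: list[Segment],
    min_distance_s: float = 0.33,
    percentile: float = 60.0,
) -> list[Segment]:
    """Fill each segment's SBP/DBP reference from the ABP channel.

    SBP is the mean of per-beat systolic maxima within the window; DBP the
    mean of per-beat minima (each taken over the interval preceding a
    systolic peak). Windows with no detectable beats — or only one peak, so
    no complete inter-peak interval — are excluded with a logged count.
    """
    abp = np.asarray(abp, dtype=np.float64)
    kept, excluded = [], 0
    for seg in segments:
        lo, hi = seg.start_index, seg.start_index + len(seg.x)
        if hi > len(abp):
            raise ValueError(
                f"ABP channel ({len(abp)} samples) does not cover segment "
                f"[{lo}, {hi})"
            )
        window = abp[lo:hi]
        peaks, heights, minima = _beat_extrema(
            window, fs, min_distance_s, percentile
        )
        if len(peaks) < 2 or len(minima) == 0:
            excluded += 1
            continue
        kept.append(
            Segment(
                seg.x,
                seg.start_index,
                seg.fs,
                sbp_ref=float(np.mean(heights)),
                dbp_ref=float(np.mean(minima)),
            )
        )
    if excluded:
        logger.info("extract_bp_refs: excluded %d window(s) with no usable beats",
                    excluded)
    return kept


def preprocess_pipeline(
    record: WaveformRecord, config: PreprocessConfig | None = None,
    require_abp: bool = True,
) -> list[Segment]:
    """remove_baseline → lowpass → segment → extract_bp_refs, in that order."""
    config = config or PreprocessConfig()
    ppg = record.channel("PPG")
    corrected = remove_baseline(
        ppg, record.fs, config.baseline_window1_s, config.baseline_window2_s,
        config.baseline_smooth_hz,
    )
    filtered = lowpass(
        corrected, record.fs, config.lowpass_cutoff_hz, config.lowpass_order
    )
    segments = segment_signal(
        filtered, record.fs, config.segment_window_s, config.segment_overlap
    )
    if not require_abp:
        return segments
    abp = record.channel("ABP")
    return extract_bp_refs(
        abp, record.fs, segments,
        config.peaks_min_distance_s, config.peaks_percentile,
    )
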