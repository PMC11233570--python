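"""Stride-interval extraction from the foot accelerometer.

The foot signal is reduced to its vector norm, integrated over time and
detrended to obtain a smooth speed-like trace with one dominant local
maximum per gait cycle; successive peak-time differences are the stride
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .preprocess import GaitRecording, PreprocessError, vector_norm

logger = logging.getLogger(__name__)

#: Physiologic stride-interval bounds (seconds).
STRIDE_BOUNDS = (0.4, 3.0)
MIN_STRIDES = 16


class StrideDetectionError(ValueError):
    pass


@dataclass
class StrideSeries:
    """Ordered stride intervals in seconds."""

    intervals: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise StrideDetectionError("intervals must be 1-D")
        if (self.intervals <= 0).any():
            raise StrideDetectionError("intervals must be positive")

    @property
    def n(self) -> int:
        return len(self.intervals)

    def to_csv(self, path) -> None:
        pd.DataFrame({"stride_interval_s": self.intervals}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StrideSeries":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(float), source={"source": str(path)})


def _nominal_stride_s(norm: np.ndarray, fs_hz: float) -> float:
    """Dominant period of the detrended acceleration norm, restricted to
    the physiologic stride-frequency band."""
    x = norm - norm.mean()
    nfft = int(2 ** np.ceil(np.log2(max(len(x), fs_hz / 0.01))))
    spec = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    lo, hi = 1.0 / STRIDE_BOUNDS[1], 1.0 / STRIDE_BOUNDS[0]
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any() or spec[in_band].max() <= 0:
        raise StrideDetectionError("cannot estimate nominal stride duration")
    f = freqs[in_band][np.argmax(spec[in_band])]
    return 1.0 / f


def detect_stride_times(rec: GaitRecording, nominal_stride_s: float | None = None,
                        detrend: str = "moving",
                        prominence_frac: float = 0.25) -> StrideSeries:
    """Detect stride intervals from a foot recording.

    Pipeline: vector norm -> cumulative time-integration -> detrend ->
    peak detection with a physiologic spacing constraint -> successive
    peak-time differences.

    Parameters
    ----------
    nominal_stride_s : float, optional
        Expected stride duration; estimated spectrally when omitted.
    detrend : {"moving", "linear"}
        Baseline removal for the integrated signal: subtraction of a
        moving-average baseline spanning two nominal strides (robust to
        slow drift, the default) or a single global linear fit.
    prominence_frac : float
        Minimum peak prominence as a fraction of the median prominence.
    """
    norm = vector_norm(rec)
    if nominal_stride_s is None:
        nominal_stride_s = _nominal_stride_s(norm, rec.fs_hz)
    speed = np.cumsum(norm) / rec.fs_hz
    if detrend == "moving":
        win = max(int(round(2 * nominal_stride_s * rec.fs_hz)), 3)
        baseline = uniform_filter1d(speed, size=win, mode="nearest")
        y = speed - baseline
    elif detrend == "linear":
        y = sps.detrend(speed, type="linear")
    else:
        raise ValueError(f"unknown detrend mode {detrend!r}")

    min_dist = max(int(round(0.5 * nominal_stride_s * rec.fs_hz)), 1)
    peaks, _ = sps.find_peaks(y, distance=min_dist)
    if len(peaks) >= 3:
        prom = sps.peak_prominences(y, peaks)[0]
        keep = prom >= prominence_frac * np.median(prom)
        peaks = peaks[keep]
    # boundary transients of the integration: drop first and last peak
    peaks = peaks[1:-1]
    if len(peaks) < MIN_STRIDES + 1:
        raise StrideDetectionError(f"too few strides ({max(len(peaks) - 1, 0)} intervals)")

    times = peaks / rec.fs_hz
    intervals = np.diff(times)
    out_of_range = (intervals <= STRIDE_BOUNDS[0]) | (intervals >= STRIDE_BOUNDS[1])
    if out_of_range.mean() > 0.10:
        raise StrideDetectionError(
            f"unreliable detection: {out_of_range.mean():.0%} of intervals outside "
            f"{STRIDE_BOUNDS} s"
        )
    logger.info("detect_stride_times: %d intervals, nominal stride %.3f s",
                len(intervals), nominal_stride_s)
    return StrideSeries(
        intervals,
        source={
            "peak_indices": peaks.tolist(),
            "nominal_stride_s": float(nominal_stride_s),
            "detrend": detrend,
            "prominence_frac": prominence_frac,
            "fs_hz": rec.fs_hz,
        },
    )
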