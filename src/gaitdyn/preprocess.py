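"""Preprocessing of lumbar accelerometer recordings.

Turns a raw tri-axial recording into analysis-ready signals: tilt
realignment so that gravity lies on the vertical axis, vector norm,
spectral cadence estimation, steady-segment selection, and
crop-plus-resample normalization to a fixed number of samples.

Axis convention throughout the package: channels ordered (AP, V, ML),
units of g, with the vertical axis carrying the +1 g static component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Normalization constants: each analysed bout is reduced to this many
#: steps and resampled to this many samples (75 samples per step,
#: 150 per stride).
N_STEPS = 250
SAMPLES_PER_STEP = 75
TOTAL_SAMPLES = N_STEPS * SAMPLES_PER_STEP  # 18750

#: Physiologic search band (Hz) for the step-frequency spectral peak.
#: Brackets older-adult cadence while rejecting the stride subharmonic.
STEP_FREQ_BAND = (1.2, 3.0)

AXES = ("AP", "V", "ML")


class PreprocessError(ValueError):
    """Raised when a recording violates a preprocessing precondition."""


@dataclass
class GaitRecording:
    """One walking bout from a tri-axial accelerometer.

    Parameters
    ----------
    samples : ndarray, shape (3, T)
        Acceleration in g, rows ordered (AP, V, ML).
    fs_hz : float
        Sampling rate in Hz.
    sensor : {"lumbar", "foot"}
    meta : dict
        Free-form provenance (file of origin, selection bounds, ...).
    """

    samples: np.ndarray
    fs_hz: float
    axes: tuple = AXES
    sensor: str = "lumbar"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise PreprocessError("samples must have shape (3, T)")
        if self.samples.shape[1] == 0:
            raise PreprocessError("empty recording")
        if not np.isfinite(self.samples).all():
            raise PreprocessError("recording contains missing samples")
        if self.fs_hz <= 0:
            raise PreprocessError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def axis(self, name: str) -> np.ndarray:
        return self.samples[self.axes.index(name.upper())]

    def copy_with(self, samples: np.ndarray, **meta) -> "GaitRecording":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return GaitRecording(samples, self.fs_hz, self.axes, self.sensor, new_meta)


@dataclass
class NormalizedSignal:
    """A 1-D signal cropped to ``N_STEPS`` steps and resampled to
    exactly ``TOTAL_SAMPLES`` samples (75 per step, 150 per stride)."""

    values: np.ndarray
    step_freq_hz: float
    n_steps: int = N_STEPS
    samples_per_step: int = SAMPLES_PER_STEP

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise PreprocessError("NormalizedSignal must be 1-D")
        if len(self.values) != self.total_samples:
            raise PreprocessError(
                f"NormalizedSignal must have exactly {self.total_samples} samples"
            )

    @property
    def total_samples(self) -> int:
        return self.n_steps * self.samples_per_step

    @property
    def samples_per_stride(self) -> int:
        return 2 * self.samples_per_step


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_accel_csv(path, sensor: str = "lumbar") -> GaitRecording:
    """Read a ``t,ap,v,ml`` CSV (seconds, g) into a :class:`GaitRecording`.

    The sampling rate is inferred from the median time step.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    missing = {"t", "ap", "v", "ml"} - set(cols)
    if missing:
        raise PreprocessError(f"CSV missing columns: {sorted(missing)}")
    t = df[cols["t"]].to_numpy(dtype=float)
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise PreprocessError("non-increasing time column")
    samples = np.vstack(
        [df[cols["ap"]].to_numpy(float), df[cols["v"]].to_numpy(float), df[cols["ml"]].to_numpy(float)]
    )
    return GaitRecording(samples, fs_hz=1.0 / dt, sensor=sensor, meta={"source": str(path)})


def write_accel_csv(path, rec: GaitRecording) -> None:
    t = np.arange(rec.n_samples) / rec.fs_hz
    df = pd.DataFrame({"t": t, "ap": rec.samples[0], "v": rec.samples[1], "ml": rec.samples[2]})
    df.to_csv(path, index=False)


def write_normalized_csv(path, sig: NormalizedSignal) -> None:
    pd.DataFrame({"value": sig.values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def moe_nilssen_correct(rec: GaitRecording) -> GaitRecording:
    """Realign a lumbar recording so mean gravity lies on the V axis.

    A fixed (time-invariant) rotation is derived from the segment means:
    first a pitch rotation in the AP-V plane nulls the mean AP component,
    then a roll rotation in the ML-V plane nulls the mean ML component.
    The composition is rigid, so per-sample vector norms are preserved.
    """
    mean_norm = float(np.mean(np.linalg.norm(rec.samples, axis=0)))
    if abs(mean_norm - 1.0) > 0.3:
        raise PreprocessError(
            f"not a quiet-gravity segment (mean |a| = {mean_norm:.3f} g)"
        )
    m_ap, m_v, m_ml = rec.samples.mean(axis=1)

    pitch = np.arctan2(m_ap, m_v)
    cp, sp = np.cos(pitch), np.sin(pitch)
    # rotation in AP-V plane about the ML axis
    r_pitch = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    m1 = r_pitch @ np.array([m_ap, m_v, m_ml])

    roll = np.arctan2(m1[2], m1[1])
    cr, sr = np.cos(roll), np.sin(roll)
    # rotation in ML-V plane about the AP axis
    r_roll = np.array([[1.0, 0.0, 0.0], [0.0, cr, sr], [0.0, -sr, cr]])

    rot = r_roll @ r_pitch
    out = rot @ rec.samples
    logger.info(
        "moe_nilssen_correct: pitch=%.3f deg roll=%.3f deg",
        np.degrees(pitch), np.degrees(roll),
    )
    return rec.copy_with(out, realigned=True,
                         pitch_deg=float(np.degrees(pitch)),
                         roll_deg=float(np.degrees(roll)))


def vector_norm(rec: GaitRecording) -> np.ndarray:
    """Per-sample Euclidean magnitude of the tri-axial signal (rotation
    invariant)."""
    return np.linalg.norm(rec.samples, axis=0)


def step_frequency(vertical: np.ndarray, fs_hz: float,
                   band: tuple = STEP_FREQ_BAND) -> float:
    """Step frequency (Hz) from the largest spectral peak of the vertical
    acceleration within a physiologic band.

    The FFT is zero-padded to reach a grid finer than 0.01 Hz and the
    peak is refined by parabolic interpolation of log-magnitude.
    """
    x = np.asarray(vertical, dtype=float)
    if len(x) < 16:
        raise PreprocessError("signal too short for spectral cadence estimation")
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(max(len(x), fs_hz / 0.005))))
    spec = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise PreprocessError("search band empty at this sampling rate")
    mags = spec[in_band]
    if mags.max() <= 0 or mags.max() < 5.0 * np.median(mags):
        raise PreprocessError("no clear spectral peak in band")
    idx = np.flatnonzero(in_band)[np.argmax(mags)]
    # parabolic refinement on log magnitude
    if 0 < idx < len(spec) - 1 and spec[idx - 1] > 0 and spec[idx + 1] > 0:
        a, b, c = np.log(spec[idx - 1: idx + 2])
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    return float((idx + shift) * fs_hz / nfft)


def select_steady_segment(rec: GaitRecording, step_freq_hz: float,
                          start: int | None = None, end: int | None = None,
                          min_active_s: float = 10.0,
                          trim_s: float = 5.0) -> GaitRecording:
    """Select the contiguous steady-walking segment used downstream.

    Explicit ``start``/``end`` sample indices are the primary interface
    (matching manual inspection); when absent, a sliding-window RMS
    heuristic on the detrended norm finds the longest active stretch
    (RMS above 3x the quiescent floor, sustained >= ``min_active_s``),
    then trims ``trim_s`` at each boundary.
    """
    if start is not None or end is not None:
        s = int(start or 0)
        e = int(end) if end is not None else rec.n_samples
        seg = rec.samples[:, s:e]
        mode = "manual"
    else:
        norm = np.linalg.norm(rec.samples, axis=0)
        win = max(int(rec.fs_hz), 8)
        hop = max(win // 4, 1)
        starts = np.arange(0, len(norm) - win + 1, hop)
        # per-window SD: immune to the DC offset between standing (~1 g)
        # and the global mean of a mixed recording
        act = np.array([np.std(norm[i:i + win]) for i in starts])
        quiet, loud = np.percentile(act, [1, 90])
        if loud <= 3.0 * max(quiet, 1e-9):
            # no quiescent part: the whole recording is treated as steady
            s, e = 0, rec.n_samples
            mode = "auto-full"
        else:
            active = act > 3.0 * max(quiet, 1e-9)
            best = (0, 0)
            i = 0
            while i < len(active):
                if active[i]:
                    j = i
                    while j < len(active) and active[j]:
                        j += 1
                    if j - i > best[1] - best[0]:
                        best = (i, j)
                    i = j
                else:
                    i += 1
            if best == (0, 0):
                raise PreprocessError("no active (walking) segment found")
            s = int(starts[best[0]])
            e = int(starts[best[1] - 1] + win)
            if (e - s) / rec.fs_hz < min_active_s:
                raise PreprocessError("active segment shorter than minimum duration")
            trim = int(trim_s * rec.fs_hz)
            if e - s > 2 * trim + win:
                s, e = s + trim, e - trim
            mode = "auto"
        seg = rec.samples[:, s:e]
    n_steps_avail = seg.shape[1] / rec.fs_hz * step_freq_hz
    if n_steps_avail < N_STEPS:
        raise PreprocessError(
            f"insufficient steps: segment holds ~{n_steps_avail:.0f} < {N_STEPS}"
        )
    logger.info("select_steady_segment: mode=%s start=%d end=%d", mode, s, e)
    return rec.copy_with(seg, segment_mode=mode, segment_start=s, segment_end=e)


def normalize_length(values: np.ndarray, fs_hz: float,
                     step_freq_hz: float) -> NormalizedSignal:
    """Crop to exactly ``N_STEPS`` steps, then resample to
    ``TOTAL_SAMPLES`` samples with a polyphase anti-aliased resampler.

    Cropping precedes resampling: the kept duration is
    ``N_STEPS / step_freq_hz`` seconds from the segment start.
    """
    x = np.asarray(values, dtype=float)
    n_keep = int(round(N_STEPS / step_freq_hz * fs_hz))
    if len(x) < n_keep:
        raise PreprocessError(
            f"input too short: {len(x)} samples < {n_keep} needed for {N_STEPS} steps"
        )
    x = x[:n_keep]
    g = np.gcd(TOTAL_SAMPLES, n_keep)
    y = sps.resample_poly(x, TOTAL_SAMPLES // g, n_keep // g)
    if len(y) > TOTAL_SAMPLES:
        y = y[:TOTAL_SAMPLES]
    elif len(y) < TOTAL_SAMPLES:
        y = np.pad(y, (0, TOTAL_SAMPLES - len(y)), mode="edge")
    return NormalizedSignal(y, step_freq_hz=step_freq_hz)
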