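"""Detrended fluctuation analysis (DFA-1) of stride-interval series.

Yields the scaling exponent alpha: ~0.5 for uncorrelated series, >0.5
for persistent (fractal-like) series, <0.5 for anti-persistent series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_BOX = 16
DEFAULT_N_BOXES = 18
MIN_SERIES_LEN = 32


class DFAError(ValueError):
    pass


@dataclass
class DFAResult:
    alpha: float
    box_sizes: np.ndarray
    fluct: np.ndarray
    fit_r2: float
    n_series: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"box_size": self.box_sizes, "fluctuation": self.fluct})


def evenly_spaced_box_sizes(n_min: int, n_max: int, k: int = DEFAULT_N_BOXES) -> np.ndarray:
    """``k`` integers approximately equally spaced on a log scale between
    ``n_min`` and ``n_max`` inclusive, deduplicated after rounding."""
    if n_min < 4 or n_max < n_min:
        raise DFAError("need n_max >= n_min >= 4")
    if n_min == n_max:
        return np.array([n_min])
    sizes = np.unique(np.rint(np.logspace(np.log10(n_min), np.log10(n_max), k)).astype(int))
    sizes = sizes[(sizes >= n_min) & (sizes <= n_max)]
    if len(sizes) < min(4, k):
        raise DFAError(f"fewer than {min(4, k)} distinct box sizes in [{n_min}, {n_max}]")
    return sizes


def _fluctuation(profile: np.ndarray, n: int) -> float:
    """RMS residual of per-window linear detrending, forward pass only;
    remainder samples at the tail are discarded."""
    n_win = len(profile) // n
    w = profile[: n_win * n].reshape(n_win, n)
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    slope = (w @ tc) / denom
    resid = w - w.mean(axis=1, keepdims=True) - slope[:, None] * tc
    return float(np.sqrt(np.mean(resid ** 2)))


def dfa_alpha(series, box_sizes=None) -> DFAResult:
    """DFA-1 scaling exponent of a stride-interval series.

    The profile is the cumulative sum of the mean-centered series; for
    each box size the profile is split into non-overlapping windows, a
    least-squares line is removed per window, and F(n) is the RMS of the
    pooled residuals.  Alpha is the OLS slope of log10 F(n) vs log10 n.

    ``series`` may be a :class:`~gaitdyn.strides.StrideSeries` or any
    1-D array.  Default box sizes: evenly log-spaced from 16 to N/2.
    """
    x = np.asarray(getattr(series, "intervals", series), dtype=float)
    n_series = len(x)
    if n_series < MIN_SERIES_LEN:
        raise DFAError(f"series too short for DFA (N={n_series} < {MIN_SERIES_LEN})")
    if np.ptp(x) == 0:
        raise DFAError("degenerate series: zero variance, alpha undefined")
    if box_sizes is None:
        box_sizes = evenly_spaced_box_sizes(MIN_BOX, n_series // 2)
    box_sizes = np.asarray(box_sizes, dtype=int)
    if (np.diff(box_sizes) <= 0).any():
        raise DFAError("box sizes must be strictly increasing")
    if box_sizes[-1] > n_series // 2:
        raise DFAError("largest box exceeds N/2")

    profile = np.cumsum(x - x.mean())
    fluct = np.array([_fluctuation(profile, int(n)) for n in box_sizes])
    if (fluct <= 0).any():
        raise DFAError("non-positive fluctuation encountered")
    log_n = np.log10(box_sizes)
    log_f = np.log10(fluct)
    slope, intercept = np.polyfit(log_n, log_f, 1)
    pred = slope * log_n + intercept
    ss_res = float(np.sum((log_f - pred) ** 2))
    ss_tot = float(np.sum((log_f - log_f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DFAResult(alpha=float(slope), box_sizes=box_sizes, fluct=fluct,
                     fit_r2=r2, n_series=n_series)
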