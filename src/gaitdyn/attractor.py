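"""State-space reconstruction by delay embedding.

Delay selection via the first minimum of the average mutual information
(AMI), dimension selection via global false nearest neighbors (GFNN),
and exact integer-indexed delay embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

AMI_BINS = 64
FNN_RTOL = 15.0
FNN_ATOL = 2.0
FNN_THRESHOLD = 0.01
DEFAULT_DIM = 5
DEFAULT_THEILER = 75
SAMPLES_PER_STRIDE = 150


class AttractorError(ValueError):
    pass


@dataclass
class EmbeddingParams:
    """Delay-embedding parameters; the dimension is fixed study-wide
    while the delay is estimated per signal."""

    dim: int = DEFAULT_DIM
    delay: int = 17
    theiler: int = DEFAULT_THEILER
    samples_per_stride: int = SAMPLES_PER_STRIDE

    def __post_init__(self):
        if self.dim < 1:
            raise AttractorError("dim must be >= 1")
        if self.delay < 1:
            raise AttractorError("delay must be >= 1")
        if self.theiler < 0:
            raise AttractorError("theiler must be >= 0")


@dataclass
class Attractor:
    points: np.ndarray  # (T - (m-1)*tau, m)
    params: EmbeddingParams
    source_len: int

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _signal_values(signal) -> np.ndarray:
    return np.asarray(getattr(signal, "values", signal), dtype=float)


def average_mutual_information(x: np.ndarray, lags, n_bins: int = AMI_BINS) -> np.ndarray:
    """AMI (nats) between x_t and x_{t+lag} from a 2-D histogram with
    equal-width bins over the observed range."""
    x = np.asarray(x, dtype=float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    out = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag == 0:
            a = b = x
        else:
            a, b = x[:-lag], x[lag:]
        h, _, _ = np.histogram2d(a, b, bins=[edges, edges])
        p = h / h.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        nz = p > 0
        out[i] = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return out


def ami_delay(signal, max_lag: int = 40, n_bins: int = AMI_BINS,
              rise_frac: float = 0.05) -> int:
    """Embedding delay: first minimum of the AMI curve.

    The histogram AMI estimate carries small binning ripples, so the
    minimum is detected with hysteresis: the running minimum is declared
    the delay once the curve has risen above it by ``rise_frac`` of the
    total drop from lag 0.  An uncorrelated signal (AMI collapsed at lag
    1 already) returns 1 with a warning; if no valley is confirmed below
    ``max_lag``, the argmin is returned with a warning.
    """
    x = _signal_values(signal)
    if max_lag < 2:
        raise AttractorError("max_lag must be >= 2")
    if np.ptp(x) == 0:
        raise AttractorError("constant signal: AMI undefined")
    if len(x) <= max_lag + 1:
        raise AttractorError("signal shorter than max_lag")
    ami = average_mutual_information(x, np.arange(0, max_lag + 1), n_bins)
    if ami[1] < 0.05 * ami[0]:
        warnings.warn("AMI negligible at lag 1 (uncorrelated signal); returning 1")
        return 1
    best_lag, best = 1, ami[1]
    for lag in range(2, max_lag + 1):
        if ami[lag] < best:
            best, best_lag = ami[lag], lag
        elif ami[lag] > best + rise_frac * (ami[0] - best):
            return best_lag
    warnings.warn(f"no AMI minimum confirmed below lag {max_lag}; "
                  f"returning argmin {best_lag}")
    return best_lag


def embed(signal, params: EmbeddingParams) -> Attractor:
    """Exact delay embedding: row i is [x(i), x(i+tau), ..., x(i+(m-1)tau)]."""
    x = _signal_values(signal)
    m, tau = params.dim, params.delay
    n_rows = len(x) - (m - 1) * tau
    if n_rows < 1:
        raise AttractorError(f"signal too short to embed: T={len(x)}, m={m}, tau={tau}")
    idx = np.arange(n_rows)[:, None] + np.arange(m)[None, :] * tau
    return Attractor(points=x[idx], params=params, source_len=len(x))


def gfnn_fractions(signal, delay: int, max_dim: int = 10,
                   rtol: float = FNN_RTOL, atol: float = FNN_ATOL,
                   theiler: int | None = None) -> np.ndarray:
    """False-nearest-neighbor fraction for m = 1..max_dim (Kennel
    criteria: distance-ratio test against ``rtol`` and attractor-size
    test against ``atol``).

    ``theiler`` excludes temporally close candidates from the neighbor
    search (default: the delay), which prevents trivial true neighbors
    from oversampled trajectories.
    """
    x = _signal_values(signal)
    if theiler is None:
        theiler = delay
    r_a = float(np.std(x))
    if r_a == 0:
        raise AttractorError("constant signal")
    fracs = np.empty(max_dim)
    for m in range(1, max_dim + 1):
        n_rows = len(x) - m * delay  # need x at i + m*tau for the (m+1)-th coord
        if n_rows < 10:
            fracs[m - 1:] = np.nan
            break
        pts = embed(x, EmbeddingParams(dim=m, delay=delay, theiler=theiler)).points[:n_rows]
        tree = cKDTree(pts)
        k = min(2 * theiler + 2, n_rows)
        dists, idxs = tree.query(pts, k=k)
        nn = np.full(n_rows, -1)
        nn_dist = np.full(n_rows, np.nan)
        rows = np.arange(n_rows)
        for col in range(1, k):
            cand = idxs[:, col]
            ok = (nn < 0) & (np.abs(cand - rows) > theiler) & (dists[:, col] > 0)
            nn[ok] = cand[ok]
            nn_dist[ok] = dists[ok, col]
        valid = nn >= 0
        extra = np.abs(x[rows[valid] + m * delay] - x[nn[valid] + m * delay])
        rd = nn_dist[valid]
        false_1 = extra / rd > rtol
        false_2 = np.sqrt(rd ** 2 + extra ** 2) / r_a > atol
        fracs[m - 1] = float(np.mean(false_1 | false_2)) if valid.any() else np.nan
    return fracs


def gfnn_dimension(signal, delay: int, max_dim: int = 10,
                   rtol: float = FNN_RTOL, atol: float = FNN_ATOL,
                   threshold: float = FNN_THRESHOLD,
                   theiler: int | None = None) -> int:
    """Smallest embedding dimension whose FNN fraction drops below
    ``threshold``; returns ``max_dim`` with a warning otherwise."""
    fracs = gfnn_fractions(signal, delay, max_dim, rtol, atol, theiler)
    for m, frac in enumerate(fracs, start=1):
        if np.isfinite(frac) and frac < threshold:
            return m
    warnings.warn(f"FNN fraction never fell below {threshold}; returning max_dim {max_dim}")
    return max_dim
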