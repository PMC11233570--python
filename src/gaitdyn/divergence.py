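"""Logarithmic divergence of nearby attractor trajectories.

Implements the nearest-neighbor divergence-curve construction (mean of
ln distance between initially neighboring trajectories, tracked
downstream with a Theiler exclusion window) and the extraction of the
short-term exponent (LDS, fit over 0-0.5 stride) and the long-term
exponent (ACI, fit over 5-12 strides by default), both in ln-divergence
per stride.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import attractor as attr
from . import preprocess as prep
from .attractor import Attractor, EmbeddingParams

logger = logging.getLogger(__name__)

DEFAULT_HORIZON = 1800  # samples = 12 strides at 150 samples/stride
LDS_RANGE = (0.0, 0.5)  # strides
ACI_RANGE = (5.0, 12.0)  # strides
AXES_WITH_NORM = ("AP", "V", "ML", "norm")


class DivergenceError(ValueError):
    pass


@dataclass
class DivergenceCurve:
    """Mean log-divergence ``<ln d_j(i)>`` versus horizon sample i."""

    mean_log_div: np.ndarray
    n_pairs: np.ndarray
    samples_per_stride: int = attr.SAMPLES_PER_STRIDE

    @property
    def horizon_samples(self) -> int:
        return len(self.mean_log_div) - 1

    @property
    def stride_axis(self) -> np.ndarray:
        return np.arange(len(self.mean_log_div)) / self.samples_per_stride

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "i": np.arange(len(self.mean_log_div)),
            "strides": self.stride_axis,
            "mean_log_div": self.mean_log_div,
            "n_pairs": self.n_pairs,
        })


@dataclass
class DivergenceExponents:
    lds: float
    aci: float
    fit_ranges: dict = field(default_factory=lambda: {"lds": LDS_RANGE, "aci": ACI_RANGE})
    axis: str = "norm"


def nearest_neighbors(points: np.ndarray, theiler: int,
                      ref_stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """For each reference index j (every ``ref_stride``-th point), the
    index j* of its Euclidean nearest neighbor subject to the temporal
    exclusion |j - j*| > theiler and d(j, j*) > 0.

    Returns (refs, neighbors) for the admissible references.
    """
    n = len(points)
    refs_all = np.arange(0, n, ref_stride)
    tree = cKDTree(points)
    k = min(2 * theiler + 3, n)
    found_ref, found_nn = [], []
    pending = refs_all
    while len(pending) and k <= n:
        dists, idxs = tree.query(points[pending], k=k)
        if k == 1:
            dists, idxs = dists[:, None], idxs[:, None]
        nn = np.full(len(pending), -1)
        for col in range(k):
            cand = idxs[:, col]
            ok = (nn < 0) & (np.abs(cand - pending) > theiler) & (dists[:, col] > 0)
            nn[ok] = cand[ok]
        got = nn >= 0
        found_ref.append(pending[got])
        found_nn.append(nn[got])
        pending = pending[~got]
        if k == n:
            break
        k = min(2 * k, n)
    refs = np.concatenate(found_ref) if found_ref else np.empty(0, int)
    nns = np.concatenate(found_nn) if found_nn else np.empty(0, int)
    if len(refs) < 0.5 * len(refs_all):
        raise DivergenceError(
            f"no admissible neighbor for {len(refs_all) - len(refs)} of "
            f"{len(refs_all)} references"
        )
    order = np.argsort(refs)
    return refs[order], nns[order]


def rosenstein_curve(att: Attractor, horizon: int = DEFAULT_HORIZON,
                     ref_stride: int = 1,
                     incomplete: str = "truncate") -> DivergenceCurve:
    """Divergence curve: for each admissible reference j with nearest
    neighbor j*, track d_j(i) = ||p_{j+i} - p_{j*+i}|| for i = 0..horizon
    while both trajectories remain inside the attractor; the curve value
    at i is the mean of ln d_j(i) over the pairs still contributing.

    ``incomplete`` controls pairs whose trajectories exit the attractor
    before ``horizon``: ``"truncate"`` (default) keeps them up to their
    last valid step, ``"drop"`` excludes them entirely so the averaged
    set is identical at every horizon step.
    """
    pts = att.points
    n = len(pts)
    refs, nns = nearest_neighbors(pts, att.params.theiler, ref_stride)
    limits = (n - 1) - np.maximum(refs, nns)
    if incomplete == "drop":
        keep = limits >= horizon
        if not keep.any():
            raise DivergenceError("no pair survives the full horizon")
        refs, nns, limits = refs[keep], nns[keep], limits[keep]
    elif incomplete != "truncate":
        raise ValueError(f"unknown incomplete mode {incomplete!r}")
    order = np.argsort(-limits)  # longest-lived pairs first
    refs, nns, limits = refs[order], nns[order], limits[order]
    # number of pairs contributing at horizon step i
    counts = np.searchsorted(-limits, -np.arange(horizon + 1), side="right")
    mean_log = np.full(horizon + 1, np.nan)
    n_contrib = np.zeros(horizon + 1, dtype=int)
    for i in range(horizon + 1):
        c = counts[i]
        if c == 0:
            break
        diff = pts[refs[:c] + i] - pts[nns[:c] + i]
        d2 = np.einsum("ij,ij->i", diff, diff)
        # coincident downstream points (degenerate periodic signals)
        # cannot contribute ln 0; drop them from the mean at this step
        nz = d2 > 0
        if nz.any():
            mean_log[i] = 0.5 * np.mean(np.log(d2[nz]))
        n_contrib[i] = int(nz.sum())
    return DivergenceCurve(mean_log, n_contrib,
                           samples_per_stride=att.params.samples_per_stride)


def fit_exponent(curve: DivergenceCurve, range_strides: tuple) -> float:
    """OLS slope of the divergence curve over ``range_strides`` (a, b),
    in ln-divergence per stride."""
    a, b = range_strides
    if not (a < b):
        raise DivergenceError("need a < b")
    if a < 0 or b * curve.samples_per_stride > curve.horizon_samples:
        raise DivergenceError(f"fit range {range_strides} outside curve horizon")
    i0 = int(round(a * curve.samples_per_stride))
    i1 = int(round(b * curve.samples_per_stride))
    sl = slice(i0, i1 + 1)
    y = curve.mean_log_div[sl]
    x = curve.stride_axis[sl]
    ok = np.isfinite(y) & (curve.n_pairs[sl] > 0)
    if ok.sum() < 3:
        raise DivergenceError("fewer than 3 curve points in fit range")
    slope = np.polyfit(x[ok], y[ok], 1)[0]
    return float(slope)


def divergence_curve_for_signal(values: np.ndarray, dim: int = attr.DEFAULT_DIM,
                                theiler: int = attr.DEFAULT_THEILER,
                                max_lag: int = 40, horizon: int = DEFAULT_HORIZON,
                                ref_stride: int = 1) -> tuple[DivergenceCurve, EmbeddingParams]:
    """AMI delay -> embedding -> divergence curve for one 1-D signal."""
    tau = attr.ami_delay(values, max_lag=max_lag)
    params = EmbeddingParams(dim=dim, delay=tau, theiler=theiler)
    att = attr.embed(values, params)
    curve = rosenstein_curve(att, horizon=horizon, ref_stride=ref_stride)
    return curve, params


def lds_aci_per_axis(rec: prep.GaitRecording, dim: int = attr.DEFAULT_DIM,
                     theiler: int = attr.DEFAULT_THEILER,
                     lds_range: tuple = LDS_RANGE, aci_range: tuple = ACI_RANGE,
                     realign: bool = True, remove_mean: bool = True,
                     ref_stride: int = 1, step_freq_hz: float | None = None,
                     return_curves: bool = False):
    """Per-axis and vector-norm divergence exponents of a lumbar bout.

    Runs realignment, length/rate normalization, embedding and the
    divergence curve for each axis (AP, V, ML) and for the vector norm.
    LDS is reported per axis only; ACI for all four.  Returns a dict
    mapping axis -> :class:`DivergenceExponents` (plus axis -> curve
    when ``return_curves``).
    """
    work = prep.moe_nilssen_correct(rec) if realign else rec
    if step_freq_hz is None:
        step_freq_hz = prep.step_frequency(work.axis("V"), work.fs_hz)
    signals = {name: work.axis(name) for name in ("AP", "V", "ML")}
    signals["norm"] = prep.vector_norm(rec)  # rotation-invariant: raw axes
    out, curves = {}, {}
    for name, sig in signals.items():
        x = sig - sig.mean() if remove_mean else sig
        ns = prep.normalize_length(x, work.fs_hz, step_freq_hz)
        curve, params = divergence_curve_for_signal(
            ns.values, dim=dim, theiler=theiler, ref_stride=ref_stride)
        lds = fit_exponent(curve, lds_range) if name != "norm" else np.nan
        aci = fit_exponent(curve, aci_range)
        out[name] = DivergenceExponents(
            lds=lds, aci=aci, fit_ranges={"lds": lds_range, "aci": aci_range},
            axis=name)
        curves[name] = curve
        logger.info("lds_aci_per_axis: axis=%s tau=%d lds=%.4f aci=%.4f",
                    name, params.delay, lds, aci)
    if return_curves:
        return out, curves
    return out


def tuning_sweep(curves: dict, ranges, level: float = 0.99,
                 n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Sweep candidate fit ranges: paired effect size between conditions
    and between-lap ICC, per range and axis.

    Parameters
    ----------
    curves : dict
        ``(participant, condition, lap, axis) -> DivergenceCurve`` with
        condition in {"normal", "metronome"} and lap in {"out", "return"}.
    ranges : list of (a, b)
        Candidate fit ranges in stride units.

    Returns a tidy table with columns (a, b, axis, es, icc, n_pairs).
    Effect sizes use lap-averaged exponents; ICC uses the unaveraged
    normal-walking laps.
    """
    from .reliability_stats import StatsError, hedges_g_paired, icc_3k

    keys = pd.DataFrame(
        [k for k in curves], columns=["participant", "condition", "lap", "axis"])
    if keys.empty:
        raise DivergenceError("no curves supplied")
    rows = []
    for a, b in ranges:
        for axis in sorted(keys["axis"].unique()):
            per_pc = {}
            for (pid, cond), grp in keys[keys.axis == axis].groupby(
                    ["participant", "condition"]):
                vals = [fit_exponent(curves[(pid, cond, lap, axis)], (a, b))
                        for lap in grp["lap"]]
                per_pc[(pid, cond)] = (np.mean(vals), dict(zip(grp["lap"], vals)))
            pids = sorted({p for p, _ in per_pc})
            x = np.array([per_pc.get((p, "normal"), (np.nan,))[0] for p in pids])
            y = np.array([per_pc.get((p, "metronome"), (np.nan,))[0] for p in pids])
            try:
                es = hedges_g_paired(x, y, level=level, n_boot=n_boot, seed=seed).g
            except StatsError:
                es = np.nan
            t1 = np.array([per_pc.get((p, "normal"), (None, {}))[1].get("out", np.nan)
                           for p in pids])
            t2 = np.array([per_pc.get((p, "normal"), (None, {}))[1].get("return", np.nan)
                           for p in pids])
            try:
                icc = icc_3k(t1, t2, n_boot=n_boot, seed=seed).icc
            except StatsError:
                icc = np.nan
            ok = np.isfinite(x) & np.isfinite(y)
            rows.append({"a": a, "b": b, "axis": axis, "es": es, "icc": icc,
                         "n_pairs": int(ok.sum())})
    return pd.DataFrame(rows)
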