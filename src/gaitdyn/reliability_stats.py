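"""Validation statistics: paired Hedges' g with bootstrap CIs, Pearson
correlation tables, ICC(3,k)/(A,k) test-retest reliability, SEM and the
smallest detectable difference (SDD)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

DEFAULT_N_BOOT = 10_000

#: Koo-Li interpretation thresholds for ICC point estimates.
ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))


class StatsError(ValueError):
    pass


@dataclass
class EffectSize:
    g: float
    ci_low: float
    ci_high: float
    level: float
    n_pairs: int


@dataclass
class ReliabilityResult:
    icc: float
    ci_low: float
    ci_high: float
    sem: float
    sdd: float
    sdd_relative: float
    band: str
    n: int


def koo_li_band(icc: float) -> str:
    for threshold, label in ICC_BANDS:
        if icc < threshold:
            return label
    return "excellent"


def _small_sample_correction(df: int) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def _paired_g(x: np.ndarray, y: np.ndarray, standardizer: str) -> float:
    n = len(x)
    diff = y - x
    if standardizer == "average":
        s = np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
    elif standardizer == "difference":
        s = np.std(diff, ddof=1)
    else:
        raise StatsError(f"unknown standardizer {standardizer!r}")
    if s == 0:
        raise StatsError("zero variance: effect size undefined")
    return _small_sample_correction(n - 1) * diff.mean() / s


def hedges_g_paired(x, y, level: float = 0.99, n_boot: int = DEFAULT_N_BOOT,
                    seed: int = 0, standardizer: str = "average") -> EffectSize:
    """Paired standardized mean difference (y - x) with small-sample
    correction and a percentile-bootstrap CI over participants.

    Pairs with either value missing are dropped (complete case).  The
    default standardizer is the average of the two condition SDs; the
    difference-score standardizer is available via ``standardizer``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("x and y must be paired (same length)")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise StatsError(f"need >= 3 complete pairs, got {n}")
    g = _paired_g(x, y, standardizer)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, (n_boot, n))
    xb, yb = x[idx], y[idx]
    if standardizer == "average":
        s = np.sqrt((np.var(xb, axis=1, ddof=1) + np.var(yb, axis=1, ddof=1)) / 2.0)
    else:
        s = np.std(yb - xb, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = _small_sample_correction(n - 1) * (yb - xb).mean(axis=1) / s
    boot[s == 0] = np.nan
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanpercentile(boot, [100 * alpha, 100 * (1 - alpha)])
    return EffectSize(g=float(g), ci_low=float(lo), ci_high=float(hi),
                      level=level, n_pairs=n)


def pearson_correlations(table: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Pairwise complete-case Pearson correlations of all numeric
    columns, as a tidy long table (var1, var2, n, r, p, flag)."""
    num = table.select_dtypes(include=[np.number])
    cols = list(num.columns)
    rows = []
    for i, c1 in enumerate(cols):
        for c2 in cols[i:]:
            sub = num[[c1, c2]].dropna()
            n = len(sub)
            if c1 == c2:
                r, p, flag = 1.0, 0.0, ""
            elif n < 3:
                r, p, flag = np.nan, np.nan, "too few complete cases"
            elif sub[c1].nunique() == 1 or sub[c2].nunique() == 1:
                r, p, flag = np.nan, np.nan, "constant column"
            else:
                r, p = sstats.pearsonr(sub[c1], sub[c2])
                flag = ""
            rows.append({"var1": c1, "var2": c2, "n": n, "r": r, "p": p,
                         "flag": flag, "group": group})
    return pd.DataFrame(rows)


def _icc_anova(data: np.ndarray) -> tuple[float, float]:
    """Two-way ANOVA ICC(A,k): absolute agreement, average measures,
    subjects random / trials fixed.  Returns (icc, mse)."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (msc - mse) / n)
    return float(icc), float(mse)


def icc_3k(trial1, trial2, ci_level: float = 0.95, n_boot: int = DEFAULT_N_BOOT,
           seed: int = 0) -> ReliabilityResult:
    """Test-retest reliability of two trials: two-way model with
    subjects random and trials fixed, absolute-agreement,
    average-measures ICC (ICC(3,k) in Shrout-Fleiss terms, ICC(A,k) in
    McGraw-Wong terms), with a subject-resampling percentile-bootstrap
    CI, SEM (root error variance), SDD and relative SDD.

    Subjects missing either trial are dropped before estimation.
    """
    t1 = np.asarray(trial1, dtype=float)
    t2 = np.asarray(trial2, dtype=float)
    if t1.shape != t2.shape:
        raise StatsError("trials must be paired by subject")
    ok = np.isfinite(t1) & np.isfinite(t2)
    data = np.column_stack([t1[ok], t2[ok]])
    n = len(data)
    if n < 5:
        raise StatsError(f"need >= 5 subjects with both trials, got {n}")
    icc, mse = _icc_anova(data)
    rng = np.random.default_rng(seed)
    d = data[rng.integers(0, n, (n_boot, n))]
    k = 2
    grand = d.mean(axis=(1, 2))
    ss_rows = k * ((d.mean(axis=2) - grand[:, None]) ** 2).sum(axis=1)
    ss_cols = n * ((d.mean(axis=1) - grand[:, None]) ** 2).sum(axis=1)
    ss_tot = ((d - grand[:, None, None]) ** 2).sum(axis=(1, 2))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse_b = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    denom = msr + (msc - mse_b) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = (msr - mse_b) / denom
    boot[denom == 0] = np.nan
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.nanpercentile(boot, [100 * alpha, 100 * (1 - alpha)])
    sem = float(np.sqrt(max(mse, 0.0)))
    grand = float(data.mean())
    sdd, sdd_rel = sdd_from_sem(sem, grand if grand != 0 else None)
    return ReliabilityResult(icc=icc, ci_low=float(lo), ci_high=float(hi),
                             sem=sem, sdd=sdd, sdd_relative=sdd_rel,
                             band=koo_li_band(icc), n=n)


def sdd_from_sem(sem: float, mean: float | None = None) -> tuple[float, float]:
    """Smallest detectable difference from the standard error of
    measurement: ``SDD = 1.96 * sqrt(2) * SEM``; the relative form is
    ``100 * SDD / |mean|`` (NaN when the mean is zero/unavailable)."""
    if sem < 0:
        raise StatsError("sem must be >= 0")
    sdd = 1.96 * np.sqrt(2.0) * sem
    if mean is None or mean == 0:
        return float(sdd), float("nan")
    return float(sdd), float(100.0 * sdd / abs(mean))
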