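"""Per-recording and per-cohort orchestration.

``analyze_recording`` runs the lumbar branch (realignment, cadence,
normalization, embedding, divergence exponents) and the foot branch
(stride detection, DFA) for one lap; ``cohort_tables`` aggregates lap
results into condition-contrast, reliability and correlation tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import attractor as attr
from . import divergence as dvg
from . import preprocess as prep
from .dfa import DFAError, dfa_alpha
from .reliability_stats import StatsError, hedges_g_paired, icc_3k, pearson_correlations
from .strides import StrideDetectionError, detect_stride_times

logger = logging.getLogger(__name__)

LDS_AXES = ("AP", "V", "ML")
ACI_AXES = ("norm", "AP", "V", "ML")


@dataclass
class AnalysisConfig:
    """Study-protocol parameters; the defaults match the normalization
    and embedding conventions used throughout the package."""

    fs_hz: float = 256.0
    n_steps: int = prep.N_STEPS
    total_samples: int = prep.TOTAL_SAMPLES
    dim: int = attr.DEFAULT_DIM
    theiler: int = attr.DEFAULT_THEILER
    horizon: int = dvg.DEFAULT_HORIZON
    lds_range: tuple = dvg.LDS_RANGE
    aci_range: tuple = dvg.ACI_RANGE
    ami_max_lag: int = 40
    ref_stride: int = 1
    realign: bool = True
    remove_mean: bool = True
    segment: tuple | None = None  # manual (start, end) sample bounds
    lds_axes: tuple = LDS_AXES
    aci_axes: tuple = ACI_AXES

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        for key in ("lds_range", "aci_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        if cfg.segment is not None:
            cfg.segment = tuple(cfg.segment)
        return cfg


@dataclass
class LapResult:
    participant: str
    condition: str  # normal | metronome
    lap: str  # out | return
    walking_speed: float = np.nan  # m/s, externally timed; metadata only
    step_freq: float = np.nan
    alpha: float = np.nan
    n_strides: int = 0
    lds: dict = field(default_factory=dict)  # axis -> exponent
    aci: dict = field(default_factory=dict)  # axis -> exponent
    delays: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "participant": self.participant, "condition": self.condition,
            "lap": self.lap, "walking_speed": self.walking_speed,
            "step_freq": self.step_freq, "alpha": self.alpha,
            "n_strides": self.n_strides,
        }
        for ax in LDS_AXES:
            row[f"lds_{ax.lower()}"] = self.lds.get(ax, np.nan)
        for ax in ACI_AXES:
            row[f"aci_{ax.lower()}"] = self.aci.get(ax, np.nan)
        return row


#: Table-1 style variables, mapped to LapResult row columns.
VARIABLES = (
    ("walking_speed", "Walking speed (m/s)"),
    ("step_freq", "Step frequency (Hz)"),
    ("lds_ap", "LDS-AP"), ("lds_v", "LDS-V"), ("lds_ml", "LDS-ML"),
    ("aci_norm", "ACI-N"), ("aci_ap", "ACI-AP"),
    ("aci_v", "ACI-V"), ("aci_ml", "ACI-ML"),
    ("alpha", "Alpha (DFA)"),
)


def analyze_recording(lumbar: prep.GaitRecording | None,
                      foot: prep.GaitRecording | None,
                      config: AnalysisConfig | None = None,
                      participant: str = "P0", condition: str = "normal",
                      lap: str = "out", walking_speed: float = np.nan,
                      return_curves: bool = False):
    """Analyze one lap.  Either sensor may be absent; stage failures are
    collected in ``LapResult.errors`` and leave the affected fields
    missing rather than aborting the lap."""
    config = config or AnalysisConfig()
    result = LapResult(participant=participant, condition=condition, lap=lap,
                       walking_speed=walking_speed)
    curves = {}

    if foot is not None:
        try:
            series = detect_stride_times(foot)
            result.n_strides = series.n
            result.alpha = dfa_alpha(series).alpha
        except (StrideDetectionError, DFAError, prep.PreprocessError) as exc:
            result.errors.append(f"foot: {exc}")
            logger.warning("foot branch failed for %s/%s/%s: %s",
                           participant, condition, lap, exc)

    if lumbar is not None:
        try:
            rec = lumbar
            if config.segment is not None:
                rec = rec.copy_with(
                    rec.samples[:, config.segment[0]:config.segment[1]],
                    segment_mode="manual")
            work = prep.moe_nilssen_correct(rec) if config.realign else rec
            step_freq = prep.step_frequency(work.axis("V"), work.fs_hz)
            result.step_freq = step_freq
            needed = tuple(dict.fromkeys(tuple(config.lds_axes) + tuple(config.aci_axes)))
            signals = {}
            for name in needed:
                signals[name] = (prep.vector_norm(rec) if name == "norm"
                                 else work.axis(name))
            for name, sig in signals.items():
                x = sig - sig.mean() if config.remove_mean else sig
                ns = prep.normalize_length(x, work.fs_hz, step_freq)
                curve, params = dvg.divergence_curve_for_signal(
                    ns.values, dim=config.dim, theiler=config.theiler,
                    max_lag=config.ami_max_lag, horizon=config.horizon,
                    ref_stride=config.ref_stride)
                result.delays[name] = params.delay
                if name in config.lds_axes:
                    result.lds[name] = dvg.fit_exponent(curve, config.lds_range)
                if name in config.aci_axes:
                    result.aci[name] = dvg.fit_exponent(curve, config.aci_range)
                curves[name] = curve
        except (prep.PreprocessError, attr.AttractorError,
                dvg.DivergenceError) as exc:
            result.errors.append(f"lumbar: {exc}")
            logger.warning("lumbar branch failed for %s/%s/%s: %s",
                           participant, condition, lap, exc)

    if return_curves:
        return result, curves
    return result


def lap_results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def average_laps(df: pd.DataFrame) -> pd.DataFrame:
    """Average the two laps per participant and condition; when one lap
    is missing for a variable, the remaining lap's value is used (the
    mean over available laps does exactly that)."""
    value_cols = [c for c, _ in VARIABLES]
    return (df.groupby(["participant", "condition"], as_index=False)[value_cols]
              .mean())


def cohort_tables(results, level: float = 0.99, icc_ci_level: float = 0.95,
                  n_boot: int = 2000, seed: int = 0) -> dict:
    """Cohort aggregation: condition contrasts on lap-averaged values
    (Hedges' g with bootstrap CI), test-retest reliability on the
    unaveraged normal-walking laps (ICC, SEM, SDD), and the pooled
    correlation table.
    """
    df = results if isinstance(results, pd.DataFrame) else lap_results_frame(results)
    if df["participant"].nunique() < 2:
        raise StatsError("need >= 2 participants")
    averaged = average_laps(df)
    value_cols = [c for c, _ in VARIABLES]

    # Table 1: descriptive statistics + paired effect sizes
    rows1 = []
    for col, label in VARIABLES:
        normal = averaged[averaged.condition == "normal"].set_index("participant")[col]
        metro = averaged[averaged.condition == "metronome"].set_index("participant")[col]
        pids = sorted(set(normal.index) | set(metro.index))
        x = normal.reindex(pids).to_numpy()
        y = metro.reindex(pids).to_numpy()
        row = {"variable": label,
               "n_normal": int(np.isfinite(x).sum()),
               "mean_normal": np.nanmean(x) if np.isfinite(x).any() else np.nan,
               "sd_normal": np.nanstd(x, ddof=1) if np.isfinite(x).sum() > 1 else np.nan,
               "n_metronome": int(np.isfinite(y).sum()),
               "mean_metronome": np.nanmean(y) if np.isfinite(y).any() else np.nan,
               "sd_metronome": np.nanstd(y, ddof=1) if np.isfinite(y).sum() > 1 else np.nan}
        try:
            es = hedges_g_paired(x, y, level=level, n_boot=n_boot, seed=seed)
            row.update(g=es.g, ci_low=es.ci_low, ci_high=es.ci_high)
        except StatsError as exc:
            row.update(g=np.nan, ci_low=np.nan, ci_high=np.nan)
            logger.warning("effect size unavailable for %s: %s", label, exc)
        rows1.append(row)
    table1 = pd.DataFrame(rows1)

    # Table 2: reliability on normal-walking laps only, unaveraged
    normal_laps = df[df.condition == "normal"]
    out = normal_laps[normal_laps.lap == "out"].set_index("participant")
    ret = normal_laps[normal_laps.lap == "return"].set_index("participant")
    pids = sorted(set(out.index) | set(ret.index))
    rows2 = []
    for col, label in VARIABLES:
        t1 = out[col].reindex(pids).to_numpy() if col in out else np.full(len(pids), np.nan)
        t2 = ret[col].reindex(pids).to_numpy() if col in ret else np.full(len(pids), np.nan)
        try:
            rel = icc_3k(t1, t2, ci_level=icc_ci_level, n_boot=n_boot, seed=seed)
            rows2.append({"variable": label, "n": rel.n, "icc": rel.icc,
                          "ci_low": rel.ci_low, "ci_high": rel.ci_high,
                          "sem": rel.sem, "sdd": rel.sdd,
                          "sdd_relative_pct": rel.sdd_relative, "band": rel.band})
        except StatsError as exc:
            logger.warning("reliability unavailable for %s: %s", label, exc)
            rows2.append({"variable": label, "n": 0, "icc": np.nan,
                          "ci_low": np.nan, "ci_high": np.nan, "sem": np.nan,
                          "sdd": np.nan, "sdd_relative_pct": np.nan, "band": ""})
    table2 = pd.DataFrame(rows2)

    corr_frames = []
    for grouping, sub in (("pooled", averaged),
                          ("normal", averaged[averaged.condition == "normal"]),
                          ("metronome", averaged[averaged.condition == "metronome"])):
        corr_frames.append(pearson_correlations(sub[value_cols], group=grouping))
    correlations = pd.concat(corr_frames, ignore_index=True)

    return {"table1": table1, "table2": table2, "correlations": correlations}


def write_manifest(path, config: AnalysisConfig, extra: dict | None = None) -> None:
    payload = asdict(config)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
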