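import warnings

import numpy as np
import pandas as pd
import pytest

from gaitdyn.pipeline import AnalysisConfig, analyze_recording
from gaitdyn.synthgait import cohort_configs, simulate_lap

COHORT_SEED = 20240709
COHORT_N = 30


@pytest.fixture(scope="session")
def headline_cohort():
    """Paired persistent/antipersistent cohort of 30 simulated
    participants, analysed once and shared by the directional tests.

    Returns (DataFrame with one row per participant x condition, dict of
    vector-norm divergence curves keyed (participant, condition)).
    """
    cfg = AnalysisConfig(ref_stride=5, lds_axes=("AP",), aci_axes=("norm",))
    rows, curves = [], {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, conds in cohort_configs(COHORT_N, seed=COHORT_SEED):
            for condition, sc in conds.items():
                lap = simulate_lap(sc)
                res, lap_curves = analyze_recording(
                    lap["lumbar"], lap["foot"], cfg, participant=pid,
                    condition=condition, return_curves=True)
                assert not res.errors, res.errors
                rows.append({
                    "participant": pid, "condition": condition,
                    "alpha": res.alpha, "aci_norm": res.aci["norm"],
                    "lds_ap": res.lds["AP"],
                    "true_alpha": sc.hurst if sc.structure == "persistent" else np.nan,
                })
                curves[(pid, condition)] = lap_curves["norm"]
    return pd.DataFrame(rows), curves
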