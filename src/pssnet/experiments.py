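"""Simulation experiments: planted-coefficient recovery and type-I control.

Each replicate generates a synthetic dataset, runs the full analysis path
(SUD flagging, cohort, keyword case-finding, monthly networks, panel
assembly) and fits the correctly specified adoption model: the generator's
hazard is logistic in the lagged peer-exposure proportion and the
standardized log cumulative caseload, so the matching GEE uses those two
regressors. Because the adoption outcome is an event history (each row is
Bernoulli given the past, prescribers exit at the event), the independence
working structure — ordinary pooled logistic with cluster-robust errors — is
the consistent estimator and is used here; see the methods note.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import gee, panel as panel_mod, pipeline, synth

RECOVERY_SPEC = gee.ModelSpec(
    categorical={}, continuous=["exposure", "caseload_z"], cov_struct="independence"
)
TYPE_I_SPEC = gee.ModelSpec(
    categorical={"exposure_category": "none"},
    continuous=["caseload_z"],
    cov_struct="independence",
)

_LEAN_PANEL = panel_mod.PanelConfig(include_case_mix=False)


def run_replicate(config: synth.SimulationConfig, spec: gee.ModelSpec) -> gee.ModelResult:
    """One generate-analyze-fit replicate on the adoption panel."""
    data = synth.simulate(config)
    result = pipeline.run_analysis(data.tables, panel_config=_LEAN_PANEL, build_panels=False)
    adoption_panel = panel_mod.assemble_panel(
        "adoption",
        data.dispensations,
        result.classification,
        result.cohort,
        data.prescribers,
        data.clients,
        _LEAN_PANEL,
    )
    return gee.fit_panel_model(adoption_panel, spec)


def recovery_experiment(
    n_replicates: int = 50,
    base_config: synth.SimulationConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit the planted continuous exposure coefficient across replicates.

    Returns one row per replicate with the estimate, robust SE and whether
    the 95% CI covers the planted value. Replicates whose fit fails are
    recorded with NaN (they are rare; callers should check ``ok``).
    """
    base = base_config or synth.SimulationConfig()
    rows = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    for r in range(n_replicates):
        config = replace(base, seed=int(child_seeds[r]))
        try:
            fit = run_replicate(config, RECOVERY_SPEC)
            row = fit.table[fit.table["term"] == "exposure"].iloc[0]
            lo = row["estimate"] - gee.Z95 * row["se"]
            hi = row["estimate"] + gee.Z95 * row["se"]
            rows.append(
                {
                    "replicate": r,
                    "ok": True,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "covered": lo <= base.adopt_beta_exposure <= hi,
                    "n_obs": fit.n_obs,
                }
            )
        except (RuntimeError, ValueError):
            rows.append(
                {"replicate": r, "ok": False, "estimate": np.nan, "se": np.nan,
                 "covered": False, "n_obs": 0}
            )
    return pd.DataFrame(rows)


def type_i_experiment(
    n_replicates: int = 50,
    base_config: synth.SimulationConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Null-coefficient coverage for the exposure categories (planted effect 0).

    Returns one row per replicate per estimated exposure-category term with
    the estimate and whether its 95% CI covers 0 (odds ratio 1).
    """
    base = base_config or synth.SimulationConfig()
    base = replace(base, adopt_beta_exposure=0.0)
    rows = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    for r in range(n_replicates):
        config = replace(base, seed=int(child_seeds[r]))
        try:
            fit = run_replicate(config, TYPE_I_SPEC)
        except (RuntimeError, ValueError):
            rows.append({"replicate": r, "ok": False, "term": None,
                         "estimate": np.nan, "covered": False})
            continue
        cat = fit.table[fit.table["term"].str.startswith("C(exposure_category")]
        for _, row in cat.iterrows():
            lo = row["estimate"] - gee.Z95 * row["se"]
            hi = row["estimate"] + gee.Z95 * row["se"]
            rows.append(
                {"replicate": r, "ok": True, "term": row["term"],
                 "estimate": row["estimate"], "covered": lo <= 0.0 <= hi}
            )
    return pd.DataFrame(rows)


def summarize_recovery(results: pd.DataFrame, truth: float) -> dict:
    ok = results[results["ok"]]
    mean = float(ok["estimate"].mean())
    mc_se = float(ok["estimate"].std(ddof=1) / np.sqrt(len(ok)))
    return {
        "n_ok": int(len(ok)),
        "mean_estimate": mean,
        "mc_se": mc_se,
        "bias": mean - truth,
        "abs_bias_in_mc_se": abs(mean - truth) / mc_se if mc_se > 0 else np.inf,
        "coverage": float(ok["covered"].mean()),
    }
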