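"""Repeated-measures logistic models with robust (sandwich) inference.

The mean model is logistic in the panel terms; clustering is on the
prescriber, and standard errors are sandwich-robust, so point estimates stay
consistent whichever working correlation is used. The requested working
correlation (unstructured by default, matching the monthly repeated-measures
design) falls back along unstructured -> exchangeable -> independence when
estimation fails or degenerates on unbalanced cluster lengths; the structure
actually used is recorded in the result metadata.

A small random-intercept logistic companion (adaptive Gauss-Hermite
maximum likelihood) is provided as an advisory diagnostic for the size of
the cluster variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from statsmodels.genmod.cov_struct import Exchangeable, Independence, Unstructured

from .defaults import ConfigurationError

Z95 = 1.96

FALLBACK_CHAIN = ("unstructured", "exchangeable", "independence")


@dataclass
class ModelSpec:
    """Terms and settings for one panel model.

    ``categorical`` maps a column name to its reference level; ``continuous``
    lists columns entering linearly. Cluster id defaults to the prescriber.
    """

    outcome: str = "outcome"
    categorical: dict = field(default_factory=dict)
    continuous: list = field(default_factory=list)
    cov_struct: str = "unstructured"
    cluster: str = "prescriber_id"
    time: str = "study_month"

    def formula(self) -> str:
        terms = []
        for col, ref in self.categorical.items():
            terms.append(f"C({col}, Treatment(reference={ref!r}))")
        terms.extend(self.continuous)
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.outcome} ~ {rhs}"


def adoption_spec(include_case_mix: bool = True, exposure: str = "categorical") -> ModelSpec:
    """Default adoption-model terms (reference levels as reported)."""
    categorical = {
        "region": "Interior",
        "specialty": "general practice",
        "experience_category": "Q1",
        "caseload_category": "Q1",
    }
    continuous = ["study_month", "clustering", "adjusted_strength", "oat_history"]
    if exposure == "categorical":
        categorical = {"exposure_category": "none", **categorical}
    else:
        continuous = ["exposure", *continuous]
    if include_case_mix:
        continuous += [
            "pct_age40", "pct_cci_gt1", "pct_benzo",
            "pct_social_assistance", "pct_overdose_12m", "covid_flag",
        ]
    return ModelSpec(categorical=categorical, continuous=continuous)


def discontinuation_spec(include_case_mix: bool = True) -> ModelSpec:
    return adoption_spec(include_case_mix=include_case_mix)


@dataclass
class ModelResult:
    """Tidy coefficient table plus fit metadata."""

    table: pd.DataFrame  # term, estimate, se, aor, ci_low, ci_high
    n_obs: int
    n_clusters: int
    cov_struct_used: str
    converged: bool
    fallbacks: list = field(default_factory=list)

    def term(self, name_fragment: str) -> pd.Series:
        hits = self.table[self.table["term"].str.contains(name_fragment, regex=False)]
        if len(hits) != 1:
            raise KeyError(f"{name_fragment!r} matches {len(hits)} terms")
        return hits.iloc[0]


def _make_cov_struct(name: str):
    if name == "unstructured":
        return Unstructured()
    if name == "exchangeable":
        return Exchangeable()
    if name == "independence":
        return Independence()
    raise ConfigurationError(f"unknown working correlation {name!r}")


def _check_panel(panel: pd.DataFrame, spec: ModelSpec) -> None:
    if not len(panel):
        raise ValueError("empty panel")
    y = panel[spec.outcome]
    if y.nunique() < 2:
        raise ValueError(f"outcome {spec.outcome!r} is constant ({y.iloc[0]}); model not estimable")
    for col, ref in spec.categorical.items():
        levels = set(panel[col].unique())
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from {col!r}")
        for lev in levels - {ref}:
            sub = y[panel[col] == lev]
            if sub.nunique() < 2 and len(sub) > 0 and len(levels) > 1 and sub.iloc[0] == 1:
                raise ValueError(f"separation: outcome constant at 1 within {col}={lev!r}")
    for col in spec.continuous:
        if panel[col].nunique() < 2:
            raise ValueError(f"singular design: term {col!r} is constant")


def fit_panel_model(panel: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit the logistic GEE and return adjusted odds ratios with 95% CIs.

    Deterministic given fixed input; invariant to row order within clusters
    and to cluster relabeling. CIs use the normal 1.96 multiplier:
    aOR = exp(estimate), CI = exp(estimate +/- 1.96 * robust SE).
    """
    _check_panel(panel, spec)
    data = panel.sort_values([spec.cluster, spec.time], kind="mergesort").reset_index(drop=True)
    data = data.copy()
    data[spec.outcome] = data[spec.outcome].astype(float)
    time = (data[spec.time] - data[spec.time].min()).astype(int)

    chain = list(FALLBACK_CHAIN[FALLBACK_CHAIN.index(spec.cov_struct):])
    fallbacks, fit, used = [], None, None
    last_error: Exception | None = None
    for name in chain:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GEE.from_formula(
                    spec.formula(),
                    groups=spec.cluster,
                    data=data,
                    time=time.to_numpy(),
                    family=sm.families.Binomial(),
                    cov_struct=_make_cov_struct(name),
                )
                candidate = model.fit(maxiter=100)
                bad = (
                    not np.all(np.isfinite(candidate.params))
                    or not np.all(np.isfinite(np.asarray(candidate.bse)))
                    or np.any(np.asarray(candidate.bse) <= 0)
                    or np.any(np.abs(candidate.params) > 30)
                )
            if bad:
                raise RuntimeError(f"degenerate fit under {name} working correlation")
            fit, used = candidate, name
            break
        except Exception as exc:  # noqa: BLE001 - record and fall back
            last_error = exc
            fallbacks.append(name)
            continue
    if fit is None:
        raise RuntimeError(f"GEE failed under all working correlations: {last_error}")

    est = fit.params
    se = fit.bse
    table = pd.DataFrame(
        {
            "term": est.index,
            "estimate": est.to_numpy(),
            "se": se.to_numpy(),
            "aor": np.exp(est.to_numpy()),
            "ci_low": np.exp(est.to_numpy() - Z95 * se.to_numpy()),
            "ci_high": np.exp(est.to_numpy() + Z95 * se.to_numpy()),
        }
    )
    return ModelResult(
        table=table,
        n_obs=int(len(data)),
        n_clusters=int(data[spec.cluster].nunique()),
        cov_struct_used=used,
        converged=bool(getattr(fit, "converged", True)),
        fallbacks=fallbacks,
    )


def glmm_variance_check(
    panel: pd.DataFrame, spec: ModelSpec, n_quad: int = 25
) -> dict:
    """Random-intercept logistic ML fit; reports the intercept variance.

    Advisory only: marginal likelihood by Gauss-Hermite quadrature over the
    cluster intercept, maximized jointly over the fixed effects and the
    random-intercept standard deviation (bounded at 0). Returns a dict with
    ``variance`` (None when unidentifiable, e.g. all clusters singleton),
    ``converged`` and ``message``.
    """
    _check_panel(panel, spec)
    sizes = panel.groupby(spec.cluster).size()
    if (sizes <= 1).all():
        return {"variance": None, "converged": False,
                "message": "all clusters have a single row; variance unidentifiable"}

    from patsy import dmatrices

    y_mat, x_mat = dmatrices(spec.formula(), panel, return_type="dataframe")
    y = y_mat.to_numpy().ravel()
    X = x_mat.to_numpy()
    groups, group_idx = np.unique(panel[spec.cluster].to_numpy(), return_inverse=True)
    nodes, weights = hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)

    start = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    theta0 = np.concatenate([start.params, [0.3]])

    def negll(theta):
        beta, sigma = theta[:-1], abs(theta[-1])
        eta = X @ beta
        b = np.sqrt(2.0) * sigma * nodes  # (K,)
        with np.errstate(over="ignore"):
            lin = eta[:, None] + b[None, :]
            logp = np.where(y[:, None] == 1, -np.logaddexp(0, -lin), -np.logaddexp(0, lin))
        per_cluster = np.zeros((len(groups), len(nodes)))
        np.add.at(per_cluster, group_idx, logp)
        m = per_cluster.max(axis=1, keepdims=True)
        ll = (m.ravel() + np.log(np.exp(per_cluster - m + log_w[None, :]).sum(axis=1))).sum()
        return -ll

    res = minimize(negll, theta0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-7})
    sigma = abs(res.x[-1])
    return {
        "variance": float(sigma**2),
        "converged": bool(res.success),
        "message": res.message,
    }
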