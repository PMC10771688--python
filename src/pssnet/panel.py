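"""Prescriber-month panels for the adoption and discontinuation models.

Each row is one prescriber-month. Outcomes: for the adoption panel, 1 in the
month of the first safer-supply dispensation (the prescriber then exits the
risk set); for the discontinuation panel, 1 at the first month of a gap of at
least three consecutive months with no safer-supply dispensation (the gap
must be fully observable inside the study window to count). Every
time-varying regressor is measured in the previous month: network exposure,
clustering, adjusted strength, caseload, and the client case-mix aggregates
are all computed from records dated no later than the end of month m-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import months, network, pss as pss_mod
from .defaults import ConfigurationError

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")

#: Replication cut points mirroring the published tables. ``closed`` gives the
#: side on which the lower bins are closed: "right" means x <= cut stays in
#: the lower bin (integer caseloads), "left" means x < cut does (continuous
#: years of experience).
PRINTED_SCHEMES = {
    "adoption": {
        "caseload": {"cuts": (2, 6, 13), "closed": "right"},
        "experience": {"cuts": (4.5, 10.9, 22.4), "closed": "left"},
    },
    "discontinuation": {
        "caseload": {"cuts": (18, 43, 85), "closed": "right"},
        "experience": {"cuts": (4.0, 8.3, 17.4), "closed": "left"},
    },
}


@dataclass
class QuartileScheme:
    """Three increasing cut points splitting a variable into quartile bins."""

    variable: str
    cuts: tuple[float, float, float]
    mode: str = "empirical"
    closed: str = "right"

    def __post_init__(self) -> None:
        if not (self.cuts[0] < self.cuts[1] < self.cuts[2]):
            raise ConfigurationError(f"quartile cuts for {self.variable} must strictly increase")

    def assign(self, values: pd.Series) -> pd.Series:
        v = values.astype(float)
        c = self.cuts
        if self.closed == "right":
            conds = [v <= c[0], v <= c[1], v <= c[2]]
        else:
            conds = [v < c[0], v < c[1], v < c[2]]
        out = np.select(conds, QUARTILE_LABELS[:3], default=QUARTILE_LABELS[3])
        return pd.Series(out, index=values.index)


def empirical_scheme(variable: str, values: pd.Series) -> QuartileScheme:
    """Quartile cuts from the empirical distribution (panel-entry snapshot)."""
    v = values.astype(float).to_numpy()
    cuts = tuple(np.quantile(v, [0.25, 0.5, 0.75]))
    if not (cuts[0] < cuts[1] < cuts[2]):
        # heavily tied data: nudge to keep cuts strictly increasing
        eps = [i * 1e-9 for i in range(3)]
        cuts = tuple(c + e for c, e in zip(cuts, eps))
    return QuartileScheme(variable=variable, cuts=cuts, mode="empirical", closed="right")


def adoption_outcome(first_pss_month: str | None, month: str) -> int:
    """1 iff the first safer-supply dispensation falls in this month."""
    return int(first_pss_month is not None and first_pss_month == month)


def discontinuation_month(
    pss_months: set[str], study_months: list[str], gap: int = 3
) -> str | None:
    """First month of a fully observable >=gap-month safer-supply gap.

    Returns None when no gap is confirmable inside the study window (either
    dispensations continue, or too few observable months remain).
    """
    if not pss_months:
        raise ValueError("prescriber has no safer-supply dispensations")
    first = min(pss_months)
    try:
        start_idx = study_months.index(first) + 1
    except ValueError as exc:
        raise ValueError(f"first PSS month {first} outside study months") from exc
    for i in range(start_idx, len(study_months)):
        window = study_months[i : i + gap]
        if len(window) < gap:
            return None  # gap not observable to the end
        if not any(mk in pss_months for mk in window):
            return window[0]
    return None


def discontinuation_outcome(
    pss_months: set[str], month: str, study_months: list[str], gap: int = 3
) -> int:
    """1 iff ``month`` is the confirmed discontinuation month."""
    if month < min(pss_months):
        raise ValueError("month precedes the first safer-supply month")
    event = discontinuation_month(pss_months, study_months, gap=gap)
    return int(event == month)


def aggregate_case_mix(
    caseload_clients: pd.Series,
    clients: pd.DataFrame,
    benzo_clients_12m: set,
    month: str,
) -> dict:
    """Client case-mix aggregates over one prescriber's monthly caseload.

    Percentages are over the caseload clients; an empty caseload yields 0 for
    every percentage and a 0 COVID flag (convention, so rows stay estimable).
    """
    ids = list(caseload_clients)
    if not ids:
        return {
            "pct_age40": 0.0, "pct_cci_gt1": 0.0, "pct_benzo": 0.0,
            "pct_social_assistance": 0.0, "pct_overdose_12m": 0.0, "covid_flag": 0,
        }
    sub = clients.loc[clients.index.intersection(ids)]
    n = len(ids)
    end = months.month_end(month)
    year = months.to_period(month).year
    age40 = (year - sub["birth_year"]) >= 40
    od = pd.to_datetime(sub["overdose_date"], errors="coerce")
    od_12m = (od > end - pd.Timedelta(days=365)) & (od <= end)
    covid = pd.to_datetime(sub["covid_diagnosis_date"], errors="coerce") <= end
    return {
        "pct_age40": 100.0 * age40.sum() / n,
        "pct_cci_gt1": 100.0 * (sub["cci"] > 1).sum() / n,
        "pct_benzo": 100.0 * len(set(ids) & benzo_clients_12m) / n,
        "pct_social_assistance": 100.0 * (sub["social_assistance_months"] > 0).sum() / n,
        "pct_overdose_12m": 100.0 * od_12m.sum() / n,
        "covid_flag": int(covid.any()),
    }


@dataclass
class PanelConfig:
    """Assembly settings shared by both panels."""

    origin_month: str = "2020-03"
    study_start: str = "2020-03-27"
    study_end_month: str = "2021-08"
    adoption_start: str = "2020-05"
    discontinuation_start: str = "2020-07"
    scheme: str = "calendar"  # month binning, pipeline-wide
    window: str = "cumulative"  # edge accumulation window
    exposure_variant: str = "unweighted"
    include_two_degree: bool = False
    gap: int = 3
    quartile_mode: str = "empirical"  # or "printed"
    include_case_mix: bool = True
    min_monthly_clients: int = 0  # caseload inclusion threshold sensitivity
    med_classes: list | None = None  # medication-subgroup variant (e.g. ["opioid"])

    @property
    def study_months(self) -> list[str]:
        return months.month_range(self.origin_month, self.study_end_month)


def _monthly_covariates(
    dispensations: pd.DataFrame,
    cohort: list[str],
    clients: pd.DataFrame,
    adoption: pd.DataFrame,
    lag_months: list[str],
    config: PanelConfig,
) -> dict[str, pd.DataFrame]:
    """Covariate table per lag month, computed from records through month end."""
    first_pss = adoption.set_index("prescriber_id")["first_pss_month"]
    disp = dispensations.copy()
    disp["_month"] = months.month_key(disp["date"], scheme=config.scheme)
    disp["_date"] = pd.to_datetime(disp["date"])
    clients_idx = clients.set_index("client_id")
    ref_caseload = None
    out = {}
    for lm in lag_months:
        snapshot = network.build_monthly_network(
            dispensations, cohort, lm, window=config.window, study_start=config.study_start
        )
        start, end, _ = network._window_bounds(lm, config.window, config.study_start)
        pairs = network.attachment_pairs(dispensations, cohort=cohort, start=start, end=end)
        metrics = network.node_metrics(snapshot, pairs).set_index("prescriber_id")
        adopters = set(first_pss[first_pss.notna() & (first_pss <= lm)].index)
        exposure = network.peer_exposure(snapshot, adopters, variant=config.exposure_variant)
        metrics["exposure"] = exposure
        metrics["exposure_category"] = network.categorize_exposure(exposure)
        if config.include_two_degree:
            metrics["exposure_two_degree"] = network.peer_exposure(
                snapshot, adopters, variant="two-degree"
            )
        caseload_cum = network.cumulative_caseload(
            dispensations, cohort, lm, study_start=config.study_start
        )
        if ref_caseload is None:
            ref_caseload = caseload_cum.copy()
        metrics["caseload_cum"] = caseload_cum
        metrics["caseload_z"] = network.caseload_log_z(caseload_cum, ref=ref_caseload)

        in_month = disp[disp["_month"] == lm]
        month_clients = in_month.groupby("prescriber_id")["client_id"].agg(lambda s: set(s))
        metrics["caseload_month"] = [
            len(month_clients.get(p, set())) for p in metrics.index
        ]
        if config.include_case_mix:
            end_ts = months.month_end(lm)
            recent = disp[(disp["_date"] > end_ts - pd.Timedelta(days=365)) & (disp["_date"] <= end_ts)]
            benzo_12m = set(recent.loc[recent["med_class"] == "benzodiazepine", "client_id"])
            rows = {
                p: aggregate_case_mix(month_clients.get(p, set()), clients_idx, benzo_12m, lm)
                for p in metrics.index
            }
            metrics = metrics.join(pd.DataFrame.from_dict(rows, orient="index"))
        out[lm] = metrics
    return out


def assemble_panel(
    kind: str,
    dispensations: pd.DataFrame,
    classification: pd.DataFrame,
    cohort: list[str],
    prescribers: pd.DataFrame,
    clients: pd.DataFrame,
    config: PanelConfig | None = None,
) -> pd.DataFrame:
    """Build the adoption or discontinuation analysis panel.

    Adoption: months ``adoption_start``..study end over prescribers with no
    prior safer-supply dispensation, plus the initiation-month row (outcome
    1); prescribers whose initiation precedes the panel start (the
    innovators) contribute no rows. Discontinuation: months
    ``discontinuation_start``..study end over initiators, from the month
    after initiation until the confirmed discontinuation month or study end.
    All time-varying regressors are the previous month's values.
    """
    if kind not in ("adoption", "discontinuation"):
        raise ConfigurationError(f"unknown panel kind {kind!r}")
    config = config or PanelConfig()
    study_months = config.study_months
    panel_start = config.adoption_start if kind == "adoption" else config.discontinuation_start
    panel_months = [m for m in study_months if m >= panel_start]
    if not panel_months:
        raise ConfigurationError("panel start is after the study end")

    adoption = pss_mod.derive_adoption(
        dispensations, classification, cohort,
        scheme=config.scheme, med_classes=config.med_classes,
    )
    pss_months = pss_mod.pss_months_by_prescriber(
        dispensations, classification, scheme=config.scheme, med_classes=config.med_classes
    )

    lag_months = [months.shift(m, -1) for m in panel_months]
    covars = _monthly_covariates(
        dispensations, cohort, clients, adoption, lag_months, config
    )
    for lm in lag_months:
        if lm not in covars:
            raise ConfigurationError(f"missing covariate month {lm}")

    presc = prescribers.set_index("prescriber_id")
    first_pss = adoption.set_index("prescriber_id")["first_pss_month"]

    rows = []
    for pid in cohort:
        fp = first_pss.get(pid)
        fp = None if pd.isna(fp) else fp
        if kind == "adoption":
            if fp is not None and fp < panel_start:
                continue  # innovation-period initiators are not at risk in the panel
            for m in panel_months:
                if fp is not None and m > fp:
                    break
                rows.append((pid, m, adoption_outcome(fp, m)))
        else:
            if fp is None:
                continue
            event = discontinuation_month(pss_months[pid], study_months, gap=config.gap)
            if event is not None and event < panel_start:
                continue  # event precedes the panel window
            start = max(months.shift(fp, 1), panel_start)
            for m in panel_months:
                if m < start:
                    continue
                if event is not None and m > event:
                    break
                rows.append((pid, m, int(m == event)))
    panel = pd.DataFrame(rows, columns=["prescriber_id", "month", "outcome"])
    if not len(panel):
        return panel

    lag = panel["month"].map(lambda m: months.shift(m, -1))
    cov_frames = []
    for lm, sub in panel.groupby(lag):
        block = covars[lm].loc[sub["prescriber_id"]].reset_index()
        block.index = sub.index
        cov_frames.append(block.drop(columns=["prescriber_id", "month"]))
    cov = pd.concat(cov_frames).sort_index()
    panel = pd.concat([panel, cov], axis=1)

    panel["study_month"] = panel["month"].map(lambda m: months.month_index(m, config.origin_month))
    panel = panel.join(
        presc[["region", "specialty", "oat_prescriber", "first_sud_billing_date"]],
        on="prescriber_id",
    )
    panel["oat_history"] = panel["oat_prescriber"].astype(bool)
    lag_end = lag.map(months.month_end)
    billed = pd.to_datetime(panel["first_sud_billing_date"])
    panel["experience_years"] = (lag_end - billed).dt.days / 365.25

    if config.min_monthly_clients > 0:
        panel = panel[panel["caseload_month"] >= config.min_monthly_clients]

    # quartile categorization from the panel-entry distribution (or printed cuts)
    if config.quartile_mode == "printed":
        spec = PRINTED_SCHEMES[kind]
        schemes = {
            "caseload_month": QuartileScheme("caseload", spec["caseload"]["cuts"], "printed", spec["caseload"]["closed"]),
            "experience_years": QuartileScheme("experience", spec["experience"]["cuts"], "printed", spec["experience"]["closed"]),
        }
    else:
        entry = panel[panel["month"] == panel_months[0]]
        base = entry if len(entry) else panel
        schemes = {
            "caseload_month": empirical_scheme("caseload", base["caseload_month"]),
            "experience_years": empirical_scheme("experience", base["experience_years"]),
        }
    panel["caseload_category"] = schemes["caseload_month"].assign(panel["caseload_month"])
    panel["experience_category"] = schemes["experience_years"].assign(panel["experience_years"])

    panel = panel.drop(columns=["oat_prescriber", "first_sud_billing_date"])
    return panel.sort_values(["prescriber_id", "month"], kind="mergesort").reset_index(drop=True)
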