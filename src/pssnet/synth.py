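"""Synthetic administrative-claims generator with known diffusion ground truth.

Emulates the record-level structure the analysis assumes: a regionally
clustered bipartite prescriber-client affiliation with heavy-tailed
caseloads, monthly dispensation records, substance-use-disorder (SUD)
indication records (opioid agonist treatment, outpatient visits, acute care,
perinatal), and a peer-driven adoption process for prescribed safer supply
(PSS). Adoption is seeded with a configurable number of innovators in the
first months; thereafter each non-adopter's monthly adoption indicator is
Bernoulli on the logit scale in the *lagged* peer-exposure proportion and a
standardized log caseload — computed with the very same network code path the
analysis uses, so the planted coefficients are the estimands of the panel
regression. Every draw flows from one master seed; identical seeds reproduce
byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import months, network
from .defaults import ConfigurationError

REGION_NAMES = ["Interior", "Fraser", "Vancouver Coastal", "Vancouver Island", "Northern"]
REGION_WEIGHTS_5 = [0.16, 0.25, 0.34, 0.18, 0.07]
SPECIALTIES = ["general practice", "nurse practitioner", "psychiatry", "other", "unknown"]

BACKGROUND_DRUGS = ["AMOXICILLIN", "RAMIPRIL", "METFORMIN", "SERTRALINE", "GABAPENTIN", "LORAZEPAM"]
BACKGROUND_DRUG_P = [0.18, 0.20, 0.20, 0.22, 0.15, 0.05]
BACKGROUND_DRUG_P_BENZO = [0.12, 0.14, 0.14, 0.15, 0.15, 0.30]
BACKGROUND_DIRECTIONS = [
    "Take one tablet by mouth daily",
    "Take as directed",
    "One tablet twice daily with food",
    "Take at bedtime",
    "One capsule every morning",
]
PSS_DRUGS = ["HYDROMORPHONE-TAB", "MORPHINE-SR", "DEXTROAMPHETAMINE", "METHYLPHENIDATE", "DIAZEPAM", "CLONAZEPAM"]
PSS_DRUG_P = [0.45, 0.20, 0.12, 0.08, 0.08, 0.07]
PSS_DRUG_CLASS = {
    "HYDROMORPHONE-TAB": "opioid",
    "MORPHINE-SR": "opioid",
    "DEXTROAMPHETAMINE": "stimulant",
    "METHYLPHENIDATE": "stimulant",
    "DIAZEPAM": "benzodiazepine",
    "CLONAZEPAM": "benzodiazepine",
}
# Directions planted on PSS dispensations. The first tier matches both
# case-finding algorithms; the second only the sensitive one.
PSS_DIRECTIONS_SPECIFIC = [
    "Dispense daily - Risk Mitigation (COVID-19)",
    "RMG: witnessed dose, dispense weekly",
]
PSS_DIRECTIONS_SENSITIVE_ONLY = [
    "Daily dispense during COVID-19 pandemic",
    "Pandemic interim measure, dispense daily",
]
NONSUD_DIAG_CODES = ["I10", "E11", "J45", "M54"]
SUD_PATHWAYS = ["oat", "outpatient", "acute", "perinatal"]


@dataclass
class SimulationConfig:
    """Generator knobs; defaults are the bundled study conditions."""

    n_prescribers: int = 500
    n_clients: int = 2000
    n_regions: int = 5
    region_unknown_frac: float = 0.035
    specialty_mix: dict = field(
        default_factory=lambda: {
            "general practice": 0.56,
            "nurse practitioner": 0.05,
            "psychiatry": 0.05,
            "other": 0.23,
            "unknown": 0.11,
        }
    )
    caseload_dispersion: float = 1.0  # lognormal sigma of prescriber attachment weights
    sharing_rate: float = 2.0  # expected prescribers per client (>= 1)
    region_mixing: float = 0.10  # prob. a client draws prescribers province-wide
    visit_rate: float = 0.35  # per-attachment monthly dispensation probability
    n_months: int = 18
    origin_month: str = "2020-03"
    study_start: str = "2020-03-27"
    history_start: str = "1996-01-01"
    oat_prescriber_frac: float = 0.35
    sud_client_frac: float = 1.0
    oat_client_frac: float = 0.28
    benzo_client_frac: float = 0.15
    covid_client_frac: float = 0.04
    overdose_client_frac: float = 0.08
    social_assistance_frac: float = 0.45
    # diffusion model (all log-odds; monthly hazards)
    adopt_intercept: float = -5.0
    adopt_beta_exposure: float = float(np.log(3.79))
    adopt_beta_caseload: float = 0.4
    discont_intercept: float = -2.2
    discont_beta_exposure: float = -1.2
    n_innovator_seed: int = 10
    innovation_months: int = 2
    pss_rx_rate: float = 1.5  # mean PSS dispensations per adopted prescriber-month
    pss_specific_frac: float = 0.7  # share of PSS directions matching the specific tier
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_prescribers", "n_clients", "n_regions", "n_innovator_seed"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_months < 4:
            raise ConfigurationError("n_months must be >= 4 (discontinuation needs a 3-month gap)")
        if self.n_months <= self.innovation_months:
            raise ConfigurationError("study window must be longer than the innovation period")
        if self.n_innovator_seed > self.n_prescribers:
            raise ConfigurationError("n_innovator_seed exceeds n_prescribers")
        if self.sharing_rate < 1:
            raise ConfigurationError("sharing_rate must be >= 1 (each client has a prescriber)")
        total = sum(self.specialty_mix.values())
        if abs(total - 1.0) > 1e-6 or any(v < 0 for v in self.specialty_mix.values()):
            raise ConfigurationError("specialty_mix must be a probability vector summing to 1")
        if not set(self.specialty_mix) <= set(SPECIALTIES):
            raise ConfigurationError(f"specialty_mix keys must be among {SPECIALTIES}")

    @property
    def month_keys(self) -> list[str]:
        return months.month_range(self.origin_month, months.shift(self.origin_month, self.n_months - 1))


@dataclass
class SimulationTruth:
    """Ledger of the generator's coefficients and per-prescriber event months."""

    true_coefficients: dict
    adoption_month: dict  # prescriber -> "YYYY-MM" or None
    discontinuation_month: dict  # prescriber -> "YYYY-MM" or None (first month with no PSS)
    innovator_seeds: list
    pss_dispensation_ids: list
    #: regressors the adoption hazard actually used, one row per at-risk
    #: prescriber-month (month, prescriber_id, exposure, caseload_z); lets
    #: tests assert the analysis panel reproduces the generator's estimand.
    hazard_trace: pd.DataFrame | None = None

    def validate(self, config: SimulationConfig) -> None:
        window = set(config.month_keys[: config.innovation_months])
        for pid, dm in self.discontinuation_month.items():
            if dm is not None:
                am = self.adoption_month.get(pid)
                assert am is not None and am < dm, f"discontinuation without prior adoption for {pid}"
        for pid in self.innovator_seeds:
            assert self.adoption_month[pid] in window, f"seed {pid} adopted outside innovation window"


@dataclass
class SimulationData:
    config: SimulationConfig
    prescribers: pd.DataFrame
    clients: pd.DataFrame
    dispensations: pd.DataFrame
    visits: pd.DataFrame
    acute_visits: pd.DataFrame
    truth: SimulationTruth

    @property
    def tables(self) -> dict:
        return {
            "prescribers": self.prescribers,
            "clients": self.clients,
            "dispensations": self.dispensations,
            "visits": self.visits,
            "acute_visits": self.acute_visits,
        }


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[stage])


def _region_labels(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    if config.n_regions <= len(REGION_NAMES):
        names = REGION_NAMES[: config.n_regions]
        weights = np.array(REGION_WEIGHTS_5[: config.n_regions], dtype=float)
    else:
        names = REGION_NAMES + [f"Region {i}" for i in range(6, config.n_regions + 1)]
        weights = np.ones(config.n_regions)
    return names, weights / weights.sum()


def _random_dates(rng, start: str, end: str, size: int) -> pd.Series:
    lo, hi = pd.Timestamp(start).value // 86_400_000_000_000, pd.Timestamp(end).value // 86_400_000_000_000
    days = rng.integers(lo, hi + 1, size=size)
    return pd.Series(pd.to_datetime(days * 86_400_000_000_000)).dt.normalize()


def simulate_population(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw the prescriber and client attribute tables."""
    rng = rng if rng is not None else _rng(config, 0)
    n_p, n_c = config.n_prescribers, config.n_clients
    names, weights = _region_labels(config)

    region = np.array(names, dtype=object)[rng.choice(config.n_regions, size=n_p, p=weights)]
    unknown = rng.random(n_p) < config.region_unknown_frac
    region = np.where(unknown, "Unknown", region)
    spec_names = list(config.specialty_mix)
    spec_p = np.array([config.specialty_mix[s] for s in spec_names])
    specialty = np.array(spec_names, dtype=object)[rng.choice(len(spec_names), size=n_p, p=spec_p)]
    prescribers = pd.DataFrame(
        {
            "prescriber_id": [f"P{i:05d}" for i in range(1, n_p + 1)],
            "region": region,
            "specialty": specialty,
            "oat_prescriber": rng.random(n_p) < config.oat_prescriber_frac,
            "first_sud_billing_date": _random_dates(
                rng, config.history_start, str(pd.Timestamp(config.study_start) - pd.Timedelta(days=1)), n_p
            ).dt.strftime("%Y-%m-%d"),
        }
    )

    client_region = np.array(names, dtype=object)[rng.choice(config.n_regions, size=n_c, p=weights)]
    birth_year = np.clip(rng.normal(1980, 12, size=n_c).round().astype(int), 1940, 2003)
    sud = rng.random(n_c) < config.sud_client_frac
    pathway = np.where(
        sud,
        np.array(SUD_PATHWAYS, dtype=object)[rng.choice(4, size=n_c, p=[0.28, 0.47, 0.20, 0.05])],
        "none",
    )
    # qualification date: mostly before the study, some during (realistic churn)
    pre = _random_dates(rng, "2012-01-01", str(pd.Timestamp(config.study_start) - pd.Timedelta(days=1)), n_c)
    study_end = months.month_end(config.month_keys[-1])
    during = _random_dates(rng, config.study_start, str(study_end.date()), n_c)
    indication = pd.Series(np.where(rng.random(n_c) < 0.97, pre, during))
    indication = pd.to_datetime(indication).where(sud, pd.NaT)

    sa = np.where(rng.random(n_c) < config.social_assistance_frac, rng.integers(1, 13, size=n_c), 0)
    overdose = _random_dates(rng, "2019-09-01", str(study_end.date()), n_c).where(
        rng.random(n_c) < config.overdose_client_frac, pd.NaT
    )
    covid = _random_dates(rng, config.study_start, str(study_end.date()), n_c).where(
        rng.random(n_c) < config.covid_client_frac, pd.NaT
    )
    clients = pd.DataFrame(
        {
            "client_id": [f"C{i:06d}" for i in range(1, n_c + 1)],
            "region": client_region,
            "birth_year": birth_year,
            "cds": rng.gamma(1.2, 1.5, size=n_c).round(1),
            "cci": rng.choice([0, 1, 2, 3], size=n_c, p=[0.55, 0.25, 0.13, 0.07]),
            "social_assistance_months": sa,
            "benzo_user": rng.random(n_c) < config.benzo_client_frac,
            "overdose_date": pd.to_datetime(overdose).dt.strftime("%Y-%m-%d"),
            "covid_diagnosis_date": pd.to_datetime(covid).dt.strftime("%Y-%m-%d"),
            "sud_pathway": pathway,
            "sud_qualifying_date": indication.dt.strftime("%Y-%m-%d"),
            "perinatal_sud_date": indication.where(pd.Series(pathway) == "perinatal").dt.strftime("%Y-%m-%d"),
        }
    )
    return prescribers, clients


def _month_day_bounds(config: SimulationConfig, key: str) -> tuple[str, str]:
    start = max(months.month_start(key), pd.Timestamp(config.study_start))
    return str(start.date()), str(months.month_end(key).date())


def simulate_affiliation(
    prescribers: pd.DataFrame,
    clients: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Attach clients to prescribers and emit the pre-PSS record stream.

    Each client draws ``1 + Poisson(sharing_rate - 1)`` distinct prescribers,
    within their own region unless a mixing coin sends them province-wide;
    prescriber selection weights are lognormal (heavy-tailed caseloads). Each
    attachment emits a dispensation in each study month independently with
    probability ``visit_rate`` (at least one overall), and SUD indication
    records are emitted per the client's pathway.
    """
    rng = rng if rng is not None else _rng(config, 1)
    weights = rng.lognormal(0.0, config.caseload_dispersion, size=len(prescribers))
    pid = prescribers["prescriber_id"].to_numpy()
    by_region: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for reg in sorted(set(prescribers["region"])):
        idx = np.flatnonzero((prescribers["region"] == reg).to_numpy())
        by_region[reg] = (idx, weights[idx] / weights[idx].sum())
    all_p = weights / weights.sum()

    n_extra = rng.poisson(config.sharing_rate - 1.0, size=len(clients))
    mix = rng.random(len(clients)) < config.region_mixing
    att_client, att_presc = [], []
    for i, (cid, creg) in enumerate(zip(clients["client_id"], clients["region"])):
        k = int(n_extra[i]) + 1
        if mix[i] or creg not in by_region:
            pool, p = np.arange(len(pid)), all_p
        else:
            pool, p = by_region[creg]
        k = min(k, len(pool))
        chosen = rng.choice(pool, size=k, replace=False, p=p)
        att_client.extend([cid] * k)
        att_presc.extend(pid[j] for j in chosen)
    attachments = pd.DataFrame({"client_id": att_client, "prescriber_id": att_presc})

    # monthly emissions per attachment
    keys = config.month_keys
    n_att = len(attachments)
    active = rng.random((n_att, config.n_months)) < config.visit_rate
    silent = ~active.any(axis=1)
    active[silent, rng.integers(0, config.n_months, size=int(silent.sum()))] = True
    rec_att, rec_month = np.nonzero(active)
    n_rec = len(rec_att)

    # draw a date within each record's month (clipped to the study window)
    starts = np.array([pd.Timestamp(_month_day_bounds(config, k)[0]).value for k in keys]) // 86_400_000_000_000
    ends = np.array([pd.Timestamp(_month_day_bounds(config, k)[1]).value for k in keys]) // 86_400_000_000_000
    days = rng.integers(starts[rec_month], ends[rec_month] + 1)
    dates = pd.to_datetime(days * 86_400_000_000_000).normalize()

    benzo = clients.set_index("client_id")["benzo_user"]
    is_benzo = benzo.reindex(attachments["client_id"].iloc[rec_att]).to_numpy()
    u = rng.random(n_rec)
    cum_a = np.cumsum(BACKGROUND_DRUG_P)
    cum_b = np.cumsum(BACKGROUND_DRUG_P_BENZO)
    drug_idx = np.where(is_benzo, np.searchsorted(cum_b, u), np.searchsorted(cum_a, u))
    drugs = np.array(BACKGROUND_DRUGS, dtype=object)[drug_idx]
    directions = np.array(BACKGROUND_DIRECTIONS, dtype=object)[
        rng.integers(0, len(BACKGROUND_DIRECTIONS), size=n_rec)
    ]
    from .defaults import DEFAULT_DRUG_CLASS_MAP

    disp = pd.DataFrame(
        {
            "client_id": attachments["client_id"].iloc[rec_att].to_numpy(),
            "prescriber_id": attachments["prescriber_id"].iloc[rec_att].to_numpy(),
            "date": pd.Series(dates).dt.strftime("%Y-%m-%d"),
            "drug_code": drugs,
            "med_class": [DEFAULT_DRUG_CLASS_MAP[d] for d in drugs],
            "directions": directions,
        }
    )

    # SUD indication records
    cl = clients.merge(
        attachments.groupby("client_id")["prescriber_id"].first().rename("first_prescriber"),
        left_on="client_id",
        right_index=True,
        how="left",
    )
    extra_disp, visits_rows, acute_rows = [], [], []
    for row in cl.itertuples(index=False):
        if row.sud_pathway == "none" or pd.isna(row.sud_qualifying_date):
            continue
        qdate = pd.Timestamp(row.sud_qualifying_date)
        if row.sud_pathway == "oat":
            extra_disp.append(
                (row.client_id, row.first_prescriber, str(qdate.date()), "METHADONE", "other", "Daily witnessed ingestion")
            )
        elif row.sud_pathway == "outpatient":
            for lag in (75, 30, 0):  # third distinct visit date is the qualifying date
                visits_rows.append(
                    (row.client_id, row.first_prescriber, str((qdate - pd.Timedelta(days=lag)).date()), "F19")
                )
        elif row.sud_pathway == "acute":
            acute_rows.append((row.client_id, str(qdate.date()), "F19"))
        # perinatal pathway lives in the client table (perinatal_sud_date)

    # background non-SUD outpatient noise
    n_noise = len(clients) // 2
    noise_clients = clients["client_id"].iloc[rng.integers(0, len(clients), size=n_noise)].to_numpy()
    noise_presc = cl.set_index("client_id")["first_prescriber"].reindex(noise_clients).to_numpy()
    noise_dates = _random_dates(rng, "2015-01-01", str(months.month_end(keys[-1]).date()), n_noise)
    for cid, pidv, dt, code in zip(
        noise_clients,
        noise_presc,
        noise_dates.dt.strftime("%Y-%m-%d"),
        np.array(NONSUD_DIAG_CODES, dtype=object)[rng.integers(0, len(NONSUD_DIAG_CODES), size=n_noise)],
    ):
        if isinstance(pidv, str):
            visits_rows.append((cid, pidv, dt, code))

    if extra_disp:
        disp = pd.concat(
            [disp, pd.DataFrame(extra_disp, columns=disp.columns.tolist())], ignore_index=True
        )
    visits = pd.DataFrame(visits_rows, columns=["client_id", "prescriber_id", "date", "diagnostic_code"])
    acute = pd.DataFrame(acute_rows, columns=["client_id", "date", "diagnostic_code"])
    disp = disp.sort_values(["date", "prescriber_id", "client_id", "drug_code"], kind="mergesort").reset_index(drop=True)
    visits = visits.sort_values(["date", "client_id"], kind="mergesort").reset_index(drop=True)
    acute = acute.sort_values(["date", "client_id"], kind="mergesort").reset_index(drop=True)
    return disp, visits, acute


def simulate_diffusion(
    dispensations: pd.DataFrame,
    prescribers: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Run the peer-driven adoption/discontinuation process and emit PSS records.

    Month by month: active adopters may discontinue (hazard on lagged
    exposure), non-adopters may adopt (hazard on lagged exposure and
    standardized log cumulative caseload), and every adopted, not-yet-stopped
    prescriber emits PSS dispensations whose directions text carries a planted
    case-finding keyword. Exposure is computed with the analysis modules
    themselves on the records emitted so far.
    """
    rng = rng if rng is not None else _rng(config, 2)
    keys = config.month_keys
    pid = prescribers["prescriber_id"].tolist()
    cohort = sorted(pid)

    attach = dispensations.groupby("prescriber_id")["client_id"].agg(lambda s: sorted(set(s)))
    attach = attach.reindex(cohort).apply(lambda v: v if isinstance(v, list) else [])

    # innovator seeds, weighted towards heavy caseloads
    n_clients_per = attach.apply(len).to_numpy(dtype=float)
    p_seed = n_clients_per / n_clients_per.sum()
    seeds = list(np.array(cohort, dtype=object)[
        rng.choice(len(cohort), size=config.n_innovator_seed, replace=False, p=p_seed)
    ])
    seed_month_idx = rng.integers(0, config.innovation_months, size=len(seeds))

    adoption: dict[str, str | None] = {p: None for p in cohort}
    stopped: dict[str, str | None] = {p: None for p in cohort}
    for s, mi in zip(seeds, seed_month_idx):
        adoption[s] = keys[int(mi)]

    ref_month = keys[config.innovation_months - 1]
    all_records = [dispensations[["client_id", "prescriber_id", "date"]]]
    pss_rows: list[tuple] = []

    def emit(prescriber: str, month_key: str) -> None:
        clients_avail = attach[prescriber]
        if not clients_avail:
            return
        n_rx = min(len(clients_avail), 1 + rng.poisson(max(config.pss_rx_rate - 1.0, 0.0)))
        chosen = rng.choice(len(clients_avail), size=n_rx, replace=False)
        lo, hi = _month_day_bounds(config, month_key)
        lo_d, hi_d = pd.Timestamp(lo).value // 86_400_000_000_000, pd.Timestamp(hi).value // 86_400_000_000_000
        for j in chosen:
            drug = PSS_DRUGS[int(rng.choice(len(PSS_DRUGS), p=PSS_DRUG_P))]
            if rng.random() < config.pss_specific_frac:
                text = PSS_DIRECTIONS_SPECIFIC[int(rng.integers(0, len(PSS_DIRECTIONS_SPECIFIC)))]
            else:
                text = PSS_DIRECTIONS_SENSITIVE_ONLY[int(rng.integers(0, len(PSS_DIRECTIONS_SENSITIVE_ONLY)))]
            date = pd.Timestamp(int(rng.integers(lo_d, hi_d + 1)) * 86_400_000_000_000).normalize()
            pss_rows.append(
                (clients_avail[j], prescriber, str(date.date()), drug, PSS_DRUG_CLASS[drug], text)
            )

    ref_caseload = None
    trace_rows: list[tuple] = []
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    for m, key in enumerate(keys, start=1):
        if m <= config.innovation_months:
            for s, mi in zip(seeds, seed_month_idx):
                if int(mi) == m - 1:
                    emit(s, key)
            # seeds keep prescribing through the innovation window
            for s, mi in zip(seeds, seed_month_idx):
                if int(mi) < m - 1:
                    emit(s, key)
            continue
        current = pd.concat(all_records + [
            pd.DataFrame(pss_rows, columns=["client_id", "prescriber_id", "date", "drug_code", "med_class", "directions"])[
                ["client_id", "prescriber_id", "date"]
            ]
        ] if pss_rows else all_records, ignore_index=True)
        prev = keys[m - 2]
        snapshot = network.build_monthly_network(
            current, cohort, prev, window="cumulative", study_start=config.study_start
        )
        adopters_prev = {p for p, am in adoption.items() if am is not None and am <= prev}
        exposure = network.peer_exposure(snapshot, adopters_prev, variant="unweighted")
        caseload = network.cumulative_caseload(current, cohort, prev, study_start=config.study_start)
        if ref_caseload is None:
            ref_caseload = caseload.copy()
        z = network.caseload_log_z(caseload, ref=ref_caseload)

        # discontinuation draws for prescribers adopted before this month
        for p in cohort:
            am = adoption[p]
            if am is not None and am < key and stopped[p] is None:
                ph = expit(config.discont_intercept + config.discont_beta_exposure * exposure[p])
                if rng.random() < ph:
                    stopped[p] = key
        # adoption draws for non-adopters
        for p in cohort:
            if adoption[p] is None:
                trace_rows.append((key, p, float(exposure[p]), float(z[p])))
                pa = expit(
                    config.adopt_intercept
                    + config.adopt_beta_exposure * exposure[p]
                    + config.adopt_beta_caseload * z[p]
                )
                if rng.random() < pa:
                    adoption[p] = key
        for p in cohort:
            am = adoption[p]
            if am is not None and am <= key and (stopped[p] is None or stopped[p] > key):
                emit(p, key)

    pss = pd.DataFrame(
        pss_rows, columns=["client_id", "prescriber_id", "date", "drug_code", "med_class", "directions"]
    )
    pss = pss.sort_values(["date", "prescriber_id", "client_id", "drug_code"], kind="mergesort").reset_index(drop=True)
    truth = SimulationTruth(
        true_coefficients={
            "adopt_intercept": config.adopt_intercept,
            "adopt_beta_exposure": config.adopt_beta_exposure,
            "adopt_beta_caseload": config.adopt_beta_caseload,
            "discont_intercept": config.discont_intercept,
            "discont_beta_exposure": config.discont_beta_exposure,
        },
        adoption_month={p: adoption[p] for p in cohort},
        discontinuation_month={p: stopped[p] for p in cohort},
        innovator_seeds=sorted(seeds),
        pss_dispensation_ids=[],
        hazard_trace=pd.DataFrame(
            trace_rows, columns=["month", "prescriber_id", "exposure", "caseload_z"]
        ),
    )
    return pss, truth


def simulate(config: SimulationConfig) -> SimulationData:
    """Full generation: population, affiliation stream, diffusion, truth ledger."""
    prescribers, clients = simulate_population(config, _rng(config, 0))
    disp, visits, acute = simulate_affiliation(prescribers, clients, config, _rng(config, 1))
    pss, truth = simulate_diffusion(disp, prescribers, config, _rng(config, 2))
    all_disp = pd.concat([disp, pss], ignore_index=True)
    all_disp = all_disp.sort_values(
        ["date", "prescriber_id", "client_id", "drug_code", "directions"], kind="mergesort"
    ).reset_index(drop=True)
    all_disp.insert(0, "dispensation_id", [f"D{i:07d}" for i in range(1, len(all_disp) + 1)])
    planted = all_disp["dispensation_id"][all_disp["drug_code"].isin(PSS_DRUG_CLASS)].tolist()
    truth.pss_dispensation_ids = planted
    truth.validate(config)
    return SimulationData(
        config=config,
        prescribers=prescribers,
        clients=clients,
        dispensations=all_disp,
        visits=visits,
        acute_visits=acute,
        truth=truth,
    )


def write_dataset(data: SimulationData, outdir: str | Path, fmt: str = "csv") -> None:
    """Write the five record tables plus the truth ledger (JSON key-value + events)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in data.tables.items():
        if fmt == "csv":
            table.to_csv(out / f"{name}.csv", index=False)
        elif fmt == "parquet":
            table.to_parquet(out / f"{name}.parquet", index=False)
        else:
            raise ConfigurationError(f"unknown table format {fmt!r}")
    payload = {
        "config": asdict(data.config),
        "true_coefficients": data.truth.true_coefficients,
        "innovator_seeds": data.truth.innovator_seeds,
        "events": [
            {
                "prescriber_id": p,
                "adoption_month": data.truth.adoption_month[p],
                "discontinuation_month": data.truth.discontinuation_month[p],
            }
            for p in sorted(data.truth.adoption_month)
        ],
        "pss_dispensation_ids": data.truth.pss_dispensation_ids,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_dataset(indir: str | Path, fmt: str = "csv") -> dict:
    """Read back the record tables (and truth ledger if present)."""
    out = {}
    indir = Path(indir)
    for name in ("prescribers", "clients", "dispensations", "visits", "acute_visits"):
        path = indir / f"{name}.{'csv' if fmt == 'csv' else 'parquet'}"
        out[name] = pd.read_csv(path, dtype={"diagnostic_code": str}) if fmt == "csv" else pd.read_parquet(path)
    truth_path = indir / "truth.json"
    if truth_path.exists():
        out["truth"] = json.loads(truth_path.read_text())
    return out
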