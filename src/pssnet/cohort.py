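"""SUD client case definition and the eligible prescriber cohort.

A client is considered to have a substance use disorder (SUD) if any of four
pathways qualifies them: receipt of opioid agonist treatment (OAT), at least
three outpatient visits on distinct dates with an SUD diagnostic code, at
least one acute-care visit with an SUD diagnostic code, or an SUD-indicating
perinatal record. The first indication date is the earliest date at which any
pathway's condition is met (for the visit-count rule, the date of the
qualifying third distinct visit), evaluated over all historical records.

The prescriber cohort contains every prescriber with at least one
dispensation inside the study window to a client whose first indication date
strictly precedes that dispensation.
"""

from __future__ import annotations

import pandas as pd

from .defaults import ConfigurationError

PATHWAY_ORDER = ["OAT receipt", "visit-count rule", "acute-care rule", "perinatal record"]

STUDY_WINDOW = ("2020-03-27", "2021-08-31")


def _validate_codes(codes, name: str) -> list[str]:
    codes = list(codes)
    if not codes:
        raise ConfigurationError(f"{name} must be non-empty")
    for entry in codes:
        if not isinstance(entry, str) or not entry.strip():
            raise ConfigurationError(f"invalid {name} entry: {entry!r}")
    return codes


def _matches_prefix(series: pd.Series, prefixes: list[str]) -> pd.Series:
    s = series.astype(str)
    out = pd.Series(False, index=series.index)
    for p in prefixes:
        out |= s.str.startswith(p)
    return out


def flag_sud_clients(
    dispensations: pd.DataFrame,
    visits: pd.DataFrame,
    acute_visits: pd.DataFrame,
    perinatal: pd.DataFrame,
    diagnostic_code_set,
    oat_drug_set,
    min_visits: int = 3,
    visit_window_days: int | None = None,
) -> pd.DataFrame:
    """Flag SUD clients and date their first indication.

    ``perinatal`` needs columns ``client_id`` and ``date`` (one row per
    SUD-indicating perinatal record). Diagnostic codes match by prefix; OAT
    drug codes match exactly. The visit-count rule requires ``min_visits``
    SUD-coded outpatient visits on distinct dates — over the client's whole
    history by default, or within a rolling window of ``visit_window_days``
    when set; the qualifying date is the visit completing the (first) run.
    Returns one row per client seen in any input with ``sud_indicated``,
    ``first_indication_date`` and ``pathway`` (earliest qualifying pathway;
    ties broken in the order OAT, visit-count, acute-care, perinatal).
    """
    diag = _validate_codes(diagnostic_code_set, "diagnostic code set")
    oat = _validate_codes(oat_drug_set, "OAT drug set")

    candidates = []
    if len(dispensations):
        d = dispensations[dispensations["drug_code"].isin(set(oat))]
        if len(d):
            first = pd.to_datetime(d["date"]).groupby(d["client_id"]).min()
            candidates.append(first.rename("date").reset_index().assign(pathway=PATHWAY_ORDER[0]))
    if len(visits):
        v = visits[_matches_prefix(visits["diagnostic_code"], diag)]
        if len(v):
            dates = v.assign(date=pd.to_datetime(v["date"]))[["client_id", "date"]].drop_duplicates()
            dates = dates.sort_values(["client_id", "date"])
            if visit_window_days is None:
                nth = dates.groupby("client_id").nth(min_visits - 1)  # k-th distinct visit date
                if len(nth):
                    candidates.append(nth.reset_index(drop=True).assign(pathway=PATHWAY_ORDER[1]))
            else:
                span = pd.Timedelta(days=visit_window_days)
                rows = []
                for cid, g in dates.groupby("client_id"):
                    d = g["date"].to_numpy()
                    for i in range(min_visits - 1, len(d)):
                        if d[i] - d[i - (min_visits - 1)] <= span:
                            rows.append((cid, d[i]))
                            break
                if rows:
                    candidates.append(
                        pd.DataFrame(rows, columns=["client_id", "date"]).assign(pathway=PATHWAY_ORDER[1])
                    )
    if len(acute_visits):
        a = acute_visits[_matches_prefix(acute_visits["diagnostic_code"], diag)]
        if len(a):
            first = pd.to_datetime(a["date"]).groupby(a["client_id"]).min()
            candidates.append(first.rename("date").reset_index().assign(pathway=PATHWAY_ORDER[2]))
    if len(perinatal):
        p = perinatal.dropna(subset=["date"])
        if len(p):
            first = pd.to_datetime(p["date"]).groupby(p["client_id"]).min()
            candidates.append(first.rename("date").reset_index().assign(pathway=PATHWAY_ORDER[3]))

    universe = pd.Index(
        pd.concat(
            [t["client_id"] for t in (dispensations, visits, acute_visits, perinatal) if len(t)],
            ignore_index=True,
        ).unique()
        if any(len(t) for t in (dispensations, visits, acute_visits, perinatal))
        else [],
        name="client_id",
    )
    flags = pd.DataFrame(index=universe).assign(
        sud_indicated=False, first_indication_date=pd.NaT, pathway=pd.NA
    )
    if candidates:
        cand = pd.concat(candidates, ignore_index=True)
        cand["rank"] = cand["pathway"].map({p: i for i, p in enumerate(PATHWAY_ORDER)})
        cand = cand.sort_values(["client_id", "date", "rank"], kind="mergesort")
        best = cand.groupby("client_id").first()
        flags.loc[best.index, "sud_indicated"] = True
        flags.loc[best.index, "first_indication_date"] = best["date"]
        flags.loc[best.index, "pathway"] = best["pathway"]
    return flags.reset_index()


def perinatal_records(clients: pd.DataFrame) -> pd.DataFrame:
    """Extract SUD-indicating perinatal records from the client table."""
    if "perinatal_sud_date" not in clients.columns:
        return pd.DataFrame(columns=["client_id", "date"])
    p = clients.loc[clients["perinatal_sud_date"].notna(), ["client_id", "perinatal_sud_date"]]
    return p.rename(columns={"perinatal_sud_date": "date"}).reset_index(drop=True)


def build_prescriber_cohort(
    dispensations: pd.DataFrame,
    sud_flags: pd.DataFrame,
    study_window: tuple[str, str] = STUDY_WINDOW,
) -> tuple[list[str], pd.DataFrame]:
    """Eligible prescribers and their qualifying client attachments.

    A prescriber is eligible if, inside the study window, they have at least
    one dispensation to a client whose first SUD indication date *strictly*
    precedes that dispensation. Returns ``(sorted prescriber ids, attachment
    table)`` where the attachment table holds the qualifying
    dispensation-level links (prescriber, client, date).
    """
    start, end = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
    if end < start:
        raise ConfigurationError("study window end precedes start")
    flagged = sud_flags[sud_flags["sud_indicated"]].set_index("client_id")["first_indication_date"]
    d = dispensations.copy()
    d["date"] = pd.to_datetime(d["date"])
    d = d[(d["date"] >= start) & (d["date"] <= end)]
    d = d[d["client_id"].isin(flagged.index)]
    indication = flagged.reindex(d["client_id"]).to_numpy()
    qualifying = d[pd.to_datetime(pd.Series(indication, index=d.index)) < d["date"]]
    attachments = qualifying[["prescriber_id", "client_id", "date"]].reset_index(drop=True)
    return sorted(attachments["prescriber_id"].unique()), attachments
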