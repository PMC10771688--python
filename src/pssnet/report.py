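"""Descriptive outputs with privacy-style small-cell suppression.

Counts below 10 are never shown: a primary-suppressed cell renders as
``"<10"``, and when exactly one cell of a variable-stratum group is
suppressed the next-smallest cell is secondarily suppressed as ``"<=10"`` so
the hidden count cannot be recovered from the group total. Percentages are
rendered to one decimal, medians to one decimal, both rounded half-up.
Re-running any report on identical inputs is byte-identical.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import months, network, pss as pss_mod

SUPPRESS_THRESHOLD = 10
SUPPRESSED = "<10"
SUPPRESSED_SECONDARY = "<=10"


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rendered half-up to ``decimals`` places (91.2 for 91.2%)."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, decimals)


def _suppress_group(counts: pd.Series) -> pd.Series:
    """Apply primary and complementary suppression within one group of cells.

    Zero cells are safe to show (they reveal only a category's absence);
    counts in 1..9 are masked, and when exactly one cell of the group is
    masked the smallest remaining nonzero cell is masked too, so the hidden
    count cannot be recovered from a printed group total.
    """
    display = counts.astype(object).copy()
    primary = (counts > 0) & (counts < SUPPRESS_THRESHOLD)
    display[primary] = SUPPRESSED
    rest = counts[~primary & (counts > 0)]
    if primary.sum() == 1 and len(rest):
        display[rest.idxmin()] = SUPPRESSED_SECONDARY
    return display


def stratified_summary(
    df: pd.DataFrame,
    stratum_col: str,
    categorical: list[str],
    continuous: list[str],
    strata_order: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format stratified characteristics table.

    Categorical variables render as ``count (pct%)`` with suppression applied
    per (variable, stratum) group *after* aggregation; continuous variables
    as ``median (Q1-Q3)``. Idempotent: suppression operates on counts, so
    re-summarizing the rendered table changes nothing.
    """
    strata = strata_order or sorted(df[stratum_col].dropna().unique())
    rows = []
    for var in categorical:
        for stratum in strata:
            sub = df[df[stratum_col] == stratum]
            counts = sub[var].value_counts().sort_index()
            counts = counts.reindex(sorted(df[var].dropna().unique()), fill_value=0)
            display = _suppress_group(counts)
            for level in counts.index:
                shown = display[level]
                if shown in (SUPPRESSED, SUPPRESSED_SECONDARY):
                    text = shown
                else:
                    text = f"{int(shown)} ({percent(int(shown), len(sub))}%)"
                rows.append((var, str(level), stratum, text))
    for var in continuous:
        for stratum in strata:
            vals = df.loc[df[stratum_col] == stratum, var].dropna()
            if not len(vals):
                rows.append((var, "median (IQR)", stratum, ""))
                continue
            med = round_half_up(float(vals.median()))
            q1 = round_half_up(float(vals.quantile(0.25)))
            q3 = round_half_up(float(vals.quantile(0.75)))
            rows.append((var, "median (IQR)", stratum, f"{med} ({q1}-{q3})"))
    return pd.DataFrame(rows, columns=["variable", "level", "stratum", "display"])


def table_one(
    prescribers: pd.DataFrame,
    adoption: pd.DataFrame,
    metrics_by_month: dict[str, pd.DataFrame],
    end_month: str,
) -> pd.DataFrame:
    """Characteristics of prescribers stratified by adoption status.

    Adopters are measured at their initiation month, non-adopters at the end
    of follow-up; network covariates come from ``metrics_by_month`` (the
    panel's monthly covariate tables). No test statistics are computed.
    """
    merged = adoption.merge(prescribers, on="prescriber_id")
    merged["measure_month"] = merged["first_pss_month"].fillna(end_month)
    merged["measure_month"] = merged["measure_month"].where(
        merged["measure_month"].isin(metrics_by_month), end_month
    )
    blocks = []
    for m, sub in merged.groupby("measure_month"):
        metrics = metrics_by_month[m]
        blocks.append(sub.join(metrics, on="prescriber_id", rsuffix="_m"))
    frame = pd.concat(blocks, ignore_index=True)
    continuous = [
        c
        for c in ("degree", "strength", "exposure", "clustering", "adjusted_strength",
                  "degree_centrality", "caseload_month")
        if c in frame.columns
    ]
    return stratified_summary(
        frame,
        "status",
        categorical=["region", "specialty", "oat_prescriber"],
        continuous=continuous,
        strata_order=[s for s in pss_mod.STATUSES if s in set(frame["status"])],
    )


def monthly_active_series(
    dispensations: pd.DataFrame,
    classification: pd.DataFrame,
    study_months: list[str],
    scheme: str = "calendar",
) -> pd.DataFrame:
    """Per-month active, cumulative-ever and lapsed safer-supply prescribers."""
    pss = pss_mod.pss_dispensations(dispensations, classification)
    keys = months.month_key(pss["date"], scheme=scheme) if len(pss) else pd.Series(dtype=str)
    rows = []
    seen: set[str] = set()
    for m in study_months:
        active = set(pss.loc[keys == m, "prescriber_id"]) if len(pss) else set()
        seen |= active
        rows.append((m, len(active), len(seen), len(seen) - len(active)))
    return pd.DataFrame(rows, columns=["month", "active", "cumulative", "lapsed"])


def prune_edges_top_quantile(snapshot: network.NetworkSnapshot, q: float = 0.20) -> pd.DataFrame:
    """Edges whose weight ranks in the top-``q`` share for BOTH endpoints.

    For a node of degree d, its top-q edges are the ``ceil(q*d)`` heaviest
    incident edges; ties at the boundary weight are retained.
    """
    edges = snapshot.edges
    if not len(edges):
        return edges
    incident: dict[str, list[float]] = {}
    for s, t, w in edges.itertuples(index=False):
        incident.setdefault(s, []).append(w)
        incident.setdefault(t, []).append(w)
    cutoff = {
        node: sorted(ws, reverse=True)[int(np.ceil(q * len(ws))) - 1]
        for node, ws in incident.items()
    }
    keep = [
        w >= cutoff[s] and w >= cutoff[t] for s, t, w in edges.itertuples(index=False)
    ]
    return edges[keep].reset_index(drop=True)


def render_markdown(summary: pd.DataFrame) -> str:
    """Render a stratified summary as a markdown table (stable ordering)."""
    strata = list(dict.fromkeys(summary["stratum"]))
    lines = ["| Variable | Level | " + " | ".join(strata) + " |",
             "|---|---|" + "---|" * len(strata)]
    for (var, level), sub in summary.groupby(["variable", "level"], sort=False):
        by = sub.set_index("stratum")["display"]
        cells = [str(by.get(s, "")) for s in strata]
        lines.append(f"| {var} | {level} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
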