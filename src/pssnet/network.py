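"""Monthly patient-sharing networks among prescribers.

Two prescribers are connected in a given measurement month if at least one
client received a medication dispensation from both of them within the
month's accumulation window; the edge weight is the number of distinct
shared clients. Per-node covariates (clustering coefficient, adjusted
strength, degree centrality) and the lagged peer-exposure measure — the
proportion of a prescriber's connected peers who had previously prescribed
safer supply — are computed from these snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from . import months
from .defaults import ConfigurationError

#: Ordered labels for the peer-exposure categories. Boundaries are closed on
#: the right: 0 -> none, (0, 0.10] -> "10% or less", (0.10, 0.20], (0.20, 1].
EXPOSURE_CATEGORIES = ("none", "10% or less", ">10 to 20%", ">20%")

EXPOSURE_VARIANTS = ("unweighted", "weighted", "two-degree")

STUDY_START = "2020-03-27"


@dataclass
class NetworkSnapshot:
    """Weighted prescriber-prescriber graph for one measurement month."""

    month: str
    nodes: list[str]
    graph: nx.Graph
    accumulation_window: str

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            (a, b, d["weight"]) if a < b else (b, a, d["weight"])
            for a, b, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "weight"])
        return df.sort_values(["source", "target"]).reset_index(drop=True)


def attachment_pairs(
    dispensations: pd.DataFrame,
    cohort: Iterable[str] | None = None,
    start: pd.Timestamp | str | None = None,
    end: pd.Timestamp | str | None = None,
) -> pd.DataFrame:
    """Distinct (client_id, prescriber_id) pairs with >=1 dispensation in window."""
    d = dispensations
    dates = pd.to_datetime(d["date"])
    mask = pd.Series(True, index=d.index)
    if start is not None:
        mask &= dates >= pd.Timestamp(start)
    if end is not None:
        mask &= dates <= pd.Timestamp(end)
    pairs = d.loc[mask, ["client_id", "prescriber_id"]].drop_duplicates()
    if cohort is not None:
        pairs = pairs[pairs["prescriber_id"].isin(set(cohort))]
    return pairs.reset_index(drop=True)


def project_shared_clients(pairs: pd.DataFrame) -> pd.DataFrame:
    """Project the bipartite client-prescriber pairs onto prescribers.

    Returns an edge list (source < target) with weight = number of distinct
    shared clients.
    """
    merged = pairs.merge(pairs, on="client_id")
    merged = merged[merged["prescriber_id_x"] < merged["prescriber_id_y"]]
    edges = (
        merged.groupby(["prescriber_id_x", "prescriber_id_y"], sort=True)["client_id"]
        .nunique()
        .reset_index()
    )
    edges.columns = ["source", "target", "weight"]
    return edges


def _window_bounds(month: str, window: str, study_start: str) -> tuple[pd.Timestamp, pd.Timestamp, str]:
    end = months.month_end(month)
    if window == "cumulative":
        start = pd.Timestamp(study_start)
        desc = f"cumulative {study_start}..{month}"
    elif window.startswith("trailing:"):
        k = int(window.split(":", 1)[1])
        if k < 1:
            raise ConfigurationError("trailing window length must be >= 1")
        start = max(pd.Timestamp(study_start), months.month_start(months.shift(month, -(k - 1))))
        desc = f"trailing {k} months ending {month}"
    else:
        raise ConfigurationError(f"unknown accumulation window {window!r}")
    return start, end, desc


def build_monthly_network(
    dispensations: pd.DataFrame,
    cohort: Iterable[str],
    month: str,
    window: str = "cumulative",
    study_start: str = STUDY_START,
) -> NetworkSnapshot:
    """Patient-sharing snapshot for one month.

    All cohort prescribers appear as nodes (isolates included); edges come from
    dispensation records inside the accumulation window, which by default
    accumulates from the study start through the end of the measurement month.
    """
    nodes = sorted(set(cohort))
    start, end, desc = _window_bounds(month, window, study_start)
    pairs = attachment_pairs(dispensations, cohort=nodes, start=start, end=end)
    edges = project_shared_clients(pairs)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_weighted_edges_from(edges.itertuples(index=False, name=None))
    return NetworkSnapshot(month=month, nodes=nodes, graph=graph, accumulation_window=desc)


def node_metrics(snapshot: NetworkSnapshot, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-node network covariates for one snapshot.

    ``pairs`` must be the client-prescriber attachment pairs of the same
    accumulation window; adjusted strength is defined on clients (the mean,
    over a prescriber's clients, of the number of *other* prescribers each
    client received dispensations from), not on the projected graph.
    """
    g = snapshot.graph
    n = len(snapshot.nodes)
    degree = dict(g.degree())
    clustering = nx.clustering(g)
    per_client = pairs.groupby("client_id")["prescriber_id"].transform("nunique")
    others = (
        pairs.assign(others=per_client - 1)
        .groupby("prescriber_id")["others"]
        .mean()
    )
    rows = []
    for node in snapshot.nodes:
        deg = degree.get(node, 0)
        rows.append(
            {
                "prescriber_id": node,
                "month": snapshot.month,
                "degree": deg,
                "clustering": float(clustering.get(node, 0.0)),
                "adjusted_strength": float(others.get(node, 0.0)),
                "degree_centrality": deg / (n - 1) if n > 1 else 0.0,
                "strength": float(sum(d["weight"] for _, _, d in g.edges(node, data=True))),
            }
        )
    return pd.DataFrame(rows)


def peer_exposure(
    snapshot: NetworkSnapshot,
    adopters: Iterable[str],
    variant: str = "unweighted",
) -> pd.Series:
    """Proportion of each node's connected peers who have previously adopted.

    ``adopters`` must already be restricted to prescribers with at least one
    safer-supply dispensation *before* the exposure month (the caller lags).
    Variants: ``unweighted`` (share of neighbours), ``weighted`` (share of
    incident edge weight attached to adopter neighbours), ``two-degree``
    (share of adopters within the two-step neighbourhood). Nodes with no
    peers get exposure 0.
    """
    if variant not in EXPOSURE_VARIANTS:
        raise ConfigurationError(
            f"unknown exposure variant {variant!r}; expected one of {EXPOSURE_VARIANTS}"
        )
    adopters = set(adopters)
    g = snapshot.graph
    out = {}
    for node in snapshot.nodes:
        if variant == "two-degree":
            hood = set(g.neighbors(node))
            for nb in list(hood):
                hood.update(g.neighbors(nb))
            hood.discard(node)
            out[node] = len(hood & adopters) / len(hood) if hood else 0.0
        elif variant == "weighted":
            total = adopted = 0.0
            for _, nb, d in g.edges(node, data=True):
                total += d["weight"]
                if nb in adopters:
                    adopted += d["weight"]
            out[node] = adopted / total if total > 0 else 0.0
        else:
            nbrs = list(g.neighbors(node))
            out[node] = (
                sum(nb in adopters for nb in nbrs) / len(nbrs) if nbrs else 0.0
            )
    return pd.Series(out, name="exposure").reindex(snapshot.nodes)


def cumulative_caseload(
    dispensations: pd.DataFrame,
    cohort: Iterable[str],
    month: str,
    study_start: str = STUDY_START,
) -> pd.Series:
    """Distinct clients per prescriber from study start through month end.

    Shared between the diffusion generator (whose adoption hazard uses this
    caseload, log-transformed and standardized) and the panel assembly, so the
    estimator's regressor is exactly the generator's.
    """
    pairs = attachment_pairs(
        dispensations, cohort=cohort, start=pd.Timestamp(study_start), end=months.month_end(month)
    )
    counts = pairs.groupby("prescriber_id")["client_id"].nunique()
    return counts.reindex(sorted(set(cohort))).fillna(0).astype(int)


def caseload_log_z(caseload: pd.Series, ref: pd.Series | None = None) -> pd.Series:
    """Standardized log(1 + caseload), using ``ref`` for centering/scaling."""
    x = np.log1p(caseload.astype(float))
    r = np.log1p(ref.astype(float)) if ref is not None else x
    sd = r.std(ddof=0)
    return (x - r.mean()) / (sd if sd > 0 else 1.0)


def categorize_exposure(exposure):
    """Map exposure proportions onto the four reporting categories.

    Accepts a scalar or a Series; boundaries at 0.10 and 0.20 are closed on
    the right, and exactly 0 (including isolated nodes) is "none".
    """
    e = pd.Series(exposure, dtype=float)
    if ((e < 0) | (e > 1)).any():
        raise ValueError("exposure must lie in [0, 1]")
    cats = np.select(
        [e == 0, e <= 0.10, e <= 0.20],
        [EXPOSURE_CATEGORIES[0], EXPOSURE_CATEGORIES[1], EXPOSURE_CATEGORIES[2]],
        default=EXPOSURE_CATEGORIES[3],
    )
    if np.isscalar(exposure) or isinstance(exposure, (int, float)):
        return cats[0]
    result = pd.Series(cats, index=e.index, name="exposure_category")
    return result
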