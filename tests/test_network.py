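"""Patient-sharing projection, node metrics and peer exposure vs brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pssnet import network
from pssnet.defaults import ConfigurationError

from conftest import make_dispensations


def random_pairs(rng, n_prescribers, n_clients, density=2.0):
    rows = []
    for c in range(n_clients):
        k = 1 + rng.poisson(density - 1)
        chosen = rng.choice(n_prescribers, size=min(k, n_prescribers), replace=False)
        rows.extend((f"C{c}", f"P{p:03d}") for p in chosen)
    return pd.DataFrame(rows, columns=["client_id", "prescriber_id"]).drop_duplicates()


def brute_force_projection(pairs):
    """Oracle: double loop over prescriber pairs intersecting client sets."""
    clients_of = pairs.groupby("prescriber_id")["client_id"].agg(set)
    edges = {}
    for a, b in itertools.combinations(sorted(clients_of.index), 2):
        shared = clients_of[a] & clients_of[b]
        if shared:
            edges[(a, b)] = len(shared)
    return edges


def snapshot_from_pairs(pairs, month="2020-06"):
    disp = pairs.assign(date="2020-06-10")
    cohort = sorted(pairs["prescriber_id"].unique())
    return network.build_monthly_network(disp, cohort, month)


def test_projection_minimal_cases():
    # one shared client -> single edge of weight 1
    pairs = pd.DataFrame({"client_id": ["C1", "C1"], "prescriber_id": ["A", "B"]})
    edges = network.project_shared_clients(pairs)
    assert edges.values.tolist() == [["A", "B", 1]]
    # three prescribers sharing one client -> triangle, all weights 1
    pairs = pd.DataFrame({"client_id": ["C1"] * 3, "prescriber_id": ["A", "B", "C"]})
    edges = network.project_shared_clients(pairs)
    assert len(edges) == 3 and set(edges["weight"]) == {1}


def test_projection_matches_brute_force():
    rng = np.random.default_rng(5)
    for trial in range(20):
        pairs = random_pairs(rng, n_prescribers=30, n_clients=60)
        edges = network.project_shared_clients(pairs)
        got = {(s, t): w for s, t, w in edges.itertuples(index=False)}
        assert got == brute_force_projection(pairs)


def test_clustering_and_centrality_match_brute_force():
    rng = np.random.default_rng(11)
    for trial in range(10):
        pairs = random_pairs(rng, n_prescribers=50, n_clients=80)
        snap = snapshot_from_pairs(pairs)
        metrics = network.node_metrics(snap, pairs).set_index("prescriber_id")
        g = snap.graph
        n = len(snap.nodes)
        for node in snap.nodes:
            nbrs = list(g.neighbors(node))
            deg = len(nbrs)
            tri = sum(
                1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
            )
            expected = tri / (deg * (deg - 1) / 2) if deg >= 2 else 0.0
            assert metrics.loc[node, "clustering"] == pytest.approx(expected)
            assert metrics.loc[node, "degree_centrality"] == pytest.approx(deg / (n - 1))


def test_adjusted_strength_from_client_attachments():
    # A's clients: C1 (sees A,B,C -> 2 others), C2 (sees A only -> 0); mean = 1
    disp = make_dispensations(
        [
            ("C1", "A", "2020-06-01"),
            ("C1", "B", "2020-06-02"),
            ("C1", "C", "2020-06-03"),
            ("C2", "A", "2020-06-04"),
        ]
    )
    snap = network.build_monthly_network(disp, ["A", "B", "C"], "2020-06")
    pairs = network.attachment_pairs(disp)
    metrics = network.node_metrics(snap, pairs).set_index("prescriber_id")
    assert metrics.loc["A", "adjusted_strength"] == pytest.approx(1.0)
    assert metrics.loc["B", "adjusted_strength"] == pytest.approx(2.0)


def test_exposure_variants_trivial_cases():
    pairs = pd.DataFrame(
        {"client_id": [f"C{i}" for i in range(5) for _ in (0, 1)],
         "prescriber_id": [x for i in range(5) for x in ("HUB", f"P{i}")]}
    )
    snap = snapshot_from_pairs(pairs)
    # 5 neighbours, 2 adopters -> 0.40
    e = network.peer_exposure(snap, {"P0", "P1"})
    assert e["HUB"] == pytest.approx(0.40)
    # isolated node: degree 0 -> exposure 0, category none
    disp = pairs.assign(date="2020-06-10")
    snap_iso = network.build_monthly_network(disp, sorted(set(pairs["prescriber_id"])) + ["LONER"], "2020-06")
    e_iso = network.peer_exposure(snap_iso, {"P0"})
    assert e_iso["LONER"] == 0.0
    assert network.categorize_exposure(e_iso)["LONER"] == "none"


def test_weighted_exposure_ratio():
    # weights: adopter edge 3, non-adopter edge 1 -> 0.75
    rows = [("C1", "A"), ("C2", "A"), ("C3", "A"), ("C4", "A")]
    rows += [("C1", "AD"), ("C2", "AD"), ("C3", "AD"), ("C4", "NA1")]
    pairs = pd.DataFrame(rows, columns=["client_id", "prescriber_id"])
    snap = snapshot_from_pairs(pairs)
    e = network.peer_exposure(snap, {"AD"}, variant="weighted")
    assert e["A"] == pytest.approx(0.75)


def test_exposure_matches_brute_force_all_variants():
    rng = np.random.default_rng(23)
    for trial in range(10):
        pairs = random_pairs(rng, n_prescribers=40, n_clients=70)
        snap = snapshot_from_pairs(pairs)
        nodes = snap.nodes
        adopters = set(rng.choice(nodes, size=len(nodes) // 4, replace=False))
        g = snap.graph
        uw = network.peer_exposure(snap, adopters, "unweighted")
        w = network.peer_exposure(snap, adopters, "weighted")
        two = network.peer_exposure(snap, adopters, "two-degree")
        for node in nodes:
            nbrs = list(g.neighbors(node))
            assert uw[node] == pytest.approx(
                (sum(n in adopters for n in nbrs) / len(nbrs)) if nbrs else 0.0
            )
            tw = sum(g[node][n]["weight"] for n in nbrs)
            aw = sum(g[node][n]["weight"] for n in nbrs if n in adopters)
            assert w[node] == pytest.approx(aw / tw if tw else 0.0)
            hood = set()
            for n1 in nbrs:
                hood.add(n1)
                hood.update(g.neighbors(n1))
            hood.discard(node)
            assert two[node] == pytest.approx(
                len(hood & adopters) / len(hood) if hood else 0.0
            )


def test_exposure_monotone_in_adopter_set():
    rng = np.random.default_rng(31)
    pairs = random_pairs(rng, n_prescribers=40, n_clients=60)
    snap = snapshot_from_pairs(pairs)
    nodes = snap.nodes
    small = set(rng.choice(nodes, size=5, replace=False))
    large = small | set(rng.choice(nodes, size=10, replace=False))
    e_small = network.peer_exposure(snap, small)
    e_large = network.peer_exposure(snap, large)
    assert (e_large >= e_small - 1e-12).all()


def test_cumulative_window_edges_monotone(small_data):
    cohort = sorted(small_data.prescribers["prescriber_id"])
    prev_edges = set()
    for m in ["2020-04", "2020-08", "2021-02"]:
        snap = network.build_monthly_network(small_data.dispensations, cohort, m)
        edges = {tuple(r[:2]) for r in snap.edges.itertuples(index=False)}
        assert prev_edges <= edges
        prev_edges = edges


@pytest.mark.parametrize(
    "value,expected",
    [
        (0.0, "none"),
        (0.05, "10% or less"),
        (0.10, "10% or less"),
        (0.1000001, ">10 to 20%"),
        (0.20, ">10 to 20%"),
        (0.21, ">20%"),
        (1.0, ">20%"),
        (1 / 10, "10% or less"),  # exact ratio at the boundary
        (2 / 10, ">10 to 20%"),
    ],
)
def test_exposure_categories(value, expected):
    assert network.categorize_exposure(value) == expected


def test_exposure_category_errors():
    with pytest.raises(ValueError):
        network.categorize_exposure(1.2)
    with pytest.raises(ConfigurationError):
        network.peer_exposure(
            snapshot_from_pairs(
                pd.DataFrame({"client_id": ["C1", "C1"], "prescriber_id": ["A", "B"]})
            ),
            set(),
            variant="cubed",
        )


def test_trailing_window_drops_old_edges():
    disp = make_dispensations(
        [("C1", "A", "2020-04-10"), ("C1", "B", "2020-04-12"), ("C2", "A", "2020-08-01"), ("C2", "C", "2020-08-02")]
    )
    cohort = ["A", "B", "C"]
    cum = network.build_monthly_network(disp, cohort, "2020-08", window="cumulative")
    assert cum.graph.has_edge("A", "B") and cum.graph.has_edge("A", "C")
    trail = network.build_monthly_network(disp, cohort, "2020-08", window="trailing:2")
    assert not trail.graph.has_edge("A", "B") and trail.graph.has_edge("A", "C")
    with pytest.raises(ConfigurationError):
        network.build_monthly_network(disp, cohort, "2020-08", window="yearly")


def test_empty_records_give_empty_graph():
    disp = make_dispensations([]).iloc[0:0]
    snap = network.build_monthly_network(disp, ["A", "B"], "2020-06")
    assert snap.graph.number_of_edges() == 0 and len(snap.nodes) == 2
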