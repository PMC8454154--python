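"""Co-occurrence networks, centralities, hubs, and the removal experiment."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from trophoweb.io import OtuTable, TaxonomyTable
from trophoweb.network import (
    NetworkModel,
    aggregate_to_rank,
    build_network,
    centralities,
    clr_pearson,
    hub_scores,
    perturb_and_compare,
    top_hub_unknown_fraction,
)


def _net_from_graph(g, flags=None):
    flags = flags or {n: False for n in g.nodes}
    for n in g.nodes:
        g.nodes[n]["unknown"] = flags[n]
    return NetworkModel(rank="genus", graph=g, unknown_flags=flags, threshold=0.35)


class TestAggregate:
    def test_same_genus_merged(self):
        tax = TaxonomyTable(
            {
                "o1": ["Bacteria", "P", "C", "O", "F", "GenA", "s"],
                "o2": ["Bacteria", "P", "C", "O", "F", "GenA", "s"],
                "o3": ["Bacteria", "P", "C", "O", "F", "GenB", "s"],
            }
        )
        table = OtuTable([[1, 2, 3]], ["s1"], ["o1", "o2", "o3"])
        agg, flags = aggregate_to_rank(table, tax, "genus")
        assert agg.counts[0, agg.otu_ids.index("GenA")] == 3
        assert not flags["GenA"]

    def test_unknown_marker_flagged(self):
        tax = TaxonomyTable(
            {"o1": ["Bacteria", "P", "C", "O", "F", "Uncultured bacterium", "s"]}
        )
        table = OtuTable([[4]], ["s1"], ["o1"])
        agg, flags = aggregate_to_rank(table, tax, "genus")
        assert all(flags.values())

    def test_matches_groupby_oracle(self, random_table):
        genera = [f"G{j % 6}" for j in range(random_table.n_otus)]
        tax = TaxonomyTable(
            {o: ["Bacteria", "P", "C", "O", "F", g, "s"] for o, g in zip(random_table.otu_ids, genera)}
        )
        agg, _ = aggregate_to_rank(random_table, tax, "genus")
        df = pd.DataFrame(random_table.counts, columns=genera)
        expect = df.T.groupby(level=0).sum().T
        got = pd.DataFrame(agg.counts, columns=agg.otu_ids)
        assert np.array_equal(got[expect.columns].to_numpy(), expect.to_numpy())

    def test_unsupported_rank(self, random_table):
        tax = TaxonomyTable({})
        with pytest.raises(ValueError):
            aggregate_to_rank(random_table, tax, "species")


def _correlated_block_table(rng, n_samples=200, n_noise=30):
    """Two planted co-varying taxa + independent noise taxa."""
    driver = rng.lognormal(0, 1, size=n_samples)
    a = rng.poisson(driver * 50) + 1
    b = rng.poisson(driver * 30) + 1
    noise = rng.poisson(20, size=(n_samples, n_noise)) + 1
    counts = np.column_stack([a, b, noise])
    ids = ["covA", "covB"] + [f"n{i}" for i in range(n_noise)]
    return OtuTable(counts, [f"s{i}" for i in range(n_samples)], ids)


class TestBuildNetwork:
    def test_planted_covariates_connected(self):
        rng = np.random.default_rng(1)
        table = _correlated_block_table(rng)
        net = build_network(table, threshold=0.35)
        assert net.graph.has_edge("covA", "covB")

    def test_null_edge_density_low(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, size=(200, 40)) + 1
        table = OtuTable(counts, [f"s{i}" for i in range(200)], [f"t{j}" for j in range(40)])
        net = build_network(table, threshold=0.35)
        possible = 40 * 39 / 2
        assert net.graph.number_of_edges() / possible < 0.02

    def test_impossible_threshold_gives_empty_graph(self):
        rng = np.random.default_rng(3)
        table = _correlated_block_table(rng)
        net = build_network(table, threshold=1.01)
        assert net.graph.number_of_edges() == 0

    def test_too_few_samples(self):
        table = OtuTable(np.ones((3, 12), dtype=int), ["a", "b", "c"], [f"t{j}" for j in range(12)])
        with pytest.raises(ValueError):
            build_network(table)


def _betweenness_oracle(g):
    """All-pairs shortest-path enumeration (n <= 12), normalized like networkx."""
    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            score[v] += frac
    denom = (n - 1) * (n - 2) / 2
    return {v: x / denom for v, x in score.items()}


class TestCentralities:
    def test_star_graph_closed_form(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        cent = centralities(g)
        assert cent.loc[0, "betweenness"] == pytest.approx(1.0)  # all 6 leaf pairs
        assert cent.loc[0, "closeness"] == pytest.approx(1.0)
        assert cent.loc[0, "degree"] == 4
        assert cent.loc[1, "closeness"] == pytest.approx((1 + 3 * 0.5) / 4)

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("loner")
        cent = centralities(g)
        assert (cent.loc["loner"] == 0).all()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        cent = centralities(g)
        oracle = _betweenness_oracle(g)
        for v in g.nodes:
            assert cent.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)


class TestHubScores:
    def test_eigenvector_oracle(self):
        g = nx.gnp_random_graph(10, 0.4, seed=6)
        scores = hub_scores(g)
        a = nx.to_numpy_array(g, nodelist=list(g.nodes))
        evals, evecs = np.linalg.eigh(a)
        principal = np.abs(evecs[:, np.argmax(evals)])
        principal /= principal.max()
        assert np.allclose(scores.to_numpy(), principal, atol=1e-6)

    def test_regular_graph_uniform(self):
        g = nx.cycle_graph(6)
        scores = hub_scores(g)
        assert np.allclose(scores.to_numpy(), 1.0, atol=1e-8)

    def test_disconnected_component_unaffected(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])  # dominant triangle
        g.add_edge("x", "y")
        before = hub_scores(g)
        g.add_edge("y", "z")  # still dominated by the triangle
        after = hub_scores(g)
        for v in ("a", "b", "c"):
            assert after[v] == pytest.approx(before[v], abs=1e-6)

    def test_edgeless_graph_warns_and_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        with pytest.warns(UserWarning):
            scores = hub_scores(g)
        assert (scores == 0).all()


class TestTopHubFraction:
    @pytest.mark.parametrize("flag_all,expected", [(True, 1.0), (False, 0.0)])
    def test_uniform_flags(self, flag_all, expected):
        g = nx.cycle_graph(8)
        net = _net_from_graph(g, {n: flag_all for n in g.nodes})
        assert top_hub_unknown_fraction(net, k=5) == expected

    def test_planted_connectors_dominate_top(self):
        # unknown nodes form the dense core; known nodes hang off it
        g = nx.complete_graph(6)
        mapping = {i: f"u{i}" for i in range(6)}
        g = nx.relabel_nodes(g, mapping)
        for i in range(12):
            g.add_edge(f"u{i % 6}", f"k{i}")
        flags = {n: n.startswith("u") for n in g.nodes}
        net = _net_from_graph(g, flags)
        assert top_hub_unknown_fraction(net, k=8) > 0.5


class TestPerturbation:
    @staticmethod
    def _connector_network(rng, n_clusters=4, cluster_size=6, flag_connectors=True):
        """Clusters joined only through unknown connector nodes."""
        g = nx.Graph()
        for c in range(n_clusters):
            members = [f"c{c}_{i}" for i in range(cluster_size)]
            for a, b in itertools.combinations(members, 2):
                if rng.random() < 0.8:
                    g.add_edge(a, b)
        connectors = [f"u{c}" for c in range(n_clusters)]
        for c in range(n_clusters):
            g.add_edge(connectors[c], f"c{c}_0")
            g.add_edge(connectors[c], f"c{(c + 1) % n_clusters}_0")
        flags = {n: (n in connectors if flag_connectors else False) for n in g.nodes}
        return _net_from_graph(g, flags)

    def test_removing_planted_connectors_drops_betweenness(self):
        rng = np.random.default_rng(7)
        net = self._connector_network(rng)
        res = perturb_and_compare(net, B=100, seed=1)
        m = "betweenness"
        wo = np.mean(res.distributions[m]["without_unknown"])
        boot = np.mean(res.distributions[m]["bootstrap"])
        assert wo < boot
        assert res.wilcoxon_p[m][("without_unknown", "bootstrap")] < 0.05

    def test_random_flags_are_null_vs_bootstrap(self):
        calm = 0
        for seed in range(10):
            rng = np.random.default_rng(50 + seed)
            g = nx.gnp_random_graph(40, 0.12, seed=int(rng.integers(1e6)))
            nodes = list(g.nodes)
            flagged = set(rng.choice(len(nodes), size=6, replace=False))
            flags = {n: (i in flagged) for i, n in enumerate(nodes)}
            net = _net_from_graph(g, flags)
            res = perturb_and_compare(net, B=40, seed=seed)
            ps = [res.wilcoxon_p[m][("original", "bootstrap")] for m in ("betweenness", "degree")]
            if all(p > 0.05 for p in ps):
                calm += 1
        assert calm >= 9

    def test_no_unknown_nodes_degenerate(self):
        g = nx.cycle_graph(8)
        net = _net_from_graph(g)
        res = perturb_and_compare(net, B=10, seed=0)
        assert res.degenerate
        assert res.wilcoxon_p == {}

    def test_deletion_never_increases_degree(self):
        rng = np.random.default_rng(8)
        net = self._connector_network(rng)
        deg_before = dict(net.graph.degree())
        g2 = net.graph.copy()
        g2.remove_nodes_from(net.unknown_nodes())
        for v, d in g2.degree():
            assert d <= deg_before[v]
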