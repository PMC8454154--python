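"""Co-occurrence networks and the role of unidentified ("dark matter") taxa.

Counts are aggregated to a taxonomic rank (class, family or genus); nodes
whose rank label is an unknown marker are flagged as dark matter.  The
association graph uses a centered-log-ratio (CLR) transform per sample —
the standard guard against compositional spurious correlation — followed
by pairwise Pearson correlation and a fixed absolute threshold.  The
estimator is pluggable: any callable mapping an aggregated count matrix to
an association matrix can be substituted.

The ecological role of the unknown nodes is probed by a node-removal
experiment: centralities of the Original network are compared with the
network after deleting all unknown nodes (Without-Unknown) and with B
bootstrap networks each deleting the same number of uniformly random
nodes, using two-sided Wilcoxon rank-sum tests per metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import OtuTable, TaxonomyTable, is_unknown_label

METRICS = ("betweenness", "degree", "closeness")


def aggregate_to_rank(
    table: OtuTable, taxonomy: TaxonomyTable, rank: str
) -> tuple[OtuTable, dict[str, bool]]:
    """Sum counts per rank label; flag unknown-marker labels.

    Unknown labels are kept distinct per marker+deepest-resolved prefix so
    that dark-matter reads form identifiable nodes instead of one blob.
    """
    if rank not in {"class", "family", "genus"}:
        raise ValueError("rank must be one of class, family, genus")
    labels = []
    for otu in table.otu_ids:
        lab = taxonomy.rank_label(otu, rank)
        if is_unknown_label(lab):
            labels.append(f"unknown_{rank}_{otu}")
        else:
            labels.append(lab)
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=labels)
    pooled = df.T.groupby(level=0).sum().T
    flags = {
        str(c): str(c).startswith(f"unknown_{rank}_") for c in pooled.columns
    }
    agg = OtuTable(
        pooled.to_numpy(), list(pooled.index), [str(c) for c in pooled.columns]
    )
    return agg, flags


def clr_pearson(counts: np.ndarray) -> np.ndarray:
    """CLR transform (pseudocount 0.5 on zeros) then Pearson correlation."""
    x = counts.astype(float)
    x[x == 0] = 0.5
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(clr, rowvar=False)
    return np.nan_to_num(r)


@dataclass
class NetworkModel:
    rank: str
    graph: nx.Graph  # nodes carry 'unknown' flag; edges carry 'weight'
    unknown_flags: dict[str, bool]
    threshold: float

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def unknown_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.nodes[n]["unknown"]]


def build_network(
    aggregated: OtuTable,
    unknown_flags: dict[str, bool] | None = None,
    min_prevalence: float = 0.2,
    assoc=clr_pearson,
    threshold: float = 0.35,
    rank: str = "genus",
    seed: int = 0,
) -> NetworkModel:
    """Thresholded CLR-Pearson co-occurrence network.

    Taxa present in fewer than ``min_prevalence`` of samples are dropped
    before association estimation; an edge joins two taxa when the absolute
    association exceeds ``threshold``.
    """
    if aggregated.n_samples < 4:
        raise ValueError("need at least 4 samples to estimate associations")
    prev = (aggregated.counts > 0).mean(axis=0)
    keep = prev >= min_prevalence
    ids = [o for o, k in zip(aggregated.otu_ids, keep) if k]
    if len(ids) < 10:
        raise ValueError("fewer than 10 nodes after the prevalence filter")
    sub = aggregated.select_otus(ids)
    r = assoc(sub.counts)
    g = nx.Graph()
    flags = unknown_flags or {}
    for n in ids:
        g.add_node(n, unknown=bool(flags.get(n, False)))
    n_taxa = len(ids)
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            if abs(r[i, j]) >= threshold:
                g.add_edge(ids[i], ids[j], weight=float(r[i, j]))
    return NetworkModel(
        rank=rank,
        graph=g,
        unknown_flags={n: bool(flags.get(n, False)) for n in ids},
        threshold=threshold,
    )


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and harmonic closeness per node.

    Betweenness is the fraction of all shortest paths passing through the
    node; closeness is harmonic (finite on disconnected graphs) normalized
    by n - 1.  All on the binarized graph.
    """
    n = graph.number_of_nodes()
    deg = dict(graph.degree())
    btw = nx.betweenness_centrality(graph, normalized=True)
    har = nx.harmonic_centrality(graph)
    norm = max(n - 1, 1)
    return pd.DataFrame(
        {
            "degree": pd.Series(deg, dtype=float),
            "betweenness": pd.Series(btw, dtype=float),
            "closeness": pd.Series({k: v / norm for k, v in har.items()}, dtype=float),
        }
    )


def hub_scores(net: NetworkModel | nx.Graph, tol: float = 1e-10, max_iter: int = 1000) -> pd.Series:
    """Principal-eigenvector hub score by power iteration, max normalized to 1.

    On an undirected graph HITS hub and authority scores coincide with the
    principal eigenvector of the adjacency matrix.
    """
    graph = net.graph if isinstance(net, NetworkModel) else net
    nodes = list(graph.nodes)
    if graph.number_of_edges() == 0:
        warnings.warn("edgeless graph: hub scores are all zero", stacklevel=2)
        return pd.Series(0.0, index=nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    x = np.ones(len(nodes)) / len(nodes)
    for _ in range(max_iter):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y = y / norm
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    return pd.Series(x / x.max(), index=nodes)


def top_hub_unknown_fraction(net: NetworkModel, k: int = 50) -> float:
    """Fraction of the top-k hub-score nodes flagged unknown.

    Ranking is deterministic: descending score, ties broken by node id.
    """
    scores = hub_scores(net)
    k = min(k, len(scores))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    if k == 0:
        return 0.0
    return sum(net.unknown_flags[n] for n, _ in ranked) / k


@dataclass
class PerturbationResult:
    distributions: dict[str, dict[str, np.ndarray]]  # metric -> network -> values
    wilcoxon_p: dict[str, dict[tuple[str, str], float]]
    direction: dict[str, dict[tuple[str, str], str]]
    n_bootstrap: int
    #: Monte-Carlo p per metric: two-sided rank of the Without-Unknown
    #: network's mean centrality among the bootstrap replicates' means.
    #: Exactly calibrated when the flags are exchangeable with random nodes.
    mc_p: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False


def perturb_and_compare(
    net: NetworkModel, B: int = 100, seed: int | np.random.Generator = 0
) -> PerturbationResult:
    """Original vs Without-Unknown vs Bootstrap centrality comparison.

    Without-Unknown deletes every unknown-flagged node.  Each of the B
    bootstrap replicates deletes the same *number* of uniformly random
    nodes; node values are pooled across replicates.  Distributions are
    compared pairwise per metric by two-sided Wilcoxon rank-sum tests, with
    the direction of the median shift recorded.

    Metrics are size-normalized before comparison (degree divided by the
    network's n-1; betweenness and harmonic closeness are already
    normalized), so that networks of different node counts are comparable
    and random deletion is distribution-neutral.
    """

    def _norm_cent(graph):
        c = centralities(graph)
        c["degree"] = c["degree"] / max(graph.number_of_nodes() - 1, 1)
        return c

    rng = np.random.default_rng(seed)
    unknown = net.unknown_nodes()
    cent_orig = _norm_cent(net.graph)
    if not unknown:
        return PerturbationResult(
            distributions={m: {"original": cent_orig[m].to_numpy()} for m in METRICS},
            wilcoxon_p={}, direction={}, n_bootstrap=B, degenerate=True,
        )
    g_wo = net.graph.copy()
    g_wo.remove_nodes_from(unknown)
    cent_wo = _norm_cent(g_wo)

    nodes = list(net.graph.nodes)
    n_remove = len(unknown)
    boot_vals: dict[str, list[np.ndarray]] = {m: [] for m in METRICS}
    for _ in range(B):
        drop = rng.choice(len(nodes), size=n_remove, replace=False)
        g_b = net.graph.copy()
        g_b.remove_nodes_from([nodes[i] for i in drop])
        cent_b = _norm_cent(g_b)
        for m in METRICS:
            boot_vals[m].append(cent_b[m].to_numpy())

    distributions = {
        m: {
            "original": cent_orig[m].to_numpy(),
            "without_unknown": cent_wo[m].to_numpy(),
            "bootstrap": np.concatenate(boot_vals[m]) if boot_vals[m] else np.array([]),
        }
        for m in METRICS
    }
    # Monte-Carlo exceedance: under random flags Without-Unknown is one more
    # draw from the bootstrap ensemble, so the rank of its mean among the B
    # replicate means is uniform on 1..B+1
    mc_p: dict[str, float] = {}
    for m in METRICS:
        wu_mean = float(np.mean(cent_wo[m])) if len(cent_wo) else np.nan
        boot_means = np.array([float(np.mean(v)) if len(v) else np.nan for v in boot_vals[m]])
        r_low = int(np.sum(boot_means <= wu_mean))
        r_high = int(np.sum(boot_means >= wu_mean))
        mc_p[m] = min(1.0, 2.0 * min(r_low + 1, r_high + 1) / (B + 1))

    pairs = [
        ("original", "without_unknown"),
        ("original", "bootstrap"),
        ("without_unknown", "bootstrap"),
    ]
    wilcoxon_p: dict[str, dict[tuple[str, str], float]] = {}
    direction: dict[str, dict[tuple[str, str], str]] = {}
    for m in METRICS:
        wilcoxon_p[m] = {}
        direction[m] = {}
        for a, b in pairs:
            xa, xb = distributions[m][a], distributions[m][b]
            if len(xa) == 0 or len(xb) == 0:
                wilcoxon_p[m][(a, b)] = np.nan
                direction[m][(a, b)] = "undefined"
                continue
            stat = sps.ranksums(xa, xb)
            wilcoxon_p[m][(a, b)] = float(stat.pvalue)
            ma, mb = np.median(xa), np.median(xb)
            direction[m][(a, b)] = (
                "decrease" if mb < ma else "increase" if mb > ma else "equal"
            )
    return PerturbationResult(
        distributions=distributions,
        wilcoxon_p=wilcoxon_p,
        direction=direction,
        n_bootstrap=B,
        mc_p=mc_p,
    )
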