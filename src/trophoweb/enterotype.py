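"""Enterotyping: Jensen-Shannon distance + partitioning around medoids.

Samples of one host group are clustered on genus-level relative-abundance
profiles using the Jensen-Shannon distance (square root of the base-2
Jensen-Shannon divergence, so distances lie in [0, 1]) and the PAM
k-medoids algorithm (BUILD + SWAP).  The number of clusters is chosen by
maximizing the Calinski-Harabasz index computed from the distance matrix;
silhouette widths are reported alongside.  Clustering is always performed
per host group, never across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .beta import DistanceMatrix
from .io import OtuTable, TaxonomyTable, is_unknown_label


def genus_profiles(table: OtuTable, taxonomy: TaxonomyTable) -> pd.DataFrame:
    """Genus-level relative-abundance profiles (samples x genera).

    OTU counts are summed per genus label and row-normalized.  OTUs without
    a resolved genus are pooled under ``unclassified_<deepest resolved
    rank>`` so that dark-matter reads are retained rather than dropped.
    """
    labels = []
    for otu in table.otu_ids:
        genus = taxonomy.rank_label(otu, "genus")
        if is_unknown_label(genus):
            labels.append(f"unclassified_{taxonomy.deepest_resolved(otu)}")
        else:
            labels.append(genus)
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=labels)
    pooled = df.T.groupby(level=0).sum().T
    totals = pooled.sum(axis=1)
    totals[totals == 0] = 1.0
    return pooled.div(totals, axis=0)


def jsd_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Jensen-Shannon distance (sqrt of base-2 JSD) between rows."""
    p = profiles.to_numpy(dtype=float)
    if (p < 0).any():
        raise ValueError("profiles must be non-negative")
    n = p.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jensenshannon(p[i], p[j], base=2)
    d = np.nan_to_num(d)  # identical rows can give tiny negative radicands
    return DistanceMatrix([str(s) for s in profiles.index], d, "jensen-shannon")


def _total_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam(
    dist: DistanceMatrix, k: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, list[int]]:
    """PAM k-medoids: greedy BUILD then SWAP until no improving exchange.

    Returns (assignment array of medoid indices per sample, medoid indices).
    Deterministic: ties are broken toward the lowest sample index; the seed
    is accepted for interface uniformity but the algorithm itself is
    deterministic given the distance matrix.
    """
    d = dist.data
    n = d.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [2, {n - 1}]")
    # BUILD: first medoid minimizes total distance; then greedy additions
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        best_gain, best_j = -np.inf, None
        current = d[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - d[:, j], 0.0).sum()
            if gain > best_gain + 1e-15:
                best_gain, best_j = gain, j
        medoids.append(int(best_j))
    # SWAP
    improved = True
    while improved:
        improved = False
        cost = _total_cost(d, medoids)
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1 :]
                delta = cost - _total_cost(d, trial)
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            improved = True
    medoids = sorted(medoids)
    assignment = np.asarray(medoids)[np.argmin(d[:, medoids], axis=1)]
    return assignment, medoids


def calinski_harabasz(dist: DistanceMatrix, assignment: np.ndarray) -> float:
    """CH index from a distance matrix via within/total sums of squares.

    Uses the identity sum of squared deviations = sum of squared pairwise
    distances / group size, so no coordinates are needed.
    """
    d2 = dist.data**2
    n = d2.shape[0]
    labels = pd.unique(assignment)
    k = len(labels)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in labels:
        idx = np.flatnonzero(assignment == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssb = sst - ssw
    if k < 2 or ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def silhouette(dist: DistanceMatrix, assignment: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    if len(pd.unique(assignment)) < 2:
        return np.nan
    return float(silhouette_score(dist.data, assignment, metric="precomputed"))


def choose_k(
    dist: DistanceMatrix,
    k_range=range(2, 11),
    seed: int | np.random.Generator = 0,
) -> tuple[int, dict[int, float]]:
    """Pick k maximizing the Calinski-Harabasz index over ``k_range``."""
    ks = [k for k in k_range if 2 <= k <= len(dist.sample_ids) - 1]
    if not ks:
        raise ValueError("empty or infeasible k range")
    index_values: dict[int, float] = {}
    for k in ks:
        assignment, _ = pam(dist, k, seed)
        index_values[k] = calinski_harabasz(dist, assignment)
    k_best = max(index_values, key=lambda k: (index_values[k], -k))
    return k_best, index_values


@dataclass
class EnterotypeResult:
    group: str
    k: int
    assignment: pd.Series  # sample_id -> cluster label
    medoid_ids: list[str]
    index_values: dict[int, float]
    driver_genus: dict[str, str]  # cluster label -> top mean-abundance genus
    silhouette: float


def enterotype_group(
    table: OtuTable,
    taxonomy: TaxonomyTable,
    group: str = "",
    k: int | None = None,
    k_range=range(2, 11),
    seed: int | np.random.Generator = 0,
) -> EnterotypeResult:
    """Cluster one host group's samples into enterotypes.

    Cluster labels follow the convention ``<first letter of group><driver
    genus>`` where the driver is the genus with the highest mean relative
    abundance within the cluster.
    """
    profiles = genus_profiles(table, taxonomy)
    dist = jsd_matrix(profiles)
    if k is None:
        k, index_values = choose_k(dist, k_range, seed)
    else:
        index_values = {}
    assignment, medoids = pam(dist, k, seed)
    prefix = group[0].upper() if group else "E"
    labels = {}
    driver: dict[str, str] = {}
    for m in medoids:
        members = profiles.iloc[np.flatnonzero(assignment == m)]
        top = str(members.mean(axis=0).idxmax())
        label = f"{prefix}_{top}"
        suffix = 2
        while label in driver:  # two clusters can share a driver genus
            label = f"{prefix}_{top}_{suffix}"
            suffix += 1
        labels[m] = label
        driver[label] = top
    series = pd.Series(
        [labels[m] for m in assignment], index=profiles.index, name="enterotype"
    )
    return EnterotypeResult(
        group=group,
        k=k,
        assignment=series,
        medoid_ids=[str(profiles.index[m]) for m in medoids],
        index_values=index_values,
        driver_genus=driver,
        silhouette=silhouette(dist, assignment),
    )
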