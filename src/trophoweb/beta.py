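"""Between-sample distances, ordination, and permutational ANOVA.

UniFrac distances are computed through scikit-bio's validated branch-walk
implementation; Jaccard is a direct set computation on presence/absence.
PCoA is classical metric scaling (double-centering + eigendecomposition)
with negative eigenvalues reported rather than corrected.  PERMANOVA uses
Anderson's pseudo-F on squared distances with a seeded label-permutation
null; the pairwise variant adjusts p-values (Benjamini-Hochberg by default)
and assigns compact letters so that groups sharing a letter are not
significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity import beta_diversity

from .io import OtuTable


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix."""

    sample_ids: list[str]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.isfinite(d).all():
            raise ValueError("non-finite distances")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        self.data = d

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


def _check_tips(table: OtuTable, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    present = np.asarray(table.counts).sum(axis=0) > 0
    for j, otu in enumerate(table.otu_ids):
        if present[j] and otu not in tips:
            raise ValueError(f"OTU {otu!r} has reads but is not a tip of the tree")


def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Presence/absence UniFrac: unshared branch length over total branch length."""
    _check_tips(table, tree)
    keep = table.counts.sum(axis=0) > 0
    ids = [o for o, k in zip(table.otu_ids, keep) if k]
    dm = beta_diversity(
        "unweighted_unifrac",
        table.counts[:, keep],
        ids=table.sample_ids,
        taxa=ids,
        tree=tree,
    )
    return DistanceMatrix(list(dm.ids), dm.data.copy(), "unweighted_unifrac")


def weighted_unifrac(table: OtuTable, tree: TreeNode, normalized: bool = True) -> DistanceMatrix:
    """Abundance-weighted UniFrac; normalized (bounded [0,1]) by default."""
    _check_tips(table, tree)
    keep = table.counts.sum(axis=0) > 0
    ids = [o for o, k in zip(table.otu_ids, keep) if k]
    dm = beta_diversity(
        "weighted_unifrac",
        table.counts[:, keep],
        ids=table.sample_ids,
        taxa=ids,
        tree=tree,
        normalized=normalized,
    )
    name = "weighted_unifrac_normalized" if normalized else "weighted_unifrac"
    return DistanceMatrix(list(dm.ids), dm.data.copy(), name)


def jaccard_distance(table: OtuTable) -> DistanceMatrix:
    """1 - |A&B|/|A|B| on presence sets; two empty samples have distance 0."""
    pres = table.counts > 0
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = np.count_nonzero(pres[i] | pres[j])
            if union == 0:
                dij = 0.0
            else:
                inter = np.count_nonzero(pres[i] & pres[j])
                dij = 1.0 - inter / union
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(table.sample_ids), d, "jaccard")


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    explained: np.ndarray  # fraction of positive-eigenvalue variance per axis
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Negative eigenvalues are reported as-is and excluded from both the
    coordinates and the explained-variance denominator.
    """
    d = dist.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals).max()) if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    explained = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    axes = [f"PC{i+1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dist.sample_ids, columns=axes),
        explained=explained,
        eigenvalues=evals,
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    df: tuple[int, int]


def _pseudo_f(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Anderson's pseudo-F and R^2 from squared distances and group labels."""
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    labels = pd.unique(groups)
    for g in labels:
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(labels)
    ssa = sst - ssw
    f = (ssa / (a - 1)) / (ssw / (n - a)) if ssw > 0 else np.inf
    r2 = ssa / sst if sst > 0 else 0.0
    return f, r2


def permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA (Adonis) with a seeded label-permutation p-value.

    ``exhaustive=True`` enumerates every distinct assignment of samples to
    the observed group sizes instead of sampling; the p-value is then the
    exact proportion of assignments (the observed one included) with
    F >= F_observed.
    """
    groups = np.asarray([str(x) for x in labels])
    if groups.shape[0] != len(dist.sample_ids):
        raise ValueError("labels length must match the distance matrix")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d2 = dist.data**2
    n = d2.shape[0]
    f_obs, r2 = _pseudo_f(d2, groups)
    if exhaustive:
        count = 0
        total = 0
        for assignment in _distinct_assignments(groups):
            f_perm, _ = _pseudo_f(d2, assignment)
            total += 1
            if f_perm >= f_obs - 1e-12:
                count += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            f_perm, _ = _pseudo_f(d2, groups[rng.permutation(n)])
            if f_perm >= f_obs - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        n_used = n_perm
    return PermanovaResult(
        pseudo_F=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_used,
        df=(len(uniq) - 1, n - len(uniq)),
    )


def _distinct_assignments(groups: np.ndarray):
    """Yield every distinct multiset permutation of the group labels."""
    from sympy.utilities.iterables import multiset_permutations

    for perm in multiset_permutations(list(groups)):
        yield np.asarray(perm)


def _compact_letters(groups: list[str], different: set[tuple[str, str]]) -> dict[str, str]:
    """Insertion-style compact letter display.

    Groups sharing a letter are not significantly different; every group
    gets at least one letter.
    """
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(tuple(sorted((g, h))) not in different for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in groups:
            if g in s:
                out[g] += alphabet[i % len(alphabet)]
    return out


def pairwise_permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    correction: str = "fdr_bh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """PERMANOVA for every unordered pair of groups, with adjusted p-values.

    Returns one row per pair (F, R^2, raw and adjusted p) plus a
    ``letters`` attribute in ``DataFrame.attrs`` giving the compact letter
    display at the chosen alpha.
    """
    from statsmodels.stats.multitest import multipletests

    groups = np.asarray([str(x) for x in labels])
    uniq = [str(g) for g in pd.unique(groups)]
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    base_seed = int(np.random.default_rng(seed).integers(2**31))
    rows = []
    for pair_idx, (ga, gb) in enumerate(combinations(uniq, 2)):
        mask = (groups == ga) | (groups == gb)
        ids = [s for s, m in zip(dist.sample_ids, mask) if m]
        sub = dist.submatrix(ids)
        # per-pair seed is reproducible independently of pair order
        res = permanova(sub, groups[mask], n_perm=n_perm, seed=np.random.default_rng([base_seed, pair_idx]))
        rows.append(dict(group_a=ga, group_b=gb, pseudo_F=res.pseudo_F, r_squared=res.r_squared, p_value=res.p_value))
    df = pd.DataFrame(rows)
    if correction == "none":
        df["p_adjusted"] = df["p_value"]
    else:
        method = {"fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}[correction]
        df["p_adjusted"] = multipletests(df["p_value"], method=method)[1]
    different = {
        tuple(sorted((r.group_a, r.group_b)))
        for r in df.itertuples()
        if r.p_adjusted < alpha
    }
    df.attrs["letters"] = _compact_letters(uniq, different)
    return df
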