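"""Distances, ordination and PERMANOVA against brute-force oracles."""

import io as _io
from itertools import combinations

import numpy as np
import pytest
from skbio import TreeNode
from sympy.utilities.iterables import multiset_permutations

from trophoweb.beta import (
    DistanceMatrix,
    jaccard_distance,
    pairwise_permanova,
    pcoa,
    permanova,
    unweighted_unifrac,
    weighted_unifrac,
)
from trophoweb.io import OtuTable


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick))


def _branch_sets(tree):
    """(branch length, descendant tip set) for every branch — oracle helper."""
    out = []
    for node in tree.traverse(include_self=False):
        if node.length:
            out.append((node.length, {t.name for t in node.tips()} or {node.name}))
    return out


def _unifrac_oracle(tree, pres_a: set, pres_b: set) -> float:
    shared = unique = 0.0
    for length, tips in _branch_sets(tree):
        in_a = bool(tips & pres_a)
        in_b = bool(tips & pres_b)
        if in_a and in_b:
            shared += length
        elif in_a or in_b:
            unique += length
    total = shared + unique
    return unique / total if total else 0.0


def _weighted_oracle(tree, rel_a: dict, rel_b: dict, normalized: bool) -> float:
    num = 0.0
    denom = 0.0
    root_dist = {}
    for tip in tree.tips():
        d = 0.0
        node = tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        root_dist[tip.name] = d
    for length, tips in _branch_sets(tree):
        a = sum(rel_a.get(t, 0.0) for t in tips)
        b = sum(rel_b.get(t, 0.0) for t in tips)
        num += length * abs(a - b)
    for name in set(rel_a) | set(rel_b):
        denom += root_dist[name] * (rel_a.get(name, 0.0) + rel_b.get(name, 0.0))
    return num / denom if normalized else num


class TestUnweightedUnifrac:
    def test_identical_profiles_zero(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        table = OtuTable([[1, 0, 2, 0], [5, 0, 1, 0]], ["s1", "s2"], list("ABCD"))
        d = unweighted_unifrac(table, tree)
        assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_star_tree_is_one(self):
        # star topology with unit branches (zero-length internal edges)
        tree = _tree("((A:1,B:1):0,(C:1,D:1):0);")
        table = OtuTable([[1, 1, 0, 0], [0, 0, 1, 1]], ["s1", "s2"], list("ABCD"))
        d = unweighted_unifrac(table, tree)
        assert d.data[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_branch_walk_oracle(self):
        rng = np.random.default_rng(5)
        tree = _tree("(((A:0.3,B:0.7):0.2,(C:0.5,D:0.1):0.9):0.4,((E:0.6,F:0.2):0.3,(G:0.8,H:0.4):0.1):0.5);")
        counts = rng.integers(0, 3, size=(4, 8))
        counts[:, 0] += 1  # no empty samples
        table = OtuTable(counts, [f"s{i}" for i in range(4)], list("ABCDEFGH"))
        d = unweighted_unifrac(table, tree)
        pres = [set(np.array(list("ABCDEFGH"))[row > 0]) for row in counts]
        for i in range(4):
            for j in range(i + 1, 4):
                assert d.data[i, j] == pytest.approx(_unifrac_oracle(tree, pres[i], pres[j]), abs=1e-9)

    def test_missing_tip_errors(self):
        tree = _tree("(A:1,B:1);")
        table = OtuTable([[1, 1]], ["s1"], ["A", "Z"])
        with pytest.raises(ValueError, match="Z"):
            unweighted_unifrac(table, tree)


class TestWeightedUnifrac:
    def test_identical_relative_profiles_zero(self):
        tree = _tree("((A:1,B:2):1,C:3);")
        table = OtuTable([[2, 2, 4], [1, 1, 2]], ["s1", "s2"], list("ABC"))
        d = weighted_unifrac(table, tree, normalized=True)
        assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_tip_swap_closed_form(self):
        # all mass on A vs all on B: raw distance = sum of both branch lengths
        tree = _tree("(A:0.4,B:0.6);")
        table = OtuTable([[10, 0], [0, 10]], ["s1", "s2"], ["A", "B"])
        d = weighted_unifrac(table, tree, normalized=False)
        assert d.data[0, 1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_brute_force(self, normalized):
        rng = np.random.default_rng(8)
        tree = _tree("((A:0.3,(B:0.2,C:0.4):0.5):0.1,(D:0.8,(E:0.6,F:0.9):0.2):0.7);")
        counts = rng.integers(1, 20, size=(3, 6))
        table = OtuTable(counts, ["s1", "s2", "s3"], list("ABCDEF"))
        d = weighted_unifrac(table, tree, normalized=normalized)
        rel = counts / counts.sum(axis=1, keepdims=True)
        profiles = [dict(zip("ABCDEF", row)) for row in rel]
        for i, j in combinations(range(3), 2):
            expect = _weighted_oracle(tree, profiles[i], profiles[j], normalized)
            assert d.data[i, j] == pytest.approx(expect, abs=1e-9)


class TestJaccard:
    def test_identical_and_disjoint(self):
        table = OtuTable([[1, 1, 0, 0], [1, 2, 0, 0], [0, 0, 3, 1]], ["a", "b", "c"], list("wxyz"))
        d = jaccard_distance(table)
        assert d.data[0, 1] == 0.0
        assert d.data[0, 2] == 1.0

    def test_matches_set_oracle(self, random_table):
        d = jaccard_distance(random_table)
        pres = random_table.counts > 0
        for i, j in combinations(range(random_table.n_samples), 2):
            a = {k for k in range(pres.shape[1]) if pres[i, k]}
            b = {k for k in range(pres.shape[1]) if pres[j, k]}
            expect = 1 - len(a & b) / len(a | b) if (a | b) else 0.0
            assert d.data[i, j] == pytest.approx(expect, abs=1e-12)

    def test_both_empty_defined_zero(self):
        table = OtuTable([[0, 0], [0, 0]], ["a", "b"], ["x", "y"])
        assert jaccard_distance(table).data[0, 1] == 0.0


class TestPcoa:
    def test_three_equidistant_points(self):
        d = DistanceMatrix(["a", "b", "c"], 1 - np.eye(3), "toy")
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], abs=1e-10)

    def test_reconstructs_euclidean_configuration(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d, "euclid"))
        coords = res.coordinates.to_numpy()
        d_rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(d_rec, d, atol=1e-9)
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_distances(self):
        res = pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "zero"))
        assert res.coordinates.shape[1] == 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]), "bad")


def _permanova_f_oracle(d, labels):
    """Direct Anderson pseudo-F from definition — independent re-derivation."""
    n = len(labels)
    sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        ssw += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    a = len(set(labels))
    return ((sst - ssw) / (a - 1)) / (ssw / (n - a))


class TestPermanova:
    def test_exhaustive_enumeration_matches_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 2))
        pts[:3] += 1.5
        dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dist = DistanceMatrix([f"s{i}" for i in range(6)], dmat, "euclid")
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dist, labels, exhaustive=True)
        # oracle: enumerate all C(6,3)=20 label arrangements by hand
        f_obs = _permanova_f_oracle(dmat, labels)
        count = total = 0
        for perm in multiset_permutations(labels):
            total += 1
            if _permanova_f_oracle(dmat, perm) >= f_obs - 1e-12:
                count += 1
        assert res.n_permutations == 20
        assert res.pseudo_F == pytest.approx(f_obs, abs=1e-9)
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = ["a"] * 5 + ["b"] * 5
        mine = permanova(DistanceMatrix([f"s{i}" for i in range(10)], dmat, "e"), labels, n_perm=99, seed=0)
        theirs = sk_permanova(SkDM(dmat, [f"s{i}" for i in range(10)]), labels, permutations=99)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_identical_groups_rarely_significant(self):
        rng = np.random.default_rng(10)
        hits = 0
        for rep in range(20):
            x = rng.normal(size=(12, 3))
            dmat = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
            res = permanova(
                DistanceMatrix([f"s{i}" for i in range(12)], dmat, "e"),
                ["a"] * 6 + ["b"] * 6,
                n_perm=99,
                seed=rng,
            )
            if res.p_value > 0.05:
                hits += 1
        assert hits >= 18

    def test_invariant_to_sample_reordering(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 2))
        x[:4] += 2
        dmat = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        ids = [f"s{i}" for i in range(8)]
        perm = rng.permutation(8)
        r1 = permanova(DistanceMatrix(ids, dmat, "e"), labels, exhaustive=True)
        r2 = permanova(
            DistanceMatrix([ids[i] for i in perm], dmat[np.ix_(perm, perm)], "e"),
            labels[perm],
            exhaustive=True,
        )
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_single_group_rejected(self):
        d = DistanceMatrix(["a", "b"], 1 - np.eye(2), "t")
        with pytest.raises(ValueError):
            permanova(d, ["g", "g"])


class TestPairwisePermanova:
    @staticmethod
    def _blobs(rng, centers, n_per):
        pts = np.vstack([rng.normal(c, 0.3, size=(n_per, 2)) for c in centers])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [f"g{k}" for k in range(len(centers)) for _ in range(n_per)]
        return DistanceMatrix([f"s{i}" for i in range(len(labels))], d, "e"), labels

    def test_two_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        dist, labels = self._blobs(rng, [(0, 0), (5, 5)], 6)
        df = pairwise_permanova(dist, labels, n_perm=199, seed=0)
        assert len(df) == 1
        letters = df.attrs["letters"]
        assert letters["g0"] != letters["g1"]

    def test_three_identical_groups_share_letter(self):
        shared = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            pts = rng.normal(size=(15, 2))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            dist = DistanceMatrix([f"s{i}" for i in range(15)], d, "e")
            labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
            df = pairwise_permanova(dist, labels, n_perm=99, seed=seed)
            letters = df.attrs["letters"]
            if len(set(letters.values())) == 1:
                shared += 1
        assert shared >= 9

    def test_consistent_with_direct_calls(self):
        rng = np.random.default_rng(2)
        dist, labels = self._blobs(rng, [(0, 0), (2, 0), (0, 2)], 4)
        df = pairwise_permanova(dist, labels, n_perm=99, seed=5)
        base_seed = int(np.random.default_rng(5).integers(2**31))
        groups = np.asarray(labels)
        for pair_idx, row in df.iterrows():
            mask = (groups == row.group_a) | (groups == row.group_b)
            ids = [s for s, m in zip(dist.sample_ids, mask) if m]
            direct = permanova(
                dist.submatrix(ids),
                groups[mask],
                n_perm=99,
                seed=np.random.default_rng([base_seed, pair_idx]),
            )
            assert direct.p_value == pytest.approx(row.p_value, abs=1e-12)
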