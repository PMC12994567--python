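"""Sharing matrices, public clonotypes, dissimilarity, UPGMA and PCoA."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from conftest import make_repertoire
from wildtcr.repertoire_io import AAKey, MouseMetadata, Repertoire
from wildtcr.sharing import (
    SharingMatrix,
    build_pair_table,
    dendrogram_order,
    linkage_to_newick,
    pairwise_shared,
    pcoa,
    public_clonotypes,
    sharing_percentage,
    sharing_to_dissimilarity,
)


def _rep(mouse_id, labels, count=1):
    clones = {AAKey(f"V{x}", f"C{x}", f"J{x}"): count for x in labels}
    return Repertoire(mouse_id=mouse_id, subset="CD4", chain="alpha",
                      clones=clones)


def _cohort(*mouse_labels):
    return {(f"m{i}", "CD4_alpha"): _rep(f"m{i}", labels)
            for i, labels in enumerate(mouse_labels)}


class TestPairwiseShared:
    def test_identical_repertoires_share_everything(self):
        labels = [f"k{i}" for i in range(30)]
        S = pairwise_shared(_cohort(labels, labels), "CD4_alpha", seed=0)
        assert S.S[0, 1] == 30 == S.S[0, 0]

    def test_disjoint_repertoires_share_nothing(self):
        S = pairwise_shared(_cohort(["a", "b"], ["c", "d"]), "CD4_alpha",
                            seed=0)
        assert S.S[0, 1] == 0

    def test_constructed_overlap_matches_set_intersection(self):
        """Equal-size repertoires (no resampling): shared counts equal
        brute-force set intersections."""
        a = [f"s{i}" for i in range(17)] + [f"a{i}" for i in range(23)]
        b = [f"s{i}" for i in range(17)] + [f"b{i}" for i in range(23)]
        c = [f"a{i}" for i in range(10)] + [f"c{i}" for i in range(30)]
        cohort = _cohort(a, b, c)
        S = pairwise_shared(cohort, "CD4_alpha", seed=0)
        sets = {mid: set(rep.clones) for (mid, _), rep in cohort.items()}
        for i, mi in enumerate(S.mouse_ids):
            for j, mj in enumerate(S.mouse_ids):
                assert S.S[i, j] == len(sets[mi] & sets[mj])
        assert S.S[0, 1] == 17

    def test_symmetry_bound_and_order_invariance(self):
        cohort = _cohort(["a", "b", "c"], ["b", "c", "d"], ["c", "d", "e"])
        S = pairwise_shared(cohort, "CD4_alpha", seed=1)
        assert (S.S == S.S.T).all()
        diag = np.diag(S.S)
        for i in range(3):
            for j in range(3):
                assert S.S[i, j] <= min(diag[i], diag[j])
        reordered = dict(reversed(list(cohort.items())))
        S2 = pairwise_shared(reordered, "CD4_alpha", seed=1)
        assert (S.S == S2.S).all() and S.mouse_ids == S2.mouse_ids

    def test_fewer_than_two_mice_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            pairwise_shared(_cohort(["a"]), "CD4_alpha", seed=0)


class TestPublicClonotypes:
    def _sets(self, *labelsets):
        return {f"m{i}": {AAKey(f"V{x}", f"C{x}", f"J{x}") for x in labels}
                for i, labels in enumerate(labelsets)}

    def test_three_of_four_is_public_at_75pct(self):
        sets = self._sets(["a", "b"], ["a"], ["a", "c"], ["d"])
        table, fraction = public_clonotypes(sets, threshold=0.75)
        assert list(table["cdr3_aa"]) == ["Ca"]
        assert table["prevalence"].iloc[0] == 3
        assert fraction == pytest.approx(1 / 4)

    def test_two_of_four_is_not_public(self):
        sets = self._sets(["a"], ["a"], ["b"], ["c"])
        table, _ = public_clonotypes(sets, threshold=0.75)
        assert table.empty

    def test_threshold_one_is_intersection(self):
        sets = self._sets(["a", "b"], ["a", "c"], ["a", "d"])
        table, _ = public_clonotypes(sets, threshold=1.0)
        assert list(table["cdr3_aa"]) == ["Ca"]

    def test_public_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(0)
        sets = {f"m{i}": {AAKey("V", f"C{k}", "J")
                          for k in rng.choice(40, size=15, replace=False)}
                for i in range(8)}
        counts = [len(public_clonotypes(sets, threshold=t)[0])
                  for t in (0.25, 0.5, 0.75, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            public_clonotypes(self._sets(["a"], ["b"]), threshold=0.0)


def _matrix(S):
    S = np.asarray(S)
    return SharingMatrix(mouse_ids=[f"m{i}" for i in range(S.shape[0])],
                         receptor_type="CD4_alpha", S=S,
                         downsample_target=10, seed=0)


class TestDissimilarity:
    def test_rescaled_example(self):
        S = _matrix([[20, 10, 4], [10, 20, 7], [4, 7, 20]])
        d = sharing_to_dissimilarity(S)
        assert d[0, 1] == 0 and d[0, 2] == 6 and d[1, 2] == 3
        assert (np.diag(d) == 0).all()

    def test_most_similar_pair_at_zero_and_symmetric(self):
        rng = np.random.default_rng(1)
        M = rng.integers(0, 50, size=(5, 5))
        M = (M + M.T) // 2
        np.fill_diagonal(M, 60)
        d = sharing_to_dissimilarity(_matrix(M))
        off = ~np.eye(5, dtype=bool)
        assert d[off].min() == 0
        assert (d == d.T).all()
        # order reversal: argmax similarity pair == argmin dissimilarity pair
        assert np.unravel_index(np.argmax(np.where(off, M, -1)), M.shape) == \
            np.unravel_index(np.argmin(np.where(off, d, np.inf)), d.shape)

    def test_all_equal_sharing_warns(self):
        S = _matrix([[5, 2, 2], [2, 5, 2], [2, 2, 5]])
        with pytest.warns(UserWarning, match="equal"):
            d = sharing_to_dissimilarity(S)
        assert (d == 0).all()

    def test_relative_form(self):
        S = _matrix([[20, 10, 5], [10, 20, 5], [5, 5, 20]])
        d = sharing_to_dissimilarity(S, form="relative")
        assert d[0, 1] == 0 and d[0, 2] == pytest.approx(0.5)

    def test_sharing_percentage(self):
        S = _matrix([[100, 6, 4], [6, 100, 2], [4, 2, 100]])
        assert sharing_percentage(S) == pytest.approx(4.0)


class TestDendrogram:
    def test_two_leaves_single_merge(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        order, Z = dendrogram_order(d)
        assert sorted(order) == [0, 1]
        assert Z.shape == (1, 4) and Z[0, 2] == 3.0

    def test_planted_blocks_are_contiguous(self):
        rng = np.random.default_rng(2)
        n = 10
        d = 5.0 + rng.uniform(0, 0.5, (n, n))
        d[:5, :5] = rng.uniform(0, 0.5, (5, 5))
        d[5:, 5:] = rng.uniform(0, 0.5, (5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        order, _ = dendrogram_order(d)
        first_block = {i for i in order[:5]}
        assert first_block in ({0, 1, 2, 3, 4}, {5, 6, 7, 8, 9})

    def test_permutation_invariance_up_to_relabelling(self):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        d = rng.uniform(1, 9, (6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        perm = rng.permutation(6)
        _, Z1 = dendrogram_order(d)
        _, Z2 = dendrogram_order(d[np.ix_(perm, perm)])
        c1 = squareform(cophenet(Z1))
        c2 = squareform(cophenet(Z2))
        assert np.allclose(c1[np.ix_(perm, perm)], c2)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            dendrogram_order(np.array([[0, 1], [2, 0.0]]))

    def test_newick_output_parses_with_correct_tips(self):
        from skbio import TreeNode

        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0.0]])
        _, Z = dendrogram_order(d)
        tree = TreeNode.read(io.StringIO(linkage_to_newick(Z, ["a", "b", "c"])))
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}
        # UPGMA tree is ultrametric: every tip sits at the root merge height
        depths = {t.name: tree.distance(t) for t in tree.tips()}
        assert np.allclose(list(depths.values()), Z[-1, 2])


class TestPCoA:
    def test_planted_configuration_recovered(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 2))
        res = pcoa(cdist(pts, pts))
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, res.coordinates[:, :2])
        assert disparity < 1e-8
        assert (res.eigenvalues[2:] < 1e-8).all()  # Euclidean-embeddable

    def test_uniform_weights_equal_classical(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(5, 3))
        d = cdist(pts, pts)
        mine = pcoa(d, weights=[1, 1, 1, 1, 1])
        ref = skbio_pcoa(d, method="eigh")
        ref_coords = np.asarray(ref.samples)
        k = mine.coordinates.shape[1]
        assert np.allclose(np.asarray(ref.eigvals)[:k],
                           mine.eigenvalues[:k], atol=1e-10)
        for j in range(min(3, k)):
            col, refcol = mine.coordinates[:, j], ref_coords[:, j]
            sign = np.sign(col @ refcol)
            assert np.allclose(sign * col, refcol, atol=1e-10)

    def test_weighted_matches_vegan_wcmdscale(self):
        """Frozen oracle: vegan::wcmdscale(d, w=c(1,2,1,3,1), eig=TRUE) on
        the Euclidean distances of five planted 2-D points."""
        pts = np.array([[0, 0], [1, 0], [0, 2], [3, 1], [2, 2]], float)
        res = pcoa(cdist(pts, pts), weights=[1, 2, 1, 3, 1])
        vegan_pts = np.array([
            [-1.7754474214, 0.5040202911],
            [-0.7989718795, 0.7196484807],
            [-1.3441910423, -1.4489307926],
            [1.3696073938, 0.1744293179],
            [0.6087600414, -1.0176744135]])
        vegan_eig = [12.23383726, 4.51616274]
        assert np.allclose(res.eigenvalues[:2], vegan_eig, atol=1e-7)
        for j in range(2):
            col = res.coordinates[:, j]
            sign = np.sign(col @ vegan_pts[:, j])
            assert np.allclose(sign * col, vegan_pts[:, j], atol=1e-7)

    def test_zero_distances_give_zero_coordinates(self):
        res = pcoa(np.zeros((4, 4)))
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.zeros((3, 3)), weights=[1, 1])


class TestPairTable:
    meta = [
        MouseMetadata("m0", "M", 10.0, "Nottingham"),
        MouseMetadata("m1", "F", 30.0, "Nottingham"),
        MouseMetadata("m2", "F", 5.0, "Nottingham"),
        MouseMetadata("m3", "M", 20.0, "Wirral"),
    ]

    def _S(self):
        S = np.array([[9, 1, 2, 3], [1, 9, 4, 5], [2, 4, 9, 6], [3, 5, 6, 9]])
        return SharingMatrix(mouse_ids=["m0", "m1", "m2", "m3"],
                             receptor_type="CD8_beta", S=S,
                             downsample_target=9, seed=0)

    def test_pair_combinatorics_and_fields(self):
        pairs = build_pair_table(self._S(), self.meta)
        assert len(pairs) == 6
        row = pairs[(pairs.mouse_a == "m0") & (pairs.mouse_b == "m1")].iloc[0]
        assert row["age_diff"] == 20.0 and row["age_sum"] == 40.0
        assert not row["same_sex"]
        assert row["shared"] == 1

    def test_site_filter(self):
        pairs = build_pair_table(self._S(), self.meta,
                                 site_filter="Nottingham")
        assert len(pairs) == 3
        assert set(pairs.mouse_a) | set(pairs.mouse_b) == {"m0", "m1", "m2"}

    def test_unknown_mouse_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_pair_table(self._S(), self.meta[:2])


@given(st.integers(0, 10**6))
def test_downsampled_sharing_is_reproducible(seed):
    reps = {}
    rng = np.random.default_rng(0)
    for i in range(3):
        labels = rng.choice(50, size=20, replace=False)
        reps[(f"m{i}", "CD4_alpha")] = _rep(
            f"m{i}", [f"k{x}" for x in labels], count=3 + i)
    a = pairwise_shared(reps, "CD4_alpha", seed=seed)
    b = pairwise_shared(reps, "CD4_alpha", seed=seed)
    assert (a.S == b.S).all()
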