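"""Mann-Whitney marker ranking, BH, Jaccard merging, final selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retrotag.markers import (
    MergeMap,
    jaccard_topsets,
    mann_whitney,
    merge_by_jaccard,
    rank_markers,
    select_final_markers,
)
from retrotag.qc import normalize_log

from conftest import make_adata


def exact_mw_p(x, y):
    """Full permutation enumeration oracle (no ties): two-sided p of the
    Mann-Whitney U under all C(m+n, m) group assignments."""
    x, y = list(x), list(y)
    m = len(x)
    combined = x + y

    def u_stat(idx):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(len(combined)) if i not in idx]
        return sum(1 for a in xs for b in ys if a > b)

    observed = u_stat(tuple(range(m)))
    mn = m * len(y)
    # two-sided: as extreme in either direction
    dev = abs(observed - mn / 2)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(combined)), m):
        u = u_stat(idx)
        if abs(u - mn / 2) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_strict_separation_exact_p(self):
        u, z, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(exact_mw_p([1, 2, 3], [4, 5, 6]), abs=1e-12)
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("m,n,seed", [(3, 4, 0), (4, 4, 1), (5, 3, 2),
                                          (2, 6, 3), (5, 5, 4)])
    def test_matches_enumeration_no_ties(self, m, n, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(m + n, dtype=float) + 1)
        x, y = vals[:m], vals[m:]
        _, _, p = mann_whitney(x, y)
        assert p == pytest.approx(exact_mw_p(x, y), abs=1e-9)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.5, 1, 40)
        y = rng.normal(0.0, 1, 60)
        _, z, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tie_correction_matches_scipy(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 4, 30).astype(float)
        _, _, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_z_sign_reflects_direction(self):
        _, z_hi, _ = mann_whitney([10, 11, 12, 13] * 4, [1, 2, 3, 4] * 4)
        _, z_lo, _ = mann_whitney([1, 2, 3, 4] * 4, [10, 11, 12, 13] * 4)
        assert z_hi > 0 > z_lo


def toy_marker_adata(seed=0, n_per=30):
    """Three clusters; gene0 marks cluster 0, gene1 marks cluster 1,
    gene2 is flat everywhere."""
    rng = np.random.default_rng(seed)
    n = 3 * n_per
    counts = rng.poisson(2.0, size=(n, 5))
    counts[:n_per, 0] += rng.poisson(15.0, n_per)
    counts[n_per: 2 * n_per, 1] += rng.poisson(15.0, n_per)
    counts[:, 2] = 3
    adata = make_adata(counts)
    normalize_log(adata)
    labels = np.repeat([0, 1, 2], n_per)
    return adata, labels


class TestRankMarkers:
    def test_marker_genes_top_ranked(self):
        adata, labels = toy_marker_adata()
        table = rank_markers(adata, labels, n_top=2)
        top0 = table.query("cluster == 0").iloc[0]
        top1 = table.query("cluster == 1").iloc[0]
        assert top0["gene"] == "g0" and top0["q"] < 0.01
        assert top1["gene"] == "g1" and top1["q"] < 0.01

    def test_flat_gene_never_beats_enriched(self):
        # constant gene has z ~ 0: never top where an enriched gene exists
        adata, labels = toy_marker_adata()
        table = rank_markers(adata, labels, n_top=1)
        assert "g2" not in set(table.query("cluster in (0, 1)")["gene"])

    def test_row_count_per_cluster(self):
        adata, labels = toy_marker_adata()
        table = rank_markers(adata, labels, n_top=4)
        assert (table.groupby("cluster").size() == 4).all()

    def test_bh_monotone_in_p(self):
        adata, labels = toy_marker_adata()
        table = rank_markers(adata, labels, n_top=5)
        for _, grp in table.groupby("cluster"):
            srt = grp.sort_values("p")
            assert srt["q"].ge(srt["p"] - 1e-15).all()
            # q ordering preserves p ordering
            assert (srt["q"].diff().dropna() >= -1e-12).all()

    def test_small_cluster_skipped_with_warning(self):
        adata, labels = toy_marker_adata()
        labels = labels.copy()
        labels[:2] = 9
        labels[2:30] = 0
        with pytest.warns(UserWarning, match="skipped"):
            table = rank_markers(adata, labels, n_top=2)
        assert 9 not in set(table["cluster"])

    def test_single_cluster_rejected(self):
        adata, labels = toy_marker_adata()
        with pytest.raises(ValueError):
            rank_markers(adata, np.zeros_like(labels))


class TestJaccard:
    def _table(self, sets):
        rows = [{"gene": g, "cluster": c} for c, gs in sets.items() for g in gs]
        return pd.DataFrame(rows)

    def test_identical_and_disjoint(self):
        tab = self._table({0: ["a", "b"], 1: ["a", "b"], 2: ["x", "y"]})
        J = jaccard_topsets(tab)
        assert J.loc[0, 1] == 1.0
        assert J.loc[0, 2] == 0.0
        assert np.all(np.diag(J.values) == 1.0)

    def test_forty_of_fifty_shared(self):
        a = [f"g{i}" for i in range(50)]
        b = [f"g{i}" for i in range(10, 60)]
        J = jaccard_topsets(self._table({0: a, 1: b}))
        assert J.loc[0, 1] == pytest.approx(40 / 60)

    def test_overlap_mode(self):
        a = [f"g{i}" for i in range(50)]
        b = [f"g{i}" for i in range(10, 60)]
        J = jaccard_topsets(self._table({0: a, 1: b}), mode="overlap")
        assert J.loc[0, 1] == pytest.approx(40 / 50)


def union_find_components(mat, threshold):
    """Independent connected-components oracle (union-find)."""
    n = mat.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] >= threshold:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


class TestMerge:
    def test_no_pair_above_threshold_identity(self):
        J = pd.DataFrame(np.eye(3), index=[0, 1, 2], columns=[0, 1, 2])
        merge = merge_by_jaccard(J, 0.8)
        assert merge.mapping == {0: 0, 1: 1, 2: 2}

    def test_transitive_closure(self):
        J = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.85], [0.1, 0.85, 1.0]],
            index=[0, 1, 2], columns=[0, 1, 2],
        )
        merge = merge_by_jaccard(J, 0.8)
        assert len(set(merge.mapping.values())) == 1

    def test_random_matrix_matches_union_find(self):
        rng = np.random.default_rng(7)
        n = 6
        mat = rng.random((n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        J = pd.DataFrame(mat, index=range(n), columns=range(n))
        merge = merge_by_jaccard(J, 0.7)
        oracle = union_find_components(mat, 0.7)
        # same partition (compare as co-membership)
        for i in range(n):
            for j in range(n):
                assert (merge.mapping[i] == merge.mapping[j]) == (
                    oracle[i] == oracle[j])

    def test_threshold_one_merges_only_identical_sets(self):
        J = pd.DataFrame(
            [[1.0, 1.0, 0.99], [1.0, 1.0, 0.99], [0.99, 0.99, 1.0]],
            index=[0, 1, 2], columns=[0, 1, 2],
        )
        merge = merge_by_jaccard(J, 1.0)
        assert merge.mapping[0] == merge.mapping[1] != merge.mapping[2]

    def test_bad_threshold_rejected(self):
        J = pd.DataFrame(np.eye(2), index=[0, 1], columns=[0, 1])
        with pytest.raises(ValueError):
            merge_by_jaccard(J, 0.0)

    def test_relabel_contiguous_by_smallest_member(self):
        J = pd.DataFrame(np.eye(4), index=[0, 1, 2, 3], columns=[0, 1, 2, 3])
        J.loc[1, 3] = J.loc[3, 1] = 0.9
        merge = merge_by_jaccard(J, 0.8)
        assert merge.mapping == {0: 0, 1: 1, 2: 2, 3: 1}

    def test_apply(self):
        merge = MergeMap({0: 0, 1: 0, 2: 1},
                         pd.DataFrame(np.eye(3)), 0.8)
        np.testing.assert_array_equal(
            merge.apply(np.array([2, 1, 0, 1])), [1, 0, 0, 0])


class TestFinalMarkers:
    def _table(self):
        return pd.DataFrame(
            {
                "gene": ["a", "a", "b", "c", "d"],
                "cluster": [0, 1, 0, 1, 1],
                "z_score": [5.0, 4.0, 3.0, 6.0, 2.0],
                "frac_in": [1.0, 1.0, 0.9, 0.8, 0.3],
                "frac_out": [0.0, 0.0, 0.1, 0.05, 0.0],
            }
        )

    def test_perfect_marker_kept(self):
        final = select_final_markers(self._table())
        assert "b" in set(final["gene"])
        assert "c" in set(final["gene"])

    def test_shared_gene_dropped_from_both(self):
        final = select_final_markers(self._table())
        assert "a" not in set(final["gene"])

    def test_low_frac_in_dropped(self):
        final = select_final_markers(self._table())
        assert "d" not in set(final["gene"])

    def test_empty_result_warns(self):
        tab = self._table()
        tab["frac_in"] = 0.0
        with pytest.warns(UserWarning, match="no genes"):
            final = select_final_markers(tab)
        assert final.empty
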