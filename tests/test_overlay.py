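"""Transgene overlay: calls, enrichment, contingency stats, diagnostics."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from retrotag.overlay import (
    CoexpressionRecord,
    ContingencyTable,
    TransgeneCalls,
    breadth,
    call_positive,
    chisq_2x2,
    cluster_enrichment,
    coexpression_rate,
    compartment_table,
    contamination_verdict,
    percent,
    perturbation_check,
)
from retrotag.qc import normalize_log

from conftest import make_adata


def calls_from_bool(flags: np.ndarray, name="tg") -> TransgeneCalls:
    return TransgeneCalls(
        calls=pd.DataFrame({name: np.asarray(flags, bool)}), theta=1)


class TestCallPositive:
    def test_zero_column_no_positives(self):
        adata = make_adata([[3, 0], [1, 0]],
                           classes=["endogenous", "transgene"])
        calls = call_positive(adata)
        assert calls.n_positive()["g1"] == 0

    def test_threshold_boundary(self):
        adata = make_adata([[0, 1], [0, 0], [0, 3]],
                           classes=["endogenous", "transgene"])
        assert call_positive(adata, theta=1).calls["g1"].sum() == 2
        assert call_positive(adata, theta=2).calls["g1"].sum() == 1

    def test_no_transgene_features_rejected(self):
        adata = make_adata([[1]])
        with pytest.raises(ValueError):
            call_positive(adata)


def enumerate_enrichment_p(N, K, n, k_obs):
    """Exhaustive placement oracle: P(>= k_obs positives in a size-n cluster
    when K positives fall on N cells uniformly without replacement)."""
    hits = 0
    cells = range(N)
    cluster = set(range(n))
    for placement in itertools.combinations(cells, K):
        if len(cluster & set(placement)) >= k_obs:
            hits += 1
    return hits / comb(N, K)


class TestEnrichment:
    def test_concentrated_positives_assigned(self):
        labels = np.repeat([0, 1], 50)
        pos = np.zeros(100, bool)
        pos[:20] = True
        df = cluster_enrichment(calls_from_bool(pos), labels)
        row0 = df.query("cluster == 0").iloc[0]
        row1 = df.query("cluster == 1").iloc[0]
        assert row0["p"] == df["p"].min() and row0["assigned"]
        assert not row1["assigned"]

    def test_small_toy_matches_exhaustive_enumeration(self):
        # 20 cells, 2 clusters of 12/8, 4 positives, 3 in cluster 0
        labels = np.repeat([0, 1], [12, 8])
        pos = np.zeros(20, bool)
        pos[[0, 1, 2, 15]] = True
        df = cluster_enrichment(calls_from_bool(pos), labels)
        p = df.query("cluster == 0")["p"].iloc[0]
        assert p == pytest.approx(enumerate_enrichment_p(20, 4, 12, 3),
                                  abs=1e-12)

    def test_uniform_positives_rarely_assigned(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(5), 40)
        n_bad = 0
        for _ in range(10):
            pos = np.zeros(200, bool)
            pos[rng.choice(200, 30, replace=False)] = True
            df = cluster_enrichment(calls_from_bool(pos), labels)
            n_bad += df["assigned"].any()
        assert n_bad <= 1


class TestChisq:
    def test_equal_proportions_zero(self):
        chi2, p = chisq_2x2(ContingencyTable(10, 30, 20, 60))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            a, b, c, d = rng.integers(1, 80, 4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            chi2, _ = chisq_2x2(t)
            N = a + b + c + d
            direct = N * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(direct, abs=1e-9)

    def test_two_proportion_z_squared_equals_chi2(self):
        t = ContingencyTable(15, 45, 30, 110)
        chi2, _ = chisq_2x2(t)
        p1, n1 = 15 / 60, 60
        p2, n2 = 30 / 140, 140
        pool = 45 / 200
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert z**2 == pytest.approx(chi2, rel=1e-9)

    def test_yates_reduces_statistic(self):
        t = ContingencyTable(12, 5, 7, 15)
        chi_plain, _ = chisq_2x2(t)
        chi_yates, _ = chisq_2x2(t, correction="yates")
        assert chi_yates < chi_plain

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="exact"):
            chisq_2x2(ContingencyTable(0, 0, 5, 5))

    def test_matches_scipy_contingency(self):
        from scipy.stats import chi2_contingency

        t = ContingencyTable(33, 34, 21, 139)
        chi2, p = chisq_2x2(t)
        ref = chi2_contingency([[33, 34], [21, 139]], correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestCompartmentTable:
    def _setup(self, n_pos_nn, n_pos_neu, n_neg_nn, n_neg_neu):
        pos = np.array([True] * (n_pos_nn + n_pos_neu)
                       + [False] * (n_neg_nn + n_neg_neu))
        comp = np.array(
            ["non_neuronal"] * n_pos_nn + ["neuronal"] * n_pos_neu
            + ["non_neuronal"] * n_neg_nn + ["neuronal"] * n_neg_neu)
        return calls_from_bool(pos), comp

    def test_published_collicular_counts(self):
        # 54,267 nuclei, 11,377 positive (153 non-neuronal),
        # 797 non-neuronal in total
        calls, comp = self._setup(153, 11224, 644, 42246)
        t = compartment_table(calls, comp, "tg", "versus_negative")
        assert (t.a, t.b, t.c, t.d) == (153, 11224, 644, 42246)
        t2 = compartment_table(calls, comp, "tg", "versus_total")
        assert (t2.a, t2.b, t2.c, t2.d) == (153, 11224, 797, 53470)

    def test_no_positives_degenerate_with_warning(self):
        calls, comp = self._setup(0, 0, 5, 5)
        with pytest.warns(UserWarning, match="degenerate"):
            t = compartment_table(calls, comp, "tg")
        assert t.a + t.b == 0

    def test_synthetic_truth_recount(self):
        rng = np.random.default_rng(2)
        pos = rng.random(200) < 0.3
        comp = np.where(rng.random(200) < 0.4, "non_neuronal", "neuronal")
        t = compartment_table(calls_from_bool(pos), comp, "tg")
        assert t.a == int((pos & (comp == "non_neuronal")).sum())
        assert t.n == 200


class TestVerdict:
    def test_zero_positives_undetected(self):
        pos = np.zeros(40, bool)
        comp = np.array(["neuronal"] * 30 + ["non_neuronal"] * 10)
        labels = np.repeat([0, 1], 20)
        with pytest.warns(UserWarning):
            v = contamination_verdict(calls_from_bool(pos), comp, labels, "tg")
        assert v.verdict == "undetected"

    def test_single_compartment_rejected(self):
        pos = np.ones(10, bool)
        comp = np.array(["neuronal"] * 10)
        with pytest.raises(ValueError):
            contamination_verdict(calls_from_bool(pos), comp,
                                  np.zeros(10, int), "tg")

    def test_depleted_positives_retrograde_consistent(self):
        # positives exclusively neuronal, strongly depleted of non-neuronal
        pos = np.array([True] * 80 + [False] * 220)
        comp = np.array(["neuronal"] * 160 + ["non_neuronal"] * 140)
        labels = np.zeros(300, int)
        v = contamination_verdict(calls_from_bool(pos), comp, labels, "tg")
        assert v.verdict == "retrograde_consistent"
        assert v.p_one_sided < 0.05

    def test_uniform_broad_positives_ambient_suspect(self):
        rng = np.random.default_rng(3)
        pos = rng.random(400) < 0.3
        comp = np.array(["neuronal"] * 240 + ["non_neuronal"] * 160)
        labels = np.repeat(np.arange(4), 100)
        v = contamination_verdict(calls_from_bool(pos), comp, labels, "tg")
        assert v.verdict == "ambient_suspect"
        assert v.breadth == 1.0


class TestBreadth:
    @pytest.mark.parametrize(
        "pos_clusters,expected",
        [(range(5), 1.0), ([], 0.0), ([0, 2, 4], 0.6)],
    )
    def test_fraction_of_clusters_with_positive(self, pos_clusters, expected):
        labels = np.repeat(np.arange(5), 10)
        pos = np.zeros(50, bool)
        for c in pos_clusters:
            pos[c * 10] = True
        assert breadth(calls_from_bool(pos), labels, "tg") == expected


class TestPerturbation:
    def _cluster_adata(self, spike=False, seed=0, n=60):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, size=(n, 20))
        pos = np.zeros(n, bool)
        pos[: n // 2] = True
        if spike:
            counts[pos, 5] = rng.poisson(12.0, pos.sum())
        adata = make_adata(counts)
        normalize_log(adata)
        return adata, pos

    def test_null_positives_nothing_significant(self):
        adata, pos = self._cluster_adata(spike=False)
        res = perturbation_check(
            adata, np.zeros(60, int), calls_from_bool(pos), 0, "tg")
        assert res.sufficient and res.n_significant == 0

    def test_spiked_gene_detected(self):
        adata, pos = self._cluster_adata(spike=True)
        res = perturbation_check(
            adata, np.zeros(60, int), calls_from_bool(pos), 0, "tg")
        assert "g5" in res.genes

    def test_insufficient_positives_explicit(self):
        adata, pos = self._cluster_adata()
        pos[:] = False
        pos[:5] = True
        res = perturbation_check(
            adata, np.zeros(60, int), calls_from_bool(pos), 0, "tg",
            min_pos=10)
        assert not res.sufficient and res.n_significant == 0


class TestCoexpression:
    @pytest.mark.parametrize(
        "probe,double,expected",
        [(145, 120, 83), (353, 307, 87), (67, 33, 49), (160, 21, 13),
         (173, 123, 71), (100, 0, 0)],
    )
    def test_rates(self, probe, double, expected):
        assert coexpression_rate(
            CoexpressionRecord(probe, double)) == expected

    def test_zero_probe_rejected(self):
        with pytest.raises(ValueError):
            coexpression_rate(CoexpressionRecord(0, 0))

    def test_double_exceeding_probe_rejected(self):
        with pytest.raises(ValueError):
            CoexpressionRecord(10, 11)

    def test_percent_half_up(self):
        assert percent(10, 1531, 2) == 0.65
        assert percent(1, 800, 2) == 0.13  # 0.125 rounds up
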