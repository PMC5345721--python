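"""Rank-sum and hypergeometric statistics against independent oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from dosagegi.features import (
    feature_report,
    group_means,
    rank_sum_test,
    substrate_enrichment,
)


def brute_force_rank_sum_p(a, b):
    """Two-sided exact P by explicit enumeration of all labelings."""
    vals = np.concatenate([a, b])
    ranks = rankdata(vals)
    na = len(a)
    w_obs = ranks[:na].sum()
    low = high = tot = 0
    for idx in itertools.combinations(range(len(vals)), na):
        w = ranks[list(idx)].sum()
        tot += 1
        low += w <= w_obs + 1e-9
        high += w >= w_obs - 1e-9
    return min(1.0, 2 * min(low, high) / tot)


class TestRankSum:
    def test_separated_groups_exact_p(self):
        """A={1,2,3} vs B={4,5,6}: most extreme of C(6,3)=20 labelings,
        one-sided 1/20, two-sided 0.1."""
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3], mode="exact")
        assert p == 1.0
        _, p = rank_sum_test([5, 5, 5], [5, 5], mode="auto")
        assert p == 1.0

    @given(st.data())
    @settings(max_examples=60)
    def test_exact_equals_brute_force_enumeration(self, data):
        """DP-based exact null equals explicit enumeration, ties included."""
        na = data.draw(st.integers(2, 6))
        nb = data.draw(st.integers(2, 8))
        vals = data.draw(st.lists(st.integers(0, 5), min_size=na + nb,
                                  max_size=na + nb))
        a, b = np.array(vals[:na], float), np.array(vals[na:], float)
        _, p = rank_sum_test(a, b, mode="exact")
        assert p == pytest.approx(brute_force_rank_sum_p(a, b), abs=1e-12)

    def test_normal_approx_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.gamma(3, 100, size=26)
            b = rng.gamma(3, 100, size=103)
            u, p = rank_sum_test(a, b, mode="normal_approx")
            ref = mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approx_close_to_exact_on_subsample(self):
        """On exact-capable subsamples of a 50/50 comparison, the normal
        approximation is within 10% relative of the exact P."""
        rng = np.random.default_rng(8)
        big_a = rng.normal(0.0, 1.0, 50)
        big_b = rng.normal(0.8, 1.0, 50)
        checked = 0
        for seed in range(12):
            sub = np.random.default_rng(seed)
            a = sub.choice(big_a, 10, replace=False)
            b = sub.choice(big_b, 10, replace=False)
            _, p_exact = rank_sum_test(a, b, mode="exact")
            _, p_norm = rank_sum_test(a, b, mode="normal_approx")
            if 0.05 <= p_exact <= 0.9:  # regime where a relative bound is fair
                assert abs(p_norm - p_exact) / p_exact < 0.10
                checked += 1
        assert checked >= 5

    def test_auto_switches_on_group_size(self):
        a = list(range(8))
        b = list(range(4, 16))
        _, p_auto = rank_sum_test(a, b, mode="auto")
        _, p_exact = rank_sum_test(a, b, mode="exact")
        assert p_auto == p_exact  # min(n) <= 10 -> exact
        with pytest.raises(ValueError):
            rank_sum_test(a, b, mode="bogus")
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestHypergeometric:
    def test_worked_overlap_example(self):
        """10 hits, 5 in a 20-gene substrate set, background 100:
        fold 2.5 and P by direct summation."""
        bg = [f"g{i}" for i in range(100)]
        fold, p = substrate_enrichment(bg[:10], bg[5:25], bg)
        p_direct = sum(comb(20, k) * comb(80, 10 - k)
                       for k in range(5, 11)) / comb(100, 10)
        assert fold == pytest.approx(2.5)
        assert p == pytest.approx(p_direct, rel=1e-12)

    def test_matches_direct_summation_small_universes(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n_bg = int(rng.integers(10, 61))
            bg = [f"g{i}" for i in range(n_bg)]
            hits = list(rng.choice(bg, int(rng.integers(1, n_bg // 2 + 1)),
                                   replace=False))
            subs = list(rng.choice(bg, int(rng.integers(1, n_bg // 2 + 1)),
                                   replace=False))
            k_obs = len(set(hits) & set(subs))
            fold, p = substrate_enrichment(hits, subs, bg)
            K, n = len(subs), len(hits)
            p_direct = sum(comb(K, k) * comb(n_bg - K, n - k)
                           for k in range(k_obs, min(K, n) + 1)) / comb(n_bg, n)
            assert p == pytest.approx(p_direct, rel=1e-9)
            assert 0 < p <= 1

    def test_monotone_decreasing_in_overlap(self):
        bg = [f"g{i}" for i in range(60)]
        subs = bg[:20]
        last = 1.1
        for k in range(0, 11):
            hits = subs[:k] + bg[20:30 + (10 - k)][: 10 - k]
            _, p = substrate_enrichment(hits, subs, bg)
            assert p <= last + 1e-12
            last = p

    def test_degenerate_cases(self):
        bg = [f"g{i}" for i in range(30)]
        fold, p = substrate_enrichment(bg[:5], bg[10:20], bg)  # no overlap
        assert fold == 0.0 and p == 1.0
        fold, p = substrate_enrichment(bg, bg, bg)  # saturation
        assert fold == 1.0 and p == 1.0
        with pytest.raises(ValueError):
            substrate_enrichment([], bg[:5], bg)
        with pytest.raises(ValueError):
            substrate_enrichment(["zz"], bg[:5], bg)


class TestGroupMeans:
    def _table(self):
        return pd.DataFrame({
            "gene": [f"g{i}" for i in range(6)],
            "klass": ["kinase"] * 4 + ["TF"] * 2,
            "disorder_len": [300.0, 318.0, 200.0, 236.0, 100.0, 150.0],
            "n_motifs": [4, 5, 2, 3, 1, 2],
            "n_ppi": [30, 22, 18, 22, 0, 12],
            "toxic": [True, True, False, False, True, False],
        })

    def test_arithmetic_means_and_extrema(self):
        s = group_means(self._table(), "kinase", "disorder_len")
        assert (s.toxic_mean, s.nontoxic_mean) == (309.0, 218.0)
        assert (s.toxic_min, s.toxic_max) == (300.0, 318.0)

    def test_single_member_group(self):
        s = group_means(self._table(), "TF", "disorder_len")
        assert s.toxic_mean == s.toxic_min == s.toxic_max == 100.0

    def test_ppi_excludes_unannotated(self):
        """Genes with no reported physical interaction leave the PPI
        comparison (never-tested is not zero-interaction)."""
        s = group_means(self._table(), "TF", "n_ppi")
        assert s.n_toxic == 0 and not s.defined

    def test_dual_class_genes_count_in_both_classes(self):
        df = self._table()
        df.loc[5, "klass"] = "both"
        kin = group_means(df, "kinase", "disorder_len")
        tf = group_means(df, "TF", "disorder_len")
        assert kin.n_nontoxic == 3  # picked up the dual-class gene
        assert tf.n_nontoxic == 1


class TestFeatureReport:
    def test_report_shape_and_bh(self):
        rng = np.random.default_rng(0)
        n = 120
        df = pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)],
            "klass": ["kinase"] * (n // 2) + ["TF"] * (n // 2),
            "disorder_len": rng.gamma(3, 100, n),
            "n_motifs": rng.poisson(3, n),
            "n_ppi": rng.poisson(20, n) + 1,
            "toxic": rng.random(n) < 0.3,
        })
        rep = feature_report(df, bh=True)
        assert len(rep) == 6
        assert {"p", "p_adj", "significant"} <= set(rep.columns)
        assert ((rep.p_adj >= rep.p) | rep.p.isna()).all()
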