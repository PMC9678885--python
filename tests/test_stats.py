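"""Statistical kernel: Fisher exact vs hypergeometric enumeration, BH step-up
vs a hand-coded oracle, bound-gene flagging, binned enrichment and chi-squared
homogeneity with adjusted residuals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, kstest

from regulome.intervals import AnnotatedPeak, GeneModel, ValidationError
from regulome.stats import (
    bh_adjust,
    binned_binding_enrichment,
    chisq_homogeneity,
    fisher_2x2,
    flag_bound_genes,
    gene_set_cooccurrence,
)


def fisher_oracle(a, b, c, d, alternative):
    """Full enumeration of the conditional hypergeometric distribution."""
    r, cc, n = a + b, a + c, a + b + c + d
    support = np.arange(max(0, r + cc - n), min(r, cc) + 1)
    pmf = hypergeom.pmf(support, n, r, cc)
    obs = pmf[support == a][0]
    if alternative == "greater":
        return float(pmf[support >= a].sum())
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


class TestFisher:
    def test_diagonal_table_exact_value(self):
        # margins (2,2), N=4: only the a=2 outcome is as extreme -> 1/6
        _, p = fisher_2x2(2, 0, 0, 2, "greater")
        assert p == pytest.approx(1 / 6)

    def test_balanced_table(self):
        odds, p = fisher_2x2(5, 5, 5, 5, "greater")
        assert odds == 1.0
        assert p == pytest.approx(fisher_oracle(5, 5, 5, 5, "greater"))

    def test_zero_top_left_gives_p_one(self):
        _, p = fisher_2x2(0, 7, 4, 9, "greater")
        assert p == 1.0

    def test_sample_odds_ratio_with_infinity(self):
        odds, _ = fisher_2x2(3, 0, 2, 5, "greater")
        assert odds == np.inf
        odds, _ = fisher_2x2(6, 3, 2, 4, "two_sided")
        assert odds == pytest.approx(6 * 4 / (3 * 2))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fisher_2x2(-1, 2, 3, 4)

    @pytest.mark.parametrize("alternative", ["greater", "two_sided"])
    def test_exhaustive_oracle_sweep(self, alternative):
        """p-values match hypergeometric enumeration for every small 2x2
        table (the full N <= 40 sweep runs in the acceptance suite)."""
        for n in range(1, 16):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        _, p = fisher_2x2(a, b, c, d, alternative)
                        assert p == pytest.approx(
                            fisher_oracle(a, b, c, d, alternative), rel=1e-7
                        ), (a, b, c, d)


def bh_oracle(p):
    """Hand-coded step-up: q_i = p_(i) * m / i, cumulative min from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, None, 1.0)
    return out


class TestBH:
    def test_uniformly_spaced_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = int(rng.integers(1, 201))
            p = rng.uniform(1e-12, 1.0, m)
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 0.0])

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_order_preservation(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12) and np.all(q <= 1.0)
        # order relations of distinct p-values are preserved
        p_arr = np.asarray(p)
        for i in range(len(p)):
            for j in range(len(p)):
                if p_arr[i] < p_arr[j]:
                    assert q[i] <= q[j] + 1e-12


class TestFlagBoundGenes:
    def make_genes(self, n=5):
        return [GeneModel(f"g{i}", "chr1", "+", i * 1000, i * 1000 + 500) for i in range(n)]

    def test_no_peaks_all_false(self):
        flags = flag_bound_genes([], self.make_genes())
        assert not flags["bound"].any()

    def test_single_annotation_flags_single_gene(self):
        flags = flag_bound_genes([AnnotatedPeak("p1", "g2", 10, "tss")], self.make_genes())
        assert flags.set_index("gene_id")["bound"].to_dict() == {
            "g0": False, "g1": False, "g2": True, "g3": False, "g4": False}

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValidationError):
            flag_bound_genes([AnnotatedPeak("p1", "nope", 0, "tss")], self.make_genes())

    def test_matches_linear_scan_oracle(self, rng):
        genes = [GeneModel(f"g{i}", "chr1", "+", i * 100, i * 100 + 50) for i in range(200)]
        anns = [AnnotatedPeak(f"p{j}", f"g{int(rng.integers(200))}", 0, "tss")
                for j in range(500)]
        flags = flag_bound_genes(anns, genes).set_index("gene_id")
        counts = {}
        for a in anns:
            counts[a.gene_id] = counts.get(a.gene_id, 0) + 1
        for g in genes:
            assert flags.loc[g.gene_id, "bound"] == (g.gene_id in counts)
            assert flags.loc[g.gene_id, "n_peaks"] == counts.get(g.gene_id, 0)


def make_de(rng, n=400, bound_p=0.2):
    return pd.DataFrame({
        "gene_id": [f"g{i:04d}" for i in range(n)],
        "log2fc": rng.normal(0, 1, n),
        "pvalue": rng.uniform(1e-12, 1, n),
        "padj": rng.uniform(1e-12, 1, n),
        "bound": rng.random(n) < bound_p,
    })


class TestBinnedEnrichment:
    def test_concentrated_binding_consistent_with_fisher(self, rng):
        de = make_de(rng, n=300)
        order = de.sort_values(["log2fc", "gene_id"]).index
        de["bound"] = False
        de.loc[order[:30], "bound"] = True  # all bound genes in the bottom bin
        res = binned_binding_enrichment(de, rank_bins=10)
        assert res[0].pvalue == min(r.pvalue for r in res)
        _, p = fisher_2x2(res[0].n_bound, res[0].n_genes - res[0].n_bound,
                          res[0].background_bound,
                          res[0].background_n - res[0].background_bound, "greater")
        assert res[0].pvalue == pytest.approx(p)

    def test_equal_bin_sizes(self, rng):
        de = make_de(rng, n=103)
        res = binned_binding_enrichment(de, rank_bins=10)
        sizes = [r.n_genes for r in res]
        assert sum(sizes) == 103 and max(sizes) - min(sizes) <= 1

    def test_group_binning_uses_raw_p_for_ns(self, rng):
        de = make_de(rng, n=50)
        de.loc[:, "pvalue"] = 0.5      # everything raw-nonsignificant
        de.loc[:, "padj"] = 0.01       # padj significant, but ns wins by raw p
        res = binned_binding_enrichment(de, groups=True)
        by_label = {r.bin_label: r for r in res}
        assert by_label["ns"].n_genes == 50
        assert by_label["up"].n_genes == 0

    def test_empty_bin_reports_p_one(self, rng):
        de = make_de(rng, n=20)
        labels = {g: "x" for g in de["gene_id"]}
        res = binned_binding_enrichment(de, bin_labels=labels)
        assert all(r.pvalue == 1.0 for r in res if r.n_genes == 0)


class TestChisq:
    def test_homogeneous_table_is_zero(self):
        res = chisq_homogeneity([[10, 10], [10, 10]])
        assert res.statistic == 0
        assert np.allclose(res.std_residuals, 0)

    def test_hand_computed_statistic(self):
        # all expected counts are 20: sum (O-E)^2/E = 4 * 100/20 = 20
        res = chisq_homogeneity([[30, 10], [10, 30]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_df_for_two_by_six(self):
        res = chisq_homogeneity(np.full((2, 6), 17))
        assert res.df == 5

    def test_residuals_antisymmetric_for_2x2(self, rng):
        t = rng.integers(5, 50, (2, 2))
        r = chisq_homogeneity(t).std_residuals.to_numpy()
        assert r[0, 0] == pytest.approx(-r[0, 1])
        assert r[0, 0] == pytest.approx(-r[1, 0])
        assert r[0, 0] == pytest.approx(r[1, 1])

    def test_statistic_invariant_under_permutation(self, rng):
        t = rng.integers(1, 40, (3, 4))
        s0 = chisq_homogeneity(t).statistic
        assert chisq_homogeneity(t[::-1]).statistic == pytest.approx(s0)
        assert chisq_homogeneity(t[:, ::-1]).statistic == pytest.approx(s0)

    def test_zero_margin_names_offender(self):
        with pytest.raises(ValidationError, match="column"):
            chisq_homogeneity([[1, 0], [2, 0]])


class TestCooccurrence:
    def test_identical_flags_are_maximally_associated(self):
        idx = [f"g{i}" for i in range(40)]
        flags = pd.Series([True] * 15 + [False] * 25, index=idx)
        odds, p = gene_set_cooccurrence(flags, flags)
        assert odds == np.inf
        assert p < 1e-8

    def test_consistent_with_fisher_on_joint_table(self, rng):
        idx = [f"g{i}" for i in range(100)]
        a = pd.Series(rng.random(100) < 0.3, index=idx)
        b = pd.Series(rng.random(100) < 0.4, index=idx)
        odds, p = gene_set_cooccurrence(a, b)
        tab = pd.crosstab(a, b).reindex(index=[True, False], columns=[True, False],
                                        fill_value=0)
        odds2, p2 = fisher_2x2(tab.iloc[0, 0], tab.iloc[0, 1],
                               tab.iloc[1, 0], tab.iloc[1, 1], "two_sided")
        assert p == pytest.approx(p2)

    def test_universe_mismatch_rejected(self):
        a = pd.Series([True], index=["g1"])
        b = pd.Series([True], index=["g2"])
        with pytest.raises(ValidationError):
            gene_set_cooccurrence(a, b)

    def test_null_p_values_roughly_uniform(self):
        """Independent random flags give p-values consistent with uniformity
        (KS over 200 null draws)."""
        rng = np.random.default_rng(11)
        n = 1000  # large universe keeps the exact test's discreteness negligible
        idx = [f"g{i}" for i in range(n)]
        ps = []
        for _ in range(200):
            a = pd.Series(rng.random(n) < 0.5, index=idx)
            b = pd.Series(rng.random(n) < 0.5, index=idx)
            ps.append(gene_set_cooccurrence(a, b)[1])
        assert kstest(ps, "uniform").pvalue > 0.01
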