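"""Core-program consensus filter, GSEA rank metric and preranked GSEA,
quadrant concordance and signature-restricted PCA."""

import numpy as np
import pandas as pd
import pytest

from regulome.coreprog import (
    MultiLineDE,
    core_consensus_filter,
    gsea_preranked,
    quadrant_concordance,
    rank_metric,
    signature_pca,
)
from regulome.intervals import ValidationError


def de_frame(gene_ids, log2fc, padj, pvalue=None):
    return pd.DataFrame({
        "gene_id": gene_ids,
        "log2fc": log2fc,
        "pvalue": pvalue if pvalue is not None else padj,
        "padj": padj,
    })


def random_multiline(rng, n_genes=50, n_lines=5):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    lines = {
        f"line{i}": de_frame(genes, rng.normal(0, 1, n_genes),
                             rng.uniform(1e-6, 1, n_genes))
        for i in range(n_lines)
    }
    lrt = de_frame(genes, rng.normal(0, 1, n_genes), rng.uniform(1e-6, 1, n_genes))
    return MultiLineDE(lines, lrt)


class TestCoreFilter:
    def test_consistent_gene_at_published_thresholds(self):
        """padj just under 0.1 in all five lines with concordant direction
        and LRT padj just under 0.05 qualifies as core-up."""
        genes = ["g1"]
        lines = {
            f"l{i}": de_frame(genes, [1.0], [padj])
            for i, padj in enumerate([0.09, 0.05, 0.01, 0.08, 0.099])
        }
        lrt = de_frame(genes, [1.0], [0.049])
        up, down = core_consensus_filter(MultiLineDE(lines, lrt))
        assert up == {"g1"} and down == set()

    def test_direction_discordance_excludes(self):
        genes = ["g1"]
        lines = {f"l{i}": de_frame(genes, [1.0], [0.01]) for i in range(4)}
        lines["l4"] = de_frame(genes, [-1.0], [0.01])
        up, down = core_consensus_filter(MultiLineDE(lines, de_frame(genes, [1.0], [0.001])))
        assert up == set() and down == set()

    def test_lrt_gate_required(self):
        genes = ["g1"]
        lines = {f"l{i}": de_frame(genes, [-2.0], [0.01]) for i in range(5)}
        up, down = core_consensus_filter(MultiLineDE(lines, de_frame(genes, [-2.0], [0.2])))
        assert down == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_algebra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_multiline(rng)
        up, down = core_consensus_filter(m, padj_pair=0.3, padj_lrt=0.3)
        lrt = m.lrt.set_index("gene_id")
        for g in m.lrt["gene_id"]:
            rows = [df.set_index("gene_id").loc[g] for df in m.lines.values()]
            exp_up = all(r["padj"] < 0.3 and r["log2fc"] > 0 for r in rows) \
                and lrt.loc[g, "padj"] < 0.3
            exp_dn = all(r["padj"] < 0.3 and r["log2fc"] < 0 for r in rows) \
                and lrt.loc[g, "padj"] < 0.3
            assert (g in up) == exp_up
            assert (g in down) == exp_dn
        assert not (up & down)

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(5)
        m = random_multiline(rng, n_genes=200)
        prev_up, prev_dn = set(), set()
        for a1, a2 in [(0.05, 0.01), (0.2, 0.05), (0.5, 0.2), (0.9, 0.9)]:
            up, dn = core_consensus_filter(m, padj_pair=a1, padj_lrt=a2)
            assert prev_up <= up and prev_dn <= dn
            prev_up, prev_dn = up, dn


class TestRankMetric:
    def test_signed_logp_arithmetic(self):
        de = de_frame(["a", "b", "c"], [2.0, -1.0, 0.5], [1, 1, 1],
                      pvalue=[0.01, 0.1, 1.0])
        ranked = rank_metric(de, mode="signed_logp").set_index("gene_id")["score"]
        assert ranked["a"] == pytest.approx(2.0)
        assert ranked["b"] == pytest.approx(-1.0)
        assert ranked["c"] == pytest.approx(0.0)

    def test_descending_with_deterministic_ties(self):
        de = de_frame(["b", "a", "c"], [1.0, 1.0, -1.0], [1, 1, 1],
                      pvalue=[0.1, 0.1, 0.01])
        ranked = rank_metric(de)
        assert list(ranked["gene_id"]) == ["a", "b", "c"]

    def test_zero_p_clamped(self):
        de = de_frame(["a"], [1.0], [1], pvalue=[0.0])
        score = rank_metric(de)["score"].iloc[0]
        assert np.isfinite(score) and score > 100


def make_ranked(n=10):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                         "score": np.linspace(3, -3, n)})


class TestGsea:
    def test_all_hits_at_top_gives_es_one(self):
        res = gsea_preranked(make_ranked(), {"g0", "g1"}, weight=0, n_perm=100, seed=0)
        assert res.es == pytest.approx(1.0)
        assert set(res.leading_edge) == {"g0", "g1"}

    def test_all_hits_at_bottom_gives_es_minus_one(self):
        res = gsea_preranked(make_ranked(), {"g8", "g9"}, weight=0, n_perm=100, seed=0)
        assert res.es == pytest.approx(-1.0)
        assert set(res.leading_edge) == {"g8", "g9"}

    def test_matches_brute_force_running_sum(self, rng):
        """ES equals an independently coded running-sum maximum for random
        sets, both weights."""
        ranked = pd.DataFrame({"gene_id": [f"g{i}" for i in range(40)],
                               "score": np.sort(rng.normal(0, 2, 40))[::-1]})
        for weight in (0, 1):
            for _ in range(20):
                members = set(rng.choice(ranked["gene_id"], 8, replace=False))
                res = gsea_preranked(ranked, members, weight=weight, n_perm=50, seed=1)
                running, best = 0.0, 0.0
                w = [abs(s) ** weight if g in members else 0
                     for g, s in zip(ranked["gene_id"], ranked["score"])]
                tot = sum(w) if sum(w) else 1
                miss = 1 / (40 - len(members))
                for g, wi in zip(ranked["gene_id"], w):
                    running += wi / tot if g in members else -miss
                    if abs(running) > abs(best):
                        best = running
                assert res.es == pytest.approx(best)

    def test_es_bounded(self, rng):
        ranked = make_ranked(50)
        for _ in range(20):
            members = set(rng.choice(ranked["gene_id"], 10, replace=False))
            res = gsea_preranked(ranked, members, weight=1, n_perm=50, seed=2)
            assert -1 <= res.es <= 1
            assert set(res.leading_edge) <= members

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValidationError):
            gsea_preranked(make_ranked(), {"absent"}, n_perm=100, seed=0)

    def test_appending_tail_genes_preserves_es_weight0(self):
        ranked = make_ranked(10)
        res1 = gsea_preranked(ranked, {"g0", "g2"}, weight=0, n_perm=100, seed=0)
        longer = pd.concat([
            ranked,
            pd.DataFrame({"gene_id": [f"x{i}" for i in range(5)],
                          "score": np.linspace(-4, -5, 5)}),
        ], ignore_index=True)
        res2 = gsea_preranked(longer, {"g0", "g2"}, weight=0, n_perm=100, seed=0)
        # extremum still at the same prefix; only the miss decrement changes slightly
        assert np.sign(res1.es) == np.sign(res2.es)
        assert set(res1.leading_edge) == set(res2.leading_edge)


class TestQuadrant:
    def test_identical_tables_all_concordant(self, rng):
        genes = [f"g{i}" for i in range(100)]
        de = de_frame(genes, rng.normal(0, 1, 100), rng.uniform(0.0001, 0.2, 100))
        res = quadrant_concordance(de, de, alpha=0.1)
        assert res["concordant_fraction"] == 1.0

    def test_negated_tables_all_anticorrelated(self, rng):
        genes = [f"g{i}" for i in range(100)]
        de = de_frame(genes, rng.normal(0, 1, 100), rng.uniform(0.0001, 0.2, 100))
        neg = de.copy()
        neg["log2fc"] = -neg["log2fc"]
        res = quadrant_concordance(de, neg, alpha=0.1)
        assert res["anticorrelated_fraction"] == 1.0

    def test_planted_anticorrelation_recovered(self):
        """Bivariate-normal effects with rho=-0.7 give a predominantly
        anti-diagonal sign table among jointly significant genes."""
        rng = np.random.default_rng(21)
        n = 2000
        cov = [[1, -0.7], [-0.7, 1]]
        eff = rng.multivariate_normal([0, 0], cov, n)
        genes = [f"g{i}" for i in range(n)]
        # strong effects -> small padj; weak -> large
        pa = np.clip(2 * (1 - np.abs(eff[:, 0])), 1e-6, 1)
        pb = np.clip(2 * (1 - np.abs(eff[:, 1])), 1e-6, 1)
        de_a = de_frame(genes, eff[:, 0], pa)
        de_b = de_frame(genes, eff[:, 1], pb)
        res = quadrant_concordance(de_a, de_b, alpha=0.1)
        assert res["n"] > 50
        assert res["anticorrelated_fraction"] > 0.8
        assert res["pvalue"] < 1e-6

    def test_no_passing_genes_warns_empty(self, rng):
        genes = ["g1", "g2"]
        de = de_frame(genes, [1, -1], [0.5, 0.9])
        res = quadrant_concordance(de, de, alpha=0.1)
        assert res["n"] == 0 and res["pvalue"] is None


class TestSignaturePca:
    def test_identical_samples_share_scores(self):
        expr = pd.DataFrame(np.vstack([[1, 2, 3, 4]] * 2 + [[4, 3, 2, 1]] * 2),
                            columns=list("abcd"))
        scores = signature_pca(expr, {"a", "b", "c", "d"})
        assert scores.iloc[0]["PC1"] == pytest.approx(scores.iloc[1]["PC1"])

    def test_invariant_to_gene_order(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 8)), columns=list("abcdefgh"))
        s1 = signature_pca(expr, set("abcdef"))
        s2 = signature_pca(expr[list("hgfedcba")], set("abcdef"))
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_matches_covariance_eigendecomposition(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 10)),
                            columns=[f"g{i}" for i in range(10)])
        scores = signature_pca(expr, set(expr.columns))
        x = expr.to_numpy() - expr.to_numpy().mean(0)
        evals, evecs = np.linalg.eigh(x.T @ x)
        for j, col in enumerate(["PC1", "PC2"]):
            v = evecs[:, -1 - j]
            proj = x @ v
            assert np.allclose(np.abs(scores[col]), np.abs(proj), atol=1e-8)

    def test_constant_gene_dropped(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 3)), columns=["a", "b", "c"])
        expr["c"] = 7.0
        scores = signature_pca(expr, {"a", "b", "c"})
        assert scores.shape == (4, 2)
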