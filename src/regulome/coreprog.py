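"""Cross-cell-line core program extraction and preranked GSEA.

A "core" target gene of a transcription factor is one that responds
consistently to its depletion in every cell line tested: adjusted p below a
pairwise threshold with the same direction of change in all lines, plus a
significant joint likelihood-ratio test across lines.  Ranked lists for GSEA
are built either from a supplied test statistic or as
sign(LFC) * -log10(p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import ValidationError
from .stats import fisher_2x2

logger = logging.getLogger(__name__)


@dataclass
class MultiLineDE:
    """Per-line differential-expression tables plus a joint LRT-style table.

    Each line table and the LRT table must have columns gene_id, log2fc,
    pvalue, padj over a shared gene universe.
    """

    lines: dict[str, pd.DataFrame]
    lrt: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.lines) < 2:
            raise ValidationError("MultiLineDE: need at least 2 cell lines")


def core_consensus_filter(
    m: MultiLineDE, padj_pair: float = 0.1, padj_lrt: float = 0.05
) -> tuple[set[str], set[str]]:
    """Core up/down gene sets: consistent pairwise response + joint LRT.

    A gene is core-up iff padj < ``padj_pair`` with log2fc > 0 in every line
    and LRT padj < ``padj_lrt``; core-down analogously with log2fc < 0.
    Genes missing from any table are excluded (counted in the log).
    """
    universe = None
    for df in list(m.lines.values()) + [m.lrt]:
        s = set(df["gene_id"])
        universe = s if universe is None else universe & s
    n_dropped = len(set(m.lrt["gene_id"]) - universe)
    if n_dropped:
        logger.info("core_consensus_filter: %d genes missing from some line, excluded", n_dropped)

    lrt = m.lrt.set_index("gene_id")
    lrt_ok = lrt.loc[sorted(universe), "padj"] < padj_lrt
    up = pd.Series(True, index=lrt_ok.index)
    down = pd.Series(True, index=lrt_ok.index)
    for df in m.lines.values():
        t = df.set_index("gene_id").loc[lrt_ok.index]
        sig = t["padj"] < padj_pair
        up &= sig & (t["log2fc"] > 0)
        down &= sig & (t["log2fc"] < 0)
    core_up = set(lrt_ok.index[up & lrt_ok])
    core_down = set(lrt_ok.index[down & lrt_ok])
    return core_up, core_down


def rank_metric(de: pd.DataFrame, mode: str = "signed_logp") -> pd.DataFrame:
    """Descending ranked gene list for preranked GSEA.

    ``signed_logp``: sign(log2fc) * -log10(p); ``stat``: the supplied ``stat``
    column.  Zero p-values are clamped to the smallest positive float.  Ties
    break by gene_id so the ordering is deterministic.
    """
    if de["gene_id"].duplicated().any():
        raise ValidationError("rank_metric: duplicate gene_ids")
    if mode == "signed_logp":
        p = de["pvalue"].to_numpy(float)
        n_zero = int((p <= 0).sum())
        if n_zero:
            logger.warning("rank_metric: clamped %d nonpositive p-values", n_zero)
            p = np.maximum(p, np.finfo(float).tiny)
        score = np.sign(de["log2fc"].to_numpy(float)) * -np.log10(p)
    elif mode == "stat":
        score = de["stat"].to_numpy(float)
    else:
        raise ValidationError(f"rank_metric: unknown mode {mode!r}")
    out = pd.DataFrame({"gene_id": de["gene_id"].to_numpy(), "score": score})
    return out.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class GseaResult:
    es: float
    nes: float
    pvalue: float
    leading_edge: list[str]


def _running_es(in_set: np.ndarray, scores: np.ndarray, weight: int) -> tuple[float, int]:
    """Enrichment score and the index of the running-sum extremum."""
    w = np.abs(scores) ** weight
    hit_w = np.where(in_set, w, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:
        # degenerate: all member scores are 0 under weight=1; fall back to counts
        hit_w = in_set.astype(float)
        total_hit = hit_w.sum()
    n_miss = len(scores) - int(in_set.sum())
    miss_step = 1.0 / n_miss if n_miss else 0.0
    running = np.cumsum(hit_w / total_hit - np.where(in_set, 0.0, miss_step))
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def gsea_preranked(
    ranked: pd.DataFrame,
    gene_set: set[str],
    weight: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA with a gene-label permutation null.

    The running sum adds |score|^weight (normalised over set members) at hits
    and subtracts 1/(N-k) at misses; ES is its signed extremum.  The null
    permutes set membership over rank positions; p is the fraction of
    same-sign null ES at least as extreme (with the observed list counted),
    and NES divides ES by the mean |null ES| of the same sign.  The leading
    edge contains the set members at or before the extremum for positive ES,
    at or after it for negative ES.
    """
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(float)
    in_set = np.isin(genes, list(gene_set))
    k = int(in_set.sum())
    if k == 0:
        raise ValidationError("gsea_preranked: gene set has no overlap with the ranked list")
    if weight not in (0, 1):
        raise ValidationError("gsea_preranked: weight must be 0 or 1")
    es, idx = _running_es(in_set, scores, weight)
    if es >= 0:
        leading = [g for g, m in zip(genes[: idx + 1], in_set[: idx + 1]) if m]
    else:
        leading = [g for g, m in zip(genes[idx:], in_set[idx:]) if m]

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    perm_mask = in_set.copy()
    for i in range(n_perm):
        rng.shuffle(perm_mask)
        null_es[i], _ = _running_es(perm_mask, scores, weight)
    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        p, nes = 1.0 / (n_perm + 1), np.nan
    else:
        extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
        p = (extreme + 1) / (n_same + 1)
        mean_abs = float(np.abs(null_es[same_sign]).mean())
        nes = es / mean_abs if mean_abs > 0 else np.nan
    return GseaResult(es, float(nes), float(p), leading)


def quadrant_concordance(
    de_a: pd.DataFrame, de_b: pd.DataFrame, alpha: float = 0.1
) -> dict:
    """Sign cross-tabulation of genes significant in two datasets.

    Restricts to genes with padj < alpha in both tables, tabulates
    sign(log2fc_a) x sign(log2fc_b), runs a two-sided Fisher test, and
    reports the concordant (same-sign) and anticorrelated fractions.
    """
    a = de_a.set_index("gene_id")
    b = de_b.set_index("gene_id")
    shared = a.index.intersection(b.index)
    sel = shared[(a.loc[shared, "padj"] < alpha) & (b.loc[shared, "padj"] < alpha)]
    if len(sel) == 0:
        logger.warning("quadrant_concordance: no genes pass padj < %s in both", alpha)
        return {"n": 0, "table": None, "pvalue": None,
                "concordant_fraction": None, "anticorrelated_fraction": None}
    sa = a.loc[sel, "log2fc"] > 0
    sb = b.loc[sel, "log2fc"] > 0
    tbl = pd.crosstab(sa, sb).reindex(index=[True, False], columns=[True, False], fill_value=0)
    tbl.index = ["a_up", "a_down"]
    tbl.columns = ["b_up", "b_down"]
    _, p = fisher_2x2(tbl.iloc[0, 0], tbl.iloc[0, 1], tbl.iloc[1, 0], tbl.iloc[1, 1],
                      alternative="two_sided")
    conc = (tbl.iloc[0, 0] + tbl.iloc[1, 1]) / len(sel)
    return {"n": int(len(sel)), "table": tbl, "pvalue": p,
            "concordant_fraction": float(conc),
            "anticorrelated_fraction": float(1 - conc)}


def signature_pca(expr: pd.DataFrame, signature: set[str], n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the leading principal components of signature genes.

    ``expr`` is samples x genes.  Genes are restricted to the signature,
    centred across samples (constant genes dropped with a warning), and
    decomposed by SVD.  Sign convention: for each component, the gene loading
    of largest absolute value is made positive, so scores are deterministic.
    """
    present = [g for g in expr.columns if g in signature]
    if expr.shape[0] < 2 or len(present) < 2:
        raise ValidationError("signature_pca: need >= 2 samples and >= 2 signature genes present")
    x = expr[present].to_numpy(float)
    centred = x - x.mean(axis=0)
    keep = centred.std(axis=0) > 0
    if not keep.all():
        logger.warning("signature_pca: dropped %d constant genes", int((~keep).sum()))
    centred = centred[:, keep]
    if centred.shape[1] < 2:
        raise ValidationError("signature_pca: fewer than 2 non-constant signature genes")
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    n_components = min(n_components, len(s))
    scores = u[:, :n_components] * s[:n_components]
    for j in range(n_components):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=expr.index, columns=[f"PC{j + 1}" for j in range(n_components)]
    )
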