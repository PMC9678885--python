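"""Statistical kernel: Fisher tests, BH-FDR, binned enrichment, chi-squared
homogeneity with adjusted standardized residuals, and gene-set co-occurrence.

All enrichment analyses share the same framing: a set of genes carries a
boolean "bound" flag (derived from peak-to-gene annotation) and is partitioned
into bins or groups; per bin a one-sided Fisher exact test asks whether bound
genes are overrepresented relative to all genes outside the bin, and the
per-bin p-values are corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .intervals import AnnotatedPeak, GeneModel, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    bin_label: str
    n_genes: int
    n_bound: int
    background_n: int
    background_bound: int
    odds_ratio: float
    pvalue: float
    padj: float | None = None


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    df: int
    pvalue: float
    std_residuals: pd.DataFrame


def fisher_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "greater"
) -> tuple[float, float]:
    """Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, pvalue)``.  The p-value is the conditional
    hypergeometric tail ("one-way" overrepresentation = ``greater``); the odds
    ratio is the unconditional sample OR a*d / (b*c), with inf when b*c == 0
    and a*d > 0.
    """
    counts = (a, b, c, d)
    if any((not np.isfinite(x)) or x < 0 for x in counts):
        raise ValidationError(f"fisher_2x2: counts must be finite and nonnegative, got {counts}")
    if alternative not in ("greater", "two_sided", "two-sided"):
        raise ValidationError(f"fisher_2x2: unknown alternative {alternative!r}")
    alt = "two-sided" if alternative.startswith("two") else "greater"
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=alt)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("bh_adjust: p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flag_bound_genes(
    annotations: Sequence[AnnotatedPeak], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-gene bound flag and peak count from nearest-gene annotations.

    A gene is bound iff at least one peak was annotated to it.  Annotations
    with a null gene are ignored; an annotation naming a gene absent from
    ``genes`` is an error.
    """
    gene_ids = [g.gene_id for g in genes]
    known = set(gene_ids)
    counts = dict.fromkeys(gene_ids, 0)
    for ann in annotations:
        if ann.gene_id is None:
            continue
        if ann.gene_id not in known:
            raise ValidationError(f"annotation for peak {ann.peak_id} names unknown gene {ann.gene_id}")
        counts[ann.gene_id] += 1
    df = pd.DataFrame({"gene_id": gene_ids, "n_peaks": [counts[g] for g in gene_ids]})
    df["bound"] = df["n_peaks"] > 0
    return df


def _rank_bins(de: pd.DataFrame, k: int) -> pd.Series:
    """Equal-size (+-1) bins over genes ranked by log2fc, ties by gene_id."""
    order = de.sort_values(["log2fc", "gene_id"], kind="mergesort").index
    bins = np.empty(len(de), dtype=int)
    # np.array_split yields k chunks with sizes differing by at most 1
    for i, chunk in enumerate(np.array_split(np.asarray(order), k)):
        bins[chunk] = i + 1
    return pd.Series(bins, index=de.index)


def _de_groups(de: pd.DataFrame, alpha: float, ns_p: float) -> pd.Series:
    """up / dn by padj < alpha and sign(log2fc); ns by raw p > ns_p."""
    g = pd.Series("other", index=de.index)
    sig = de["padj"] < alpha
    g[sig & (de["log2fc"] > 0)] = "up"
    g[sig & (de["log2fc"] < 0)] = "dn"
    g[de["pvalue"] > ns_p] = "ns"
    return g


def binned_binding_enrichment(
    de: pd.DataFrame,
    rank_bins: int | None = None,
    groups: bool = False,
    bin_labels: Mapping | pd.Series | None = None,
    alpha: float = 0.05,
    ns_p: float = 0.05,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Bound-gene enrichment per expression bin.

    ``de`` needs columns gene_id, log2fc, pvalue, padj, bound.  Binning is one
    of: ``rank_bins=k`` equal-size bins over the log2fc ranking (bin 1 = most
    down-regulated); ``groups=True`` for up / dn / ns classes; or an explicit
    ``bin_labels`` gene->label mapping (used for meta-score bins).  Each bin is
    tested against all genes outside it with a one-sided Fisher (greater), and
    BH correction runs across the bins of the analysis.
    """
    de = de.reset_index(drop=True)
    if rank_bins is not None:
        if rank_bins < 2:
            raise ValidationError("rank_bins must be >= 2")
        labels = _rank_bins(de, rank_bins).astype(str)
        order = [str(i) for i in range(1, rank_bins + 1)]
    elif groups:
        labels = _de_groups(de, alpha, ns_p)
        order = ["up", "dn", "ns", "other"]
    elif bin_labels is not None:
        labels = de["gene_id"].map(dict(bin_labels) if not isinstance(bin_labels, pd.Series) else bin_labels)
        order = list(pd.unique(labels.dropna()))
    else:
        raise ValidationError("one of rank_bins, groups, bin_labels is required")

    bound = de["bound"].to_numpy(bool)
    total, total_bound = len(de), int(bound.sum())
    results = []
    for lab in order:
        mask = (labels == lab).to_numpy()
        n, nb = int(mask.sum()), int(bound[mask].sum())
        if n == 0:
            logger.warning("binned_binding_enrichment: empty bin %s", lab)
            results.append(EnrichmentResult(lab, 0, 0, total, total_bound, np.nan, 1.0))
            continue
        a, b = nb, n - nb
        c, d = total_bound - nb, (total - n) - (total_bound - nb)
        odds, p = fisher_2x2(a, b, c, d, alternative=alternative)
        results.append(EnrichmentResult(lab, n, nb, total - n, total_bound - nb, odds, p))
    padj = bh_adjust([r.pvalue for r in results])
    return [
        EnrichmentResult(r.bin_label, r.n_genes, r.n_bound, r.background_n,
                         r.background_bound, r.odds_ratio, r.pvalue, float(q))
        for r, q in zip(results, padj)
    ]


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Fixed-column-order TSV-ready frame of enrichment results."""
    return pd.DataFrame(
        [
            (r.bin_label, r.n_genes, r.n_bound, r.background_n, r.background_bound,
             r.odds_ratio, r.pvalue, r.padj)
            for r in results
        ],
        columns=["bin", "n_genes", "n_bound", "background_n", "background_bound",
                 "odds_ratio", "pvalue", "padj"],
    )


def chisq_homogeneity(counts: pd.DataFrame | np.ndarray) -> ContingencyResult:
    """Pearson chi-squared homogeneity test with adjusted standardized residuals.

    For an R x K table the statistic is sum (O-E)^2/E with E from the margins,
    df = (R-1)(K-1); residuals are the adjusted form
    (O-E)/sqrt(E (1-rowfrac)(1-colfrac)), the "standardized residuals" of
    mainstream stats environments.
    """
    df_in = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(np.asarray(counts))
    obs = df_in.to_numpy(dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("chisq_homogeneity: need an R x K table with R, K >= 2")
    if np.any(obs < 0):
        raise ValidationError("chisq_homogeneity: negative counts")
    rowsum, colsum = obs.sum(1), obs.sum(0)
    if np.any(rowsum == 0):
        raise ValidationError(f"chisq_homogeneity: zero margin in row(s) {list(df_in.index[rowsum == 0])}")
    if np.any(colsum == 0):
        raise ValidationError(f"chisq_homogeneity: zero margin in column(s) {list(df_in.columns[colsum == 0])}")
    total = obs.sum()
    expected = np.outer(rowsum, colsum) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, dof))
    rowfrac = rowsum / total
    colfrac = colsum / total
    denom = np.sqrt(expected * np.outer(1 - rowfrac, 1 - colfrac))
    resid = pd.DataFrame((obs - expected) / denom, index=df_in.index, columns=df_in.columns)
    return ContingencyResult(stat, dof, p, resid)


def gene_set_cooccurrence(
    flags_a: pd.Series, flags_b: pd.Series, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Fisher test for co-occurrence of two boolean gene flags.

    Both series must be indexed by the same gene universe.  Default two-sided,
    asking whether genes bound by one factor are more (or less) likely to be
    bound by the other.
    """
    if len(flags_a) != len(flags_b) or not flags_a.index.sort_values().equals(
        flags_b.index.sort_values()
    ):
        raise ValidationError("gene_set_cooccurrence: gene universes differ")
    fb = flags_b.reindex(flags_a.index)
    a = int((flags_a & fb).sum())
    b = int((flags_a & ~fb).sum())
    c = int((~flags_a & fb).sum())
    d = int((~flags_a & ~fb).sum())
    return fisher_2x2(a, b, c, d, alternative=alternative)
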