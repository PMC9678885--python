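"""Integration of per-gene meta-analysis scores with expression changes.

Two score types are supported: a cell-cycle study count (how many published
datasets call a gene a cell-cycle gene) and a signed p53 score (strongly
negative = p53-repressed cell-cycle genes, strongly positive = p53-induced
apoptosis / DNA-damage genes).  Genes are binned by score and summarised by
mean log2 fold change with t-based confidence intervals, or grouped by the
+-17 p53-score rule and compared with Welch t-tests.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import ValidationError

logger = logging.getLogger(__name__)

GROUP_CELL_CYCLE = "cell_cycle"
GROUP_APOPTOSIS_DD = "apoptosis_dd"
GROUP_CONTROL = "control"


def bin_by_score(
    table: pd.DataFrame, score: str, edges: Sequence[float]
) -> pd.Series:
    """Assign genes to half-open score bins [e_i, e_{i+1}).

    ``edges`` must be strictly increasing; +-inf endpoints are allowed.
    Returns a gene_id-indexed series of bin labels; out-of-range genes get NA
    and are counted in the log.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin_by_score: edges must be strictly increasing")
    vals = table[score].to_numpy(float)
    idx = np.digitize(vals, edges, right=False) - 1
    labels = np.array(
        [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)], dtype=object
    )
    assigned = np.full(len(vals), None, dtype=object)
    in_range = (idx >= 0) & (idx < len(edges) - 1)
    assigned[in_range] = labels[idx[in_range]]
    n_out = int((~in_range).sum())
    if n_out:
        logger.info("bin_by_score: %d genes outside the binning range", n_out)
    return pd.Series(
        pd.Categorical(assigned, categories=list(labels), ordered=True),
        index=pd.Index(table["gene_id"], name="gene_id"),
    )


def binned_mean_ci(
    bins: pd.Series,
    lfc: pd.Series,
    level: float = 0.90,
    bound: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-bin mean log2FC with t confidence intervals.

    The interval is mean +- t_{(1+level)/2, n-1} * sd/sqrt(n); bins with a
    single gene report the mean with NaN interval bounds, and the bound-gene
    fraction is included when binding flags are provided.
    """
    if not 0 < level < 1:
        raise ValidationError("binned_mean_ci: level must be in (0,1)")
    lfc = lfc.reindex(bins.index)
    if isinstance(bins.dtype, pd.CategoricalDtype):
        labels = [c for c in bins.cat.categories if (bins == c).any()]
    else:
        labels = list(pd.unique(bins.dropna()))
    rows = []
    for lab in labels:
        mask = bins == lab
        vals = lfc[mask].to_numpy(float)
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            half = float(sps.t.ppf((1 + level) / 2, n - 1) * vals.std(ddof=1) / np.sqrt(n))
            lo, hi = mean - half, mean + half
        else:
            logger.warning("binned_mean_ci: bin %s has n=1, CI undefined", lab)
            lo = hi = float("nan")
        row = {"bin": lab, "n": n, "mean_lfc": mean, "ci_low": lo, "ci_high": hi}
        if bound is not None:
            row["bound_fraction"] = float(bound.reindex(bins.index)[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    for cut, sym in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < cut:
            return sym
    return "ns"


def score_groups(table: pd.DataFrame, cutoff: int = 17) -> pd.Series:
    """p53-score grouping: cell cycle (score <= -cutoff), apoptosis/DNA
    damage (score >= cutoff), control otherwise.  Exhaustive and disjoint."""
    s = table["p53_score"].to_numpy(float)
    lab = np.select(
        [s <= -cutoff, s >= cutoff], [GROUP_CELL_CYCLE, GROUP_APOPTOSIS_DD], GROUP_CONTROL
    )
    return pd.Series(lab, index=pd.Index(table["gene_id"], name="gene_id"))


def score_group_tests(
    table: pd.DataFrame, lfc: pd.Series, cutoff: int = 17
) -> pd.DataFrame:
    """Welch t-tests of each non-control p53-score group against control.

    Two-sided unpaired tests; significance stars follow the conventional
    bands (* <0.05 ... **** <0.0001).  Empty groups are skipped with a
    warning.
    """
    groups = score_groups(table, cutoff)
    lfc = lfc.reindex(groups.index)
    ctl = lfc[groups == GROUP_CONTROL].dropna()
    rows = []
    for g in (GROUP_CELL_CYCLE, GROUP_APOPTOSIS_DD):
        vals = lfc[groups == g].dropna()
        if len(vals) < 2 or len(ctl) < 2:
            logger.warning("score_group_tests: group %s too small, skipped", g)
            continue
        t, p = sps.ttest_ind(vals, ctl, equal_var=False)
        rows.append(
            {"group": g, "n": len(vals), "n_control": len(ctl),
             "mean_lfc": float(vals.mean()), "mean_control": float(ctl.mean()),
             "t": float(t), "pvalue": float(p), "stars": _stars(float(p))}
        )
    return pd.DataFrame(rows)
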