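"""CPM normalisation and dual-factor peak classification.

Two transcription factors with near-identical DNA-binding domains (a native
factor and an oncogenic fusion) are profiled over the same peak universe.
Each peak is classified by the log2 ratio of library-normalised signal as
bound preferentially by the native factor (R1), by the fusion (ER), or
similarly by both (R1_ER).  Downstream utilities quantify how a competing
condition shifts signal per class and how the classes distribute across a
ranked differential-acetylation axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .intervals import ValidationError

CLASS_LABELS = ("R1", "ER", "R1_ER")


def cpm_normalize(counts, library_size: float) -> np.ndarray:
    """Counts-per-million: count * 1e6 / library_size."""
    if library_size <= 0:
        raise ValidationError(f"library_size must be positive, got {library_size}")
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("cpm_normalize: negative counts")
    return arr * 1e6 / library_size


def classify_peaks(
    table: pd.DataFrame,
    tau: float = 1.0,
    pseudocount: float = 0.5,
    col_a: str = "cpm_a",
    col_b: str = "cpm_b",
) -> pd.DataFrame:
    """Assign R1 / ER / R1_ER labels from the pseudocounted CPM log-ratio.

    With a = native-factor CPM and b = fusion CPM,
    ``r = log2((b + pseudocount) / (a + pseudocount))``; peaks with r >= tau
    are ER, r <= -tau are R1, and the rest R1_ER.  Defaults tau=1 (2-fold)
    and pseudocount=0.5 are recorded by the writers alongside the labels.
    """
    if tau <= 0 or pseudocount <= 0:
        raise ValidationError("classify_peaks: tau and pseudocount must be positive")
    out = table.copy()
    r = np.log2((out[col_b] + pseudocount) / (out[col_a] + pseudocount))
    out["log_ratio"] = r
    out["class_label"] = np.select([r >= tau, r <= -tau], ["ER", "R1"], default="R1_ER")
    return out


def tau_sweep(table: pd.DataFrame, taus, pseudocount: float = 0.5) -> pd.DataFrame:
    """Class-size sensitivity to the ratio threshold tau."""
    rows = []
    for tau in taus:
        lab = classify_peaks(table, tau=tau, pseudocount=pseudocount)["class_label"]
        counts = lab.value_counts()
        rows.append([tau] + [int(counts.get(c, 0)) for c in CLASS_LABELS])
    return pd.DataFrame(rows, columns=["tau", *CLASS_LABELS])


def condition_delta(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    pseudocount: float = 0.5,
    cpm_col: str = "cpm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak log2 change of signal between conditions, summarised by class.

    Both tables must cover the identical peak universe; ``control`` carries
    the class labels.  Returns (per-peak table with ``delta``, per-class
    summary with mean delta and count).
    """
    if set(control["peak_id"]) != set(treated["peak_id"]):
        raise ValidationError("condition_delta: peak universes differ")
    ctl = control.set_index("peak_id")
    trt = treated.set_index("peak_id").reindex(ctl.index)
    delta = np.log2((trt[cpm_col] + pseudocount) / (ctl[cpm_col] + pseudocount))
    per_peak = pd.DataFrame(
        {"peak_id": ctl.index, "class_label": ctl["class_label"].to_numpy(), "delta": delta.to_numpy()}
    )
    summary = (
        per_peak.groupby("class_label", sort=False)["delta"]
        .agg(mean_delta="mean", n="count")
        .reset_index()
    )
    return per_peak, summary


@dataclass(frozen=True)
class RankedBinResult:
    table: pd.DataFrame          # bin_index, per-class counts + proportions, mean_rank_stat
    trend: dict                  # Spearman rho/p of ER+R1_ER proportion vs bin index


def ranked_bin_proportions(
    rank_stat: pd.Series | np.ndarray,
    classes: pd.Series | np.ndarray,
    k: int = 11,
    peak_ids=None,
) -> RankedBinResult:
    """Class proportions across k equal-size bins of a signed-significance ranking.

    Peaks are sorted ascending by ``rank_stat`` (sign(log2fc) * -log10(p) of a
    differential test supplied by the caller), so bin 1 holds the most
    significantly down-regulated peaks and bin k the most up-regulated; ties
    break by peak_id.  The reported trend is the Spearman correlation of the
    combined ER + R1_ER proportion against bin index.
    """
    stat = np.asarray(rank_stat, dtype=float)
    labs = np.asarray(classes, dtype=object)
    if k < 2:
        raise ValidationError("ranked_bin_proportions: k must be >= 2")
    if k > stat.size:
        raise ValidationError(f"ranked_bin_proportions: k={k} exceeds peak count {stat.size}")
    if np.any(~np.isfinite(stat)):
        raise ValidationError("ranked_bin_proportions: rank_stat must be finite")
    ids = np.asarray(peak_ids if peak_ids is not None else np.arange(stat.size), dtype=object)
    order = np.lexsort((ids, stat))
    rows = []
    for i, chunk in enumerate(np.array_split(order, k)):
        counts = {c: int(np.sum(labs[chunk] == c)) for c in CLASS_LABELS}
        n = len(chunk)
        row = {"bin_index": i + 1, "n": n, "mean_rank_stat": float(stat[chunk].mean())}
        for c in CLASS_LABELS:
            row[f"n_{c}"] = counts[c]
            row[f"prop_{c}"] = counts[c] / n
        rows.append(row)
    table = pd.DataFrame(rows)
    fusion_prop = table["prop_ER"] + table["prop_R1_ER"]
    if fusion_prop.nunique() > 1:
        rho, p = spearmanr(table["bin_index"], fusion_prop)
    else:
        rho, p = float("nan"), float("nan")  # constant share: no trend defined
    return RankedBinResult(table, {"spearman_rho": float(rho), "pvalue": float(p)})
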