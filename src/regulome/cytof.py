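"""Mass-cytometry processing: transform, SOM clustering, rule-based
annotation of metaclusters to populations and cell-cycle phases, a biaxial
gating comparator, and condition-level phase-distribution tests.

Event tables are pandas DataFrames with one row per event; marker columns
are plain names and per-event metadata columns carry a ``meta_`` prefix
(cell line, condition, optional planted truth labels).  The expected marker
panel has three roles: surface (CD45, CD45RA, CD34, CD19) for population
calls, cycle (pRb, IdU, CycB1, pHisH3) for phase calls, and death
(cisplatin, cCaspase3) for viability.

Where the underlying study annotated clusters manually, this module replaces
the manual step with an explicit ordered rule table over metacluster medians;
"high" is defined against per-marker thresholds derived from a two-component
Gaussian mixture, so the whole procedure is reproducible from the data alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.mixture import GaussianMixture

from .intervals import ValidationError
from .stats import ContingencyResult, chisq_homogeneity

logger = logging.getLogger(__name__)

SURFACE_MARKERS = ["CD45", "CD45RA", "CD34", "CD19"]
CYCLE_MARKERS = ["pRb", "IdU", "CycB1", "pHisH3"]
DEATH_MARKERS = ["cisplatin", "cCaspase3"]
ALL_MARKERS = SURFACE_MARKERS + CYCLE_MARKERS + DEATH_MARKERS

PHASES = ["G0", "G1", "S", "G2", "M"]
VIABILITY = ["apoptotic", "dead"]
PHASE_CATEGORIES = PHASES + VIABILITY

POPULATIONS = ["HSPC", "preB", "CD19low", "CD45RA", "CD45", "debris"]

# Ordered first-match rules: (label, {marker: "high" | "low" | "dim"}).
# Phase precedence: viability first, then M > S > G2 > G1, G0 as the catch-all.
PHASE_RULES: list[tuple[str, dict[str, str]]] = [
    ("dead", {"cisplatin": "high"}),
    ("apoptotic", {"cCaspase3": "high"}),
    ("M", {"pHisH3": "high"}),
    ("S", {"IdU": "high"}),
    ("G2", {"CycB1": "high"}),
    ("G1", {"pRb": "high"}),
    ("G0", {}),
]

POPULATION_RULES: list[tuple[str, dict[str, str]]] = [
    ("debris", {"CD45": "low"}),
    ("HSPC", {"CD45": "high", "CD34": "high", "CD19": "low"}),
    ("preB", {"CD45": "high", "CD34": "low", "CD19": "high"}),
    ("CD19low", {"CD45": "high", "CD34": "dim", "CD19": "dim"}),
    ("CD45RA", {"CD45": "high", "CD45RA": "high", "CD34": "low", "CD19": "low"}),
    ("CD45", {}),
]


def marker_columns(events: pd.DataFrame) -> list[str]:
    return [c for c in events.columns if not c.startswith("meta_")]


def arcsinh_scale(
    events: pd.DataFrame, cofactor: float = 5.0, q: tuple[float, float] = (0.01, 0.99)
) -> pd.DataFrame:
    """asinh(x / cofactor) followed by per-marker (1st, 99th) percentile
    scaling to [0, 1], clipped.  Negative ion counts are clipped to 0 first."""
    if cofactor <= 0:
        raise ValidationError("arcsinh_scale: cofactor must be positive")
    out = events.copy()
    markers = marker_columns(events)
    vals = out[markers].to_numpy(float)
    n_neg = int((vals < 0).sum())
    if n_neg:
        logger.info("arcsinh_scale: clipped %d negative values to 0", n_neg)
        vals = np.clip(vals, 0, None)
    t = np.arcsinh(vals / cofactor)
    lo = np.quantile(t, q[0], axis=0)
    hi = np.quantile(t, q[1], axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    out[markers] = np.clip((t - lo) / span, 0.0, 1.0)
    return out


@dataclass
class SomModel:
    """A trained batch self-organizing map over a marker subset."""

    grid: tuple[int, int]
    codebook: np.ndarray          # nodes x markers
    markers: list[str]
    seed: int
    epochs: int
    quantization_error: float = field(default=float("nan"))

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    def assign(self, events: pd.DataFrame) -> np.ndarray:
        """Nearest-codebook (Euclidean) node index per event."""
        x = events[self.markers].to_numpy(float)
        d = ((x[:, None, :] - self.codebook[None, :, :]) ** 2).sum(-1)
        return d.argmin(1)


def train_som(
    events: pd.DataFrame,
    markers: list[str] | None = None,
    grid: tuple[int, int] = (10, 10),
    epochs: int = 10,
    seed: int = 0,
) -> SomModel:
    """Batch SOM: per epoch, assign events to the nearest node, then update
    every codebook as the Gaussian-neighborhood-weighted mean of the data.

    The neighborhood width decays linearly from grid-radius/2 to 0.5 across
    epochs.  Batch updates make the result independent of event order, and
    the codebook is initialised from a seeded sample of events, so training
    is fully deterministic given (data, seed).
    """
    markers = markers or marker_columns(events)
    x = events[markers].to_numpy(float)
    g1, g2 = grid
    n_nodes = g1 * g2
    if len(x) < n_nodes:
        raise ValidationError(
            f"train_som: {len(x)} events < {n_nodes} nodes; use a smaller grid"
        )
    rng = np.random.default_rng(seed)
    # sample the initial codebook in lexicographic row order so training is
    # invariant to the order events arrive in
    canon = np.lexsort(x.T[::-1])
    codebook = x[canon[rng.choice(len(x), n_nodes, replace=False)]].copy()
    coords = np.array([(i, j) for i in range(g1) for j in range(g2)], dtype=float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    sigma0 = max(g1, g2) / 2.0
    qe_initial = None
    for epoch in range(epochs):
        d = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
        bmu = d.argmin(1)
        if qe_initial is None:
            qe_initial = float(np.sqrt(d[np.arange(len(x)), bmu]).mean())
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma0 + (0.5 - sigma0) * frac
        h = np.exp(-grid_d2 / (2 * sigma**2))        # nodes x nodes
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, x)
        num = h @ sums
        den = (h @ counts)[:, None]
        codebook = num / den
    # final polish: one neighborhood-free (Voronoi-mean) update, so the
    # quantization error ends at a k-means local-descent point
    d = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    bmu = d.argmin(1)
    counts = np.bincount(bmu, minlength=n_nodes).astype(float)
    sums = np.zeros_like(codebook)
    np.add.at(sums, bmu, x)
    occupied = counts > 0
    codebook[occupied] = sums[occupied] / counts[occupied, None]
    d = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    qe = float(np.sqrt(d.min(1)).mean())
    if qe_initial is not None and qe > qe_initial:
        logger.warning("train_som: quantization error rose from %.4f to %.4f", qe_initial, qe)
    return SomModel((g1, g2), codebook, list(markers), seed, epochs, qe)


@dataclass
class Thresholds:
    """Per-marker high/low cut and dim band, from 1-D Gaussian mixtures.

    ``cut`` is the midpoint of the two fitted component means (fallback: the
    marker median when the means sit within ``fallback_gap`` of each other);
    ``band`` defines the half-width of the "dim" (intermediate) zone used by
    population rules for genuinely intermediate markers.
    """

    cut: dict[str, float]
    band: float = 0.2

    def level(self, marker: str, value: float) -> str:
        t = self.cut[marker]
        if abs(value - t) < self.band:
            return "dim"
        return "high" if value > t else "low"

    def matches(self, marker: str, value: float, want: str) -> bool:
        t = self.cut[marker]
        if want == "high":
            return value > t
        if want == "low":
            return value <= t
        if want == "dim":
            return abs(value - t) < self.band
        raise ValidationError(f"unknown level {want!r}")


def derive_thresholds(
    events: pd.DataFrame,
    markers: list[str] | None = None,
    seed: int = 0,
    fallback_gap: float = 0.1,
    band: float = 0.2,
) -> Thresholds:
    """Per-marker threshold = midpoint of the two component means of a 1-D
    two-component Gaussian mixture over all events (marker median fallback
    when the fitted means are closer than ``fallback_gap``)."""
    markers = markers or marker_columns(events)
    cut = {}
    for m in markers:
        v = events[m].to_numpy(float).reshape(-1, 1)
        gm = GaussianMixture(2, random_state=seed, n_init=1, max_iter=200).fit(v)
        means = np.sort(gm.means_.ravel())
        if means[1] - means[0] < fallback_gap:
            cut[m] = float(np.median(v))
            logger.info("derive_thresholds: %s mixture degenerate, using median", m)
        else:
            cut[m] = float(means.mean())
    return Thresholds(cut, band)


def _first_match(
    medians: pd.Series, rules: list[tuple[str, dict[str, str]]], thr: Thresholds
) -> str:
    for label, conds in rules:
        if all(thr.matches(m, medians[m], want) for m, want in conds.items()):
            return label
    logger.warning("metacluster matched no rule; labelled 'unassigned'")
    return "unassigned"


def metacluster_annotate(
    model: SomModel,
    events: pd.DataFrame,
    k: int,
    rules: list[tuple[str, dict[str, str]]],
    thresholds: Thresholds | None = None,
    seed: int = 0,
) -> pd.Series:
    """Merge SOM nodes into k metaclusters and label each by ordered rules.

    Nodes are merged by average-linkage hierarchical clustering of codebook
    vectors; each metacluster is labelled by the FIRST rule whose conditions
    all hold for the metacluster's per-marker event medians.  Returns one
    label per event.
    """
    if thresholds is None:
        thresholds = derive_thresholds(events, model.markers, seed=seed)
    z = linkage(model.codebook, method="average")
    node_mc = fcluster(z, t=k, criterion="maxclust")       # 1..k per node
    node_per_event = model.assign(events)
    mc_per_event = node_mc[node_per_event]
    labels = {}
    for mc in np.unique(node_mc):
        mask = mc_per_event == mc
        if not mask.any():
            continue
        medians = events.loc[mask, model.markers].median()
        labels[mc] = _first_match(medians, rules, thresholds)
    return pd.Series(
        [labels[mc] for mc in mc_per_event], index=events.index, name="label"
    )


def biaxial_gate(
    events: pd.DataFrame,
    rules: list[tuple[str, dict[str, str]]],
    thresholds: Thresholds,
    markers: list[str] | None = None,
) -> pd.Series:
    """Conventional gating comparator: apply the rule table per event.

    Each event is pushed through the same ordered threshold boxes used for
    metacluster annotation, first match wins.  Deterministic and
    clustering-free, so it serves as an independent check on the SOM route.
    """
    markers = markers or marker_columns(events)
    out = []
    vals = events[markers]
    for _, row in vals.iterrows():
        out.append(_first_match(row, rules, thresholds))
    return pd.Series(out, index=events.index, name="label")


def phase_table(labels: pd.Series, condition: pd.Series) -> pd.DataFrame:
    """Condition x phase-category count table.

    Canonical categories come first (zero-filled when absent); any other
    labels present in the data are appended in sorted order.
    """
    tbl = pd.crosstab(condition, labels)
    for cat in PHASE_CATEGORIES:
        if cat not in tbl.columns:
            tbl[cat] = 0
    extra = sorted(set(tbl.columns) - set(PHASE_CATEGORIES))
    return tbl[PHASE_CATEGORIES + extra]


def phase_distribution_test(
    labels: pd.Series,
    condition: pd.Series,
    population: pd.Series | None = None,
) -> dict[str, tuple[pd.DataFrame, ContingencyResult]]:
    """Per-population chi-squared homogeneity of phase counts across conditions.

    Returns {population: (condition x category counts, ContingencyResult)};
    with no population labels a single "all" entry is produced.  Categories
    absent everywhere are dropped (they carry no information and would zero a
    margin); populations missing a condition are skipped with a warning.
    """
    if condition.nunique() < 2:
        raise ValidationError("phase_distribution_test: need >= 2 conditions")
    pops = population if population is not None else pd.Series("all", index=labels.index)
    results = {}
    for pop in pops.unique():
        mask = pops == pop
        tbl = phase_table(labels[mask], condition[mask])
        if tbl.shape[0] < condition.nunique():
            logger.warning("phase_distribution_test: population %s absent in a condition", pop)
            continue
        nonzero = tbl.columns[tbl.sum(0) > 0]
        if len(nonzero) < tbl.shape[1]:
            logger.info("phase_distribution_test: dropping empty categories %s",
                        sorted(set(tbl.columns) - set(nonzero)))
        tbl = tbl[nonzero]
        results[pop] = (tbl, chisq_homogeneity(tbl))
    return results
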