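"""Synthetic regulome generator with planted ground truth.

Every analysis stage in this package is exercised on synthetic data whose
generating process matches the assumptions of the corresponding method:

* a toy genome with gene models and true transcription-factor binding sites
  placed near TSSs, observed through several noisy peak sets (per-set
  detection sensitivity, boundary jitter, false peaks) plus an open-chromatin
  superset — the substrate for consensus/high-confidence peak calling;
* per-cell-line differential-expression tables in which bound genes carry a
  planted repressive shift, plus a pooled LRT-style table — the substrate for
  binding-expression enrichment and the core-program filter;
* dual-factor CPM signal pairs with planted R1/ER/R1_ER classes and a coupled
  differential-acetylation table;
* per-gene meta-score tables (cell-cycle study count, signed p53 score) with
  planted score-to-fold-change trends;
* CyTOF event tables drawn from population x phase mixtures with a marker
  mean table in transformed space, inverse-transformed to raw ion counts.

All functions are deterministic given the config seed, and ground-truth
labels are returned separately from the analysis-facing objects so truth
never leaks into an analysis input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coreprog import MultiLineDE
from .cytof import ALL_MARKERS, CYCLE_MARKERS, DEATH_MARKERS, SURFACE_MARKERS
from .intervals import GeneModel, GenomicInterval, PeakSet, ValidationError
from .stats import bh_adjust

# transformed-space marker means: one row per planted phase / population
PHASE_MEANS = {
    #         pRb  IdU  CycB1 pHisH3 cis  cCas
    "G0":        (0.2, 0.2, 0.2, 0.2, 0.2, 0.2),
    "G1":        (0.8, 0.2, 0.2, 0.2, 0.2, 0.2),
    "S":         (0.8, 0.8, 0.2, 0.2, 0.2, 0.2),
    "G2":        (0.8, 0.2, 0.8, 0.2, 0.2, 0.2),
    "M":         (0.8, 0.2, 0.8, 0.8, 0.2, 0.2),
    "apoptotic": (0.2, 0.2, 0.2, 0.2, 0.2, 0.8),
    "dead":      (0.2, 0.2, 0.2, 0.2, 0.8, 0.5),
}
POPULATION_MEANS = {
    #          CD45 CD45RA CD34 CD19
    "HSPC":    (0.8, 0.2, 0.8, 0.2),
    "preB":    (0.8, 0.2, 0.2, 0.8),
    "CD19low": (0.8, 0.2, 0.5, 0.5),
    "CD45RA":  (0.8, 0.8, 0.2, 0.2),
    "CD45":    (0.8, 0.2, 0.2, 0.2),
    # CD45-negative debris slipping through upstream gating; keeps the CD45
    # channel genuinely bimodal, as in real pre-gated panels
    "debris":  (0.2, 0.2, 0.2, 0.2),
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults define the study conditions.

    Seeded everywhere: identical configs give byte-identical outputs.
    """

    seed: int = 0
    # genome / regulome
    chrom: str = "chr1"
    chrom_length: int = 20_000_000
    n_genes: int = 2000
    n_true_sites: int = 400
    site_width: tuple[int, int] = (150, 300)
    category_mix: tuple[float, float, float, float] = (0.3, 0.4, 0.2, 0.1)
    # tss, intragenic, upstream_proximal, upstream_distal
    n_peak_sets: int = 2
    sensitivity: float = 0.97
    false_peak_rate: float = 0.10          # false peaks per set, as fraction of true sites
    boundary_jitter_sd: float = 20.0
    signal_log_mean: float = 3.0           # lognormal pileup signal
    signal_log_sd: float = 0.5
    n_dnase_background: int = 400
    # differential expression
    n_lines: int = 5
    de_effect: float = 0.5                 # planted |shift| for bound genes, in sd units
    de_direction: int = -1                 # repression
    de_noise_sd: float = 1.0               # = the per-gene standard error
    # peak signals / classification
    n_signal_peaks: int = 2000
    class_mix: tuple[float, float, float] = (0.25, 0.25, 0.50)   # R1, ER, R1_ER
    class_ratio_means: tuple[float, float, float] = (-2.0, 2.0, 0.0)
    class_ratio_sd: float = 0.5
    base_log2_cpm_mean: float = 5.0
    base_log2_cpm_sd: float = 1.0
    library_size: int = 20_000_000
    acetyl_effect: dict | None = None      # class -> mean lfc; None = default coupling
    acetyl_se: float = 0.35
    # meta scores
    p53_score_sd: float = 14.0
    metascore_slope: float = 0.8
    metascore_noise_sd: float = 0.3
    # CyTOF
    n_events: int = 20_000
    cytof_noise_sd: float = 0.11
    cytof_cofactor: float = 5.0
    cytof_asinh_span: float = 6.0          # transformed range mapped onto raw counts
    phase_mix: dict = field(default_factory=lambda: {
        "control": {"G0": 0.08, "G1": 0.34, "S": 0.22, "G2": 0.14, "M": 0.05,
                    "apoptotic": 0.08, "dead": 0.09},
        "fusion":  {"G0": 0.08, "G1": 0.24, "S": 0.32, "G2": 0.14, "M": 0.05,
                    "apoptotic": 0.08, "dead": 0.09},
    })
    population_mix: dict = field(default_factory=lambda: {
        "control": {"HSPC": 0.14, "preB": 0.23, "CD19low": 0.14,
                    "CD45RA": 0.14, "CD45": 0.27, "debris": 0.08},
        "fusion":  {"HSPC": 0.23, "preB": 0.09, "CD19low": 0.23,
                    "CD45RA": 0.14, "CD45": 0.23, "debris": 0.08},
    })

    def __post_init__(self) -> None:
        for mix in (self.category_mix, self.class_mix):
            if abs(sum(mix) - 1) > 1e-9 or any(p < 0 for p in mix):
                raise ValidationError(f"mixture {mix} must be nonnegative and sum to 1")
        if not 0 <= self.sensitivity <= 1:
            raise ValidationError("sensitivity must be in [0,1]")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------- regulome

def sim_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    slot = config.chrom_length // config.n_genes
    genes = []
    for i in range(config.n_genes):
        lo = i * slot
        length = int(rng.integers(1000, max(1200, int(slot * 0.6))))
        start = int(lo + rng.integers(0, max(1, slot - length)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{i:05d}", config.chrom, strand, start, start + length))
    return genes


def _place_site(g: GeneModel, category: str, rng: np.random.Generator) -> int:
    """Summit position of a true site relative to a gene, by planted category."""
    if category == "tss":
        d = int(rng.integers(-500, 501))
    elif category == "intragenic":
        off = int(rng.integers(1001, max(1002, g.body_end - g.body_start)))
        return g.body_start + off if g.strand == "+" else g.body_end - 1 - off
    elif category == "upstream_proximal":
        d = -int(rng.integers(1001, 10001))
    else:  # upstream_distal
        d = -int(rng.integers(10001, 50001))
    return g.tss + d if g.strand == "+" else g.tss - d


def sim_regulome(config: SimulationConfig):
    """Toy regulome: genes, true sites, noisy observed peak sets, DNaseI superset.

    Returns ``(genes, true_sites, observed_sets, dnase, truth)`` where
    ``truth`` maps each true site to its source gene and planted category.
    """
    if config.n_true_sites * 200 > config.chrom_length:
        raise ValidationError("site density infeasible for the chromosome length")
    rng = np.random.default_rng(config.seed)
    genes = sim_genes(config, rng)
    cats = ("tss", "intragenic", "upstream_proximal", "upstream_distal")
    truth_rows = []
    true_ivs = []
    target_idx = rng.choice(len(genes), config.n_true_sites, replace=False)
    for i, gi in enumerate(target_idx):
        g = genes[gi]
        cat = cats[int(rng.choice(4, p=config.category_mix))]
        summit = _place_site(g, cat, rng)
        # sites planted upstream of edge genes can leave the chromosome
        summit = min(max(summit, config.site_width[1]),
                     config.chrom_length - config.site_width[1])
        w = int(rng.integers(*config.site_width))
        start = max(0, summit - w // 2)
        end = min(config.chrom_length, summit + w - w // 2)
        sid = f"site{i:04d}"
        true_ivs.append(GenomicInterval(config.chrom, start, end, sid,
                                        summit_offset=summit - start))
        truth_rows.append({"site_id": sid, "gene_id": g.gene_id, "category": cat,
                           "start": start, "end": end, "summit": summit})
    true_sites = PeakSet("true_sites", true_ivs)
    truth = pd.DataFrame(truth_rows)

    observed = []
    for s in range(config.n_peak_sets):
        ivs = []
        detected = rng.random(config.n_true_sites) < config.sensitivity
        for iv, det in zip(true_ivs, detected):
            if not det:
                continue
            j1 = int(rng.normal(0, config.boundary_jitter_sd))
            j2 = int(rng.normal(0, config.boundary_jitter_sd))
            start = max(0, min(iv.summit - 10, iv.start + j1))
            end = max(iv.summit + 10, iv.end + j2)
            sig = float(rng.lognormal(config.signal_log_mean, config.signal_log_sd))
            ivs.append(GenomicInterval(config.chrom, start, end,
                                       f"ab{s}_{iv.peak_id}", sig, iv.summit - start))
        n_false = int(round(config.false_peak_rate * config.n_true_sites))
        for f in range(n_false):
            w = int(rng.integers(*config.site_width))
            start = int(rng.integers(0, config.chrom_length - w))
            sig = float(rng.lognormal(config.signal_log_mean - 1, config.signal_log_sd))
            ivs.append(GenomicInterval(config.chrom, start, start + w,
                                       f"ab{s}_false{f:04d}", sig, w // 2))
        observed.append(PeakSet(f"antibody_{s + 1}", ivs))

    dnase_ivs = [
        GenomicInterval(config.chrom, max(0, iv.start - 100), iv.end + 100,
                        f"dnase_{iv.peak_id}")
        for iv in true_ivs
    ]
    for b in range(config.n_dnase_background):
        w = int(rng.integers(200, 600))
        start = int(rng.integers(0, config.chrom_length - w))
        dnase_ivs.append(GenomicInterval(config.chrom, start, start + w, f"dnase_bg{b:04d}"))
    dnase = PeakSet("dnase", dnase_ivs)
    return genes, true_sites, observed, dnase, truth


# ---------------------------------------------------- differential expression

def _de_table(z: np.ndarray, lfc: np.ndarray, gene_ids) -> pd.DataFrame:
    from scipy.stats import norm

    p = np.clip(2 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "gene_id": gene_ids, "log2fc": lfc, "stat": z,
        "pvalue": p, "padj": bh_adjust(p),
    })


def sim_de_tables(
    config: SimulationConfig, bound: pd.Series, effect: float | None = None
) -> tuple[MultiLineDE, pd.DataFrame]:
    """Per-line DE tables with a planted shift for bound genes, plus an
    LRT-style pooled table.

    Each line's observed log2FC is effect*bound + N(0, sd) with the per-gene
    standard error equal to sd, so z = lfc/sd and p is the two-sided normal
    tail; the pooled table uses z_pool = sum(z_i)/sqrt(n_lines).  Truth (the
    planted effect per gene) is returned separately.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = np.asarray(bound.index)
    delta = (config.de_effect if effect is None else effect) * config.de_noise_sd
    true_effect = delta * config.de_direction * bound.to_numpy(float)
    lines = {}
    zs = []
    for i in range(config.n_lines):
        lfc = true_effect + rng.normal(0, config.de_noise_sd, len(gene_ids))
        z = lfc / config.de_noise_sd
        zs.append(z)
        lines[f"line{i + 1}"] = _de_table(z, lfc, gene_ids)
    z_pool = np.sum(zs, axis=0) / np.sqrt(config.n_lines)
    lfc_mean = np.mean([lines[k]["log2fc"] for k in lines], axis=0)
    lrt = _de_table(z_pool, lfc_mean, gene_ids)
    truth = pd.DataFrame({"gene_id": gene_ids, "true_effect": true_effect,
                          "bound": bound.to_numpy(bool)})
    return MultiLineDE(lines, lrt), truth


# ------------------------------------------------------------- peak signals

DEFAULT_ACETYL_EFFECT = {"R1": 0.0, "ER": -1.0, "R1_ER": -0.8}


def sim_peak_signals(config: SimulationConfig):
    """Dual-factor CPM pairs with planted classes + coupled acetylation table.

    Returns ``(signal_table, acetyl_table, truth)``.  The signal table holds
    raw featureCounts-style counts and CPM for the native factor (a) and the
    fusion (b); the planted class sets the mean log2 CPM ratio (R1 -2, ER +2,
    R1_ER 0).  The acetylation table's planted fold change is negative for
    fusion-bound classes (ER, R1_ER), emulating acetylation loss at sites
    where the fusion outcompetes the native factor.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_signal_peaks
    classes = np.array(["R1", "ER", "R1_ER"])[
        rng.choice(3, n, p=config.class_mix)
    ]
    ratio_mean = dict(zip(["R1", "ER", "R1_ER"], config.class_ratio_means))
    r = np.array([rng.normal(ratio_mean[c], config.class_ratio_sd) for c in classes])
    base = rng.normal(config.base_log2_cpm_mean, config.base_log2_cpm_sd, n)
    cpm_a_true = 2 ** (base - r / 2)
    cpm_b_true = 2 ** (base + r / 2)
    count_a = np.round(cpm_a_true * config.library_size / 1e6).astype(int)
    count_b = np.round(cpm_b_true * config.library_size / 1e6).astype(int)
    peak_ids = [f"peak{i:05d}" for i in range(n)]
    table = pd.DataFrame({
        "peak_id": peak_ids,
        "raw_count_a": count_a, "raw_count_b": count_b,
        "cpm_a": count_a * 1e6 / config.library_size,
        "cpm_b": count_b * 1e6 / config.library_size,
    })
    eff = config.acetyl_effect if config.acetyl_effect is not None else DEFAULT_ACETYL_EFFECT
    from scipy.stats import norm

    lfc = np.array([eff[c] for c in classes]) + rng.normal(0, config.acetyl_se, n)
    p = np.clip(2 * norm.sf(np.abs(lfc / config.acetyl_se)), np.finfo(float).tiny, 1.0)
    acetyl = pd.DataFrame({
        "peak_id": peak_ids, "log2fc": lfc, "pvalue": p, "padj": bh_adjust(p),
    })
    truth = pd.DataFrame({"peak_id": peak_ids, "true_class": classes,
                          "true_log_ratio": r})
    return table, acetyl, truth


# -------------------------------------------------------------- meta scores

def sim_metascores(config: SimulationConfig, gene_ids) -> pd.DataFrame:
    """Meta-score table with planted score-to-LFC couplings.

    p53 scores are integers in [-40, 40]; the cell-cycle study count rises
    with increasingly negative p53 score.  Two coupled fold-change columns
    are emitted: ``lfc_kd`` (native-factor knockdown-like; positively coupled
    across the whole score range) and ``lfc_fusion`` (fusion-like; coupled
    only on the negative, cell-cycle side — the planted asymmetry).
    Couplings scale with ``metascore_slope``; slope 0 disables them.
    """
    rng = np.random.default_rng(config.seed + 3)
    n = len(gene_ids)
    score = np.clip(np.round(rng.normal(0, config.p53_score_sd, n)), -40, 40).astype(int)
    cc_rate = np.clip(-score / 5.0, 0, None)
    cc_count = np.clip(rng.poisson(cc_rate), 0, 12).astype(int)
    s = score / 40.0
    noise = config.metascore_noise_sd
    lfc_kd = config.metascore_slope * s + rng.normal(0, noise, n)
    lfc_fusion = -config.metascore_slope * np.where(s < 0, s, 0.0) + rng.normal(0, noise, n)
    return pd.DataFrame({
        "gene_id": gene_ids, "p53_score": score, "cc_count": cc_count,
        "lfc_kd": lfc_kd, "lfc_fusion": lfc_fusion,
    })


# -------------------------------------------------------------------- CyTOF

def sim_cytof(config: SimulationConfig) -> pd.DataFrame:
    """CyTOF event table drawn from condition-specific population x phase
    mixtures, with raw-scale marker intensities and meta_/truth columns.

    Marker means live in transformed [0,1] space (PHASE_MEANS and
    POPULATION_MEANS); Gaussian noise of sd ``cytof_noise_sd`` is added there
    and values are inverse-transformed to the raw ion-count scale via
    ``raw = sinh(u * span) * cofactor``, the inverse of the arcsinh transform
    up to the percentile rescaling (which is monotone).  Truth labels sit in
    ``meta_true_phase`` / ``meta_true_population``.
    """
    rng = np.random.default_rng(config.seed + 4)
    conditions = list(config.phase_mix)
    per_cond = config.n_events // len(conditions)
    rows_cond, rows_pop, rows_phase = [], [], []
    u_blocks = []
    for cond in conditions:
        pmix = config.phase_mix[cond]
        popmix = config.population_mix[cond]
        phases = list(pmix)
        pops = list(popmix)
        ph = rng.choice(len(phases), per_cond, p=np.array([pmix[k] for k in phases]))
        po = rng.choice(len(pops), per_cond, p=np.array([popmix[k] for k in pops]))
        mean_surface = np.array([POPULATION_MEANS[pops[i]] for i in po])
        mean_cycle = np.array([PHASE_MEANS[phases[i]] for i in ph])
        u = np.concatenate([mean_surface, mean_cycle], axis=1)
        u = u + rng.normal(0, config.cytof_noise_sd, u.shape)
        u_blocks.append(np.clip(u, 0.0, 1.0))
        rows_cond += [cond] * per_cond
        rows_pop += [pops[i] for i in po]
        rows_phase += [phases[i] for i in ph]
    u = np.vstack(u_blocks)
    raw = np.sinh(u * config.cytof_asinh_span) * config.cytof_cofactor
    cols = SURFACE_MARKERS + CYCLE_MARKERS + DEATH_MARKERS
    df = pd.DataFrame(raw, columns=cols)
    df["meta_condition"] = rows_cond
    df["meta_true_population"] = rows_pop
    df["meta_true_phase"] = rows_phase
    return df
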