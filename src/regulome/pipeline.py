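"""End-to-end synthetic pipeline: simulate -> consensus -> annotate ->
enrich -> classify -> core -> metascore -> cytof.

Each stage writes its tabular outputs under the run directory and
contributes headline statistics to a JSON run report that also records every
parameter and the seed, so a run is fully reproducible from its report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import classify as cls
from . import coreprog, cytof, io, metascore
from .intervals import PeakSet, annotate_peaks, merge_intervals, support_filter
from .simulate import SimulationConfig, sim_cytof, sim_de_tables, sim_metascores, \
    sim_peak_signals, sim_regulome
from .stats import binned_binding_enrichment, enrichment_to_frame, flag_bound_genes

STAGES = ("simulate", "consensus", "annotate", "enrich", "classify",
          "core", "metascore", "cytof")


@dataclass
class RunConfig:
    """Parameters of a pipeline run; every threshold lands in the report."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    min_support: int = 2
    max_distance: int = 100_000
    rank_bins: int = 10
    tau: float = 1.0
    pseudocount: float = 0.5
    acetyl_bins: int = 11
    padj_pair: float = 0.1
    padj_lrt: float = 0.05
    core_effect: float = 3.0    # per-line knockdown effect (in sd) for the core stage
    gsea_n_perm: int = 500
    metascore_level: float = 0.90
    p53_cutoff: int = 17
    som_grid: tuple[int, int] = (10, 10)
    som_epochs: int = 10
    cofactor: float = 5.0
    n_metaclusters: int = 7
    n_pop_metaclusters: int = 7
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        self.sim.seed = self.seed


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stage chain and return the run report."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    report: dict = {
        "seed": config.seed,
        "parameters": {k: v for k, v in vars(config).items() if k not in ("outdir", "sim")},
        "sim_parameters": sim.to_dict(),
        "stages": {},
        "checksums": {},
    }
    report["parameters"]["outdir"] = str(out)

    genes, true_sites, observed, dnase, truth = sim_regulome(sim)
    stats: dict = {}
    if "simulate" in config.stages:
        io.write_genes(genes, out / "genes.tsv")
        for ps in observed:
            io.write_peaks(ps, out / f"{ps.set_id}.narrowPeak")
        io.write_peaks(dnase, out / "dnase.bed", fmt="bed")
        io.write_table(truth, out / "truth_sites.tsv")
        report["stages"]["simulate"] = {
            "n_genes": len(genes), "n_true_sites": len(true_sites),
            "n_peaks_per_set": [len(ps) for ps in observed],
        }

    # consensus: reference antibody supported by the other sets + open chromatin
    reference = merge_intervals(observed[0])
    others = [merge_intervals(ps) for ps in observed[1:]] + [merge_intervals(dnase)]
    high_conf, support = support_filter(reference, others, config.min_support)
    truth_idx = PeakSet("truth", list(true_sites))
    _, ref_hits = support_filter(high_conf, [truth_idx], 0)
    n_true_peaks = sum(1 for v in ref_hits.values() if v > 0)
    recovered, _ = support_filter(truth_idx, [high_conf], 1)
    recovery = len(recovered) / len(true_sites)
    fdr = 1 - n_true_peaks / len(high_conf) if len(high_conf) else float("nan")
    if "consensus" in config.stages:
        io.write_peaks(high_conf, out / "high_confidence.narrowPeak")
        report["stages"]["consensus"] = {
            "n_reference": len(reference), "n_high_confidence": len(high_conf),
            "recovery": recovery, "false_discovery_rate": fdr,
        }
    stats.update(high_conf_recovery=recovery, high_conf_fdr=fdr,
                 n_high_confidence=len(high_conf))

    annotations = annotate_peaks(high_conf, genes, config.max_distance)
    flags = flag_bound_genes(annotations, genes)
    if "annotate" in config.stages:
        ann_df = pd.DataFrame(
            [(a.peak_id, a.gene_id, a.signed_distance, a.category) for a in annotations],
            columns=["peak_id", "gene_id", "signed_distance", "category"],
        )
        io.write_table(ann_df, out / "annotations.tsv")
        cat_counts = ann_df["category"].value_counts().to_dict()
        report["stages"]["annotate"] = {
            "n_bound_genes": int(flags["bound"].sum()), "categories": cat_counts,
        }

    bound = pd.Series(flags["bound"].to_numpy(), index=flags["gene_id"])
    mde, de_truth = sim_de_tables(sim, bound)
    de = mde.lines["line1"].copy()
    de["bound"] = de["gene_id"].map(bound).to_numpy()
    if "enrich" in config.stages:
        enr = binned_binding_enrichment(de, rank_bins=config.rank_bins)
        enr_df = enrichment_to_frame(enr)
        io.write_table(enr_df, out / "binding_enrichment.tsv")
        sig_bins = enr_df.loc[enr_df["padj"] < 0.05, "bin"].tolist()
        report["stages"]["enrich"] = {
            "significant_bins": sig_bins,
            "down_bin_padj": float(enr_df.iloc[0]["padj"]),
            "down_bin_odds_ratio": float(enr_df.iloc[0]["odds_ratio"]),
        }
        stats.update(down_bin_odds_ratio=float(enr_df.iloc[0]["odds_ratio"]),
                     n_significant_bins=len(sig_bins))

    sig_table, acetyl, sig_truth = sim_peak_signals(sim)
    classified = cls.classify_peaks(sig_table, tau=config.tau, pseudocount=config.pseudocount)
    acc = float((classified["class_label"].to_numpy() == sig_truth["true_class"].to_numpy()).mean())
    rank_stat = np.sign(acetyl["log2fc"]) * -np.log10(acetyl["pvalue"])
    binres = cls.ranked_bin_proportions(
        rank_stat, classified["class_label"], k=config.acetyl_bins,
        peak_ids=classified["peak_id"],
    )
    if "classify" in config.stages:
        io.write_table(classified, out / "peak_classes.tsv",
                       params={"tau": config.tau, "pseudocount": config.pseudocount})
        io.write_table(binres.table, out / "ranked_bins.tsv")
        report["stages"]["classify"] = {
            "class_accuracy": acc, "trend": binres.trend,
            "class_counts": classified["class_label"].value_counts().to_dict(),
        }
    stats.update(class_accuracy=acc, ranked_bin_trend_rho=binres.trend["spearman_rho"])

    # dedicated strong-knockdown experiment across the five lines
    mde_core, _ = sim_de_tables(sim, bound, effect=config.core_effect)
    core_up, core_down = coreprog.core_consensus_filter(
        mde_core, padj_pair=config.padj_pair, padj_lrt=config.padj_lrt)
    ranked = coreprog.rank_metric(mde.lrt, mode="signed_logp")
    truly_bound = set(de_truth.loc[de_truth["bound"], "gene_id"])
    gsea = coreprog.gsea_preranked(ranked, truly_bound, weight=1,
                                   n_perm=config.gsea_n_perm, seed=config.seed)
    if "core" in config.stages:
        io.write_gmt({"core_up": sorted(core_up), "core_down": sorted(core_down)},
                     out / "core_sets.gmt")
        io.write_table(ranked, out / "ranked_list.tsv")
        report["stages"]["core"] = {
            "n_core_up": len(core_up), "n_core_down": len(core_down),
            "gsea_es": gsea.es, "gsea_nes": gsea.nes, "gsea_p": gsea.pvalue,
            "leading_edge_size": len(gsea.leading_edge),
        }
    stats.update(n_core_up=len(core_up), n_core_down=len(core_down), gsea_es=gsea.es)

    ms = sim_metascores(sim, bound.index)
    if "metascore" in config.stages:
        bins = metascore.bin_by_score(ms, "p53_score", list(range(-40, 46, 5)))
        summary = metascore.binned_mean_ci(
            bins, ms.set_index("gene_id")["lfc_kd"], level=config.metascore_level,
            bound=bound,
        )
        tests = metascore.score_group_tests(
            ms, ms.set_index("gene_id")["lfc_kd"], cutoff=config.p53_cutoff)
        io.write_table(ms, out / "meta_scores.tsv")
        io.write_table(summary, out / "metascore_bins.tsv")
        io.write_table(tests, out / "metascore_group_tests.tsv")
        rho, _ = spearmanr(np.arange(len(summary)), summary["mean_lfc"])
        report["stages"]["metascore"] = {
            "bin_trend_rho": float(rho),
            "group_tests": tests.to_dict(orient="records"),
        }
        stats.update(metascore_trend_rho=float(rho))

    if "cytof" in config.stages:
        events = sim_cytof(sim)
        scaled = cytof.arcsinh_scale(events, cofactor=config.cofactor)
        thr = cytof.derive_thresholds(scaled, seed=config.seed)
        som = cytof.train_som(scaled, markers=cytof.CYCLE_MARKERS + cytof.DEATH_MARKERS,
                              grid=config.som_grid, epochs=config.som_epochs,
                              seed=config.seed)
        phase = cytof.metacluster_annotate(som, scaled, k=config.n_metaclusters,
                                           rules=cytof.PHASE_RULES, thresholds=thr)
        som_pop = cytof.train_som(scaled, markers=cytof.SURFACE_MARKERS,
                                  grid=config.som_grid, epochs=config.som_epochs,
                                  seed=config.seed)
        pop = cytof.metacluster_annotate(som_pop, scaled, k=config.n_pop_metaclusters,
                                         rules=cytof.POPULATION_RULES, thresholds=thr)
        labels = scaled[["meta_condition", "meta_true_phase", "meta_true_population"]].copy()
        labels["phase"] = phase
        labels["population"] = pop
        io.write_events(labels, out / "cytof_labels.csv")
        phase_acc = float((phase == scaled["meta_true_phase"]).mean())
        tests = cytof.phase_distribution_test(phase, scaled["meta_condition"])
        tbl, res = tests["all"]
        io.write_table(res.std_residuals.reset_index(), out / "cytof_residuals.tsv")
        report["stages"]["cytof"] = {
            "phase_accuracy": phase_acc,
            "population_accuracy": float((pop == scaled["meta_true_population"]).mean()),
            "chisq": res.statistic, "df": res.df,
        }
        stats.update(phase_accuracy=phase_acc, phase_chisq_df=res.df)

    report["headline"] = stats
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "report.json":
            report["checksums"][p.name] = _checksum(p)
    io.write_report(report, out / "report.json")
    return report
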