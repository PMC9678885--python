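#!/usr/bin/env python
"""Binding-expression integration: are bound genes repressed?

Simulates knockdown-style differential expression coupled to the annotated
binding flags, bins genes by relative expression change, and tests each bin
for overrepresentation of bound genes (one-sided Fisher, BH across bins) —
both over equal-size rank bins and over up/dn/ns significance groups.
"""

import argparse
from pathlib import Path

import pandas as pd

from regulome import io
from regulome.simulate import SimulationConfig, sim_de_tables
from regulome.stats import (
    binned_binding_enrichment, enrichment_to_frame, flag_bound_genes,
)
from regulome.intervals import AnnotatedPeak


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--rank-bins", type=int, default=10)
    args = ap.parse_args()

    genes = io.read_genes(args.datadir / "genes.tsv")
    ann_df = io.read_table(args.outdir / "peak_annotations.tsv")
    anns = [AnnotatedPeak(r.peak_id, r.gene_id, r.signed_distance, r.category)
            for r in ann_df.dropna(subset=["gene_id"]).itertuples()]
    flags = flag_bound_genes(anns, genes)
    bound = pd.Series(flags["bound"].to_numpy(), index=flags["gene_id"])

    cfg = SimulationConfig(seed=args.seed)
    mde, _ = sim_de_tables(cfg, bound)
    de = mde.lines["line1"].copy()
    de["bound"] = de["gene_id"].map(bound).to_numpy()
    io.write_table(de, args.outdir / "knockdown_de.tsv")

    ranked = enrichment_to_frame(binned_binding_enrichment(de, rank_bins=args.rank_bins))
    # significance groups are better powered on the joint table across lines
    joint = mde.lrt.copy()
    joint["bound"] = joint["gene_id"].map(bound).to_numpy()
    groups = enrichment_to_frame(binned_binding_enrichment(joint, groups=True))
    io.write_table(ranked, args.outdir / "binding_enrichment_rankbins.tsv")
    io.write_table(groups, args.outdir / "binding_enrichment_groups.tsv")

    sig = ranked[ranked["padj"] < 0.05]["bin"].tolist()
    print(f"bound genes: {int(bound.sum())}/{len(bound)}")
    print(f"rank bins significant for bound-gene overrepresentation (padj<0.05): {sig}")
    print("(bin 1 = most down-regulated on knockdown; the planted coupling is "
          "repressive, so enrichment should sit in the lowest bins)")
    print(groups[["bin", "n_genes", "n_bound", "odds_ratio", "padj"]].to_string(index=False))
    if groups.set_index("bin").loc[["up", "dn"], "n_genes"].sum() == 0:
        print("note: at the default weak coupling (0.5 sd/line) no single gene "
              "reaches joint padj<0.05 — the repression is only visible in "
              "aggregate, through the rank bins above")


if __name__ == "__main__":
    main()
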