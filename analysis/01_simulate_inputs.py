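#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Emits, under results/data/: gene models, two antibody peak sets plus an
open-chromatin superset (narrowPeak/BED), dual-factor signal and
differential-acetylation tables, meta-score tables, CyTOF events, and
sidecar truth files.  Downstream analysis scripts read only the
analysis-facing files; truth sidecars are used for evaluation alone.
"""

import argparse
from pathlib import Path

from regulome import io
from regulome.simulate import (
    SimulationConfig, sim_cytof, sim_metascores, sim_peak_signals, sim_regulome,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    io.write_config(cfg.to_dict(), out / "sim_config.yaml")

    genes, true_sites, observed, dnase, truth = sim_regulome(cfg)
    io.write_genes(genes, out / "genes.tsv")
    for ps in observed:
        io.write_peaks(ps, out / f"{ps.set_id}.narrowPeak")
    io.write_peaks(dnase, out / "dnase.bed", fmt="bed")
    io.write_table(truth, out / "truth_sites.tsv")

    signal, acetyl, sig_truth = sim_peak_signals(cfg)
    io.write_table(signal, out / "peak_signal.tsv")
    io.write_table(acetyl, out / "acetylation_de.tsv")
    io.write_table(sig_truth, out / "truth_peak_classes.tsv")

    ms = sim_metascores(cfg, [g.gene_id for g in genes])
    io.write_table(ms, out / "meta_scores.tsv")

    events = sim_cytof(cfg)
    io.write_events(events, out / "cytof_events.csv")

    print(f"seed {args.seed}: {len(genes)} genes, {len(true_sites)} true sites, "
          f"{[len(p) for p in observed]} observed peaks, {len(events)} CyTOF events")
    print(f"inputs written to {out}/")


if __name__ == "__main__":
    main()
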