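# regulome

Toolkit and analysis pipeline for integrating a transcription factor's
genome occupancy with its transcriptional consequences, built around the
question of how an oncogenic fusion protein competes with its native
counterpart in B-cell progenitors. It covers the full arc of such a study:

1. **Consensus binding sites** — peaks supported by independent antibodies
   and open chromatin (`support_filter`), with strand-aware nearest-gene
   annotation anchored on peak summits.
2. **Binding vs expression** — genes binned by expression change, each bin
   tested for overrepresentation of bound genes (one-sided Fisher,
   Benjamini–Hochberg across bins).
3. **Occupancy classification** — peaks classed as preferentially bound by
   the native factor (R1), the fusion (ER) or both (R1_ER) from the
   pseudocounted CPM log-ratio, and tracked across a ranked
   differential-acetylation axis in 11 equal bins.
4. **Core program** — targets responding consistently in every cell line
   (padj < 0.1, concordant direction, joint LRT padj < 0.05), gene ranking
   by sign(LFC)·−log10(p), and preranked GSEA with a permutation null.
5. **Meta-score integration** — fold changes summarised along a signed p53
   score axis (mean ± 90% CI per bin) and Welch t-tests of the cell-cycle
   (score ≤ −17) and apoptosis/DNA-damage (score ≥ 17) groups vs control.
6. **Mass cytometry** — arcsinh scaling, batch SOM clustering, rule-based
   metacluster annotation to populations and cell-cycle phases, a biaxial
   gating comparator, and chi-squared phase-distribution tests with
   adjusted standardized residuals.

Real sequencing/CyTOF inputs are not shipped; a first-class generator
(`regulome.simulate`) emits every input format with planted ground truth,
so each stage is evaluated by how well it recovers what was planted. See
`docs/methods.md` for the models, defaults and their rationale.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic conditions (seed 1), writing tables under `results/`:

```bash
python analysis/01_simulate_inputs.py      # inputs + truth sidecars
python analysis/02_consensus_peaks.py      # high-confidence sites
python analysis/03_binding_expression.py   # binned Fisher enrichment
python analysis/04_peak_classes.py         # R1/ER/R1_ER + acetylation bins
python analysis/05_core_program.py         # core sets + GSEA
python analysis/06_meta_scores.py          # p53-score axis
python analysis/07_cytof_phases.py         # SOM phases + chi-squared
```

Selected output, with what it means:

```
high-confidence peaks: 373 of 422 reference
recovery of planted sites: 93.5%; false discovery rate: 0.0%
```
Two-antibody + open-chromatin consensus keeps essentially only real sites;
recovery ≈ 0.97² because a site must be detected by both antibodies.

```
rank bins significant for bound-gene overrepresentation (padj<0.05): ['1', '2', '3']
```
Bound genes pile up in the most down-regulated bins after knockdown-style
coupling — the planted repression, recovered by the binned Fisher tests.

```
class sizes: {'R1_ER': 977, 'R1': 533, 'ER': 490}; accuracy vs planted classes: 96.2%
ER+R1_ER share across acetylation bins (down -> up): Spearman rho = -0.970
```
The CPM-ratio classifier recovers the planted classes, and fusion-occupied
peaks concentrate where acetylation is lost.

```
core program at 3-sd knockdown: 52 down, 0 up (of 352 bound genes...)
GSEA of the bound set ...: ES = -0.694, NES = -2.59, p = 0.0010
```
The cross-line filter admits only consistently repressed genes, and the
bound set as a whole sits at the down-regulated end of the joint ranking.

```
phase accuracy 98.2%; population accuracy 95.5%; SOM-vs-gating agreement 96.3%
HSPC: chi-squared = 44.6, df = 6; largest positive residual at 'S' ...
```
SOM metacluster annotation recovers the planted phases, agrees with
conventional gating, and the planted S-phase excess in the fusion
condition surfaces as the largest positive standardized residual at S.

A `regulome` CLI wraps the same chain (`regulome all -o out/ -s 1`, or one
subcommand per stage); every run writes a JSON report echoing all
thresholds, the seed and output checksums.

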