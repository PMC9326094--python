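# netscope

Quantification of neutrophil extracellular traps (NETs) in equine
bronchoalveolar lavage fluid (BALF), end to end:

- **cohort** (`netscope.cohort`) — subject records with BALF differential
  cytology, rule-based classification into healthy / moderate / severe
  asthma phenotypes (strict cutoffs: neutrophils >5%, eosinophils >1%,
  mast cells >2% for asthma; labored breathing, abnormal auscultation or
  neutrophilia >20% for severe), the Neu-lo/Neu-hi split of moderate cases
  at 5% neutrophils, and CSV I/O. Two transcribed clinical tables ship as
  packaged fixtures (12 healthy controls, 21 asthmatic horses).
- **imaging** (`netscope.imaging`) — confocal NETs-area scoring: per-channel
  thresholding (manual or Otsu), binary intersection of the MPO (green) and
  Cit-H3 (red) masks, colocalization area, DAPI nucleus counting, MPO+
  neutrophil identification, and per-cell / per-neutrophil / per-individual
  normalization. The DAPI channel is deliberately excluded from the
  intersection.
- **assays** (`netscope.assays`) — PicoGreen cf-DNA quantification against a
  linear standard curve (2-fold serial dilution, 0.4 to 3.125e-3 µg/ml),
  blank-corrected MPO-DNA ELISA ODs, and DNase titration plateau selection.
- **stats** (`netscope.stats`) — Shapiro-Wilk-dispatched group comparisons
  (t-test / ANOVA+Tukey when all groups are normal, Mann-Whitney /
  Kruskal-Wallis+Dunn otherwise), Spearman correlation, and empirical
  ROC/AUC with explicit positive-class orientation (sub-0.5 AUCs are
  reported as-is).
- **simulate** (`netscope.simulate`) — ground-truthed synthetic data:
  3-channel cytospin-like fields (nuclei, MPO annuli, double-positive NET
  filaments, primed neutrophils) and cohort measurement tables with a
  severe-shifted effect structure. Deterministic under a seed.
- **pipeline / CLI** (`netscope.pipeline`, `netscope.cli`) — orchestration
  and report bundles.

## CLI

```sh
netscope classify cohort.csv
netscope quantify-images manifest.csv --out fields.csv
netscope assay plate.csv --kind picogreen
netscope stats measurements.csv --out statistics.json
netscope run --simulate-cohort --output-dir out/ --seed 1
netscope simulate-images --spec scene.yaml --out sim/ --n-fields 6
netscope simulate-cohort --out cohort.csv --measurements-out meas.csv
netscope reproduce-paper
```

`netscope reproduce-paper` recomputes the classification counts from the
packaged tables and reports pass/fail per check.

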