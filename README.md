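# cevtransport

Analysis pipeline for studying how blood-sample transport — hospital
pneumatic tube system (PTS) vs human carrier (C) — affects the proteome
and particle size distribution of circulating extracellular vesicles
(cEV). It is written for proteomics/biomarker researchers who want the
full chain from raw inputs to transport-effect calls as a reusable,
tested Python library.

The pipeline covers:

* **Transport metrics** from 3-axis accelerometer traces: mean
  Teager–Kaiser energy TK = mean(x[n]² − x[n−1]x[n+1]) (g²), RMS (g),
  vibration dose value VDV = (∫x⁴dt)^¼ (g·s^0.25), shocks > 2.5 g, and
  the walker's ground frequency from the Fourier spectrum.
* **Nanoparticle size-distribution features**: trapezoidal AUC,
  weighted mean/SD/skewness, mode and median size, dilution-corrected
  particle volume.
* **Protein classification** into origin (cellular vs serum/plasma) and
  category via an annotation cascade, detection accounting (≥ 2 of 3
  technical replicates in ≥ 1 donor), unique-to-plasma-type sets and
  platelet-contamination ratios.
* **Label-free quantification (iTop3)**: injection summing,
  variance-stabilizing glog2 calibration, Top3 protein abundances
  (log2 of the sum of the three most intense peptides), and two-branch
  MNAR imputation — N(mean − 2.5·SD, (0.3·SD)²) draws for ≥ 2 missing
  replicates, EM conditional means for single gaps.
* **Differential testing**: empirical-Bayes moderated t with
  s̃² = (d0·s0² + d·s²)/(d0 + d), BH adjustment, a fold-change-dependent
  significance threshold 0.05·(1 − e^{−(|log2fc|−1)/c}) that is 0 at
  |log2fc| = 1 and 0.05 asymptotically, and a 20-cycle imputation
  consensus; plus Welch's t and Tukey's HSD for group panels.
* **Correlation networks**: Spearman correlations recorded only at
  p ≤ 0.05, metric-subset accounting, ranked lists scored
  (1 − p)·sign(rho) for enrichment export, STRING-style edge filtering
  at combined score ≥ 0.7 and greedy-modularity community clustering.
* **Transport classification**: Lasso (mixing 1.0) and elastic net
  (0.5) on 0/1 transport labels over complete-case gene products, with
  the penalty chosen by leave-one-out cross-validation.
* **Synthetic data** for every stage, with planted effects and a truth
  record, so the whole pipeline is testable without any download.

## Worked example

`examples/transport_metrics.py` generates one synthetic trace per
transport mode and prints the metrics:

```
--- C (5.5 min) ---
  TK     0.0515 g^2   (mean Teager-Kaiser energy)
  RMS    0.3340 g     (mean acceleration)
  VDV    1.8029 g*s^0.25 (shock-weighted vibration dose)
  shocks > 2.5 g: 0
  max / median amplitude: 0.80 / 0.21 g
  ground frequency: 4.00 Hz (walker gait)
--- PTS (2.4 min) ---
  TK     0.9025 g^2   (mean Teager-Kaiser energy)
  RMS    1.4419 g     (mean acceleration)
  VDV   10.7723 g*s^0.25 (shock-weighted vibration dose)
  shocks > 2.5 g: 106
  max / median amplitude: 13.35 / 0.28 g
```

The carrier trace is a gentle ~4 Hz oscillation (no shocks, median
amplitude ~0.2 g); the pneumatic-tube trace is an order of magnitude
harsher on every metric, with over a hundred multi-directional shocks —
the contrast that the downstream correlation and classification stages
relate to cEV protein changes.

`examples/differential_consensus.py` plants ten +3 log2 transport
effects on a 500-protein null background and runs the 20-cycle
imputation consensus:

```
recovered 10/10 planted, 0 false positives
```

The other scripts in `examples/` walk the remaining capabilities:
particle features, the quantification chain, metric correlations and
ranked lists, network communities, and the Lasso transport classifier.
A thin CLI mirrors the stages (`cevtransport metrics|particles|diffexpr|
correlate|network|select|synth`); run `cevtransport --help`.

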