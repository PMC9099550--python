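# Methods

`cevtransport` implements, end to end, a desk-scale analysis of how
blood-sample transport (human carrier, "C", vs pneumatic tube system,
"PTS") affects the proteome of circulating extracellular vesicles (cEV).
This note describes the models and procedures each stage implements, the
parameters that matter, what the synthetic-data generators emulate, and
the numerical choices and known limitations.

## Accelerometry

A transport event is a 3-axis acceleration recording (25 Hz, per-axis
saturation ±16 g — the regime of a hobby-board sensor). The static
gravity component is removed by subtracting each axis's median; metrics
are computed on the Euclidean magnitude of the residual:

* **TK** — mean discrete Teager–Kaiser energy,
  `mean(x[n]² − x[n−1]·x[n+1])` (g²), an instantaneous-energy estimator;
* **RMS** — root mean square (g);
* **VDV** — vibration dose value `(Σ x⁴ dt)^¼` (g·s^0.25),
  rectangle-rule discretized with `dt` = median sampling interval
  (irregular timestamps are linearly resampled to a uniform grid);
* **shock count** — maximal contiguous excursions strictly above 2.5 g,
  one event per excursion (counting samples would scale with the
  sampling rate);
* **ground frequency** — the dominant Fourier line of a walker's gait.

Median-subtraction for gravity removal was chosen because it is robust
to shock outliers and leaves a resting trace identically zero; metrics
on the magnitude (rather than per-axis averages) make the result
orientation-invariant, which matters because pneumatic-tube shocks
arrive from arbitrary directions.

The ground frequency is computed on the **signed, gravity-removed axes**
(per-axis magnitude spectra summed), not on the Euclidean magnitude: the
magnitude is a rectified signal whose spectrum peaks at twice a pure
oscillation's frequency, so a 4 Hz gait would read as 8 Hz. The search
band is (0.2 Hz, Nyquist]; the lower bound excludes slow drift. The
default analysis window is the most stationary 60 s segment (minimal
variance of 1 s-block RMS values); explicit windows must span 0.5–3 min.

## Nanoparticle size distributions

Input is a binned concentration-vs-diameter curve (10–1000 nm). Features:
trapezoidal AUC (total concentration), concentration-weighted mean, SD
and standardized third-moment skewness of the bin centers, the mode
(center of the maximal bin), and a grouped-data median (linear
interpolation inside the crossing bin, with bin boundaries at midpoints
between centers, so a symmetric distribution's median equals its central
bin). Total particle volume treats each bin as spheres of the bin's
diameter and multiplies by the dilution factor. Multiple dilution
measurements of one sample are combined after dilution correction, with
weights proportional to each measurement's total counts.

## Protein classification and detection accounting

Proteins are classified by a cascade over curated annotation:
transmembrane/intramembrane flags together with subcellular location
decide first (cell membrane); then decisive GO cellular-component terms
(cell part / cell surface / serum-plasma); then GO biological-process
terms; finally tissue specificity, keywords or description. Serum/plasma
proteins are subcategorized (apolipoprotein, coagulation, complement,
immunoglobulin, other) by a keyword table. The decisive-term tables are
configuration: adjudicating "not conclusive" terms is curation work, so
the cascade beyond the stated order is deliberately editable.

A protein group counts as *detected* in a plasma-type/transport slice if
it appears in ≥ 2 of the 3 technical replicates of at least one donor.
Proteins detected in one plasma type and never in the other form the
unique-to sets whose platelet-annotated fractions quantify platelet
contamination. Tally totals are always computed from category counts,
never stored, so internal sums are consistent by construction.
Cell-type markers with several specificities count once per cell type,
so marker columns intentionally exceed the distinct-marker total.

## Quantification (iTop3)

1. **Injection summing.** The two mass-spectrometry injections per digest
   are summed; a missing partner contributes 0, two missing stay missing.
2. **Variance stabilization.** Each sample column gets an
   affine-then-arsinh transform `h(x) = glog2((x − a_s)/b_s)` with
   `glog2(y) = arsinh(y)/ln 2`, fitted by iterating per-sample robust
   (least-trimmed; untrimmed by default) maximum-likelihood fits against
   the row-median reference profile. The likelihood's Jacobian term
   identifies each sample's parameters, but the *common* scale of all
   `b_s` sits on a ridge (each sample's conditional optimum matches the
   others), so an explicit one-dimensional search sets it to make the
   spread of residuals against the reference independent of intensity —
   which is the transform's purpose. Output is log2-like: differences
   between large transformed intensities approach log2 ratios. Negative
   (background-subtracted) intensities are permitted; the transform is
   odd around its offset.
3. **Top3.** Per sample and protein group, the back-transformed linear
   values of the three most intense observed peptides are summed and
   re-logged; proteins with only 1–2 observed peptides are retained and
   flagged (`n_observed`), not dropped. Peptides are re-selected per
   sample, following the literal "three most intense peptides" rule.
4. **Imputation.** Within each technical-replicate triplet: if ≥ 2 of 3
   values are missing, each missing cell is drawn from
   `N(col_mean − 2.5·col_sd, (0.3·col_sd)²)` using its own column's
   observed-value moments — the standard down-shifted Gaussian for
   intensity-dependent (MNAR) missingness; a single missing value is
   filled with its conditional mean under a trivariate Gaussian fitted
   to the triplet's columns by EM (≤ 100 iterations, log-likelihood
   tolerance 1e-8). A mask records which branch produced every cell, and
   a fixed seed reproduces the matrix bit for bit. Imputation operates on
   protein-level log2 values after Top3: the replicate-group rule is
   well-defined there, and the Gaussian is specified on the normalized
   distribution. Columns with fewer than 10 observed values are rejected
   (moment estimates would be unreliable).
5. **Gene products.** Protein groups sharing a gene name are summed on
   the linear scale per sample — a group contributes in a replicate
   group only if it had at least one observed (non-imputed) value there
   — and the per-replicate log2 sums are reduced to their median.
   Subclass intensities are arithmetic means of member log2 values.

## Differential testing

Per-protein two-group comparisons use an empirical-Bayes moderated t:
the prior `(d0, s0²)` is estimated by moment matching on log sample
variances (inverse-trigamma solution of the scaled-F variance equation;
zero variances excluded; exactly-constant variances shrink to the common
value with `d0 = ∞`), `s̃² = (d0·s0² + d·s²)/(d0 + d)`, and the t
statistic is referred to `d + d0` degrees of freedom. BH step-up
adjustment controls the FDR.

Significance combines |log2fc| > 1 with a fold-change-dependent
adjusted-p threshold

    p_max · (1 − exp(−(|log2fc| − 1)/c)),   p_max = 0.05,

which is 0 at the fold-change cutoff and saturates at 0.05
asymptotically. Only the two boundary conditions and the dependence of
the curvature on the overall variance are fixed by the rules being
implemented; the exponential-saturation family is this package's choice
(smooth, monotone, satisfying both limits), with `c` defaulting to the
median moderated SD of the tested proteins. Both are configurable.

Because imputation is stochastic, the impute→test→adjust→curve cycle is
repeated (20 cycles by default) and only proteins significant in *every*
cycle are reported. Welch's unequal-variance t-test serves two-group
feature comparisons, and Tukey's HSD (one-way ANOVA residual variance +
studentized-range tail probabilities) serves four-group plasma×transport
panels at p ≤ 0.01.

## Correlations, ranked lists, networks

Spearman correlations (mid-rank ties) are recorded only when the
two-sided p ≤ 0.05, otherwise 0; fewer than three complete pairs yields
"not computed", distinct from 0. The p-value is exact (full permutation
enumeration) for n ≤ 9 and t-approximated otherwise. Recorded-rho
matrices are clustered with complete linkage on Euclidean distances
(linkage and metric are this package's choice; the procedure is
deterministic). Ranked lists order genes by `(1 − p)·sign(rho)`;
multi-metric lists give each gene its best (minimum) rank — a gene stays
top-ranked if any included metric ranks it highly, matching the lists'
purpose as enrichment input. Significantly correlating genes are
partitioned into the seven subsets of {TK, RMS, VDV} by sign, and
per-metric totals are always computed as subset sums.

Interaction edges (STRING-style combined scores; a 0–1000 scale is
normalized to 0–1) are kept at score ≥ 0.7, isolated nodes reported
separately, and communities found by greedy modularity agglomeration
with deterministic ordering — the same algorithm family as the GLay
plugin, not a bit-exact reproduction of it. GO-term redundancy filtering
is greedy set cover over a provided term-to-gene table.

## Transport classification

The classifier solves the elastic-net penalized least-squares problem on
0/1 transport labels (mixing `alpha` = 1.0 for the pure Lasso, 0.5 for
the elastic net), over gene products with no missing value anywhere.
Features are z-scored within each training fold; the penalty path is 100
log-spaced values from `lambda_max` (the smallest all-zero penalty) down
to 0.001·`lambda_max`; `lambda` is chosen by leave-one-out
cross-validated misclassification (predicted class = fitted response
≥ 0.5), ties broken toward the larger penalty. Selected markers are the
nonzero coefficients split by sign. The squared-error (gaussian)
formulation follows the 0/1-response description; coordinate descent is
provided by scikit-learn and cross-checked against a proximal-gradient
reference in the tests.

## Synthetic data

The generators produce every input the pipeline consumes, with the
statistical structure the analysis assumes:

* **Traces.** Carrier: ~5.5 min of a 4 Hz fundamental plus a weaker
  first harmonic with random-walk phase noise, amplitudes < 2.4 g,
  median dynamic amplitude ~0.2 g. Pneumatic tube: ~2.4 min of Gaussian
  baseline plus Poisson-timed biexponential shock pulses (expected 116
  above 2.5 g) with random 3D orientation and truncated-Pareto
  amplitudes reaching the ±16 g clip, so multi-axis vector maxima can
  exceed any single axis's limit.
* **Size distributions.** Binned lognormal densities (10 nm bins,
  10–1000 nm) scaled to a configured total concentration with 2%
  multiplicative bin noise — dilution-averaged instrument curves are
  smooth, and at this noise level the configured mode is recoverable to
  within one bin. Carrier defaults: mode 84 nm, GSD 1.35, 6·10¹²/mL;
  pneumatic tube: 116 nm, GSD 1.6, 8·10¹²/mL.
* **Proteomes.** Log-normal peptide intensities composed of protein base
  (N(23, 2²) log2), peptide offset (SD 1), donor effect (SD 0.3) and
  replicate noise (SD 0.25), split over two injections with a Beta(50,50)
  fraction; missingness is logistic-decreasing in log2 intensity
  (mid 20, scale 0.8). Planted transport-differential proteins are
  shifted +3 log2 in PTS; planted metric-correlated proteins track the
  standardized per-donor VDV with slope 0.8. The truth record lists all
  planted memberships, the metric table and the model-implied missing
  fraction.
* **Blood counts.** Physiological ranges per analyte, with the
  erythrocyte count and hemoglobin coupled at rho 0.9 through a Gaussian
  copula.

What the generators do **not** emulate: real spectra or retention times,
peptide-level interference, correlated missingness between peptides of
one protein, instrument drift, donor-level biological covariance
structure, or the actual ZetaView optics. Passing tests therefore
demonstrate correctness of the computations and calibration of the
statistical machinery under the stated models, not performance on real
instrument data.

## Numerical choices and degenerate inputs

* The variance-stabilization fit is untrimmed by default (the trimmed
  mode is for outlier-heavy data) and uses Nelder–Mead per sample with a
  grid-plus-bounded-scalar search for the common scale; on exactly
  proportional samples the calibration is exact at initialization.
* Zero-variance protein rows are excluded from prior estimation; a zero
  standard error with zero fold change yields t = 0.
* Welch's test returns (0, 1) when both groups are constant and equal;
  Tukey pairwise p-values are 1 for identical constant groups.
* BH adjustment caps at 1 and enforces step-up monotonicity.
* Correlation "not computed" (n < 3) is represented as `None`, never 0.
* Community ids are numbered by each community's lexicographically
  smallest member; node insertion order is sorted, making the partition
  deterministic.
* Imputation iterates replicate groups in sorted column order from a
  single `default_rng(seed)`, so results are reproducible bit for bit.

## Known limitations

* **Down-shift imputation can manufacture stable differences.** When a
  protein is observed in one transport group and missing in the whole
  opposite triplet, the −2.5 SD shift is deterministic across imputation
  cycles, so the 20-cycle consensus does not protect against it. The
  exposure is mild when missingness is a sharp detection limit near the
  imputation target and per-protein variance heterogeneity keeps the
  moderation prior df moderate; it grows when variances are homogeneous
  (the estimated prior df diverges and moderation overrules the large
  within-group variance of half-imputed proteins). Such "on–off"
  proteins deserve inspection rather than automatic trust.
* **Redundant markers are not all recovered.** L1 selection at a
  sparsity-tuned penalty intentionally drops features that are
  informative but mutually redundant; with several correlated planted
  markers, the chosen model typically keeps a subset (the elastic net
  mixing 0.5 mitigates but does not remove this). Marker lists are
  surrogates of correlated groups, not exhaustive inventories.
* The LOOCV misclassification criterion is pessimistic on balanced
  labels (each fold's training majority tips away from the held-out
  class), so absolute error values should not be read as generalization
  estimates; only the location of the minimum is used.
* The significance curve's functional family between its two fixed
  boundary values is a design choice; rankings near the boundary depend
  on it.
* Exact Spearman p-values switch to the t-approximation above n = 9;
  at n = 10–15 the approximation is mildly anticonservative in the
  extreme tails.

## Problem sizes used in the test suite

Statistical suites run at desk scale: 1000-protein null panels over 50
replicate simulations for false-positive control, 10 meta-seeds × 20
imputation cycles for planted-effect recovery, 20 seeds for
ground-frequency, particle-mode, community and marker-recovery checks,
and 2000-peptide two-replicate panels for the variance-stabilization
calibration. These sizes keep every suite well resolved (binomial SEs a
few percent) while the full suite completes in minutes on one CPU.
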