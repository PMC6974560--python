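# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices that affect results.

## CUE from growth curves

A batch culture's biomass carbon is `B(t) = OD600(t) * f * v` with
conversion factor `f` (default 130 ug C OD^-1 ml^-1, the conventional
value; the unit prefix of this factor is reported inconsistently in the
literature, so it is configurable — CUE itself only requires biomass-C and
CO2-C to share one mass unit, and is invariant to jointly rescaling both).
Headspace CO2 in ppm converts to ug C by the ideal-gas law at the assay
temperature and configured headspace volume, with the first read subtracted
as baseline; solution/headspace equilibrium is assumed instantaneous
(vortex-mixed tubes).

The exponential window is the contiguous run of 3-10 points maximising the
OLS slope of ln B vs t, found by exhaustive enumeration; ties go to the
longer window, then the earlier start (determinism — the choice among exact
ties does not affect the slope).  Because the OD-to-biomass conversion is
linear, the window and mu are identical whether ln OD or ln biomass-C is
used.

`mu` is the window's ln-biomass slope with the standard single-regressor
F-test (F = t^2, n-2 df).  The default respiration estimator regresses
cumulative CO2-C on biomass-C over the same window: under exponential
growth dCO2C/dt = R*B exactly, so that slope equals R/mu and
`R = slope * mu`; this makes CUE = 1/(1 + slope) depend only on the
CO2-vs-biomass relationship, which is what makes noiseless curves
recoverable to machine precision and slow growers (mu near 0.01 h^-1)
well-behaved.  A per-interval estimator (mean of dCO2C/dt divided by the
interval geometric-mean biomass) is available for sensitivity analysis;
both agree within 1% on clean input.  Replicates with either slope F-test
p > 0.05 are discarded, and conditions with fewer than two surviving
replicates are dropped entirely.

## Q10 and its uncertainty

Q10 = (CUE_high/CUE_low)^(10/dT).  The point estimate uses the two
replicate means (Q10 is nonlinear, so the mean of pairwise Q10s is biased
upward); the SE comes from the Q10 of every cross-pair of replicates.  The
95% CI resamples replicates with replacement within each temperature.  With
the 2-4 replicates typical of these assays the plain percentile bootstrap
of a mean ratio under-covers badly (~77-86% in our simulations at 3+3
replicates), so the default interval is an *expanded* percentile bootstrap:
log-scale bootstrap deviations around the point estimate are scaled by
`t_{df}/z * sqrt(n/(n-1))` with `df = n_lo + n_hi - 3`, the classical
small-sample expansion adapted to a two-sample ratio.  This restores
~95% coverage in the same simulations and is correspondingly conservative
for the "CI excludes 1" sensitivity call (~2-3% false-sensitive rate under
a temperature-insensitive truth).  The plain percentile interval remains
available (`ci_method="percentile"`).

## Phylogenetic comparative statistics

All statistics are built on the Brownian-motion covariance matrix V of the
rooted tree (shared root-to-MRCA branch length; diagonal = root-to-tip
distance).  Pagel's lambda scales the off-diagonal of V; it is capped at 1,
appropriate for ultrametric trees.  A single generalized eigendecomposition
of (V, diag V) prices the whole lambda family — GLS means, likelihoods and
determinants at any lambda cost O(n^2) after one O(n^3) factorisation,
which is what makes per-feature screens over thousands of KOs and
1000-replicate calibration studies cheap.

* **Blomberg's K**: observed MSE0/MSE around the GLS mean over its
  BM expectation `(tr V - n/sum(V^-1)) / (n-1)`.  The permutation test
  shuffles tip values and counts permutations whose V-weighted MSE is at
  most the observed one (one-sided: signal = relatives closer than chance),
  999 permutations, add-one smoothing.
* **Pagel's lambda**: ML on [0,1] with mean and rate profiled out
  analytically; a 17-point grid plus bounded scalar refinement (tolerance
  1e-8) guards against local optima.  The LRT against lambda = 0 uses
  chi-square with 1 df, the convention of the R packages this mirrors; at
  the boundary this is anticonservative and lambda_hat = 0 is reported with
  p = 1.  The implementation agrees with phytools' `phylosig` to ~1e-5 (K)
  and ~1e-3 (lambda log-likelihood) on shared input.
* **BM reference intervals**: K and lambda_hat percentiles over BM traits
  simulated on the observed tree — the yardstick for "consistent with
  Brownian evolution".
* **Tip prediction**: the tree is rescaled by the lambda fitted on the full
  trait, then each tip is predicted from the others by the Gaussian
  conditional expectation with the GLS mean of the remaining tips.  This is
  mathematically the re-rooting ancestral-state estimate at the tip's
  position (verified to 1e-8 against an explicit re-rooting oracle).
  Signed and absolute prediction errors are both correlated against the
  patristic distance to the nearest remaining tip, since either convention
  is defensible.
* **PGLS**: lambda profiled by ML jointly with the coefficients
  (single-model fits); coefficient t-tests use n - p df and the unbiased
  residual variance.  With lambda = 0 the fit reproduces OLS to 1e-10.
  Mass screens (`pgls_scan`, used by the marker pipeline) instead fix
  lambda at the *response's* ML value by default: re-profiling lambda per
  feature and then applying naive t-tests inflated the null hit rate from
  0.05 to ~0.063 across 2000-feature screens, while the response-lambda
  screen is calibrated.  Per-feature profiling remains available
  (`lambda_mode="profile"`).
* **Residual diagnostics**: K and lambda tests run on phylogeny-corrected
  (Cholesky-whitened) residuals, which are iid under a correctly specified
  model; raw GLS residuals retain signal by construction whenever
  lambda_hat > 0 and would fail every correct model.  The pass rule (both
  p > 0.05) intrinsically rejects ~7-8% of correct models — a cost of the
  conjunction, visible in the marker pipeline's power below.

## Marker discovery operating characteristics

The explore/validate design controls false discovery by conjunction rather
than multiple-testing correction (a Benjamini-Hochberg option exists but is
off by default, matching the raw-alpha design): exploration at alpha = 0.05
on a taxon subset, same-direction significance on the full glucose set,
same-direction validation in >= 2 of 3 other substrates *or* a significant
same-sign Spearman correlation in community data, and the residual
diagnostic.  Features present in fewer than 4 genomes are removed first.

Measured characteristics under the packaged study conditions (40 taxa,
26-taxon exploration subset):

* Null (2000 KOs, no effects): exploration hit rate ~= 0.05.  Falsely
  *finalized* markers are rare per feature (~5 x 10^-4) but not per run:
  the OR over validation routes contributes ~0.027 per candidate and the
  full-glucose confirmation is strongly correlated with exploration (the
  exploration taxa are a subset), so a 2000-feature null run finalizes
  ~0.9 false markers in expectation and ends with zero only ~40% of the
  time.  Conjunction validation is a strong filter, not an FDR guarantee;
  users scanning thousands of features should expect an occasional
  spurious "validated" marker and treat the BH option accordingly.
* Power (5 planted markers, pathway-correlated and widespread — shared
  log-density factor 0.7, prevalence 0.95 — effect size 0.025 CUE per
  density unit, shared across substrates and communities): per-marker
  exploration power ~0.93, and >= 4 of 5 markers finalized in ~90% of
  runs.  The effect size was set so exploration power lands in the low
  0.9s; larger effects push simulated CUE into its (0,1) bounds and
  truncation weakens the planted signal.

## Exoenzyme production cost

Per-residue de-novo ATP costs come from an input table (a synthetic example
ships with the package; substitute a literature table for real analyses —
its `n_carbon` column is validated against standard residue chemistry).
Total cost adds 4.2 ATP per peptide bond; regenerating ATP respires glucose
carbon at 26 ATP per 6 C, so a protein with C carbon atoms and A total ATP
has CUE = C / (C + A*6/26).  Expression weights use CAI against a
user-designated highly expressed reference set (conventionally ribosomal
protein genes): per-codon relative adaptiveness within synonymous families
(zero reference counts floored at 0.5), gene CAI as the geometric mean over
informative codons (Met/Trp and stops excluded), weights normalised over
the exoenzyme set.  The weighting function is pluggable; CAI is one
defensible codon-bias expression proxy among several.

## Auxiliary statistics

*Repeated-measures correlation* centres both variables within subject and
correlates the residuals with df = N - k - 1; with one subject it reduces
exactly to Pearson.  p-values use the t reference distribution with no
small-sample correction.

*Hartigan's dip* is computed exactly (to 1e-15 by bisection): for every
candidate mode placement the convex prefix / concave suffix feasibility at
sup-distance d reduces to greatest-convex-minorant deviations, plus an
explicit monotone-junction condition; the dip is the smallest feasible d.
The implementation was validated against an exact linear-programming oracle
over unimodal CDFs (including tied samples, where a jump of the fitted CDF
is allowed at the mode).  p-values are Monte-Carlo against the uniform
null (the conventional least-favourable choice), with the null distribution
shareable across tests of equal n.  Note the dip depends on the sample's
spacing configuration, not only on ranks: it is affine-invariant but not
invariant under general monotone transforms.  The statistic is defined for
n >= 4 and respects dip >= 1/(2n) for distinct observations.

## Synthetic data: what it does and does not emulate

Growth curves use a three-phase biomass model — flat lag, *exact*
exponential at mu_true, then a C1-continuous saturating approach to od_max
from half-maximum — with the cumulative respired CO2-C integral evaluated
in closed form, so noiseless recovery is a machine-precision identity.
OD noise is multiplicative log-normal (read error grows with signal, sd
0.01 by default — instrument-realistic but not fitted to any instrument);
CO2 noise is additive Gaussian in ppm (5 ppm default against a 420 ppm
baseline).  Not emulated: Baranyi-style smooth lag transitions, substrate
depletion kinetics, evaporation, or per-isolate conversion factors — the
estimators only use the exponential window, so flanking-phase realism is
deliberately minimal.

Trees are constant-rate Yule/birth-death stopped at n extant tips, with
terminal branches extended by the waiting time to the next event so the
final speciation leaves no zero-length terminals.  Traits are draws from
N(root, sigma2 * V_lambda).  KO tables evolve log-densities by BM around
KO-specific baselines, zero-truncated to per-KO prevalence targets;
community validation data are generated directly as (relative abundance,
CUE) pairs rather than via any metagenome-inference mechanics.  Passing
tests on these generators demonstrates estimator correctness under the
stated models, not robustness to real-data pathologies (plate effects,
non-stationary rates, annotation error).

## Reproducibility

Every stochastic routine takes an explicit seed; all generators are
bit-reproducible under a fixed seed.  The pipeline writes a manifest with
SHA-256 hashes of all inputs and outputs, so reruns are verifiable.  The
calibration studies (`cuephylo.calibration`) fix their study sizes — 200
growth replicates, 1000 Q10 conditions, 500 BM simulations on 32 tips, 200
lambda replicates on 64 tips, 50 null and 25 power marker seeds, 200
dip-test repetitions — chosen to make Monte-Carlo error small relative to
the property margins being checked while keeping a full run in the
single-digit minutes on one CPU.
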