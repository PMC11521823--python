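# Methods

This note records the statistical models, parameter conventions and design
choices of the package, in the spirit of a methods supplement: what each
stage assumes, which knobs matter, and what the synthetic cohorts do and do
not emulate.

## The paired design

The unit of inference is the participant, measured before (BT) and after
(AT) an intervention in up to three blocks: buccal-cell histone PTMs, PBMC
histone PTMs, plasma protein groups. All intensity matrices are log2 scale
at the IO boundary (linear input must be converted explicitly). Pairing is
by participant within a sample type; participants lacking one timepoint are
carried as unpaired and excluded from paired statistics but retained in the
matrices. Sample and feature order is preserved from the input files; all
paired operations index by label, never by position.

## Preprocessing

**Filters.** PTM features with ≥ 10 missing values over the paired samples
are dropped (`max_missing=10`). Plasma protein groups must be observed in
≥ 9 paired participants at BT *and* ≥ 9 at AT (`min_paired=9`, an 80% rule
at 11–12 pairs); the AND is deliberate — a group quantified at only one
timepoint cannot support a paired contrast.

**Quantile normalization** maps each sample's observed values onto the
cross-sample mean quantile curve. Missing cells are ignored in the rank
computation: a sample with k observed values is evaluated at plotting
positions (rank − ½)/k, so samples with different missingness remain
comparable. On complete matrices this is the classical procedure (all
sorted columns become identical) and it is an exact fixed point.

**Missingness model.** Per (feature, condition BT/AT): missing fraction
0 → OBSERVED; > 75% → NMAR (censored); otherwise MAR. Equality at exactly
75% resolves to MAR (the threshold is a strict inequality; at n = 12 per
condition the boundary case is 9/12). NMAR cells are imputed from
N(μ_low, σ_med²) with μ_low the mean of observed values below the
block-wide 1st percentile and σ_med the median over features of the
per-feature SD (n − 1 denominator); MAR cells from N(feature's observed
condition mean, 0.5²). Both reference quantities are computed block-wide
over observed values — at n = 12 per condition, per-sample versions are too
unstable. A MAR cell whose condition has no observed value falls back to
the NMAR rule with a warning. Observed values are never altered;
imputation is seeded and reproducible.

**Stage order** is fixed: filter → quantile normalize → classify → impute →
batch adjust → (PTM blocks) relative abundance. Batch adjustment runs on the
complete (imputed) matrix because the location/scale model has no missing-
data mechanism; relative abundance comes last so percentages are formed from
batch-corrected intensities.

**Batch adjustment** is the parametric empirical-Bayes location/scale model:
per-feature standardization against batch-structure-free residual variance,
normal prior on additive batch effects, inverse-gamma prior on
multiplicative effects, hyperparameters by method of moments, posterior
batch parameters by the standard fixed-point iteration, then
back-transformation. No covariates are modelled. The implementation agrees
with the reference R implementation (`sva::ComBat`) to ~5e-11 on a frozen
fixture (`tests/data/combat_*.tsv`). Note the intended behaviour on null
data: per-feature batch deviations at noise level are *shrunk*, not zeroed —
only the systematic component is removed.

**Relative abundance.** Within each precursor group and sample,
p_i = 100 · 2^{x_i} / Σ_j 2^{x_j} over the observed members (percentages of
log values would be meaningless, so the linear-scale conversion is
explicit). An all-missing (group, sample) stays missing; partially observed
groups normalize over the observed members. Consequently the percentages of
group-mates are coupled: a genuine change in one member induces
compensatory changes in the others. This is a property of the measurement
scale, not an artifact — composition shifts within a precursor are real
biology — but it means "markers" on the relative-abundance scale need not
coincide feature-for-feature with intensity-scale perturbations.

## Composite marker discovery

Paired t (two-sided) and Wilcoxon signed-rank (two-sided, exact null for
n ≤ 25, zeros dropped) run on AT − BT per feature over complete pairs
(≥ 3 required), BH-adjusted within block. All-zero differences give p = 1
(no evidence). A zero-variance nonzero shift floors the t p-value at 1e-300.

PLS-DA is fitted on autoscaled sample profiles with the BT/AT status as a
centered class indicator (2 components by default; the iterative PLS engine
is scikit-learn's `PLSRegression`, whose x-weights are unit-norm).
Zero-variance features are excluded with a warning. VIP uses
SS_a = Σ_k q_ak² · (t_a·t_a), the response variance explained per component;
with unit-norm weights, mean(VIP²) = 1 holds algebraically and is asserted
to 1e-8. The jackknife removes one participant (both samples), refits, and
builds delete-1 pseudo-value SEs with a t_{n−1} quantile; the CI
construction is a package convention (the field rarely states one). The
selection rule requires *both* classical tests and the VIP lower bound — an
AND composition, so each gate can only remove false positives.

Effect sizes: mean over pairs of AT − BT, read as average log2-fold change
for intensity blocks and as percentage points for relative-abundance blocks.

**Effect-size convention.** Power statements use the paired-design scale
(Cohen's d_z): "effect k·SD" means k times the SD of the AT − BT difference.
With independent BT and AT residuals of SD σ, a planted shift of k·σ√2 is
k on the d_z scale. At n = 12 this is the only scale on which the composite
selector can reach the calibrated sensitivity ≥ 0.8 the package's
acceptance experiment demonstrates; per-measurement scaling gives paired-t
power ≈ 0.55 under BH and is not the intended reading of cohort-level power.

## Integration

Affinities use the SNF scaled-exponential kernel on Euclidean distances:
W_ij = exp(−d_ij²/(μ ε_ij)) with local bandwidth
ε_ij = (mean K-NN distance of i + of j + d_ij)/3; defaults
K = max(2, ⌊n/3⌋), μ = 0.5. Change vectors are restricted to the discovered
marker panel (falling back to full profiles if none). Fusion cross-diffuses
each view's K-NN-local kernel against the average of the other views' full
kernels for t = 20 iterations, renormalizing and symmetrizing each round;
the final diagonal (a diffusion artifact holding half the mass) is replaced
by the median off-diagonal similarity for display and clustering. A
caution from the cluster-recovery experiments: K at or above the true
cluster size systematically leaks mass across clusters (a point in a
cluster of c has only c − 1 same-cluster neighbours), so K should stay
below the smallest expected subgroup.

Spectral clustering uses the symmetric normalized Laplacian, row-normalized
eigenvector embedding and a seeded k-means; with k = "auto", k maximizes
the eigengap over [2, n/2]. A disconnected affinity graph falls back to its
components with a warning.

The cross-omics network is plain Pearson correlation between PTM change and
protein change vectors over shared participants, thresholded at
|r| ≥ 0.7 (inclusive), signed. This direct change-correlation procedure
stands in for latent-variable multi-block integration: it is transparent,
exactly testable, and at n ≈ 12 a sparse multi-block latent model has
little information advantage over the raw correlations it thresholds.
Dendrogram agreement across omic types uses average-linkage hierarchical
clustering on Euclidean distances and the Pearson correlation of cophenetic
distance vectors.

## Response classes and trends

Agility percent changes (100·(AT−BT)/BT per metric) are adjusted by
regressing on the BT baseline and re-centering the residuals to the cohort
mean — removing the advantage of starting weak. The Gaussian mixture on the
adjusted 3-metric vectors uses diagonal covariances (12 participants cannot
support full covariances), 10 seeded restarts, and BIC over k = 1..4 with a
degeneracy guard: any fit owning a component with fewer than 2 members or a
collapsed variance is excluded from selection, because at n = 12 the
likelihood otherwise grows without bound as a component shrinks onto a
single point and BIC favours spurious extra components. Components are
ordered by mean overall change into moderate < intermediate < max (numeric
labels if k ≠ 3).

Trend classification is a deterministic rule on the 3-category mean profile
with tolerance tol = 0.25 of the profile range: linear requires strict
monotonicity with equal steps within tolerance; a plateau requires one
adjacent pair level within tolerance and the remaining step clearly outside.
A transparent rule replaces shape clustering so planted shapes give exact
truth. "Unimpaired" participants are excluded from self-assessment profiles
(no molecular response is expected of them); the retained ordinal sets are
(moderate, intermediate, max) and (improving, stagnating, worsening).

## Health awareness

Per (sample type × lifestyle component), a 2-component PLS-DA is fitted on
BT profiles with lifestyle categories one-hot encoded; categories with one
member are retained with a warning. AT profiles are projected through the
stored centering/scaling and rotations — an affine map, no refitting; the
linear-algebra identity P'R = I (loadings vs rotations) is used as the
projection oracle in tests. d_BT−AT is the 2D Euclidean distance between a
participant's BT and projected AT points. Kendall's W uses mean ranks for
ties and the tie-corrected denominator; χ² = m(n−1)W with df = n−1.

Health-awareness indicators are the features with map VIP ≥ 1. Indicators
are min–max normalized to [0, 1] against the cohort AT values (values
beyond the AT extremes clip). The healthy range per indicator is the
delete-1 jackknife mean ± t_{h−1,0.975}·SE over the h healthy-category
members, clipped to [0, 1] — mirroring the marker-discovery jackknife for
internal consistency. The similarity score is the package's concrete
definition: s_j = 1 inside the (inclusive) range, else
max(0, 1 − dist_j/r_j) with r_j = max(hi_j − lo_j, 0.05); the participant
score is Σ VIP_j s_j / Σ VIP_j. It is bounded in [0, 1], equals 1 iff every
indicator is in range, and is monotone in each indicator's distance to its
range. BT-vs-AT comparison uses one-sided paired t (AT > BT), with
zero-variance limits (constant positive difference → p → 0; no change →
p = 0.5), BH-adjusted across the nine cells. Robust regression of d_BT−AT
on the BT distance to the healthy centroid (in variate space) is Huber
M-estimation, tuning constant 1.345, IRLS to 1e-8, Wald test on the slope.

## The synthetic cohort

The generator emulates the statistical structure of the study design, not
its biology: 12 paired participants; 60/60/340 features per block; plasma
additionally carries 6 BT-only dropout participants so the three batches of
8/16/6 samples sum to the 30 plasma samples and unpaired handling is
exercised. Baseline log2 intensities are per-feature means uniform on
[14, 26], plus a participant offset (SD 0.3) shared between BT and AT, plus
Gaussian residual noise (SD 0.5; Student-t(4) available as a heavy-tail
switch). Planted markers (8/8/30 per block) receive a BT→AT shift of
`effect_size` (default 1.0 log2 units) with a random sign, scaled per
participant by his performance category through a planted trend shape
(linear increasing/decreasing, plateau-first-two, plateau-last-two, cycled
by default; a "constant" shape plants a flat shift for calibration
studies). Epigenetic blocks add cluster-correlated change shifts (3 planted
clusters, SD 0.8 per feature) — note these are *real* systematic responses,
so a well-calibrated selector may legitimately pick up strong
cluster-driven features beyond the planted marker list. PTM features come
in precursor groups of 2–5 co-measured modified forms.

Plasma batch effects are additive+multiplicative: batch centers are spread
by `batch_shift` (adjacent batches differ by one shift unit, small jitter)
and scale factors `batch_scale^z` with centered exponents; shift 0 and
scale 1 give the exact identity.

Left-censoring is modelled at the feature level, the way a detection limit
acts: features whose mean lies below the block censor quantile (default
0.15 of feature means) lose each cell with probability 0.95 (the rare
survivors are sporadic near-limit detections); MCAR masking (default 0.02)
then applies to the rest. The feature-level choice is deliberate: at 12
samples per condition, cell-level censoring places most censored cells in
partially censored conditions, which no 75%-rule classifier can label
correctly, whereas the below-detection-limit regime gives a censored
condition > 75% missingness with probability P(Bin(12, 0.95) ≥ 10) ≈ 0.98
— so mechanism recovery is achievable by construction, as in real
label-free data where censoring is driven by feature abundance.

What the generator does *not* emulate: peptide chemistry, retention times,
shared-peptide protein inference, correlated feature blocks beyond
precursor groups, non-Gaussian biological covariance, or longitudinal
drift. Passing tests therefore demonstrate the pipeline's statistical
behaviour under its own model assumptions, not performance on real spectra.

## Evaluation experiments and problem sizes

`pairedomics.evaluation` fixes the experiment designs reported by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`:
MAR calibration with 1000 draws; selector null calibration with 50 repeats
of 200 features × 12 pairs and power with 25 repeats of 20 planted markers
at d_z = 1.5; SNF recovery over 25 repeats of three planted 4-participant
clusters seen through two views with mutually orthogonal cluster centers
(pairwise distance 4√2, within-cluster noise 0.6, K = 3) in random
per-view orientations; batch recovery at 200 features with a 2-log2-unit
shift orthogonal to a planted condition effect; trend recovery over 400
profiles at per-participant noise 0.1·effect; and health-shift power over
100 repeats of a 0.2-fractional AT convergence toward the healthy centroid
at n = 12. These sizes keep the full evaluation under a minute on one CPU
while leaving the Monte-Carlo error well below each check's margin.

## Known limitations

- The jackknife CI assumes approximate normality of VIP pseudo-values;
  at n = 11–12 the coverage is nominal only to first order.
- ComBat assumes batch effects are location/scale per feature; interaction
  of batch with condition is not modelled (and not identifiable here).
- The eigengap heuristic for k is unstable when clusters are not well
  separated; the cluster count should be inspected against the eigenvalue
  diagnostics the function returns.
- Min–max normalization against cohort AT values makes healthy ranges
  sensitive to AT outliers; with n = 12 this is accepted for transparency
  rather than replaced by robust scaling.
- GMM-based categories at n = 12 are reliable only for well-separated
  response groups; the degeneracy guard prevents spurious components but
  cannot create resolution that is not in the data.
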