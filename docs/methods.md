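# Methods

This package re-implements, as a tested pipeline over synthetic cohorts, the
standard functional-brain-gradient analysis of parcellated resting-state fMRI:
per-subject functional connectivity, diffusion-map gradients aligned to a
healthy-control reference, multi-site harmonization, network differentiation
metrics, rank-based group inference with FDR control, and spin-permutation
association with receptor-density maps. No human data enters anywhere: a
generator plants known gradient geometry, site effects, group effects and
clinical readouts, so every downstream claim can be checked against ground
truth.

## The gradient model

Each subject contributes a timepoints-by-parcels matrix. Pearson correlations
between parcel time series, Fisher z-transformed (r clipped to ±(1−1e−7)),
give a symmetric FC matrix with zero diagonal. Each row is thresholded to its
k = ⌊density·(P−1)⌋ largest signed entries (default density 0.10; 0.20 as the
sensitivity setting; ties keep the lowest parcel id), and cosine similarity
between thresholded rows yields the affinity matrix W.

The diffusion-map embedding shifts W to be non-negative if needed (by |min|,
recorded in provenance), applies anisotropic normalization
W' = D^−α W D^−α with α = 0.5, row-normalizes to a Markov matrix, and
eigendecomposes via the symmetric conjugate. The trivial constant eigenvector
is dropped; the next n_components (default 10) eigenvectors, normalized
against the trivial one and scaled by the automatic-diffusion-time factor
λ/(1−λ), are the gradients. Column signs are fixed deterministically (largest
|entry| positive). Eigenvalue-ratio explained variance is reported per
component. A disconnected affinity graph (reducible chain) is an error —
the usual symptom of too aggressive thresholding.

The reference gradients come from the element-wise mean of the control
subjects' Fisher-z FC, pushed through the same path. Subjects are aligned to
the reference by orthogonal Procrustes (no scaling), which resolves sign
flips, component swaps and rotations; eigenvalues are left untouched because
the spectrum belongs to the subject's own embedding. Gradient *order* is taken
as computed; descriptive labels ("visual-to-sensorimotor",
"sensory-to-association") are assigned by a one-to-one matching of gradients
to network-indicator contrasts and are convenience output only.

## Harmonization

Site effects are removed with the parametric empirical-Bayes location/scale
model (ComBat): feature-wise linear fit of site plus preserved covariates
(group indicators, age, sex, mean framewise displacement), standardization,
Normal/Inverse-Gamma shrinkage of per-site location and scale via the standard
iterative conditional updates (convergence 1e−4), adjustment, and restoration
of the preserved effects. The implementation matches Bioconductor's
`sva::ComBat` to ~1e−13 RMS on a frozen fixture (tests/fixtures/). Group is
preserved in the design by default so real disease effects survive. Singleton
sites are an error (nothing can be estimated from one subject), mirroring the
practice of excluding sites too small to harmonize. Two model properties worth
knowing: (a) when features are exchangeable (identical variances and site
effects), EB shrinkage leaves a sampling-noise residual in per-feature site
differences — this is reference behaviour, not a bug; (b) harmonization is
only approximately idempotent, because a second pass re-shrinks residual
noise. Harmonization is applied after alignment, to the parcel-wise score
table of each gradient, and again to the derived-metric table (switchable).

## Differentiation metrics

With each parcel at (g1, g2): network means (arithmetic, per gradient),
gradient range (max − min per gradient), within-network dispersion (mean
Euclidean distance from the network's coordinate-wise median to all member
parcels; even counts use the midpoint of the central order statistics) and
between-network dispersion (distance between the medians of each unordered
network pair). A 7-network scheme yields 7 + 21 dispersion scores per subject.
The coordinate-wise median is used rather than the geometric median: it is
deterministic, cheap, and the convention of the dispersion methodology this
follows.

## Inference

Group contrasts (controls vs each patient group, and vs patients pooled) are
tested two ways: parcel-wise fixed-effects OLS t-maps of harmonized scores on
a group indicator with age, sex and mean FD as covariates (BH-FDR per
gradient × contrast); and Mann-Whitney U tests of confound-regressed network
means, ranges and dispersions (BH-FDR per metric family × contrast; families
are declared explicitly). The rank test uses midranks, exact enumeration of
all C(n, n_a) assignments when n ≤ 12 and the tie/continuity-corrected normal
approximation otherwise; the effect size is η² = Z²/N. Confound regression is
OLS with the grand mean added back. Explained-variance ratios are compared
across groups with a one-way F-test. Clinical scores are screened (subjects
with strictly more than 30% missing clinical entries are dropped), imputed
with group-wise medians, and correlated with metrics by Spearman rank
correlation (Pearson available), FDR over the full matrix.

## Spatial nulls

Map-map correlations are tested against spin permutations: a uniform random
rotation is applied to the left-hemisphere centroids and its x-mirrored
counterpart to the right, and each parcel takes the value of the nearest
rotated source within its hemisphere (duplicates allowed; a greedy one-to-one
variant is available). Two-sided p_spin = (1 + #{|r_null| ≥ |r_obs|})/(1 +
n_perm), so p is never 0. Receptor maps of the same receptor type are z-scored
across parcels and averaged before testing; the shipped receptor maps are
synthetic smooth stand-ins, not published PET data. Calibration: on
Gaussian-process null maps at the generator's spatial scale (lengthscale 0.5,
nugget 0.1, 100 parcels) the empirical type-I error at α = .05 is ~0.05–0.08.
Known limitation: for maps whose smoothness approaches the hemispheric scale
(few effective degrees of freedom), the nearest-neighbour parcellated spin
test becomes mildly anticonservative (~0.10 observed with ~9-dof polynomial
maps); conclusions about very smooth maps should lean on the one-to-one
variant or larger parcel counts.

## The synthetic cohort generator

The parcel scheme places quasi-uniform (Fibonacci) centroids on the left
unit hemisphere, mirrors them to the right, and assigns networks as contiguous
z-bands within each hemisphere (seven Yeo-style labels by default). Contiguity
matters: spin nulls are vacuous on spatially random labelings.

The planted geometry maps each hemisphere to a disk by a Lambert equal-area
projection about the (−1,0,0) pole (homotopic parcels coincide), giving
latent coordinates that are smooth over the sphere and uniformly dense in
latent space; gradient 1 follows z (scale 1.0), gradient 2 follows y (scale
0.8). Uniform latent density was chosen deliberately: with non-uniform
projections the embedding's leading eigenfunctions curve away from the
planted axes and the geometry is not identifiable to better than |r| ≈ 0.95
even noise-free. Group effects are applied in latent space — network mean
shifts (added last, so a configured shift is exact), per-network dispersion
scaling about the network mean, and global per-gradient range scaling.
Subject-level jitter (SD 0.05) is added per parcel.

Time series are i.i.d. Gaussian draws with covariance
K = amp·exp(−d²/2ℓ²) + nugget·I over latent distance d (ℓ = 0.5,
nugget = 0.05, amp = 1), 200 timepoints per subject — the
length of a typical ~10-minute acquisition at a 3-second repetition time. The
nugget bounds attainable correlations at amp/(amp+nugget) and guarantees a
positive-definite kernel (a failed Cholesky names the nugget). Site effects
are a multiplicative kernel-amplitude scale (acting through the nugget ratio)
plus an additive Fisher-z offset injected at the FC-edge level — the latter
is deliberately simple so ComBat's removal of it is verifiable. Cohort sizes
default to the study proportions (376/243/212/240) times a scale factor
(0.1 → 107 subjects); sites are balanced within group and cells of fewer than
two subjects are rejected. Clinical scores are noisy linear readouts of each
subject's planted metrics with missing-at-random holes; one score is pure
noise as a built-in null.

Default planted effect magnitudes (somatomotor +0.06 on g1 in all patient
groups; ventral-attention −0.06/−0.05 in the psychosis-spectrum groups;
dorsal/ventral-attention dispersion scales 0.55/0.40 and g1 range scale 0.95
in the depression group) were calibrated once so that each effect is
recoverable through the full nonlinear pipeline at the 107-subject smoke
scale. They are therefore much larger than the small effects (η² ≈ 0.01)
plausible at a thousand-subject scale; passing recovery tests shows the
pipeline ranks planted effects correctly, not that effects of realistic size
would be detectable at desk scale.

## What the generator does and does not emulate

It reproduces the statistical skeleton the pipeline must handle: planted
low-dimensional FC geometry, finite-sample correlation noise at 200
timepoints, additive/multiplicative scanner-site effects, group effects on
means and dispersion, covariates, missingness. It omits temporal
autocorrelation, head motion (mean FD is a covariate column only), ordinal
clinical scales, vertex-level data and real receptor maps. Two nonlinear
effects of the embedding are worth keeping in mind when reading results:
score units are arbitrary (the λ/(1−λ) scaling amplifies latent units
~15-fold at these settings, and overall orientation is only fixed up to the
reference), and global latent rescalings do not pass through monotonically —
a planted 5% range shrink can surface as a range *increase* of the embedded
scores because tighter geometry raises the leading eigenvalues. Rank-based
two-sided tests are unaffected by either, which is one reason they are the
right primary inference here.

## Problem sizes and numerical choices

Tests and the analysis scripts run at a deliberate smoke scale — 100 parcels,
~107 subjects, 500 spins, 20-replicate null calibrations — chosen so the full
battery, including 21 pipeline runs for the end-to-end checks, completes in a
few minutes on one core while keeping every statistical check meaningful at
its stated tolerance. Full-scale settings (1000 parcels, 10 000 spins) are
plain config changes. Degenerate inputs fail loudly and name the offending
unit: zero-variance parcels, all-zero thresholded rows, disconnected affinity
graphs, singleton sites, rank-deficient designs, constant maps. Convergence
and comparison tolerances are stated at each test; the ComBat iterative
updates stop at a relative change of 1e−4, matching the reference.
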