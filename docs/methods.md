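# Methods

This note documents the models, numerical choices and known limitations of
`connectopath`. It covers the synthetic-data generator, the connectopic
mapping stack, the connectivity and statistics layers, and the mediation
machinery, in that order.

## Synthetic cohorts

The generator produces everything the analyses consume: a triangulated ROI
mesh with a canonical axis coordinate in [0, 1], per-subject ROI and
reference time-series, parcel time-series, nuisance covariates, and symptom
scores. Its defaults are the study conditions under which the package is
validated.

**Gradient-structured ROI series.** `n_sources` (default 5) unit-variance
Gaussian latent signals occupy the first columns of the reference block
(default 60 channels; the rest are white noise). Vertex v mixes the first
two latents as (1−g(v))·s₁ + g(v)·s₂ with g equal to the mesh axis
coordinate, plus Gaussian noise of standard deviation 1/snr (default
snr = 3; the mixture's variance lies in [0.5, 1], so snr is of the order of
the amplitude signal-to-noise ratio). In the case group g is warped away
from the midpoint inside `shift_region` (default [0.6, 1.0]) by factor
1 + `group_shift` (default 1.5), emulating an excessively segregated
gradient. Latent signals are white by default; an AR(1) option exists
(φ configurable, default 0) because all downstream statistics operate on
correlations, not spectra.

**Parcel series.** 24 parcels in three strata: 7 sensory/motor (two motor
and two somatosensory subdivisions, central and peripheral visual, one
auditory), 4 subcortical (thalamus, caudate, pallidum, putamen), and 13
transmodal parcels grouped into six networks with hierarchy ranks 1–6
(dorsal attention → ventral attention → salience → frontoparietal control →
default mode → limbic). Rows are drawn from a zero-mean multivariate normal
with a group-specific correlation matrix: controls have homogeneous blocks
(within-sensory r = 0.45, sensory–subcortical 0.10, within-subcortical 0.35,
within-network transmodal 0.55, between-network 0.25, background 0.12);
cases lower the within-sensory block by 0.10, raise the sensory–subcortical
block by 0.10, and lower transmodal correlations by 0.015 per mean hierarchy
rank — so the proportion of hypoconnected edges rises along the hierarchy.
Both matrices are checked to be positive semidefinite at construction.

**Mediation path.** Each case subject draws a latent predictor
X ~ N(0, 1) (truncated at ±2.5) that shifts the within-sensory block on the
Fisher-z scale (z → z + 0.4·X); the mediator M = a·X + ε_M shifts the
within-transmodal block the same way; the latent outcome
Y = c′·X + b·M + ε_Y maps onto the ADOS scale as total = 12.7 + 3.68·Y
(clipped at 0), split into social and communication parts in the 8.40:4.25
ratio so the classic total equals their sum exactly; the
restricted/repetitive-behavior score is an independent draw (mean 2.02,
SD 1.50). Defaults a = 0.51, b = −0.62, c′ = 0 encode a complete-mediation
pattern; residual SDs make M and Y unit-variance. The z-shift slope 0.4
makes measured block-mean connectivity effectively affine in X and M — with
~20–80 edges averaged per block, measurement attenuation of the standardized
paths is negligible at T = 200.

Covariates: age ~ uniform(8, 40) years, framewise displacement ~
half-normal(σ = 0.1) mm, three synthetic sites assigned cyclically, each
adding 0.1·(site index) to the time-series mean. These mimic the ranges of
a typical multi-site pediatric/adult cohort without claiming its exact
distributions. Ground truth (the warped axis, X, M) lives in a sidecar
table read only by tests.

What the generator does **not** emulate: hemodynamic response shapes,
motion artifacts, scanner drift and multiband sequence effects, per-site
sampling-rate differences (a single nominal rate is used), and spatial
autocorrelation beyond mesh adjacency. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under a clean generative
model, not robustness to real acquisition artifacts.

## Connectopic mapping

* **SVD reduction** keeps every component with singular value above
  `max(T, V)·eps·s₁`, so the centered reference is reconstructed exactly;
  constant columns are dropped with a warning (detected by zero
  peak-to-peak range, which is robust to floating-point representation of
  constants).
* **η² similarity** uses the paired-profile form given in the README. It is
  provably in [0, 1], symmetric, and equals 1 exactly iff the two
  fingerprints are identical (the degenerate equal-constant pair, where the
  denominator vanishes, is defined as 1). The vectorized evaluation is
  locked against an unvectorized double-loop oracle at 1e−10.
* **Laplacian eigenmaps** default to the random-walk (generalized) problem
  L v = λ D v with W the η² matrix (diagonal zeroed) and D the degree
  matrix; the unnormalized form is available for testing. The graph must be
  connected (component sizes are reported otherwise); an optional ε
  threshold sparsifies W but aborts if it disconnects the graph — with
  η² ≥ 0 the default graph is nearly complete, so no sparsification is
  applied. Eigenvectors come from a dense symmetric solver; the trivial
  constant mode (λ ≈ 0) is discarded and the k smallest nontrivial modes
  (default k = 3, the first analyzed) are returned with ascending
  eigenvalues. Sign convention: each column is oriented to correlate
  nonnegatively with the mesh axis when one is supplied, otherwise the
  entry of largest magnitude is made positive; after template alignment the
  template's orientation wins.
* **Template and alignment.** The group template is the eigenmap of the
  element-wise mean of control-group similarity matrices; per-entry values
  are sorted before summation so the template is bitwise invariant to
  subject order. Subject maps are aligned by single-pass orthogonal
  Procrustes (rotation/reflection across gradient columns) to the fixed
  template — with a fixed source this single pass is the exact minimizer,
  so no iterative refinement is needed. Fingerprints are computed against
  the reduced components rather than reconstructed full maps; a consistency
  test bounds the consequence (first gradients agree at |Spearman ρ| ≥ 0.99).
* Zero-variance ROI vertices are removed before mapping and reinserted as
  NaN rows in all outputs.

## Connectivity (iFC)

Parcel series are unweighted means over member vertices (the vertex count
per parcel is small and no area weights exist for synthetic meshes; an
area-weighted variant would slot in at the same place). Pairwise Pearson
correlations are Fisher r-to-z transformed; the diagonal is masked, never
transformed. An off-diagonal |r| ≥ 1 − 1e−12 signals duplicated parcels and
raises unless explicitly clipped. Global-signal regression projects every
column on (intercept, spatial-mean series); residuals are exactly orthogonal
to the global mean and the operation is idempotent.

The altered-connectivity proportion for a network is 100 × (unique
significant edges of the requested sign incident to any parcel of the
network) / (unique edges incident to the network). The incident-edge scope
is the default because a single value per network is wanted for hierarchy
trend plots; a within-network-only scope is available. The output carries
each network's hierarchy rank so the hypoconnectivity trend along the
sensory-to-transmodal axis can be read directly.

## Group statistics

Element-wise OLS with a named design matrix (intercept, binary group, age,
framewise displacement, site dummies with the alphabetically first site as
reference, optional sex, optional centered-age × group). Rank deficiency is
reported with the offending column names. The contrast t uses the residual
degrees of freedom; all p-values are two-tailed. Cohen's d for the group
contrast is t·√(1/n₁+1/n₂) — the covariate-adjusted form, chosen because it
reduces to the classical definition in the unadjusted two-group case.

**Cluster inference.** Vertex-wise tests are corrected by permutation of
the maximum supra-threshold cluster mass. Vertices with two-tailed p below
the cluster-defining threshold (default 0.025) form sign-consistent,
mesh-connected components scored by Σ|t|. The null permutes residuals of
the nuisance-only model and adds back the nuisance fit (Freedman–Lane), so
covariate structure is preserved; cluster p_FWE is the add-one proportion
of null maxima at or above the observed mass. This permutation scheme
replaces random-field theory: RFT needs smoothness estimation on real
surfaces and has no exactness guarantee on coarse synthetic meshes, whereas
the permutation test is distribution-free and its family-wise error is
directly measurable (calibrated to [0.03, 0.07] at α = 0.05 in the
acceptance suite). Internally the permutation loop is batched: contrast
t-maps for a block of permutations are computed with one einsum, and
connected components for all permutations at once by min-label propagation
over the shared edge list.

Edge-wise (connectivity) tests use Benjamini–Hochberg FDR at q = 0.05
(delegated to statsmodels and locked against an exhaustive step-up oracle).
The age-by-group interaction is a partial F-test of the centered-age × group
column, F(1, df) = t². Brain–behavior partial correlations residualize both
variables on (intercept + covariates) with df = N − #covariates − 2, and are
run within the case group only, where symptom scores exist.

## Mediation

Variables are z-scored, so a, b, c, c′ are standardized slopes; covariates
(age, site, FD) enter all three regressions by default — the package treats
them the same way the group models do. Point estimates come from OLS;
a, b, c, c′ carry parametric t-based p-values, while the indirect effect
a·b is tested by a case-resampling percentile bootstrap (default 100,000
draws; tests use 2,000) with two-tailed p = 2·min(P(ab* ≤ 0), P(ab* ≥ 0))
under the add-one correction. The percentile interval is the default (BCa
was considered and not implemented; percentile intervals are what the
calibration targets were set for, and their coverage measures ≥ 93% at
n = 200). For nested linear models with identical covariates a·b = c − c′
holds to machine precision and is asserted on every fit. The bootstrap inner
loop solves the two normal-equation systems for all resamples in one batched
`np.linalg.solve`, which is what makes 500-simulation calibration runs
cheap.

**Predictor/mediator construction.** The pipeline averages the Fisher-z
values of within-sensory (predictor) and within-transmodal (mediator) edges
pre-selected by nominal partial association with the outcome. Selecting and
fitting on the same subjects is circular by construction — the selection
inflates the apparent X–Y and M–Y associations; a split-half variant
(select on one half, fit on the other) is available behind a flag, and
users drawing scientific conclusions should prefer it. The forward model is
accompanied by a reversed variant (mediator and predictor swapped) and a
subcortical-predictor variant; within each variant the four outcome
p-values for a·b are FDR corrected.

A sensitivity harness re-runs the forward mediation after global-signal
regression. Strictly, GSR redistributes the shared variance that carries
part of the generative path, so reject/accept decisions are only guaranteed
stable when the test is well powered; at the validated cohort size
(107 cases) no decision flips across 50 seeds.

## Pipeline

Stages run in the fixed order simulate → gradient → ifc → stats → mediate.
The master seed fans out through `numpy.random.SeedSequence(master,
spawn_key=(stage_index,))`, so each stage owns an independent, re-runnable
stream and the full bundle is bit-reproducible under an identical config.
Every stage writes a provenance record (parameters, seed, SHA-256 of its
phenotype input, output list, package version). Configs are YAML/JSON with
a closed schema: unknown keys, unknown stage parameters and out-of-order
stages are rejected before any stage runs.

## Problem sizes used in validation

The test and acceptance suites validate at desk scale: 20-subject cohorts
with 100-vertex meshes and T = 200 for end-to-end gradient recovery;
n = 200 triads with 2,000 bootstrap draws across 500 (null) and 200
(recovery) simulations for mediation calibration; 1,000 null datasets with
500 permutations on a 50-vertex mesh for cluster-FWE calibration; T = 2,000
for covariance recovery. These sizes give Monte-Carlo error well inside the
asserted bounds while keeping the whole suite to a couple of minutes.

## Known limitations

* Volumetric (non-surface) connectopic mapping and geodesic statistics
  beyond mesh adjacency are out of scope.
* Dynamic (time-varying) and partial-correlation connectivity are not
  implemented.
* Mediation results are associational; no causal ordering is established by
  the model, and the default edge selection is circular (see above).
* The ADOS score model is a linear map of a Gaussian latent; real scores
  are discrete, bounded and skewed.
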