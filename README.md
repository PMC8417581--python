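# connectopath

Connectopic gradient mapping, stratified functional connectivity, and
bootstrap mediation for resting-state fMRI cohorts — exercised end-to-end on
synthetic cohorts with known ground truth.

## The scientific problem

Autism research increasingly points at an interplay between *low-level*
sensory/motor anomalies and *high-order* (transmodal) cognitive symptoms:
atypical functional organization of primary cortices may cascade into the
association networks that support social interaction, and from there into
symptom severity. Testing that idea requires three pieces of machinery that
this package implements as a reusable, fully tested pipeline:

1. **Connectopic mapping** of a region of interest. The reference
   (rest-of-cortex) time-series is losslessly reduced by SVD; each ROI
   vertex's *connectivity fingerprint* (Pearson correlations with the
   retained components) is compared to every other vertex's with the
   η² similarity coefficient

   η²(a, b) = 1 − Σᵢ[(aᵢ−mᵢ)² + (bᵢ−mᵢ)²] / Σᵢ[(aᵢ−M̄)² + (bᵢ−M̄)²],
   mᵢ = (aᵢ+bᵢ)/2, M̄ = mean(m),

   and Laplacian eigenmaps of the similarity graph (generalized problem
   L v = λ D v, eigenvalues ascending, trivial mode discarded) yield the
   connectopic gradients. Per-subject maps are aligned to a control-group
   template by orthogonal Procrustes rotation.
2. **Stratified seed-based iFC**: parcel-mean time-series correlations,
   Fisher r-to-z transformed, for a sensory/motor + subcortical matrix and a
   high-order transmodal matrix; optional global-signal regression; a
   per-network *altered-connectivity proportion* that traces dysconnectivity
   along the cortical hierarchy.
3. **Group statistics and mediation**: element-wise OLS with nuisance
   covariates (age, site, head motion), permutation cluster FWE correction
   (Freedman–Lane shuffling of maximum cluster mass), Benjamini–Hochberg
   FDR, age-by-group interaction F-tests, partial correlations, and
   product-of-coefficients mediation X → M → Y with a = slope(M~X),
   b = slope(Y~M | X), indirect effect a·b = c − c′, tested with a
   case-resampling percentile bootstrap.

Real imaging inputs (time-series tables, meshes, parcellations) can be
ingested from plain-text formats, but nothing here requires them: the
`synthetic` module generates cohorts whose gradients, connectivity blocks
and mediation paths are known exactly, so every stage is validated against
ground truth.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import connectopath as cp

mesh = cp.make_mesh(50, 2)                      # 100-vertex strip, known axis
spec = cp.GradientSpec(snr=3.0)
roi, ref = cp.simulate_subject_timeseries(mesh, spec, "control", T=200, seed=0)

mapper = cp.ConnectopicMapping(n_gradients=3).fit(roi, ref, orient=mesh.axis_coordinate)
rho = spearmanr(mapper.gradients_[:, 0], mesh.axis_coordinate).statistic
print(f"first-gradient eigenvalues: {np.round(mapper.eigenvalues_, 3)}")
print(f"Spearman rho vs ground-truth axis: {rho:.3f}")

rng = np.random.default_rng(1)
x = rng.standard_normal(200)                    # low-level iFC summary
m = 0.5 * x + np.sqrt(0.75) * rng.standard_normal(200)   # high-order iFC
y = 0.5 * m + np.sqrt(0.75) * rng.standard_normal(200)   # symptom score
res = cp.mediation_bootstrap(x, m, y, n_boot=2000, seed=2)
print(f"a={res.a:.3f} b={res.b:.3f} ab={res.ab:.3f} "
      f"CI=({res.ci_ab[0]:.3f}, {res.ci_ab[1]:.3f}) p={res.p_ab:.4f}")

t, df, p = cp.two_sample_t_from_summary(12.1, 5.89, 57, 16.5, 8.21, 59)
print(f"replication age contrast: t={t:.2f}, df={df}, p={p:.4f}")
```

Output:

```
first-gradient eigenvalues: [0.892 1.009 1.01 ]
Spearman rho vs ground-truth axis: 0.998
a=0.538 b=0.265 ab=0.143 CI=(0.063, 0.220) p=0.0020
replication age contrast: t=-3.31, df=114, p=0.0013
```

The eigenvalues are ascending and the first (dominant) gradient recovers the
latent spatial axis almost perfectly. The mediation fit recovers a positive
indirect effect whose bootstrap interval excludes zero, and the
summary-statistics t-test reproduces a two-cohort age contrast of |t| ≈ 3.3.

## Full pipeline

The `connectopath` console script chains
simulate → gradient → ifc → stats → mediate from one YAML config
(see `examples/minimal.yaml`):

```sh
connectopath run --config examples/minimal.yaml --out out_dir --seed 7
```

Each stage writes TSV outputs plus a JSON provenance record (parameters,
seed, input hashes, package version); re-running with the same config and
master seed reproduces the bundle bit for bit.

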