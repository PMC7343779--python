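# cortexdti

Profile-based cortical grey-matter diffusion MRI analysis: columnar
cortical profiles, radiality metrics (AngleR, PerpPD, ParlPD), standard
tensor scalars (MD, FA), the accompanying group statistics, and a
PCA-filter + classifier-selection machine-learning protocol for binary
and multiclass diagnostic classification of dementia subtypes.

## The problem

The cerebral cortex is organised in radial minicolumns. Neurodegeneration
— notably in fronto-temporal dementia (FTD) and its subtypes (behavioural
variant bvFTD, semantic variant svPPA, non-fluent variant nfvPPA) —
disrupts this columnar cytoarchitecture before gross atrophy is obvious.
In diffusion tensor imaging the disruption shows up as a loss of radial
coherence of water diffusion within the grey-matter ribbon. This package
computes, per subject and per cortical region, metrics that quantify that
coherence, and wraps them in the statistical and machine-learning
analyses a subtype-discrimination study needs. It is aimed at
neuroimaging researchers who have tensor fields (or raw DWI) and a
ribbon/parcellation segmentation, and want reproducible, testable
cortical-microstructure features.

## The model

Per voxel the diffusion tensor `D` (fitted from
`ln S_i = ln S0 − b_i ĝ_iᵀ D ĝ_i` by OLS or signal²-weighted WLS) has
eigensystem `λ1 ≥ λ2 ≥ λ3` with principal direction `ê1`. A scalar
potential `u` solves Laplace's equation on the grey-matter ribbon with
`u = 0` on the white-matter boundary and `u = 1` on the pial boundary;
streamlines of `∇u` — *cortical profiles* — run from the white boundary
to the pial surface with unit tangents `p̂`. At each sampled voxel:

- `AngleR = arccos |ê1 · p̂|` ∈ [0, π/2] — small when diffusion is
  column-aligned;
- `PerpPD = λ1 sin(AngleR)`, `ParlPD = λ1 cos(AngleR)` — the principal
  diffusion component split perpendicular/parallel to the profile,
  reported in 10⁻³ mm²/s (so `PerpPD² + ParlPD² = λ1²`);
- `MD = (λ1+λ2+λ3)/3` and the standard `FA`.

Metrics are averaged along each profile, then pooled into 68
Desikan-Killiany regional means and a whole-brain mean. Group analyses
use a multivariate GLM (Wilks' Λ with Rao's F) with age, head-movement
and scanner covariates, one-way ANOVA with Fisher-LSD post-hocs, and
Benjamini–Hochberg FDR correction. Classification follows a three-cohort
protocol: PCA loading-based feature filtering and best-of-seven model
selection (KNN, SVM, elastic-net logistic, logistic regression, random
forest, Gaussian naive Bayes, LDA) by majority vote over repeated
stratified ten-fold cross-validation on a selection cohort, training on a
training cohort, and reporting confusion matrices and
accuracy/sensitivity/specificity/PPV/NPV on a held-out test cohort.

A `synthetic_data` module generates every input at desk scale: slab and
spherical-shell ribbon phantoms whose principal directions deviate from
the surface normal by a controlled angle θ\* with angular noise σ,
forward-simulated DWI with Rician noise, realignment series, and
three-cohort regional feature tables with subtype-specific regional
elevations.

## Worked example

A slab phantom with principal directions tilted exactly 30° from the
surface normal, traced and sampled end to end:

```python
import numpy as np
from cortexdti import synthetic_data as sd, cortical_profiles as cp

spec = sd.PhantomSpec(geometry="slab", theta_deg=30.0, sigma_deg=0.0, seed=1)
ribbon, tensors, truth = sd.make_phantom(spec)
potential = cp.solve_ribbon_potential(ribbon)
profiles, dropped = cp.trace_profiles(potential, ribbon, step_h=0.5)
metrics = [cp.sample_profile_metrics(p, tensors) for p in profiles]
table = cp.aggregate_regions(metrics, ribbon.region_map)
print(table.round(4))
print(f"whole-brain AngleR: {np.rad2deg(table.loc['whole_brain', 'AngleR']):.2f} degrees")
```

prints

```
               AngleR  PerpPD  ParlPD   MD      FA  n_profiles
region
phantom_left   0.5236     0.6  1.0392  0.7  0.5551         288
phantom_right  0.5236     0.6  1.0392  0.7  0.5551         288
whole_brain    0.5236     0.6  1.0392  0.7  0.5551         576
whole-brain AngleR: 30.00 degrees
```

`AngleR` recovers the generating tilt (0.5236 rad = 30°); with
eigenvalues (1.2, 0.5, 0.4)×10⁻³ mm²/s the projections are
`PerpPD = 1.2 sin 30° = 0.6` and `ParlPD = 1.2 cos 30° = 1.039` (×10⁻³
mm²/s), `MD = 0.7` and `FA = 0.555` follow from the eigenvalues, and 576
profiles were traced (one per white-boundary voxel, 288 per synthetic
hemisphere).

The same stages are exposed on the command line
(`cortexdti simulate phantom`, `fit-tensor`, `profiles`, `covariates`,
`classify binary|multiclass`, `run-all`); `run-all` writes a manifest
with a config hash and per-output hashes so a run can be reproduced
bit-identically.

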