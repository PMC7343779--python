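# Methods

## Tensor fitting

The monoexponential tensor model is fitted per voxel in log space:
`ln S_i = ln S0 − b_i ĝ_iᵀ D ĝ_i`, a linear model in `ln S0` and the six
unique tensor components (stored in lower-triangular order Dxx, Dxy,
Dyy, Dxz, Dyz, Dzz). Ordinary least squares is the default; weighted
least squares with per-volume weights `S_i²` (the first-order variance
correction for log-transformed magnitudes) is available, and the two
agree to machine precision on noise-free data. Signals are floored at
`1e-6 × S0` before the log so zeros cannot produce −inf without biasing
well-conditioned voxels. Baselines are volumes with `b < 50 s/mm²`
(vendor rounding tolerance); a fit requires at least one baseline and a
gradient set spanning all six tensor components (checked by the rank of
the design matrix). Voxels whose fitted tensor has a negative smallest
eigenvalue are flagged degenerate and excluded from profile sampling
rather than clamped — clamping would fabricate anisotropy where the data
support none.

Eigenvalues are sorted descending; eigenvector sign is fixed by
orienting each vector to have a non-negative dot product with +x (then
+y, then +z when earlier components vanish). When `λ1 − λ2 <
1e-12·λ1` the principal direction is flagged non-unique. FA is clipped
to [0, 1]; the all-zero tensor returns a configurable sentinel (NaN by
default) instead of raising.

## Cortical profiles

The columnar trajectories are realised as Laplace-potential streamlines:
the potential solves `∇²u = 0` on the grey-matter ribbon with Dirichlet
values 0 on inside-white voxels and 1 on outside-pial voxels, by Jacobi
iteration to a maximum update of 1e-6 (configurable). Grey matter is
partitioned into 6-connected components; a component disconnected from
either boundary is excluded as unreachable (an error in strict mode when
more than 5% of the ribbon is unreachable). On a flat slab the discrete
solution is linear across the ribbon; on a spherical shell it matches
`(1/r0 − 1/r)/(1/r0 − 1/r1)` to within ~1.7% at mid-shell at the grid
resolutions used in the tests — the residual is pure discretisation
error of the stair-stepped boundary.

Streamlines are seeded one per grey-matter voxel adjacent to the white
boundary and integrated with fixed Euler steps of h = 0.5 mm (default)
along the normalised world-space gradient, with trilinear interpolation.
The gradient field itself is a Gaussian-derivative estimate (σ = 1
voxel) of the nearest-filled potential: raw central differences on a
voxelised curved boundary imprint stair-step noise on the tangents,
which the derivative-of-Gaussian filter suppresses (on a slab, where the
field is exactly linear, the two estimators coincide). Undefined-gradient
voxels are filled from their nearest defined neighbour so interpolation
never mixes NaNs. Tracing stops on reaching a pial-labelled voxel or a
potential of ~1; profiles shorter than two steps, stopped by a vanishing
gradient, or exceeding a 20 mm length cap are dropped and counted in a
log. Each profile inherits the majority region code of the grey-matter
voxels it traverses, ties broken toward the seed's region.

Tensor lookup along a profile is nearest-voxel by default; trilinear
component interpolation is available behind a flag but is not the
default because interpolating across the GM/WM boundary can fabricate
orientations. AngleR uses `arccos` of the clamped absolute dot product,
which removes the eigenvector sign ambiguity. Samples whose principal
direction is numerically degenerate (`λ1 − λ2 < 1e-6·λ1`) are excluded
from the AngleR mean and, because they derive from the same angle, from
the PerpPD/ParlPD means too; MD and FA keep all non-degenerate samples.
PerpPD, ParlPD and MD are reported in 10⁻³ mm²/s; AngleR is radians
internally with a degrees flag at the CLI.

Regional values are unweighted means over the region's per-profile
means; the whole-brain value averages over profiles by default (an
averaging-over-region-means mode exists behind a flag, since either
reading of "average all cortical values" is defensible). Regions with no
profiles carry NaN with a zero profile count — never a silent zero.

## Covariates

The head-movement displacement index is the mean absolute
volume-to-volume difference over all six realignment parameters, with
rotations converted to arc length on a 50 mm sphere before pooling so
the average is dimensionally coherent (raw pooling and translations-only
variants are available, as the pooling convention of in-house motion
indices varies between labs). Structure volumes are divided by total
intracranial volume exactly; fractions above 1 trigger a plausibility
warning rather than an error.

## Group statistics

The multivariate GLM partials covariates (continuous, or categorical
such as scanner, dummy-coded against a first-level reference) and tests
the diagnosis effect via Wilks' Λ with Rao's F approximation, reporting
the (df1, df2) pair of the F statistic; per-outcome F tests come from
the extra sum of squares of the group dummies in the same linear model.
In the two-group, no-covariate case this reduces exactly to Hotelling's
T², and with one outcome the per-outcome F equals the squared pooled
t — both identities are exercised as oracle tests, alongside agreement
with statsmodels' MANOVA. Rank-deficient designs raise an error naming
the collinear columns.

Post-hoc pairwise comparisons are Fisher-LSD style: t statistics using
the omnibus ANOVA's pooled within-group variance with N − k error
degrees of freedom, returned raw so the caller can pool an entire
family (e.g. 11 regions × 6 group pairs = 66 tests) into one
Benjamini–Hochberg FDR correction. BH (not Benjamini–Yekutieli) is used
throughout — it is what "FDR < 0.05" conventionally denotes. The
step-up adjustment is implemented directly (sort, `p·m/i`, running
minimum) and verified against a brute-force double loop and statsmodels.

## Classification protocol

Three disjoint cohorts: selection (feature filtering + model choice),
training (final fit), test (reported performance). The PCA filter
z-scores features, eigendecomposes the correlation matrix, retains
components by the Kaiser rule (eigenvalue > 1; a fixed component count
is available), and selects any feature with |loading| ≥ 0.5 on a
retained component, preserving input order; constant features are
dropped with a warning and an empty selection falls back to the single
strongest-loading feature. Model selection scores seven classifiers —
KNN (k = 5, Euclidean on z-scored features), RBF-kernel SVM, elastic-net
logistic regression (l1 ratio 0.5), plain logistic regression, random
forest (100 trees), Gaussian naive Bayes, and LDA — by mean held-out
accuracy over stratified ten-fold cross-validation, re-shuffled each run
with a seed derived from the master seed plus run index; the winner of
each run is tallied and ties go to the earlier model in that fixed
listing order. KNN's k, the SVM kernel and the elastic-net mix are
package defaults (the protocol itself does not prescribe them). All
scaling statistics are learned on training folds/cohorts only.

Confusion matrices use rows = predicted, columns = true, fixed class
order HS, svPPA, bvFTD, nfvPPA. Because published tables are not always
explicit about which axis they normalise, `confusion_metrics` emits both
conventions, explicitly labelled: sensitivity/recall (column-normalised
diagonal) with `fdr_col = 100 − sensitivity`, and ppv/precision
(row-normalised diagonal) with `fdr_row = 100 − ppv`. Zero rows or
columns mark the affected metrics as undefined (`None`) rather than
propagating NaN. For 2×2 tables a declared positive class yields the
ACC/SENS/SPEC/PPV/NPV summary.

## Synthetic data: what it emulates and what it does not

Phantoms place a grey-matter ribbon (flat slab or spherical shell, two
synthetic "hemisphere" regions) with principal directions equal to the
local surface normal tilted by θ\* about a random in-tangent-plane axis
and perturbed by N(0, σ) rotations about a random perpendicular axis.
Angular noise biases the mean measured angle upward (at θ\* = 0 the mean
is σ√(2/π)); `expected_angle` computes the exact expectation of the
noise model by Monte Carlo, and recovery tests compare against that
reference rather than pretending the bias away. DWI simulation uses the
monoexponential signal with Rician magnitude noise (Gaussian noise in
both quadrature channels), the physically correct model for magnitude
MR data.

Cohort tables draw regional AngleR as baseline (0.70 rad) + a shared
per-subject offset (SD 0.015, inducing realistic cross-region
correlation) + group elevation + N(0, 0.05) regional noise. Default
elevations (0.08 rad in subtype marker regions, 0.06 rad bilateral
precentral in all patient groups, plus a 0.03 rad diffuse patient-wide
shift) correspond to marker-region effect sizes of d ≈ 1.3–1.5 — the
scale implied by strongly significant group differences at n ≈ 30 per
group — and place the markers where each subtype characteristically
degenerates (svPPA: left fusiform/entorhinal, right temporal
pole/inferior temporal; bvFTD: left caudal anterior cingulate, right
lingual; nfvPPA: left pars opercularis). Cohort sizes default to the
three-cohort design (selection 30 + 10/10/10, training 30 + 5/13/6, test
24 + 15/18/9). Clinical covariates (MMSE, CDR, grey-matter fraction,
age, education, head movement, scanner) follow typical
presenile-dementia demographics with Gaussian noise — the minimal
assumption consistent with t/F testing.

What the generators do **not** emulate: folded cortical geometry,
partial-volume and susceptibility effects, non-Gaussian feature
distributions, scanner-specific b-value differences, and any coupling
between the imaging phantoms and the cohort feature tables (the
feature tables are drawn directly, not pushed through the imaging
chain). Passing tests therefore demonstrate correctness of the
computational machinery and calibration of the statistics under the
stated models — not clinical-level classification accuracy on real
scans, which depends on data this package does not ship.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen so each check
is statistically meaningful: slab phantoms of 26×26×16 voxels (676
profiles, above the 500-profile threshold the recovery bound assumes),
a 44³ shell, 100-tensor fitting round trips, 1,000 random p-vectors for
the BH oracle, 500-replicate null simulations for the FDR family,
200-replicate label permutations, and 20–25 repeated CV runs where the
full protocol specifies 1,000 (win-share and determinism are unaffected
by the count; `n_runs` remains a parameter). Solver tolerance 1e-6
(max update), step h = 0.5 mm, gradient smoothing σ = 1 voxel, KNN
k = 5 — all configurable. Whole-brain recovery on noisy phantoms is
accurate to well under 1° against the noise-model expectation; the
dominant systematic on curved geometry is boundary discretisation,
shrinking with resolution.

## Known limitations

- The Laplace solver is a plain Jacobi iteration: robust and easily
  verified, but not the fastest choice for large high-resolution
  ribbons (a multigrid or direct sparse solve would be).
- Euler integration with h = 0.5 mm is adequate for ribbon-scale
  trajectories but accumulates curvature error on strongly folded
  geometry; profiles are capped at 20 mm as a safety net.
- Nearest-voxel tensor lookup quantises the sampled field; the
  trilinear option trades that for boundary mixing.
- The elastic-net classifier uses a fixed regularisation strength; no
  hyperparameter search is performed anywhere, by design.
- Binary and multiclass feature sets follow the declared protocol; the
  package does not attempt to reproduce real-cohort accuracy figures,
  which require restricted clinical data.
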