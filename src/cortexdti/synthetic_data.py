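"""Synthetic inputs for every pipeline stage, at desk scale.

Three generators stand in for clinical data:

* ribbon phantoms (flat slab or spherical shell) whose per-voxel principal
  diffusion direction is the local surface normal rotated by a controlled
  angle ``theta`` and perturbed by angular noise ``sigma`` — the ground
  truth against which profile metrics are validated;
* forward-simulated DWI signal sets (monoexponential tensor signal decay
  with Rician magnitude noise) to exercise tensor fitting;
* multi-cohort regional feature tables emulating a four-group study
  (healthy subjects and three fronto-temporal dementia subtypes) with
  group-specific regional AngleR elevations placed in the regions each
  subtype characteristically damages, plus demographic/clinical
  covariates.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from cortexdti import regions as regions_mod
from cortexdti.cortical_profiles import RibbonLabels
from cortexdti.covariates import RealignmentSeries
from cortexdti.errors import ParameterError
from cortexdti.tensor_fit import DwiSet, TensorField, matrices_to_components

#: synthetic phantom "regions" (hemisphere split of the shell/slab)
PHANTOM_REGION_MAP = {11: "phantom_left", 12: "phantom_right"}


@dataclasses.dataclass
class PhantomSpec:
    """Recipe for a ribbon phantom with controlled tensor orientation.

    geometry    : "slab" or "shell"
    shape       : voxel grid (nx, ny, nz)
    voxel_size  : isotropic edge length, mm
    thickness   : slab ribbon thickness in voxels (slab only)
    inner_radius, outer_radius : shell boundaries in mm (shell only)
    evals       : (lambda1, lambda2, lambda3) in mm^2/s, descending
    theta_deg   : radial-deviation angle of the principal direction
    sigma_deg   : angular noise SD about the deviated direction
    seed        : RNG seed
    """

    geometry: str = "slab"
    shape: tuple[int, int, int] = (24, 24, 16)
    voxel_size: float = 1.0
    thickness: int = 6
    inner_radius: float = 8.0
    outer_radius: float = 14.0
    evals: tuple[float, float, float] = (1.2e-3, 0.5e-3, 0.4e-3)
    theta_deg: float = 0.0
    sigma_deg: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.geometry not in ("slab", "shell"):
            raise ParameterError(f"unknown geometry {self.geometry!r}")
        l1, l2, l3 = self.evals
        if not (l1 >= l2 >= l3 > 0):
            raise ParameterError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if not 0.0 <= self.theta_deg <= 90.0:
            raise ParameterError("theta_deg must lie in [0, 90]")
        if self.sigma_deg < 0:
            raise ParameterError("sigma_deg must be non-negative")
        if self.geometry == "shell" and not self.outer_radius > self.inner_radius > 0:
            raise ParameterError("shell radii must satisfy outer > inner > 0")
        if self.geometry == "slab" and self.thickness < 3:
            raise ParameterError("slab ribbon must be at least 3 voxels thick")


def _random_tangent(rng: np.random.Generator, n: np.ndarray) -> np.ndarray:
    """A uniformly random unit vector perpendicular to each row of ``n``."""
    raw = rng.standard_normal(n.shape)
    raw -= (raw * n).sum(axis=1, keepdims=True) * n
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    # resample the (measure-zero) parallel draws deterministically
    bad = norms[:, 0] < 1e-8
    while bad.any():
        raw[bad] = rng.standard_normal((bad.sum(), 3))
        raw[bad] -= (raw[bad] * n[bad]).sum(axis=1, keepdims=True) * n[bad]
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
        bad = norms[:, 0] < 1e-8
    return raw / norms


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of rows of ``v`` about unit rows of ``axis``."""
    angle = np.asarray(angle, dtype=float).reshape(-1, 1)
    cos, sin = np.cos(angle), np.sin(angle)
    cross = np.cross(axis, v)
    dot = (axis * v).sum(axis=1, keepdims=True)
    return v * cos + cross * sin + axis * dot * (1.0 - cos)


def perturbed_direction(
    normals: np.ndarray,
    theta_deg: float,
    sigma_deg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tilt each normal by ``theta`` about a random in-tangent-plane axis,
    then perturb by an angle drawn from N(0, sigma) about a random axis
    perpendicular to the tilted vector."""
    theta = np.deg2rad(theta_deg)
    tangent = _random_tangent(rng, normals)
    e1 = _rotate_about(normals, tangent, np.full(len(normals), theta))
    if sigma_deg > 0:
        axis = _random_tangent(rng, e1)
        delta = rng.normal(0.0, np.deg2rad(sigma_deg), size=len(e1))
        e1 = _rotate_about(e1, axis, delta)
    return e1 / np.linalg.norm(e1, axis=1, keepdims=True)


def expected_angle(theta_deg: float, sigma_deg: float,
                   n: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo expectation of arccos|e1 . n| under the phantom's noise
    model, in degrees.

    Angular noise biases the mean measured angle away from ``theta``
    (most visibly at theta = 0, where the mean is ~ sigma * sqrt(2/pi));
    this is the reference value recovery tests compare against.
    """
    rng = np.random.default_rng(seed)
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    e1 = perturbed_direction(normals, theta_deg, sigma_deg, rng)
    return float(np.rad2deg(np.arccos(np.clip(np.abs(e1[:, 2]), 0, 1))).mean())


def make_phantom(spec: PhantomSpec) -> tuple[RibbonLabels, TensorField, dict]:
    """Build a labelled ribbon phantom and its ground-truth tensor field.

    The label volume marks inside-white, grey-matter ribbon (split into
    two synthetic "hemisphere" regions along x) and outside-pial shells.
    At every voxel with a defined surface normal the tensor is
    ``sum_i lambda_i e_i e_i^T`` with ``e1`` from
    :func:`perturbed_direction`; the tensor mask covers ribbon and
    boundary voxels so profile endpoints always hit valid tensors.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    vs = spec.voxel_size
    affine = np.diag([vs, vs, vs, 1.0])

    idx = np.indices(spec.shape).reshape(3, -1).T.astype(float)
    labels = np.zeros(spec.shape, dtype=int)

    if spec.geometry == "slab":
        z = idx[:, 2].reshape(spec.shape)
        z0 = 2
        z1 = z0 + spec.thickness
        labels[(z >= 0) & (z < z0)] = regions_mod.LABEL_WHITE
        labels[(z >= z0) & (z < z1)] = 11
        labels[(z >= z1) & (z < z1 + 2)] = regions_mod.LABEL_PIAL
        x = idx[:, 0].reshape(spec.shape)
        labels[(labels == 11) & (x >= nx / 2)] = 12
        normals = np.tile([0.0, 0.0, 1.0], (idx.shape[0], 1))
        defined = np.ones(idx.shape[0], dtype=bool)
    else:
        centre = (np.array(spec.shape) - 1) / 2.0
        pos = (idx - centre) * vs
        r = np.linalg.norm(pos, axis=1)
        r_grid = r.reshape(spec.shape)
        labels[r_grid < spec.inner_radius] = regions_mod.LABEL_WHITE
        gm = (r_grid >= spec.inner_radius) & (r_grid < spec.outer_radius)
        labels[gm] = 11
        pial = (r_grid >= spec.outer_radius) & (r_grid < spec.outer_radius + 2 * vs)
        labels[pial] = regions_mod.LABEL_PIAL
        x = idx[:, 0].reshape(spec.shape)
        labels[(labels == 11) & (x >= centre[0])] = 12
        defined = r > 1e-9
        normals = np.zeros_like(pos)
        normals[defined] = pos[defined] / r[defined, None]

    e1 = np.zeros((idx.shape[0], 3))
    e1[defined] = perturbed_direction(
        normals[defined], spec.theta_deg, spec.sigma_deg, rng
    )
    e2 = np.zeros_like(e1)
    e2[defined] = _random_tangent(rng, e1[defined])
    e3 = np.cross(e1, e2)

    l1, l2, l3 = spec.evals
    D = (
        l1 * e1[:, :, None] * e1[:, None, :]
        + l2 * e2[:, :, None] * e2[:, None, :]
        + l3 * e3[:, :, None] * e3[:, None, :]
    )
    comp = matrices_to_components(D).reshape(spec.shape + (6,))

    in_ribbon = np.isin(labels, list(PHANTOM_REGION_MAP))
    mask = (in_ribbon | (labels == regions_mod.LABEL_WHITE)
            | (labels == regions_mod.LABEL_PIAL)) & defined.reshape(spec.shape)
    tensors = TensorField(
        D=comp,
        S0=np.full(spec.shape, 1000.0),
        affine=affine,
        mask=mask,
        degenerate=np.zeros(spec.shape, dtype=bool),
    )
    ribbon = RibbonLabels(labels=labels, affine=affine, region_map=dict(PHANTOM_REGION_MAP))
    truth = {
        "theta_deg": spec.theta_deg,
        "sigma_deg": spec.sigma_deg,
        "normals": normals.reshape(spec.shape + (3,)),
        "e1": e1.reshape(spec.shape + (3,)),
        "evals": spec.evals,
    }
    return ribbon, tensors, truth


def make_gradient_scheme(
    n_directions: int = 64, bval: float = 2000.0, n_b0: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic b-value/direction table: ``n_b0`` baselines followed
    by ``n_directions`` Fibonacci-sphere unit directions (non-collinear by
    construction)."""
    i = np.arange(n_directions)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / n_directions
    phi = 2 * np.pi * i / golden
    sin_t = np.sqrt(1 - z**2)
    dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), z])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, bval)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return bvals, bvecs


def simulate_dwi(
    tensors: TensorField,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    s0: float = 1000.0,
    snr: float = np.inf,
    seed: int = 0,
) -> DwiSet:
    """Forward-simulate DWI signals ``S_i = S0 exp(-b_i g_i^T D g_i)``.

    Finite ``snr`` adds Rician noise (magnitude of the complex signal plus
    Gaussian noise of SD ``s0 / snr`` in each channel); ``snr = inf``
    gives noise-free signals.
    """
    if snr <= 0:
        raise ParameterError("snr must be positive (use np.inf for noise-free)")
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    Dmat = tensors.tensor_matrices()
    adc = np.einsum("ni,...ij,nj->...n", bvecs, Dmat, bvecs)
    signals = s0 * np.exp(-bvals * adc)
    signals[~tensors.mask] = 0.0
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        re = signals + rng.normal(0.0, sigma, signals.shape)
        im = rng.normal(0.0, sigma, signals.shape)
        signals = np.sqrt(re**2 + im**2)
        signals[~tensors.mask] = 0.0
    return DwiSet(
        signals=signals, bvals=bvals, bvecs=bvecs,
        affine=tensors.affine, mask=tensors.mask,
    )


# ---------------------------------------------------------------------------
# cohort tables


def default_elevations() -> dict[str, dict[str, float]]:
    """Per-subtype regional AngleR elevations (radians above baseline).

    Each dementia subtype elevates the regions it characteristically
    damages: the semantic variant in left fusiform/entorhinal and right
    temporal-pole/inferior-temporal cortex, the behavioural variant in
    left caudal anterior cingulate and right lingual cortex, the
    non-fluent variant in left pars opercularis; all patient groups share
    a bilateral precentral elevation.
    """
    shared = {"left_precentral": 0.06, "right_precentral": 0.06}
    return {
        "svPPA": {
            "left_fusiform": 0.08,
            "left_entorhinal": 0.08,
            "right_temporalpole": 0.08,
            "right_inferiortemporal": 0.08,
            **shared,
        },
        "bvFTD": {
            "left_caudalanteriorcingulate": 0.08,
            "right_lingual": 0.08,
            **shared,
        },
        "nfvPPA": {
            "left_parsopercularis": 0.08,
            **shared,
        },
        "HS": {},
    }


def default_cohort_sizes() -> dict[str, dict[str, int]]:
    """Group sizes of the three-cohort study design."""
    return {
        "selection": {"HS": 30, "bvFTD": 10, "svPPA": 10, "nfvPPA": 10},
        "training": {"HS": 30, "bvFTD": 5, "svPPA": 13, "nfvPPA": 6},
        "test": {"HS": 24, "bvFTD": 15, "svPPA": 18, "nfvPPA": 9},
    }


@dataclasses.dataclass
class CohortSpec:
    """Recipe for synthetic selection/training/test cohort tables.

    Regional AngleR values (radians) are drawn as
    ``baseline + subject offset + group elevation + noise``; the shared
    subject offset induces realistic cross-region correlation.  Patient
    groups additionally receive a small global shift (the diffuse
    whole-cortex effect of neurodegeneration).  Covariate distributions
    follow typical presenile-dementia study demographics; MMSE, CDR and
    grey-matter fraction carry the usual patient/control separation.
    """

    cohort_sizes: dict[str, dict[str, int]] = dataclasses.field(
        default_factory=default_cohort_sizes
    )
    baseline_angle: float = 0.70
    subject_sd: float = 0.015
    region_sd: float = 0.05
    elevations: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=default_elevations
    )
    global_ftd_shift: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        valid_regions = set(regions_mod.canonical_region_names())
        for group, elev in self.elevations.items():
            unknown = set(elev) - valid_regions
            if unknown:
                raise ParameterError(
                    f"elevation map for {group!r} names unknown regions: {sorted(unknown)}"
                )
        for cohort, sizes in self.cohort_sizes.items():
            if any(n < 0 for n in sizes.values()):
                raise ParameterError(f"negative group size in cohort {cohort!r}")
        if self.subject_sd <= 0 or self.region_sd <= 0:
            raise ParameterError("noise SDs must be positive")


_COVARIATE_MEANS = {
    # group -> (MMSE mean, MMSE sd, CDR mean, CDR sd, GM_fr mean, GM_fr sd)
    "HS": (28.8, 1.2, 0.0, 0.0, 0.440, 0.025),
    "FTD": (21.0, 5.7, 0.75, 0.45, 0.405, 0.030),
}

_WHOLEBRAIN_AUX = {
    # metric -> (HS mean, FTD mean, sd) in 1e-3 mm^2/s
    "PerpPD_wholebrain": (0.55, 0.62, 0.05),
    "ParlPD_wholebrain": (0.62, 0.61, 0.05),
    "MD_wholebrain": (0.85, 0.92, 0.05),
}

_SCANNERS = {"selection": "scanner_A", "training": "scanner_B", "test": "scanner_A"}


def make_cohorts(spec: CohortSpec | None = None, seed: int | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Generate the three disjoint cohort tables.

    Returns ``{"selection": ..., "training": ..., "test": ...}``; each
    DataFrame has columns ``id, cohort, diagnosis``, demographic and
    clinical covariates, the whole-brain diffusion features, and the 68
    regional AngleR columns (``AngleR_<region>``).
    """
    spec = spec or CohortSpec()
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    region_names = regions_mod.canonical_region_names()
    out: dict[str, pd.DataFrame] = {}
    uid = 0
    for cohort, sizes in spec.cohort_sizes.items():
        rows = []
        for group, n in sizes.items():
            elev = spec.elevations.get(group, {})
            is_ftd = group != "HS"
            mmse_m, mmse_s, cdr_m, cdr_s, gm_m, gm_s = _COVARIATE_MEANS[
                "FTD" if is_ftd else "HS"
            ]
            for _ in range(n):
                uid += 1
                offset = rng.normal(0.0, spec.subject_sd)
                shift = spec.global_ftd_shift if is_ftd else 0.0
                regional = {
                    f"AngleR_{r}": spec.baseline_angle + offset + shift
                    + elev.get(r, 0.0) + rng.normal(0.0, spec.region_sd)
                    for r in region_names
                }
                row = {
                    "id": f"sub-{uid:04d}",
                    "cohort": cohort,
                    "diagnosis": group,
                    "age": rng.normal(68.0, 6.0),
                    "sex": rng.choice(["F", "M"]),
                    "education": rng.normal(14.0, 3.0),
                    "MMSE": float(np.clip(rng.normal(mmse_m, mmse_s), 0, 30)),
                    "CDR": float(max(rng.normal(cdr_m, cdr_s), 0.0)) if cdr_s else cdr_m,
                    "GM_fr": float(np.clip(rng.normal(gm_m, gm_s), 0.2, 0.6)),
                    "scanner": _SCANNERS.get(cohort, "scanner_A"),
                    "head_movement": float(max(rng.normal(0.30, 0.10), 0.01)),
                }
                for metric, (hs_m, ftd_m, sd) in _WHOLEBRAIN_AUX.items():
                    row[metric] = rng.normal(ftd_m if is_ftd else hs_m, sd)
                row.update(regional)
                row["AngleR_wholebrain"] = float(
                    np.mean([regional[f"AngleR_{r}"] for r in region_names])
                )
                rows.append(row)
        out[cohort] = pd.DataFrame(rows)
    return out


def make_realignment_series(
    n_volumes: int,
    drift: float = 0.0,
    jump_magnitude: float = 0.0,
    n_jumps: int = 0,
    seed: int = 0,
) -> RealignmentSeries:
    """Synthetic realignment-parameter table: linear drift on the three
    translation channels plus ``n_jumps`` single-channel jumps of
    ``jump_magnitude`` mm at random transitions (rotations stay zero).

    The expected displacement index is computable from the recipe:
    ``(3 * drift * T + n_jumps * jump_magnitude) / (6 * T)`` with
    ``T = n_volumes - 1`` transitions, provided drift and jumps move in
    the same direction.
    """
    if n_volumes < 2:
        raise ParameterError("need at least 2 volumes")
    if n_jumps > n_volumes - 1:
        raise ParameterError("more jumps than volume transitions")
    rng = np.random.default_rng(seed)
    params = np.zeros((n_volumes, 6))
    t = np.arange(n_volumes)[:, None]
    params[:, :3] = drift * t
    if n_jumps and jump_magnitude:
        transitions = rng.choice(n_volumes - 1, size=n_jumps, replace=False)
        for tr in transitions:
            channel = int(rng.integers(0, 3))
            params[tr + 1 :, channel] += jump_magnitude
    return RealignmentSeries(params=params)
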