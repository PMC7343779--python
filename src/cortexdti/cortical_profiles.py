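"""Columnar cortical profiles and profile-based diffusivity metrics.

The cortex is organised in radial minicolumns; degeneration disrupts this
columnar architecture and with it the radial coherence of water diffusion.
To quantify that, a scalar potential is solved on the grey-matter ribbon
(Laplace's equation, 0 on the white-matter boundary, 1 on the pial
boundary) and streamlines of its gradient — "cortical profiles" — are
traced from the white boundary to the pial surface.  Along each profile
the local diffusion tensor supplies:

* ``AngleR``  — angle between the profile tangent and the principal
  diffusion direction (radians in [0, pi/2]; small when diffusion is
  radial / column-aligned),
* ``PerpPD`` / ``ParlPD`` — the principal diffusion component
  ``lambda1 * e1`` projected perpendicular to / onto the profile,
  reported in units of 1e-3 mm^2/s,
* ``MD`` and ``FA`` — the standard tensor scalars.

Each metric is averaged along the profile, then profiles are pooled into
regional and whole-brain values.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np
import pandas as pd
from scipy import ndimage

from cortexdti import regions as regions_mod
from cortexdti.errors import ContractError, ParameterError, TopologyError
from cortexdti.tensor_fit import TensorField, eigensystem_field

METRIC_NAMES = ("AngleR", "PerpPD", "ParlPD", "MD", "FA")

#: 6-connectivity structuring element
_STRUCT6 = ndimage.generate_binary_structure(3, 1)

#: relative lambda1-lambda2 gap below which AngleR is numerically meaningless
ANGLE_DEGENERACY_REL = 1e-6


@dataclasses.dataclass
class RibbonLabels:
    """Integer label volume describing the cortical ribbon.

    ``labels`` uses :mod:`cortexdti.regions` codes: 1 inside-white,
    2 outside-pial, 0 other, and per-region grey-matter codes mapped to
    canonical names by ``region_map``.
    """

    labels: np.ndarray
    affine: np.ndarray
    region_map: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def gm_mask(self) -> np.ndarray:
        gm = np.isin(self.labels, list(self.region_map))
        return gm

    @property
    def white_mask(self) -> np.ndarray:
        return self.labels == regions_mod.LABEL_WHITE

    @property
    def pial_mask(self) -> np.ndarray:
        return self.labels == regions_mod.LABEL_PIAL

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three index axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclasses.dataclass
class CorticalProfile:
    """An ordered trajectory from the white to the pial boundary.

    points   : (N, 3) world coordinates in mm, inner to outer
    tangents : (N, 3) unit step directions
    region_code : majority region of traversed grey-matter voxels
    length   : total arc length in mm
    truncated : True when tracing stopped before reaching the pial boundary
    """

    points: np.ndarray
    tangents: np.ndarray
    region_code: int
    length: float
    truncated: bool = False


@dataclasses.dataclass
class ProfileMetrics:
    """Along-profile means of the five tensor metrics.

    ``n_samples`` counts non-degenerate sampled voxels; ``n_angle_excluded``
    counts samples whose principal direction was numerically degenerate
    (lambda1 ~ lambda2) and therefore left out of the AngleR/PerpPD/ParlPD
    means.  ``missing`` is set when no sample was usable.
    """

    angle_r: float
    perp_pd: float
    parl_pd: float
    md: float
    fa: float
    n_samples: int
    n_angle_excluded: int
    region_code: int
    missing: bool = False


def solve_ribbon_potential(
    ribbon: RibbonLabels,
    tol: float = 1e-6,
    max_iter: int = 50_000,
    strict: bool = False,
    unreachable_warn_fraction: float = 0.05,
) -> np.ndarray:
    """Solve Laplace's equation on the grey-matter ribbon.

    Dirichlet boundaries: 0 on inside-white voxels, 1 on outside-pial
    voxels.  Jacobi iteration until the largest update falls below ``tol``.

    Returns the potential as a float volume: 0 at white, 1 at pial, the
    solved value on reachable grey matter, NaN elsewhere (including grey
    matter with no connection to both boundaries, which is excluded).

    Raises
    ------
    TopologyError
        If either boundary label is absent, or (in ``strict`` mode) more
        than ``unreachable_warn_fraction`` of grey matter is unreachable.
    """
    gm = ribbon.gm_mask
    white = ribbon.white_mask
    pial = ribbon.pial_mask
    if not gm.any():
        raise TopologyError("no grey-matter voxels in the ribbon")
    if not white.any() or not pial.any():
        raise TopologyError("ribbon lacks a white and/or pial boundary label")

    # a GM component is usable only if it touches both boundaries
    comp, n_comp = ndimage.label(gm, structure=_STRUCT6)
    near_white = gm & ndimage.binary_dilation(white, structure=_STRUCT6)
    near_pial = gm & ndimage.binary_dilation(pial, structure=_STRUCT6)
    good_white = set(np.unique(comp[near_white]))
    good_pial = set(np.unique(comp[near_pial]))
    good = (good_white & good_pial) - {0}
    reachable = np.isin(comp, list(good)) if good else np.zeros_like(gm)
    unreachable = gm & ~reachable
    frac_unreachable = unreachable.sum() / gm.sum()
    if not good:
        raise TopologyError("no grey matter connects both boundaries")
    if strict and frac_unreachable > unreachable_warn_fraction:
        raise TopologyError(
            f"{100 * frac_unreachable:.1f}% of grey matter is unreachable"
        )

    valid = reachable | white | pial
    u = np.zeros(ribbon.labels.shape, dtype=float)
    u[pial] = 1.0
    u[reachable] = 0.5

    shifts = [(axis, off) for axis in range(3) for off in (-1, 1)]

    def shifted(arr: np.ndarray, axis: int, off: int, fill=0.0) -> np.ndarray:
        out = np.full_like(arr, fill)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if off == 1:
            src[axis], dst[axis] = slice(1, None), slice(None, -1)
        else:
            src[axis], dst[axis] = slice(None, -1), slice(1, None)
        out[tuple(dst)] = arr[tuple(src)]
        return out

    valid_f = valid.astype(float)
    nbr_count = sum(shifted(valid_f, ax, off) for ax, off in shifts)
    interior = reachable & (nbr_count > 0)
    count = nbr_count[interior]

    for _ in range(max_iter):
        nbr_sum = sum(
            shifted(u * valid_f, ax, off) for ax, off in shifts
        )
        new_vals = nbr_sum[interior] / count
        delta = np.abs(new_vals - u[interior]).max() if new_vals.size else 0.0
        u[interior] = new_vals
        if delta < tol:
            break

    out = np.full(ribbon.labels.shape, np.nan)
    out[white] = 0.0
    out[pial] = 1.0
    out[interior] = u[interior]
    return out


def _world_gradient(
    potential: np.ndarray, affine: np.ndarray, smooth_sigma_vox: float = 1.0
) -> np.ndarray:
    """Gradient of the potential in world coordinates, (3, X, Y, Z).

    With ``smooth_sigma_vox > 0`` (default 1 voxel) the derivative is a
    Gaussian-derivative filter on the nearest-filled potential, which
    suppresses the stair-step noise a voxelised curved boundary imprints
    on raw finite differences.  With ``smooth_sigma_vox = 0``: central
    differences where both neighbours are defined, one-sided at the
    domain edge, nearest-filled elsewhere.
    """
    finite = np.isfinite(potential)
    if smooth_sigma_vox > 0:
        u = potential.copy()
        if not finite.all():
            _, idx = ndimage.distance_transform_edt(~finite, return_indices=True)
            u = u[idx[0], idx[1], idx[2]]
        grad_idx = np.stack(
            [
                ndimage.gaussian_filter(
                    u, sigma=smooth_sigma_vox,
                    order=[int(a == i) for i in range(3)],
                )
                for a in range(3)
            ]
        )
        J = affine[:3, :3]
        return np.einsum("ij,j...->i...", np.linalg.inv(J).T, grad_idx)
    grad_idx = np.zeros((3,) + potential.shape)
    for axis in range(3):
        fwd = np.full_like(potential, np.nan)
        bwd = np.full_like(potential, np.nan)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        src[axis], dst[axis] = slice(1, None), slice(None, -1)
        fwd[tuple(dst)] = potential[tuple(src)]
        src[axis], dst[axis] = slice(None, -1), slice(1, None)
        bwd[tuple(dst)] = potential[tuple(src)]
        have_f, have_b = np.isfinite(fwd), np.isfinite(bwd)
        g = np.where(
            have_f & have_b,
            0.5 * (fwd - bwd),
            np.where(have_f, fwd - potential, np.where(have_b, potential - bwd, 0.0)),
        )
        grad_idx[axis] = np.where(finite, g, np.nan)

    # index-space -> world-space: grad_w = J^{-T} grad_idx
    J = affine[:3, :3]
    Jinv_T = np.linalg.inv(J).T
    grad_w = np.einsum("ij,j...->i...", Jinv_T, grad_idx)

    defined = np.all(np.isfinite(grad_w), axis=0)
    if not defined.all():
        _, idx = ndimage.distance_transform_edt(~defined, return_indices=True)
        grad_w = grad_w[:, idx[0], idx[1], idx[2]]
    return grad_w


def trace_profiles(
    potential: np.ndarray,
    ribbon: RibbonLabels,
    step_h: float = 0.5,
    max_length_mm: float = 20.0,
    grad_smooth_sigma_vox: float = 1.0,
) -> tuple[list[CorticalProfile], dict[str, int]]:
    """Trace one streamline per white-boundary grey-matter voxel.

    Streamlines follow the normalised world-space gradient of the potential
    (Gaussian-derivative estimate, see :func:`_world_gradient`) with fixed
    Euler steps of ``step_h`` mm and trilinear gradient interpolation, from
    each seed to the pial boundary.  A profile inherits the majority region
    code of the grey-matter voxels it traverses (ties broken toward the
    seed's region).  Profiles shorter than two steps, or stopped by a
    vanishing gradient or the ``max_length_mm`` cap, are dropped and
    counted in the returned log.
    """
    if step_h <= 0:
        raise ParameterError("step_h must be positive")
    finite = np.isfinite(potential)
    grad = _world_gradient(potential, ribbon.affine, grad_smooth_sigma_vox)
    u_filled = potential.copy()
    if not finite.all():
        _, idx = ndimage.distance_transform_edt(~finite, return_indices=True)
        u_filled = u_filled[idx[0], idx[1], idx[2]]

    gm = ribbon.gm_mask
    seeds_mask = gm & finite & ndimage.binary_dilation(ribbon.white_mask, structure=_STRUCT6)
    seed_idx = np.argwhere(seeds_mask)
    drop_log = {"unreachable_seed": int((gm & ~finite
                & ndimage.binary_dilation(ribbon.white_mask, structure=_STRUCT6)).sum()),
                "too_short": 0, "zero_gradient": 0, "max_length": 0}
    if seed_idx.size == 0:
        return [], drop_log

    A = ribbon.affine
    inv_A = np.linalg.inv(A)
    n = len(seed_idx)
    max_steps = int(np.ceil(max_length_mm / step_h))

    pos = (A[:3, :3] @ seed_idx.T).T + A[:3, 3]  # world voxel centres
    active = np.ones(n, dtype=bool)
    flagged_zero = np.zeros(n, dtype=bool)
    hit_cap = np.zeros(n, dtype=bool)
    points: list[list[np.ndarray]] = [[p.copy()] for p in pos]
    tangents: list[list[np.ndarray]] = [[] for _ in range(n)]
    visited: list[Counter] = [Counter() for _ in range(n)]

    region_codes = set(ribbon.region_map)

    def record_visit(i: int, voxel: np.ndarray) -> None:
        code = int(ribbon.labels[tuple(voxel)])
        if code in region_codes:
            visited[i][code] += 1

    for i, vx in enumerate(seed_idx):
        record_visit(i, vx)

    def interp_vec(field: np.ndarray, pts_vox: np.ndarray) -> np.ndarray:
        return np.stack(
            [
                ndimage.map_coordinates(field[c], pts_vox.T, order=1, mode="nearest")
                for c in range(3)
            ],
            axis=1,
        )

    for _step in range(max_steps):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        pts_vox = (inv_A[:3, :3] @ pos[ai].T).T + inv_A[:3, 3]
        g = interp_vec(grad, pts_vox)
        norms = np.linalg.norm(g, axis=1)
        dead = norms < 1e-12
        for k in ai[dead]:
            flagged_zero[k] = True
            active[k] = False
        ai = ai[~dead]
        if ai.size == 0:
            continue
        d = g[~dead] / norms[~dead, None]
        pos[ai] = pos[ai] + step_h * d
        pts_vox = (inv_A[:3, :3] @ pos[ai].T).T + inv_A[:3, 3]
        nearest = np.clip(
            np.round(pts_vox).astype(int), 0,
            np.array(potential.shape) - 1,
        )
        u_here = ndimage.map_coordinates(u_filled, pts_vox.T, order=1, mode="nearest")
        for j, k in enumerate(ai):
            points[k].append(pos[k].copy())
            tangents[k].append(d[j].copy())
            record_visit(k, nearest[j])
            lab = int(ribbon.labels[tuple(nearest[j])])
            if lab == regions_mod.LABEL_PIAL or u_here[j] >= 1.0 - 1e-3:
                active[k] = False
    hit_cap[active] = True  # still walking after the length cap

    profiles: list[CorticalProfile] = []
    for i in range(n):
        pts = np.asarray(points[i])
        if flagged_zero[i]:
            drop_log["zero_gradient"] += 1
            continue
        if hit_cap[i]:
            drop_log["max_length"] += 1
            continue
        if len(pts) < 3:  # fewer than 2 steps
            drop_log["too_short"] += 1
            continue
        tans = np.asarray(tangents[i])
        tans = np.vstack([tans[:1], tans])  # tangent at the seed = first step
        seed_code = int(ribbon.labels[tuple(seed_idx[i])])
        counts = visited[i]
        if counts:
            best = max(counts.values())
            tied = sorted(c for c, v in counts.items() if v == best)
            code = seed_code if seed_code in tied else tied[0]
        else:
            code = seed_code
        profiles.append(
            CorticalProfile(
                points=pts,
                tangents=tans,
                region_code=code,
                length=step_h * (len(pts) - 1),
            )
        )
    return profiles, drop_log


def angle_r(e1: np.ndarray, tangent: np.ndarray) -> float:
    """Angle between the principal diffusion direction and the profile
    tangent, in radians within [0, pi/2].

    The absolute dot product removes the eigenvector sign ambiguity; the
    dot is clamped to [-1, 1] before arccos.
    """
    e1 = np.asarray(e1, dtype=float)
    tangent = np.asarray(tangent, dtype=float)
    n1, n2 = np.linalg.norm(e1), np.linalg.norm(tangent)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ContractError("angle_r requires non-zero vectors")
    if abs(n1 - 1.0) > 1e-6 or abs(n2 - 1.0) > 1e-6:
        raise ContractError("angle_r requires unit vectors")
    d = np.clip(abs(float(np.dot(e1, tangent))), 0.0, 1.0)
    return float(np.arccos(d))


def perp_parl(lambda1: float, angle: float) -> tuple[float, float]:
    """Perpendicular and parallel projections of the principal diffusion
    component, in 1e-3 mm^2/s.

    ``PerpPD = lambda1 * sin(angle)``, ``ParlPD = lambda1 * cos(angle)``;
    ``lambda1`` is given in mm^2/s and the outputs are scaled by 1e3 to the
    reporting unit.  Satisfies PerpPD^2 + ParlPD^2 = (1e3 * lambda1)^2.
    """
    if lambda1 < 0:
        raise ContractError("lambda1 must be non-negative (degenerate voxels are excluded upstream)")
    if not 0.0 <= angle <= np.pi / 2 + 1e-12:
        raise ContractError("angle must lie in [0, pi/2]")
    scale = 1e3 * lambda1
    return float(scale * np.sin(angle)), float(scale * np.cos(angle))


def sample_profile_metrics(
    profile: CorticalProfile,
    tensors: TensorField,
    lookup: str = "nearest",
) -> ProfileMetrics:
    """Sample the tensor field along a profile and average the metrics.

    At each profile point the tensor is looked up (nearest voxel by
    default; ``lookup="trilinear"`` interpolates the six components), its
    eigensystem computed, and AngleR/PerpPD/ParlPD/MD/FA evaluated against
    the local tangent.  Degenerate voxels are skipped entirely; samples
    with a numerically degenerate principal direction
    (lambda1 - lambda2 < 1e-6 * lambda1) contribute to MD/FA but are
    excluded from the AngleR/PerpPD/ParlPD means.
    """
    if lookup not in ("nearest", "trilinear"):
        raise ParameterError(f"unknown lookup {lookup!r}")
    inv_A = np.linalg.inv(tensors.affine)
    pts_vox = (inv_A[:3, :3] @ profile.points.T).T + inv_A[:3, 3]
    shape = np.array(tensors.mask.shape)
    nearest = np.clip(np.round(pts_vox).astype(int), 0, shape - 1)
    ii, jj, kk = nearest.T
    usable = tensors.mask[ii, jj, kk] & ~tensors.degenerate[ii, jj, kk]

    if lookup == "nearest":
        comps = tensors.D[ii, jj, kk]
    else:
        comps = np.stack(
            [
                ndimage.map_coordinates(tensors.D[..., c], pts_vox.T, order=1, mode="nearest")
                for c in range(6)
            ],
            axis=1,
        )
    comps = comps[usable]
    tans = profile.tangents[usable]
    n_samples = int(usable.sum())
    if n_samples == 0:
        return ProfileMetrics(
            np.nan, np.nan, np.nan, np.nan, np.nan,
            0, 0, profile.region_code, missing=True,
        )

    evals, evecs = eigensystem_field(comps)
    lam1 = evals[:, 0]
    e1 = evecs[:, 0, :]
    dots = np.clip(np.abs(np.einsum("ij,ij->i", e1, tans)), 0.0, 1.0)
    angles = np.arccos(dots)
    md = evals.mean(axis=1)
    norm = np.linalg.norm(evals, axis=1)
    fa = np.zeros_like(md)
    nz = norm > 0
    fa[nz] = np.clip(
        np.sqrt(1.5) * np.linalg.norm(evals[nz] - md[nz, None], axis=1) / norm[nz],
        0.0, 1.0,
    )

    ok_dir = (lam1 - evals[:, 1]) >= ANGLE_DEGENERACY_REL * np.maximum(lam1, 1e-300)
    n_excl = int((~ok_dir).sum())
    perp = 1e3 * lam1 * np.sin(angles)
    parl = 1e3 * lam1 * np.cos(angles)

    return ProfileMetrics(
        angle_r=float(angles[ok_dir].mean()) if ok_dir.any() else np.nan,
        perp_pd=float(perp[ok_dir].mean()) if ok_dir.any() else np.nan,
        parl_pd=float(parl[ok_dir].mean()) if ok_dir.any() else np.nan,
        md=float(1e3 * md.mean()),  # reporting unit: 1e-3 mm^2/s
        fa=float(fa.mean()),
        n_samples=n_samples,
        n_angle_excluded=n_excl,
        region_code=profile.region_code,
        missing=False,
    )


def aggregate_regions(
    metrics: list[ProfileMetrics],
    region_map: dict[int, str] | None = None,
    whole_brain: str = "profiles",
) -> pd.DataFrame:
    """Pool per-profile means into regional and whole-brain values.

    Each region's value is the unweighted mean over that region's profile
    means; the whole-brain value is the unweighted mean over all profile
    means (``whole_brain="profiles"``, default) or over the region means
    (``whole_brain="regions"``).  Regions with no profiles carry NaN and
    ``n_profiles == 0`` — an explicit missing marker, never zero.

    Returns a DataFrame indexed by region name plus ``"whole_brain"``,
    with one column per metric and an ``n_profiles`` count.
    """
    if whole_brain not in ("profiles", "regions"):
        raise ParameterError(f"unknown whole_brain mode {whole_brain!r}")
    usable = [m for m in metrics if not m.missing]
    if not metrics:
        raise ContractError("no profile metrics to aggregate")
    if region_map is None:
        codes = sorted({m.region_code for m in usable})
        region_map = {c: f"region_{c}" for c in codes}

    cols = {
        "AngleR": [m.angle_r for m in usable],
        "PerpPD": [m.perp_pd for m in usable],
        "ParlPD": [m.parl_pd for m in usable],
        "MD": [m.md for m in usable],
        "FA": [m.fa for m in usable],
    }
    df = pd.DataFrame(cols)
    df["region"] = [region_map.get(m.region_code, f"region_{m.region_code}") for m in usable]

    rows = {}
    for name in region_map.values():
        sub = df[df["region"] == name]
        if len(sub):
            rows[name] = [sub[m].mean() for m in METRIC_NAMES] + [len(sub)]
        else:
            rows[name] = [np.nan] * len(METRIC_NAMES) + [0]
    if whole_brain == "profiles":
        wb = [df[m].mean() for m in METRIC_NAMES]
    else:
        region_vals = pd.DataFrame(
            {name: vals[: len(METRIC_NAMES)] for name, vals in rows.items()},
            index=list(METRIC_NAMES),
        ).T
        wb = [region_vals[m].mean() for m in METRIC_NAMES]
    rows["whole_brain"] = wb + [len(df)]

    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(METRIC_NAMES) + ["n_profiles"]
    )
    out.index.name = "region"
    out["n_profiles"] = out["n_profiles"].astype(int)
    return out
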