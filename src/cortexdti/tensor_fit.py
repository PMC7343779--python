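"""Diffusion tensor fitting and eigensystem-derived scalars.

The diffusion tensor model relates the diffusion-weighted signal to the
symmetric tensor ``D`` through ``S_i = S0 * exp(-b_i g_i^T D g_i)``.  Taking
logs gives a linear model in the six unique tensor components plus
``ln S0``, fitted per voxel by ordinary or weighted least squares (weights
``S_i^2``, the standard first-order variance correction for log-transformed
Rician-corrupted magnitudes).

Tensor components are stored in FSL lower-triangular order
(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from cortexdti.errors import (
    ContractError,
    MissingBaselineError,
    UnfittableDesignError,
)

#: b-values below this (s/mm^2) count as non-diffusion-weighted baselines
B0_THRESHOLD = 50.0

#: lower-triangular component order used throughout
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")

#: relative signal floor applied before taking logs
SIGNAL_FLOOR_FRACTION = 1e-6

#: eigenvalue gap (relative to lambda1) below which ordering is ambiguous
EIGENVALUE_TIE_TOL = 1e-12


@dataclasses.dataclass
class DwiSet:
    """A diffusion-weighted acquisition.

    signals : (X, Y, Z, N) non-negative intensities
    bvals   : (N,) b-factors in s/mm^2
    bvecs   : (N, 3) unit gradient directions (image-coordinate convention)
    affine  : (4, 4) voxel -> world map
    mask    : (X, Y, Z) boolean inclusion mask
    """

    signals: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.signals.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_volumes(self) -> int:
        return self.signals.shape[3]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < B0_THRESHOLD

    def validate(self) -> None:
        if self.signals.ndim != 4:
            raise ContractError("signals must be 4-D (x, y, z, volume)")
        n = self.n_volumes
        if self.bvals.shape != (n,) or self.bvecs.shape != (n, 3):
            raise ContractError(
                f"bvals/bvecs inconsistent with {n} signal volumes"
            )
        if np.any(self.signals < 0):
            raise ContractError("signals must be non-negative")
        dw = ~self.b0_mask
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-3):
            raise ContractError("b>0 gradient directions must be unit norm")


@dataclasses.dataclass
class TensorField:
    """Per-voxel diffusion tensors with fit metadata.

    D          : (X, Y, Z, 6) lower-triangular components in mm^2/s
    S0         : (X, Y, Z) non-diffusion-weighted signal
    affine     : voxel -> world map
    mask       : voxels that were fitted
    degenerate : voxels whose smallest eigenvalue is negative (or fit failed)
    """

    D: np.ndarray
    S0: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    degenerate: np.ndarray

    def tensor_matrices(self) -> np.ndarray:
        """Expand stored components to full symmetric (..., 3, 3) matrices."""
        return components_to_matrices(self.D)


@dataclasses.dataclass
class EigenSystem:
    """Sorted tensor eigensystem.

    evals : (3,) eigenvalues sorted descending, mm^2/s
    evecs : (3, 3) rows are unit eigenvectors matching ``evals``
    degenerate_direction : True when the leading eigenvalue is (numerically)
        tied, so the principal direction is not unique.
    """

    evals: np.ndarray
    evecs: np.ndarray
    degenerate_direction: bool = False


def components_to_matrices(comp: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular components -> (..., 3, 3) symmetric tensors."""
    comp = np.asarray(comp, dtype=float)
    out = np.empty(comp.shape[:-1] + (3, 3), dtype=float)
    dxx, dxy, dyy, dxz, dyz, dzz = np.moveaxis(comp, -1, 0)
    out[..., 0, 0] = dxx
    out[..., 1, 1] = dyy
    out[..., 2, 2] = dzz
    out[..., 0, 1] = out[..., 1, 0] = dxy
    out[..., 0, 2] = out[..., 2, 0] = dxz
    out[..., 1, 2] = out[..., 2, 1] = dyz
    return out


def matrices_to_components(D: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric tensors -> (..., 6) lower-triangular components."""
    D = np.asarray(D, dtype=float)
    return np.stack(
        [
            D[..., 0, 0],
            D[..., 0, 1],
            D[..., 1, 1],
            D[..., 0, 2],
            D[..., 1, 2],
            D[..., 2, 2],
        ],
        axis=-1,
    )


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear design: columns (1, -b gx^2, -2b gx gy, -b gy^2,
    -2b gx gz, -2b gy gz, -b gz^2), matching the stored component order."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -2.0 * b * gx * gy,
            -b * gy * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
            -b * gz * gz,
        ]
    )


def fit_tensor(dwi: DwiSet, method: str = "ols") -> TensorField:
    """Fit the diffusion tensor model at every masked voxel.

    Parameters
    ----------
    dwi : DwiSet
        Validated acquisition.
    method : {"ols", "wls"}
        Ordinary least squares on log signals (default) or weighted least
        squares with per-volume weights equal to the squared signal.

    Returns
    -------
    TensorField
        Voxels with a negative smallest eigenvalue are flagged
        ``degenerate`` but their fitted tensors are retained.
    """
    if method not in ("ols", "wls"):
        raise ContractError(f"unknown fit method {method!r}")
    dwi.validate()
    b0 = dwi.b0_mask
    if not b0.any():
        raise MissingBaselineError("no b~0 volume in the acquisition")
    if dwi.n_volumes < 7:
        raise UnfittableDesignError(
            f"{dwi.n_volumes} volumes; at least 7 (1 baseline + 6 weighted) required"
        )
    dw_vecs = dwi.bvecs[~b0]
    # >= 6 non-collinear directions <=> rank-6 quadratic-form design
    if np.linalg.matrix_rank(design_matrix(dwi.bvals, dwi.bvecs)) < 7:
        raise UnfittableDesignError(
            "gradient directions do not span 6 independent tensor components"
        )
    del dw_vecs

    X = design_matrix(dwi.bvals, dwi.bvecs)  # (N, 7)
    vox = dwi.signals[dwi.mask]  # (M, N)
    s0_guess = vox[:, b0].mean(axis=1)
    floor = np.maximum(SIGNAL_FLOOR_FRACTION * s0_guess, 1e-300)
    clamped = np.maximum(vox, floor[:, None])
    Y = np.log(clamped)  # (M, N)

    if method == "ols":
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (7, M)
        beta = beta.T
    else:
        W = clamped**2  # (M, N)
        XtWX = np.einsum("mn,ni,nj->mij", W, X, X)
        XtWy = np.einsum("mn,ni,mn->mi", W, X, Y)
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]

    shape = dwi.signals.shape[:3]
    D = np.zeros(shape + (6,), dtype=float)
    S0 = np.zeros(shape, dtype=float)
    D[dwi.mask] = beta[:, 1:]
    S0[dwi.mask] = np.exp(beta[:, 0])

    degenerate = np.zeros(shape, dtype=bool)
    evals = np.linalg.eigvalsh(components_to_matrices(beta[:, 1:]))
    degenerate[dwi.mask] = evals[:, 0] < 0
    return TensorField(D=D, S0=S0, affine=dwi.affine, mask=dwi.mask, degenerate=degenerate)


def _orient_deterministic(evecs: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so each has non-negative dot with +x, then +y,
    then +z (first axis whose dot is non-negligible decides)."""
    out = evecs.copy()
    for i in range(out.shape[0]):
        v = out[i]
        for comp in v:
            if abs(comp) > 1e-12:
                if comp < 0:
                    out[i] = -v
                break
    return out


def eigensystem(D: np.ndarray, sym_tol: float = 1e-8) -> EigenSystem:
    """Sorted eigensystem of a symmetric 3x3 tensor.

    Eigenvalues are returned in descending order; eigenvectors (rows) are
    oriented deterministically.  When eigenvalues tie within
    ``EIGENVALUE_TIE_TOL`` (relative), ``degenerate_direction`` is set.
    """
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ContractError("tensor must be 3x3")
    scale = max(np.abs(D).max(), 1.0)
    if np.abs(D - D.T).max() > sym_tol * scale:
        raise ContractError("tensor is not symmetric within tolerance")
    w, v = np.linalg.eigh(0.5 * (D + D.T))
    order = np.argsort(w)[::-1]
    evals = w[order]
    evecs = _orient_deterministic(v[:, order].T)
    tie_scale = max(abs(evals[0]), EIGENVALUE_TIE_TOL)
    degenerate = bool(evals[0] - evals[1] < EIGENVALUE_TIE_TOL * tie_scale)
    return EigenSystem(evals=evals, evecs=evecs, degenerate_direction=degenerate)


def mean_diffusivity(evals: np.ndarray) -> float:
    """MD = (lambda1 + lambda2 + lambda3) / 3, in mm^2/s."""
    evals = np.asarray(evals, dtype=float)
    return float(evals.sum(axis=-1) / 3.0)


def fractional_anisotropy(evals: np.ndarray, undefined: float = np.nan) -> float:
    """Standard FA, clipped to [0, 1]; ``undefined`` for all-zero input."""
    evals = np.asarray(evals, dtype=float)
    norm = np.linalg.norm(evals)
    if norm == 0.0:
        return undefined
    md = evals.mean()
    fa = np.sqrt(1.5) * np.linalg.norm(evals - md) / norm
    return float(np.clip(fa, 0.0, 1.0))


def eigensystem_field(comp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised eigensystems for (..., 6) component stacks.

    Returns (evals, evecs) with evals (..., 3) descending and evecs
    (..., 3, 3) whose rows match evals.  Sign orientation is left to the
    caller; all consumers in this package use sign-invariant quantities.
    """
    w, v = np.linalg.eigh(components_to_matrices(comp))
    evals = w[..., ::-1]
    evecs = np.swapaxes(v, -1, -2)[..., ::-1, :]
    return evals, evecs
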