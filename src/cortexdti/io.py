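"""File formats and run configuration.

NIfTI-1 volumes are read and written through nibabel (sform preferred over
qform on read, both set on write); gradient tables use the FSL text
dialect (``bvals``: one whitespace-separated row; ``bvecs``: three rows,
one per image-coordinate axis).  Tensor fields are stored as a 4-D NIfTI
with six volumes in lower-triangular order plus S0 and degenerate-mask
companions.  Run configuration round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from cortexdti.cortical_profiles import RibbonLabels
from cortexdti.errors import FormatError
from cortexdti.tensor_fit import B0_THRESHOLD, TENSOR_COMPONENTS, TensorField


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI-1 volume; returns (data, affine).

    The affine follows nibabel's precedence (sform when valid, else
    qform, else the fallback header affine).
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    return np.asarray(img.dataobj), img.affine


def write_nifti(path, data: np.ndarray, affine: np.ndarray,
                description: str = "") -> None:
    """Write a NIfTI-1 volume with both sform and qform set to ``affine``."""
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    if description:
        img.header["descrip"] = description.encode()[:79]
    img.set_sform(affine, code=1)
    img.set_qform(affine, code=1)
    nib.save(img, str(path))


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an FSL-dialect gradient table.

    Returns (bvals (N,), bvecs (N, 3)); b>0 directions are normalised to
    unit length (with a warning when the input norms deviate by more than
    1e-3).  A zero direction with b>0, or a count mismatch, is a format
    error.
    """
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise FormatError("bvecs must be a 3xN (or Nx3) table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: one row per axis
    if len(bvals) != bvecs.shape[0]:
        raise FormatError(
            f"{len(bvals)} b-values but {bvecs.shape[0]} directions"
        )
    dw = bvals >= B0_THRESHOLD
    norms = np.linalg.norm(bvecs, axis=1)
    if np.any(dw & (norms < 1e-8)):
        raise FormatError("zero gradient direction with b > 0")
    if np.any(np.abs(norms[dw] - 1.0) > 1e-3):
        warnings.warn("normalising non-unit gradient directions", stacklevel=2)
    bvecs = bvecs.copy()
    bvecs[dw] /= norms[dw, None]
    bvecs[~dw] = 0.0
    return bvals, bvecs


def write_bvals_bvecs(bvals, bvecs, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, np.atleast_2d(np.asarray(bvals)), fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.8f")


def write_tensor_nifti(tensors: TensorField, stem) -> dict[str, Path]:
    """Write a tensor field as ``<stem>_tensor/_S0/_degenerate.nii.gz``."""
    stem = Path(stem)
    paths = {
        "tensor": stem.with_name(stem.name + "_tensor.nii.gz"),
        "S0": stem.with_name(stem.name + "_S0.nii.gz"),
        "degenerate": stem.with_name(stem.name + "_degenerate.nii.gz"),
    }
    write_nifti(paths["tensor"], tensors.D, tensors.affine,
                description="order " + ",".join(TENSOR_COMPONENTS))
    write_nifti(paths["S0"], tensors.S0, tensors.affine)
    write_nifti(paths["degenerate"], tensors.degenerate.astype(np.uint8), tensors.affine)
    return paths


def read_tensor_nifti(stem) -> TensorField:
    stem = Path(stem)
    D, affine = read_nifti(stem.with_name(stem.name + "_tensor.nii.gz"))
    S0, _ = read_nifti(stem.with_name(stem.name + "_S0.nii.gz"))
    degen, _ = read_nifti(stem.with_name(stem.name + "_degenerate.nii.gz"))
    return TensorField(
        D=D, S0=S0, affine=affine,
        mask=np.ones(S0.shape, dtype=bool),
        degenerate=degen.astype(bool),
    )


def write_ribbon(ribbon: RibbonLabels, stem) -> dict[str, Path]:
    """Write a label volume plus its JSON code -> region-name sidecar."""
    stem = Path(stem)
    paths = {
        "labels": stem.with_name(stem.name + "_ribbon.nii.gz"),
        "sidecar": stem.with_name(stem.name + "_ribbon.json"),
    }
    write_nifti(paths["labels"], ribbon.labels.astype(np.int32), ribbon.affine)
    paths["sidecar"].write_text(
        json.dumps({str(k): v for k, v in ribbon.region_map.items()}, indent=1)
    )
    return paths


def read_ribbon(stem) -> RibbonLabels:
    stem = Path(stem)
    labels, affine = read_nifti(stem.with_name(stem.name + "_ribbon.nii.gz"))
    sidecar = stem.with_name(stem.name + "_ribbon.json")
    region_map = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return RibbonLabels(labels=np.asarray(labels).astype(int), affine=affine,
                        region_map=region_map)


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML round-trippable)."""

    seed: int = 0
    output_dir: str = "cortexdti_out"
    # phantom / profile stage
    phantom_geometry: str = "slab"
    phantom_theta_deg: float = 30.0
    phantom_sigma_deg: float = 5.0
    dwi_snr: float = 0.0  # 0 -> noise-free
    step_h_mm: float = 0.5
    solver_tol: float = 1e-6
    angle_unit: str = "radians"
    # statistics / classification stage
    fdr_q: float = 0.05
    n_selection_runs: int = 25
    k_folds: int = 10

    def __post_init__(self) -> None:
        if self.step_h_mm <= 0 or self.solver_tol <= 0 or self.fdr_q <= 0:
            raise FormatError("tolerances and step sizes must be positive")
        if self.angle_unit not in ("radians", "degrees"):
            raise FormatError(f"unknown angle unit {self.angle_unit!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the scientific configuration (the output
        location does not affect results and is excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("output_dir")
        blob = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
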