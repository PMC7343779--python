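"""Head-movement and volumetric covariates.

Two nuisance/feature quantities accompany the diffusion metrics: a scalar
displacement index summarising between-volume head movement (used as a
GLM covariate), and structure volumes normalised by total intracranial
volume (TIV) expressed as fractions (e.g. ``GM_fr``, used both as a
covariate and a classification feature).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from cortexdti.errors import ContractError, ParameterError

#: radius (mm) of the sphere used to convert rotations to arc displacements
ROTATION_SPHERE_RADIUS_MM = 50.0


@dataclasses.dataclass
class RealignmentSeries:
    """Per-volume rigid-body realignment estimates, acquisition order.

    ``params`` is (n_volumes, 6): three translations in mm followed by
    three rotations in radians.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ContractError("realignment series must have 6 columns")
        if not np.all(np.isfinite(self.params)):
            raise ContractError("realignment estimates must be finite")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclasses.dataclass
class VolumeSummary:
    """Named structure volumes with TIV-normalised fractions."""

    volumes: dict[str, float]
    tiv: float
    fractions: dict[str, float]


def displacement_index(
    series: RealignmentSeries,
    convert_rotations: bool = True,
    rotation_radius_mm: float = ROTATION_SPHERE_RADIUS_MM,
    include_rotations: bool = True,
) -> float:
    """Mean absolute volume-to-volume change in realignment parameters.

    The six parameter traces are differentiated along acquisition order
    and the absolute differences averaged over every
    (transition x parameter) cell.  By default rotations are converted to
    millimetres as arc length on a ``rotation_radius_mm`` sphere before
    pooling, so the average is dimensionally coherent;
    ``convert_rotations=False`` reproduces raw pooling and
    ``include_rotations=False`` averages the three translations only.
    """
    if series.n_volumes < 2:
        raise ParameterError("displacement index needs at least 2 volumes")
    p = series.params.copy()
    if convert_rotations:
        p[:, 3:] *= rotation_radius_mm
    if not include_rotations:
        p = p[:, :3]
    return float(np.abs(np.diff(p, axis=0)).mean())


def volume_fractions(volumes: dict[str, float], tiv: float) -> VolumeSummary:
    """Normalise structure volumes by total intracranial volume.

    Each fraction is exactly ``volume / tiv``.  A structure volume larger
    than TIV triggers a plausibility warning (fractions are still
    computed); ``tiv <= 0`` is a parameter error.
    """
    if tiv <= 0:
        raise ParameterError("TIV must be positive")
    fractions = {}
    for name, vol in volumes.items():
        if vol < 0:
            raise ContractError(f"volume {name!r} is negative")
        if vol > tiv:
            warnings.warn(
                f"volume {name!r} ({vol} mm^3) exceeds TIV ({tiv} mm^3)",
                stacklevel=2,
            )
        fractions[name] = vol / tiv
    return VolumeSummary(volumes=dict(volumes), tiv=float(tiv), fractions=fractions)


def read_realignment(path) -> RealignmentSeries:
    """Read whitespace-delimited realignment parameters (one row per
    volume, 6 columns, FSL eddy-parameters dialect; extra columns beyond
    the first six are ignored)."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] < 6:
        raise ContractError(
            f"expected >= 6 realignment columns, found {arr.shape[1]}"
        )
    return RealignmentSeries(params=arr[:, :6])
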