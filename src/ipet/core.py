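"""Core containers shared across the pipeline.

Array conventions
-----------------
* 3-D volumes are numpy arrays indexed ``[z, y, x]``; volumes are cubic.
* 2-D images are indexed ``[y, x]``.
* The tilt axis is the image y axis; at 0 degrees the beam runs along z.
* A shift is an ``(dx, dy)`` pair in pixels, applied as a translation of the
  image content by ``+dx`` along x and ``+dy`` along y.
* Domains are ordered ``(Fab1, Fab2, Fc)`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DOMAIN_NAMES = ("Fab1", "Fab2", "Fc")
FAB1, FAB2, FC = 0, 1, 2

#: Protein partial specific volume used to convert molecular mass to an
#: enclosed density volume (about 0.81 Da per cubic angstrom).
MASS_TO_VOLUME_A3_PER_DA = 1.21


@dataclass
class DensityMap:
    """A cubic 3-D intensity grid with a physical voxel size in angstroms."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("density map must be a 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self):
        return self.data.shape

    @property
    def box_size(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "DensityMap":
        return DensityMap(self.data.copy(), self.voxel_size)


@dataclass
class TiltSeries:
    """An ordered stack of 2-D tilt projections of one particle.

    ``true_shifts`` records the translational jitter applied by the
    simulator (ground truth, absent for experimental data); ``shifts``
    carries the current alignment corrections, updated by refinement.
    """

    images: np.ndarray            # (n, ny, nx)
    angles: np.ndarray            # degrees, strictly increasing
    pixel_size: float             # angstrom per pixel
    true_shifts: np.ndarray | None = None   # (n, 2) applied (dx, dy)
    shifts: np.ndarray = None     # (n, 2) alignment corrections
    dose_note: str = ""

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, ny, nx) stack")
        if len(self.angles) != len(self.images):
            raise ValueError("one tilt angle per image required")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("tilt angles must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.shifts is None:
            self.shifts = np.zeros((len(self.images), 2), dtype=float)
        else:
            self.shifts = np.asarray(self.shifts, dtype=float)
            if self.shifts.shape != (len(self.images), 2):
                raise ValueError("shifts must be (n, 2)")
        if self.true_shifts is not None:
            self.true_shifts = np.asarray(self.true_shifts, dtype=float)
            if self.true_shifts.shape != (len(self.images), 2):
                raise ValueError("true_shifts must be (n, 2)")

    def __len__(self) -> int:
        return len(self.images)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalised")
    return v / n


@dataclass
class Conformation:
    """Three rigid domain poses plus their derived orientation vectors.

    ``centers`` are the domain mass centers in angstroms (rows ordered
    Fab1, Fab2, Fc). Each domain carries a *direction* vector (its minimum
    principal inertia axis, i.e. its long axis) and a *normal* vector (its
    maximum principal inertia axis, i.e. the normal of its flattest plane).
    ``rotations`` maps the template local frame (direction = local x,
    normal = local z) to the world frame, when the poses came from a
    template-based construction.
    """

    centers: np.ndarray                     # (3, 3) angstrom
    direction_vectors: np.ndarray           # (3, 3) unit rows
    normal_vectors: np.ndarray              # (3, 3) unit rows
    rotations: np.ndarray | None = None     # (3, 3, 3)
    source: str = "phantom"                 # phantom | fitted | pdb

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(3, 3)
        self.direction_vectors = np.array(
            [_unit(v) for v in np.asarray(self.direction_vectors, float)]
        )
        self.normal_vectors = np.array(
            [_unit(v) for v in np.asarray(self.normal_vectors, float)]
        )
        dots = np.abs(np.sum(self.direction_vectors * self.normal_vectors, axis=1))
        if np.any(dots > 1e-6):
            raise ValueError(
                "direction and normal vectors must be perpendicular per domain"
            )
        if self.rotations is not None:
            self.rotations = np.asarray(self.rotations, float).reshape(3, 3, 3)

    @classmethod
    def from_poses(cls, centers: np.ndarray, rotations: np.ndarray,
                   source: str = "phantom") -> "Conformation":
        """Build from rigid poses; local x is the direction, local z the normal."""
        rotations = np.asarray(rotations, float).reshape(3, 3, 3)
        dirs = rotations @ np.array([1.0, 0.0, 0.0])
        norms = rotations @ np.array([0.0, 0.0, 1.0])
        return cls(centers, dirs, norms, rotations=rotations, source=source)


@dataclass
class SoftMask:
    """A 2-D or 3-D weight field in [0, 1] with a tapered boundary."""

    weights: np.ndarray
    kind: str = "circular"          # circular | particle
    taper_width: float = 0.0        # pixels

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float32)
        if self.weights.ndim not in (2, 3):
            raise ValueError("mask must be 2-D or 3-D")
        if self.weights.min() < -1e-6 or self.weights.max() > 1 + 1e-6:
            raise ValueError("mask weights must lie in [0, 1]")
        np.clip(self.weights, 0.0, 1.0, out=self.weights)

    @property
    def inside(self) -> np.ndarray:
        """Boolean membership: weight of at least 0.5 counts as inside."""
        return self.weights >= 0.5


__all__ = [
    "DOMAIN_NAMES", "FAB1", "FAB2", "FC", "MASS_TO_VOLUME_A3_PER_DA",
    "DensityMap", "TiltSeries", "Conformation", "SoftMask",
]
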