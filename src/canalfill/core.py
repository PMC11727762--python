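"""Core containers shared across the pipeline.

Conventions
-----------
All volumes are indexed ``grid[ix, iy, iz]`` with

* ``+x`` medial, ``-x`` lateral (the coronal in-plane direction),
* ``+y`` anterior (the AP projection direction),
* ``+z`` proximal along the diaphyseal axis.

The ``x``–``z`` plane is therefore the coronal plane, in which loads are
applied and varus/valgus tilt is measured.  Physical coordinates are in mm;
``origin`` is the position of the center of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

AXIS_CONVENTION = "x=medial, y=anterior, z=proximal (coronal = x-z)"


@dataclass
class VoxelVolume:
    """A 3D grayscale grid with physical spacing and origin.

    Grayscale values are in arbitrary scanner units until calibrated to
    bone mineral density (mgHA/cm^3).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if any(n < 2 for n in self.grid.shape):
            raise ValueError("grid needs at least 2 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing entries must be > 0")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grayscale values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.grid.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(self.coords(0), self.coords(1), self.coords(2),
                           indexing="ij")

    def like(self, grid: np.ndarray) -> "VoxelVolume":
        """A new volume on the same lattice with different data."""
        return VoxelVolume(grid, self.spacing, self.origin, self.axes)


@dataclass
class LabelMasks:
    """Mutually disjoint tissue masks congruent with one :class:`VoxelVolume`.

    ``canal`` is the medullary cavity (marrow lumen of the diaphysis),
    ``trabecular`` the spongy interior of the metaphysis/epiphysis.  The
    union of all four masks covers the grid.
    """

    cortical: np.ndarray
    trabecular: np.ndarray
    canal: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.cortical, self.trabecular,
                                    self.canal, self.background)}
        if len(shapes) != 1:
            raise ValueError("all masks must share one shape")
        total = (self.cortical.astype(np.int8) + self.trabecular
                 + self.canal + self.background)
        if not np.all(total == 1):
            raise ValueError("masks must be disjoint and cover the grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cortical.shape

    def interior(self) -> np.ndarray:
        """Everything inside the cortical shell (canal + trabecular)."""
        return self.canal | self.trabecular

    def bone(self) -> np.ndarray:
        return self.cortical | self.trabecular | self.canal

    def copy(self) -> "LabelMasks":
        return LabelMasks(self.cortical.copy(), self.trabecular.copy(),
                          self.canal.copy(), self.background.copy())


@dataclass
class Radiograph2D:
    """Parallel-projection line-integral image.

    AP images are indexed ``[ix, iz]`` (projection along y), ML images
    ``[iy, iz]`` (projection along x); the two projection directions are
    orthogonal by construction.
    """

    pixels: np.ndarray
    spacing: tuple[float, float]
    view: str
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.view not in ("AP", "ML"):
            raise ValueError("view must be 'AP' or 'ML'")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("pixel spacing must be > 0")


@dataclass
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t`` (rotation then translation)."""

    rotation: np.ndarray = field(
        default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-9):
            raise ValueError("rotation must be orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_params(cls, tx: float = 0.0, ty: float = 0.0, tz: float = 0.0,
                    rx_deg: float = 0.0, ry_deg: float = 0.0,
                    rz_deg: float = 0.0) -> "RigidTransform":
        """Extrinsic x-y-z rotations in degrees plus translation in mm."""
        rot = Rotation.from_euler("xyz", [rx_deg, ry_deg, rz_deg],
                                  degrees=True)
        return cls(rot.as_matrix(), np.array([tx, ty, tz], dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self`` after ``other``: (self . other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def rotation_angle_deg(self) -> float:
        return float(np.degrees(
            Rotation.from_matrix(self.rotation).magnitude()))

    def almost_identity(self, atol_mm: float = 1e-9,
                        atol_deg: float = 1e-9) -> bool:
        return (np.linalg.norm(self.translation) < atol_mm
                and self.rotation_angle_deg() < atol_deg)
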