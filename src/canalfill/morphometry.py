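"""Virtual head resection, medullary canal segmentation, and the canal
fill ratios.

Three ratios quantify how completely a stemmed implant fills the canal:

* ``3D VFR``  — implant volume distal to the resection plane divided by the
  canal volume between the resection plane and the transverse level of the
  implant tip, computed by congruent voxel counting;
* ``2D metaphysis FR`` and ``2D diaphysis FR`` — implant-to-canal width
  ratios measured on the AP radiograph at a metaphyseal and a diaphyseal
  transverse line.

For concentric cylinders the construction gives VFR = (2D FR)^2 exactly,
which the test suite uses as an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelMasks, RigidTransform, VoxelVolume
from .densitometry import bmd_map
from .phantom import HumerusGeometry, ImplantSpec, voxelize_implant


class PerforationError(ValueError):
    """The implant breaches the cortical shell; the fill ratio is withheld."""

    def __init__(self, n_voxels: int):
        super().__init__(f"implant perforates cortical bone "
                         f"({n_voxels} voxels inside the cortex)")
        self.n_voxels = n_voxels


@dataclass
class ResectionPlane:
    """Anatomic-neck resection plane.

    With the 135 deg neck-shaft convention the plane normal lies at 45 deg
    to the shaft axis in the coronal (x-z) plane and points proximal-medial;
    voxels on the positive side of the plane are resected.
    """

    point: np.ndarray
    normal: np.ndarray
    inclination_deg: float = 135.0

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-9):
            self.normal = self.normal / n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal

    def signed_distance_grid(self, volume: VoxelVolume) -> np.ndarray:
        x, y, z = volume.meshgrid()
        return ((x - self.point[0]) * self.normal[0]
                + (y - self.point[1]) * self.normal[1]
                + (z - self.point[2]) * self.normal[2])

    def z_at_axis(self) -> float:
        """z where the plane crosses the shaft axis (x = y = 0)."""
        if abs(self.normal[2]) < 1e-12:
            raise ValueError("plane is parallel to the shaft axis")
        return float(self.point[2]
                     + (self.point[0] * self.normal[0]
                        + self.point[1] * self.normal[1]) / self.normal[2])


def default_resection_plane(geometry: HumerusGeometry) -> ResectionPlane:
    """Plane through the anatomic neck of the parametric phantom: 45 deg to
    the shaft axis in the coronal plane, tangent to the distal-lateral edge
    of the head sphere."""
    n = np.array([np.sin(np.radians(45.0)), 0.0, np.cos(np.radians(45.0))])
    point = geometry.head_center - geometry.head_radius * n
    return ResectionPlane(point, n)


@dataclass
class FillRatios:
    """The fill-ratio triplet for one specimen/implant combination."""

    vfr_3d: float
    metaphysis_fr_2d: float
    diaphysis_fr_2d: float
    perforated: bool = False

    def __post_init__(self) -> None:
        if self.perforated:
            return
        for name in ("vfr_3d", "metaphysis_fr_2d", "diaphysis_fr_2d"):
            v = getattr(self, name)
            if np.isnan(v):
                continue
            if not 0.0 < v <= 1.0 + 1e-9:
                raise ValueError(f"{name} = {v:.4f} outside (0, 1]")


# ---------------------------------------------------------------------------
# Resection
# ---------------------------------------------------------------------------


def resect_head(masks: LabelMasks, volume: VoxelVolume,
                plane: ResectionPlane) -> tuple[ResectionPlane, LabelMasks]:
    """Remove all bone voxels proximal to the resection plane.

    A plane that lies entirely above the bone leaves the masks unchanged
    (valid no-op); a plane that would remove every bone voxel is rejected.
    Idempotent for a fixed plane.
    """
    d = plane.signed_distance_grid(volume)
    cut = d > 0
    bone = masks.bone()
    removed = cut & bone
    if removed.sum() == bone.sum() and bone.any():
        raise ValueError("resection plane removes the entire bone")
    out = masks.copy()
    for m in (out.cortical, out.trabecular, out.canal):
        m &= ~cut
    out.background |= removed
    return plane, out


# ---------------------------------------------------------------------------
# Canal segmentation
# ---------------------------------------------------------------------------


def segment_canal(masks: LabelMasks | None = None,
                  bmd_volume: VoxelVolume | None = None,
                  method: str = "ground_truth",
                  plane: ResectionPlane | None = None,
                  cortical_threshold: float = 800.0,
                  closing_radius: int = 1) -> np.ndarray:
    """Segment the canal volume of interest (everything inside the cortical
    shell, distal to the resection).

    ``ground_truth`` passes the phantom's interior masks through.
    ``threshold`` reproduces the standard image-processing chain: threshold
    the BMD volume to get the cortical shell, close it morphologically,
    fill the shell slice-wise to obtain the interior, and keep the largest
    connected interior component.
    """
    if method == "ground_truth":
        if masks is None:
            raise ValueError("ground_truth method needs label masks")
        return masks.interior()
    if method != "threshold":
        raise ValueError("method must be 'ground_truth' or 'threshold'")
    if bmd_volume is None:
        raise ValueError("threshold method needs a BMD volume")

    # fill on the uncut shell (cross-sections stay closed rings), then
    # clip the interior by the resection plane afterwards
    cortical = bmd_volume.grid >= cortical_threshold
    if closing_radius > 0:
        ball = _ball(closing_radius)
        cortical = ndimage.binary_closing(cortical, structure=ball)

    # the shaft is an open tube in 3D, so hole filling works per z-slice
    interior = np.zeros_like(cortical)
    for k in range(cortical.shape[2]):
        sl = cortical[:, :, k]
        if not sl.any():
            continue
        interior[:, :, k] = ndimage.binary_fill_holes(sl) & ~sl
    if plane is not None:
        interior &= plane.signed_distance_grid(bmd_volume) <= 0
    labels, n = ndimage.label(interior)
    if n == 0:
        raise ValueError(
            "no interior component found: the thresholded cortical shell "
            f"({int(cortical.sum())} voxels at >= {cortical_threshold} "
            "mgHA/cm^3) encloses no cavity — solid bone or threshold too "
            "low/high")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    x, y, z = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return x * x + y * y + z * z <= r * r


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    inter = np.logical_and(a, b).sum()
    return float(2 * inter / (a.sum() + b.sum()))


# ---------------------------------------------------------------------------
# 3D volumetric fill ratio
# ---------------------------------------------------------------------------


def compute_vfr(canal_mask: np.ndarray, spec: ImplantSpec,
                pose: RigidTransform, plane: ResectionPlane,
                volume: VoxelVolume,
                cortical_mask: np.ndarray | None = None,
                implant_mask: np.ndarray | None = None,
                supersample: int = 1) -> float:
    """Volumetric canal fill ratio by congruent voxel counting.

    Numerator: implant volume (stem + cup) distal to the resection plane.
    Denominator: canal volume between the resection plane and the
    transverse level of the implant tip, both counted on the same lattice.
    ``canal_mask`` may be boolean or a fractional (partial-volume)
    occupancy; ``supersample > 1`` switches the implant voxelization to
    matching partial-volume counting.  If ``cortical_mask`` is given, any
    implant voxel center inside the cortex raises
    :class:`PerforationError` and the ratio is withheld.
    """
    if cortical_mask is not None:
        hard = voxelize_implant(spec, pose, volume) \
            if (implant_mask is None or implant_mask.dtype != bool) \
            else implant_mask
        n_perf = int((hard & cortical_mask).sum())
        if n_perf > 0:
            raise PerforationError(n_perf)
    if implant_mask is None:
        implant_mask = voxelize_implant(spec, pose, volume,
                                        supersample=supersample)
    d = plane.signed_distance_grid(volume)
    distal = d <= 0
    tip_z = float(pose.apply(np.zeros(3))[2])
    zc = volume.coords(2)
    above_tip = (zc >= tip_z)[None, None, :]
    num = float((implant_mask * distal).sum())
    den = float((canal_mask * (distal & above_tip)).sum())
    if den == 0:
        raise ValueError("empty canal region between resection plane and "
                         "implant tip")
    return num / den


# ---------------------------------------------------------------------------
# 2D fill ratios
# ---------------------------------------------------------------------------


def silhouette_ap(mask: np.ndarray) -> np.ndarray:
    """Binary AP silhouette of a voxel mask: projection along +y -> (x, z)."""
    return mask.any(axis=1)


def _width_at(sil: np.ndarray, z_index: int, spacing_x: float) -> float:
    col = sil[:, z_index]
    n = int(col.sum())
    return n * spacing_x


def default_measurement_levels(resection_z: float, diaphysis_top_z: float,
                               tip_z: float,
                               distal_diameter: float) -> tuple[float, float]:
    """Default transverse measurement lines: the metaphysis line halfway
    between the resection plane and the proximal end of the cylindrical
    diaphysis; the diaphysis line one stem-diameter above the implant tip."""
    meta_z = 0.5 * (resection_z + diaphysis_top_z)
    dia_z = tip_z + distal_diameter
    return meta_z, dia_z


def compute_2d_fill_ratios(implant_sil: np.ndarray, canal_sil: np.ndarray,
                           volume: VoxelVolume, metaphysis_z: float,
                           diaphysis_z: float) -> tuple[float, float]:
    """Width-ratio fill measures on the AP silhouettes.

    Each ratio is the implant silhouette width divided by the canal inner
    width on the same transverse line.  A line where the implant silhouette
    is empty (outside the implant extent) is rejected.
    """
    zc = volume.coords(2)
    out = []
    for z_level, label in ((metaphysis_z, "metaphysis"),
                           (diaphysis_z, "diaphysis")):
        k = int(np.argmin(np.abs(zc - z_level)))
        w_imp = _width_at(implant_sil, k, volume.spacing[0])
        w_can = _width_at(canal_sil, k, volume.spacing[0])
        if w_imp == 0:
            raise ValueError(f"{label} measurement line at z = "
                             f"{z_level:.1f} mm lies outside the implant")
        if w_can == 0:
            raise ValueError(f"{label} measurement line at z = "
                             f"{z_level:.1f} mm lies outside the canal")
        out.append(w_imp / w_can)
    return out[0], out[1]
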