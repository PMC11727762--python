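"""Grayscale-to-BMD calibration and volume-of-interest density metrics.

Calibration follows the three-anchor scheme used in patient-specific CT
densitometry: grayscale values of air, fat and muscle (measured in the scan
itself) are mapped to nominal hydroxyapatite-equivalent densities of
-840, -80 and 30 mgHA/cm^3 by piecewise-linear interpolation, which removes
intra- and inter-scanner intensity offsets.  Beyond the muscle anchor the
fat->muscle segment is extrapolated linearly so that cortical bone maps to
realistically high BMD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabelMasks, VoxelVolume

#: Nominal BMD of the calibration tissues, mgHA/cm^3.
BMD_AIR = -840.0
BMD_FAT = -80.0
BMD_MUSCLE = 30.0


@dataclass
class CalibrationAnchors:
    """Measured grayscale values of the three calibration tissues plus
    their nominal BMD values."""

    grayscale_air: float
    grayscale_fat: float
    grayscale_muscle: float
    bmd_air: float = BMD_AIR
    bmd_fat: float = BMD_FAT
    bmd_muscle: float = BMD_MUSCLE

    def __post_init__(self) -> None:
        if not (self.grayscale_air < self.grayscale_fat
                < self.grayscale_muscle):
            raise ValueError("anchor grayscales must be strictly "
                             "increasing: air < fat < muscle")

    @classmethod
    def from_phantom_patches(cls, patches: dict) -> "CalibrationAnchors":
        return cls(patches["air"]["mean"], patches["fat"]["mean"],
                   patches["muscle"]["mean"])


def bmd_map(grayscale: np.ndarray | float,
            anchors: CalibrationAnchors) -> np.ndarray:
    """Scalar piecewise-linear calibration map, vectorized.

    Exact at the three anchors; affine on each segment; linear
    extrapolation continuing the outer segments' slopes.  Monotone
    non-decreasing because the anchors are ordered in both coordinates.
    """
    g = np.asarray(grayscale, dtype=float)
    xs = np.array([anchors.grayscale_air, anchors.grayscale_fat,
                   anchors.grayscale_muscle])
    ys = np.array([anchors.bmd_air, anchors.bmd_fat, anchors.bmd_muscle])
    out = np.interp(g, xs, ys)
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[2] - ys[1]) / (xs[2] - xs[1])
    out = np.where(g < xs[0], ys[0] + (g - xs[0]) * lo_slope, out)
    out = np.where(g > xs[2], ys[2] + (g - xs[2]) * hi_slope, out)
    return out


def calibrate_bmd(volume: VoxelVolume,
                  anchors: CalibrationAnchors) -> VoxelVolume:
    """Convert a grayscale volume to BMD (mgHA/cm^3) voxel by voxel."""
    return volume.like(bmd_map(volume.grid, anchors))


# ---------------------------------------------------------------------------
# Volumes of interest
# ---------------------------------------------------------------------------


@dataclass
class CylinderVOI:
    """Axis-aligned cylindrical volume of interest in the bone frame:
    axis parallel to z through (cx, cy), spanning [z_lo, z_hi], mm."""

    cx: float
    cy: float
    radius: float
    z_lo: float
    z_hi: float

    def mask(self, volume: VoxelVolume) -> np.ndarray:
        x, y, z = volume.meshgrid()
        return ((np.hypot(x - self.cx, y - self.cy) <= self.radius)
                & (z >= self.z_lo) & (z <= self.z_hi))


@dataclass
class BoxVOI:
    """Axis-aligned box VOI, bounds in mm."""

    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float]

    def mask(self, volume: VoxelVolume) -> np.ndarray:
        xx, yy, zz = volume.meshgrid()
        return ((xx >= self.x[0]) & (xx <= self.x[1])
                & (yy >= self.y[0]) & (yy <= self.y[1])
                & (zz >= self.z[0]) & (zz <= self.z[1]))


@dataclass
class DensityMetrics:
    """The principal bone-density parameters of one specimen."""

    epi_cyl_bmd: float
    epi_cyl_bvtv: float
    meta_cyl_bvtv: float
    inf_sup_bmd: float

    def __post_init__(self) -> None:
        for v in (self.epi_cyl_bvtv, self.meta_cyl_bvtv):
            if not 0.0 <= v <= 1.0:
                raise ValueError("BV/TV must lie in [0, 1]")
        for v in (self.epi_cyl_bmd, self.inf_sup_bmd):
            if not np.isfinite(v):
                raise ValueError("BMD must be finite")


#: Default BV/TV bone threshold, mgHA/cm^3 (configurable).
DEFAULT_BONE_THRESHOLD = 250.0


def voi_bmd(bmd_volume: VoxelVolume, voi_mask: np.ndarray) -> float:
    """Mean BMD over a VOI by pixel counting."""
    n = int(voi_mask.sum())
    if n == 0:
        raise ValueError("empty VOI")
    return float(bmd_volume.grid[voi_mask].mean())


def voi_bvtv(bmd_volume: VoxelVolume, voi_mask: np.ndarray,
             threshold: float = DEFAULT_BONE_THRESHOLD) -> float:
    """Bone volume fraction: count(voxels >= threshold) / count(VOI)."""
    n = int(voi_mask.sum())
    if n == 0:
        raise ValueError("empty VOI")
    return float((bmd_volume.grid[voi_mask] >= threshold).sum() / n)


def measure_voi(bmd_volume: VoxelVolume, masks: LabelMasks,
                vois: dict | None = None,
                threshold: float = DEFAULT_BONE_THRESHOLD) -> DensityMetrics:
    """Compute the standard density metrics from named VOIs.

    ``vois`` maps the metric region names ``epi_cyl``, ``meta_cyl``,
    ``inf_sup`` to VOI objects with a ``mask(volume)`` method; when omitted,
    default cylinders are placed from the bone geometry (epiphysis = top
    quarter of the bone extent, metaphysis below it, inferior support =
    medial epiphyseal cylinder).  VOIs must intersect the volume.
    """
    if vois is None:
        vois = default_vois(bmd_volume, masks)
    for name in ("epi_cyl", "meta_cyl", "inf_sup"):
        if name not in vois:
            raise ValueError(f"missing VOI definition '{name}'")
    m = {k: v.mask(bmd_volume) for k, v in vois.items()}
    for name, mask in m.items():
        if not mask.any():
            raise ValueError(f"VOI '{name}' does not intersect the volume")
    return DensityMetrics(
        epi_cyl_bmd=voi_bmd(bmd_volume, m["epi_cyl"]),
        epi_cyl_bvtv=voi_bvtv(bmd_volume, m["epi_cyl"], threshold),
        meta_cyl_bvtv=voi_bvtv(bmd_volume, m["meta_cyl"], threshold),
        inf_sup_bmd=voi_bmd(bmd_volume, m["inf_sup"]),
    )


def default_vois(volume: VoxelVolume, masks: LabelMasks) -> dict:
    """Place the three default cylinders from the bone's z extent."""
    z_idx = np.where(masks.bone().any(axis=(0, 1)))[0]
    if z_idx.size == 0:
        raise ValueError("masks contain no bone")
    zc = volume.coords(2)
    z0, z1 = zc[z_idx[0]], zc[z_idx[-1]]
    span = z1 - z0
    return {
        "epi_cyl": CylinderVOI(0.0, 0.0, 6.0, z0 + 0.78 * span,
                               z0 + 0.95 * span),
        "meta_cyl": CylinderVOI(0.0, 0.0, 5.0, z0 + 0.58 * span,
                                z0 + 0.75 * span),
        "inf_sup": CylinderVOI(4.0, 0.0, 4.0, z0 + 0.80 * span,
                               z0 + 0.92 * span),
    }
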