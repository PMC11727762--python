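"""Synthetic data generation: humerus CT phantom, parametric stem implants,
parallel-projection radiographs, and optically tracked cyclic-loading
sequences.

The phantom is a geometric stand-in for a proximal-humerus CT scan: a
stacked-frustum shaft (cylindrical diaphysis, flaring metaphysis) capped by
a spherical head, each with a cortical shell, trabecular interior and a
medullary canal.  Ground-truth tissue masks are returned alongside the
grayscale volume so every downstream measurement can be validated against
known geometry.  Air/fat/muscle calibration patches are embedded in one
corner so densitometric calibration is self-contained.

The tracking generator emulates a dual-camera optical system recording
marker point clouds on four rigid bodies (embedding, bone, implant,
actuator) at 30 Hz during force-controlled cyclic loading
(220/520/820 N blocks, 1.5 Hz).  Marker noise defaults to 4.9 um per
coordinate, the accuracy class of such systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .core import LabelMasks, Radiograph2D, RigidTransform, VoxelVolume

# ---------------------------------------------------------------------------
# Humerus phantom
# ---------------------------------------------------------------------------

#: Default grayscale means per tissue class, arbitrary scanner units
#: (HU-like).  The calibration patches reuse the air/fat/muscle entries.
DEFAULT_GRAYSCALE = {
    "air": -1000.0,
    "fat": -100.0,
    "muscle": 40.0,
    "marrow": -50.0,
    "trabecular": 305.0,
    "cortical": 1500.0,
}


@dataclass
class HumerusGeometry:
    """Parametric proximal-humerus shape, all lengths in mm.

    The shaft axis is +z; z = 0 is the distal end of the modeled segment.
    The diaphysis is a tube (lumen radius ``canal_radius``, wall
    ``cortical_thickness``); the metaphysis flares linearly to
    ``metaphysis_outer_radius`` while the cortex thins to
    ``head_shell_thickness``; the head is a sphere of ``head_radius``
    centered ``head_medial_offset`` mm medial of the shaft axis.
    Setting ``metaphysis_length = head_radius = 0`` degenerates the phantom
    to a plain tube, which is what the analytic-oracle tests use.
    """

    canal_radius: float = 4.5
    cortical_thickness: float = 4.0
    diaphysis_outer_radius: float = 8.5
    diaphysis_length: float = 70.0
    metaphysis_length: float = 22.0
    metaphysis_outer_radius: float = 11.5
    head_radius: float = 16.0
    head_shell_thickness: float = 1.5
    head_medial_offset: float = 5.0
    neck_shaft_angle_deg: float = 135.0
    margin_xy: float = 5.0
    margin_z: float = 3.0

    def validate(self) -> None:
        if self.canal_radius <= 0:
            raise ValueError("canal_radius must be > 0")
        if self.cortical_thickness <= 0:
            raise ValueError("cortical_thickness must be > 0")
        if self.canal_radius + self.cortical_thickness \
                > self.diaphysis_outer_radius + 1e-12:
            raise ValueError(
                "inconsistent geometry: canal_radius + cortical_thickness "
                "must not exceed diaphysis_outer_radius")
        if self.metaphysis_length > 0 and \
                self.metaphysis_outer_radius < self.diaphysis_outer_radius:
            raise ValueError(
                "metaphysis_outer_radius must be >= diaphysis_outer_radius")
        if self.head_radius > 0 and \
                self.head_shell_thickness >= self.head_radius:
            raise ValueError(
                "head_shell_thickness must be smaller than head_radius")

    @property
    def neck_z(self) -> float:
        return self.diaphysis_length + self.metaphysis_length

    @property
    def head_center(self) -> np.ndarray:
        if self.head_radius <= 0:
            return np.array([0.0, 0.0, self.neck_z])
        return np.array([self.head_medial_offset, 0.0,
                         self.neck_z + 0.55 * self.head_radius])

    @property
    def shaft_axis(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])


@dataclass
class HumerusPhantom:
    """Bundle of a phantom volume, its ground-truth masks, the calibration
    patch bookkeeping and the generating geometry.

    Iterable so that ``volume, masks = generate_humerus_phantom(...)``
    unpacks as the two primary outputs.
    """

    volume: VoxelVolume
    masks: LabelMasks
    patches: dict
    geometry: HumerusGeometry
    grayscale: dict

    def __iter__(self):
        return iter((self.volume, self.masks))


def generate_humerus_phantom(
    geometry: HumerusGeometry | None = None,
    grayscale: dict | None = None,
    noise_sd: float = 20.0,
    spacing: float = 0.5,
    seed: int | None = 0,
) -> HumerusPhantom:
    """Voxelize the parametric humerus on an isotropic grid.

    Returns the grayscale volume (tissue means plus iid Gaussian noise of
    ``noise_sd`` scanner units), exact ground-truth masks, and the index
    slices plus true means of the air/fat/muscle calibration patches.
    Regeneration with the same seed is bit-identical.
    """
    geometry = geometry or HumerusGeometry()
    geometry.validate()
    gs = dict(DEFAULT_GRAYSCALE)
    if grayscale:
        gs.update(grayscale)
    g = geometry

    half_xy = max(g.diaphysis_outer_radius, g.metaphysis_outer_radius,
                  abs(g.head_center[0]) + g.head_radius) + g.margin_xy
    z_top = g.neck_z + (g.head_center[2] - g.neck_z + g.head_radius
                        if g.head_radius > 0 else 0.0) + g.margin_z
    nx = int(math.ceil(2 * half_xy / spacing))
    nz = int(math.ceil(z_top / spacing))
    origin = (-(nx - 1) / 2 * spacing, -(nx - 1) / 2 * spacing, 0.0)

    vol = VoxelVolume(np.zeros((nx, nx, nz), dtype=np.float32),
                      (spacing,) * 3, origin)
    x, y, z = vol.meshgrid()
    r_xy = np.hypot(x, y)

    # outer and inner (endosteal) radius profiles along the shaft
    outer_r = np.full(nz, np.nan)
    inner_r = np.full(nz, np.nan)
    zc = vol.coords(2)
    dia = zc < g.diaphysis_length
    outer_r[dia] = g.diaphysis_outer_radius
    inner_r[dia] = g.canal_radius
    if g.metaphysis_length > 0:
        meta = (zc >= g.diaphysis_length) & (zc < g.neck_z)
        frac = (zc[meta] - g.diaphysis_length) / g.metaphysis_length
        # sqrt flare: the metaphysis widens quickly above the diaphysis,
        # like the real bone, so the cup seats below the neck cut
        outer_r[meta] = (g.diaphysis_outer_radius
                         + np.sqrt(frac) * (g.metaphysis_outer_radius
                                            - g.diaphysis_outer_radius))
        thick = (g.cortical_thickness
                 + frac * (g.head_shell_thickness - g.cortical_thickness))
        inner_r[meta] = outer_r[meta] - thick

    shaft = r_xy < outer_r[None, None, :]
    shaft_interior = r_xy < inner_r[None, None, :]
    shaft &= np.isfinite(outer_r)[None, None, :]
    shaft_interior &= np.isfinite(inner_r)[None, None, :]

    if g.head_radius > 0:
        c = g.head_center
        d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        head = d2 < g.head_radius ** 2
        head_interior = d2 < (g.head_radius - g.head_shell_thickness) ** 2
    else:
        head = np.zeros_like(shaft)
        head_interior = head

    solid = shaft | head
    interior = shaft_interior | head_interior
    cortical = solid & ~interior
    canal = interior & (z < g.diaphysis_length)
    trabecular = interior & ~canal
    background = ~solid

    grid = np.full(vol.shape, gs["air"], dtype=np.float32)
    grid[canal] = gs["marrow"]
    grid[trabecular] = gs["trabecular"]
    grid[cortical] = gs["cortical"]

    # calibration patches: three cubes stacked along y in the -x corner
    patch_vox = max(4, int(round(3.0 / spacing)))
    patches = {}
    for i, name in enumerate(("air", "fat", "muscle")):
        sl = (slice(1, 1 + patch_vox),
              slice(1 + i * (patch_vox + 2), 1 + i * (patch_vox + 2)
                    + patch_vox),
              slice(1, 1 + patch_vox))
        grid[sl] = gs[name]
        patches[name] = {"slices": sl, "mean": gs[name]}

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise_sd,
                                 size=grid.shape).astype(np.float32)

    volume = vol.like(grid)
    masks = LabelMasks(cortical, trabecular, canal, background)
    return HumerusPhantom(volume, masks, patches, geometry, gs)


# ---------------------------------------------------------------------------
# Parametric implant
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImplantSpec:
    """Parametric humeral component: a tapered stem (frustum from distal to
    proximal diameter) carrying a cylindrical metaphyseal cup, with the
    field-standard 135 deg neck inclination.

    In the implant frame z = 0 is the stem tip and +z points proximal; the
    cup sits on [stem_length, stem_length + cup_height].
    """

    stem_type: str
    stem_length: float
    proximal_diameter: float
    distal_diameter: float
    cup_diameter: float
    cup_height: float
    neck_inclination_deg: float = 135.0

    def __post_init__(self) -> None:
        if self.stem_type not in ("short", "standard"):
            raise ValueError("stem_type must be 'short' or 'standard'")
        if self.stem_length <= 0:
            raise ValueError("stem_length must be > 0")
        if self.proximal_diameter <= 0 or self.distal_diameter <= 0:
            raise ValueError("stem diameters must be > 0")
        if self.cup_diameter < 0 or self.cup_height < 0:
            raise ValueError("cup dimensions must be >= 0")
        if abs(self.neck_inclination_deg - 135.0) > 1e-9:
            raise ValueError("neck inclination is fixed at 135 deg")

    @property
    def total_length(self) -> float:
        return self.stem_length + self.cup_height

    def radius_at(self, z: np.ndarray | float) -> np.ndarray:
        """Radius of the solid of revolution at height z (implant frame)."""
        z = np.asarray(z, dtype=float)
        r_d = self.distal_diameter / 2
        r_p = self.proximal_diameter / 2
        frac = np.clip(z / self.stem_length, 0.0, 1.0)
        r = r_d + frac * (r_p - r_d)
        if self.cup_height > 0 and self.cup_diameter > 0:
            r = np.where(z > self.stem_length, self.cup_diameter / 2, r)
        out = np.where((z < 0) | (z > self.total_length), 0.0, r)
        return out

    def analytic_volume(self) -> float:
        """Closed-form solid volume: stem frustum + cup cylinder, mm^3."""
        r_d = self.distal_diameter / 2
        r_p = self.proximal_diameter / 2
        stem = math.pi * self.stem_length / 3 * (r_d ** 2 + r_d * r_p
                                                 + r_p ** 2)
        cup = math.pi * (self.cup_diameter / 2) ** 2 * self.cup_height
        return stem + cup


def interior_occupancy(geometry: HumerusGeometry, volume: VoxelVolume,
                       supersample: int = 3) -> np.ndarray:
    """Fractional occupancy of the bone interior (canal + trabecular
    space) per voxel, by subvoxel midpoint sampling.

    Boolean masks quantize the boundary to whole voxels, which biases
    voxel-count volumes by several percent when a radius is commensurate
    with the lattice; averaging a ``supersample``^3 subgrid per voxel
    reduces that to well under 1%.  Used as the partial-volume ground
    truth for fill-ratio oracles.
    """
    g = geometry
    sp = volume.spacing
    acc = np.zeros(volume.shape, dtype=np.float64)
    offsets = (np.arange(supersample) + 0.5) / supersample - 0.5
    xc, yc, zc = (volume.coords(i) for i in range(3))
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                x = xc + ox * sp[0]
                y = yc + oy * sp[1]
                z = zc + oz * sp[2]
                inner = np.full(len(z), -1.0)
                dia = z < g.diaphysis_length
                inner[dia] = g.canal_radius
                if g.metaphysis_length > 0:
                    meta = (z >= g.diaphysis_length) & (z < g.neck_z)
                    frac = (z[meta] - g.diaphysis_length) \
                        / g.metaphysis_length
                    outer = (g.diaphysis_outer_radius
                             + np.sqrt(frac)
                             * (g.metaphysis_outer_radius
                                - g.diaphysis_outer_radius))
                    thick = (g.cortical_thickness
                             + frac * (g.head_shell_thickness
                                       - g.cortical_thickness))
                    inner[meta] = outer - thick
                r2d = np.hypot(x[:, None], y[None, :])
                inside = r2d[:, :, None] < inner[None, None, :]
                if g.head_radius > 0:
                    c = g.head_center
                    d2 = ((x[:, None, None] - c[0]) ** 2
                          + (y[None, :, None] - c[1]) ** 2
                          + (z[None, None, :] - c[2]) ** 2)
                    inside |= d2 < (g.head_radius
                                    - g.head_shell_thickness) ** 2
                acc += inside
    return acc / supersample ** 3


def generate_implant(spec: ImplantSpec, sections: int = 96) -> trimesh.Trimesh:
    """Closed triangulated surface of the implant (solid of revolution).

    The returned mesh is watertight; a non-watertight result is an internal
    failure and raises.  Voxelization onto a grid goes through
    :func:`voxelize_implant`, which uses the exact profile rather than the
    mesh.
    """
    r_d = spec.distal_diameter / 2
    r_p = spec.proximal_diameter / 2
    profile = [(0.0, 0.0), (r_d, 0.0), (r_p, spec.stem_length)]
    if spec.cup_height > 0 and spec.cup_diameter > 0:
        r_c = spec.cup_diameter / 2
        profile += [(r_c, spec.stem_length),
                    (r_c, spec.stem_length + spec.cup_height),
                    (0.0, spec.stem_length + spec.cup_height)]
    else:
        profile += [(0.0, spec.stem_length)]
    mesh = trimesh.creation.revolve(profile, sections=sections)
    mesh.merge_vertices()
    if not mesh.is_watertight:
        raise RuntimeError("implant surface generation produced a "
                           "non-watertight mesh")
    return mesh


def voxelize_implant(spec: ImplantSpec, pose: RigidTransform,
                     volume: VoxelVolume,
                     supersample: int = 1) -> np.ndarray:
    """Voxelize the posed implant onto a volume's lattice.

    With ``supersample = 1`` (default), a boolean mask of voxels whose
    centers lie inside the implant.  With ``supersample > 1``, the
    fractional occupancy per voxel from a subvoxel midpoint grid
    (partial-volume counting for high-accuracy volume ratios).
    ``pose`` maps implant-frame coordinates into the volume's physical
    frame.
    """
    if supersample > 1:
        acc = np.zeros(volume.shape, dtype=np.float64)
        offsets = (np.arange(supersample) + 0.5) / supersample - 0.5
        sp = volume.spacing
        for ox in offsets:
            for oy in offsets:
                for oz in offsets:
                    shifted = VoxelVolume(
                        np.empty(volume.shape, dtype=np.uint8),
                        volume.spacing,
                        (volume.origin[0] + ox * sp[0],
                         volume.origin[1] + oy * sp[1],
                         volume.origin[2] + oz * sp[2]))
                    acc += voxelize_implant(spec, pose, shifted)
        return acc / supersample ** 3
    if np.allclose(pose.rotation, np.eye(3), atol=1e-12):
        # axis-aligned fast path: separable radius test per z-slice
        xc = volume.coords(0) - pose.translation[0]
        yc = volume.coords(1) - pose.translation[1]
        lz = volume.coords(2) - pose.translation[2]
        r2d = np.hypot(xc[:, None], yc[None, :])
        prof = spec.radius_at(lz)
        prof[(lz < 0) | (lz > spec.total_length)] = -1.0
        return r2d[:, :, None] <= prof[None, None, :]
    x, y, z = volume.meshgrid()
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    local = pose.inverse().apply(pts)
    lz = local[:, 2]
    r = np.hypot(local[:, 0], local[:, 1])
    inside = (lz >= 0) & (lz <= spec.total_length) & (r <= spec.radius_at(lz))
    return inside.reshape(volume.shape)


# ---------------------------------------------------------------------------
# Radiographs
# ---------------------------------------------------------------------------

_VIEW_AXIS = {"AP": 1, "ML": 0}
_VIEW_DIR = {"AP": (0.0, 1.0, 0.0), "ML": (1.0, 0.0, 0.0)}


def simulate_radiograph(volume: VoxelVolume, view: str) -> Radiograph2D:
    """Parallel-beam line-integral projection of a volume.

    Each pixel is the sum of voxel values along the projection direction
    multiplied by the voxel length, i.e. a discrete line integral.  AP
    projects along +y onto the (x, z) plane; ML projects along +x onto
    (y, z).  Deterministic; no noise is added here.
    """
    if view not in _VIEW_AXIS:
        raise ValueError("view must be 'AP' or 'ML'")
    axis = _VIEW_AXIS[view]
    img = volume.grid.sum(axis=axis) * volume.spacing[axis]
    keep = [i for i in range(3) if i != axis]
    spacing = (volume.spacing[keep[0]], volume.spacing[keep[1]])
    return Radiograph2D(np.asarray(img, dtype=np.float64), spacing, view,
                        _VIEW_DIR[view])


# ---------------------------------------------------------------------------
# Cyclic-loading tracking sequences
# ---------------------------------------------------------------------------


@dataclass
class LoadProtocol:
    """Force-controlled cyclic loading: ordered (peak N, cycles) blocks at a
    fixed frequency, applied in the coronal plane at ``load_angle_deg`` from
    the implant axis.  The valley (minimum) force keeps the construct seated
    between peaks."""

    blocks: tuple = ((220.0, 1000), (520.0, 1000), (820.0, 1000))
    frequency_hz: float = 1.5
    load_angle_deg: float = 30.0
    valley_force_n: float = 20.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be > 0")
        for peak, cycles in self.blocks:
            if peak <= self.valley_force_n:
                raise ValueError("peak force must exceed valley force")
            if cycles < 1:
                raise ValueError("each block needs >= 1 cycle")


#: Default marker layouts, mm, in each body's local frame.  The embedding
#: (fixture) cloud spans the whole rig — a large, well-conditioned frame
#: keeps the lever-arm amplification of marker noise through the rigid-body
#: correction near the raw marker accuracy.  The bone cloud is a patch on
#: the medial calcar cortex; implant and actuator carry small tetrads.
DEFAULT_LAYOUTS = {
    "embedding": np.array([
        [0, 0, 0], [80, 0, 0], [0, 80, 0], [80, 80, 0],
        [0, 0, 40], [80, 0, 40], [0, 80, 40], [80, 80, 40.0]]),
    "bone": np.array([[0, 0, 0], [10, 0, 2], [0, 10, 2], [6, 6, 12.0],
                      [3, 8, 6], [8, 3, 6.0]]),
    "implant": np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0], [3, 3, 8.0]]),
    "actuator": np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [5, 5, 6.0]]),
}

#: Nominal body origins in the embedding (world) frame, mm.
DEFAULT_BODY_OFFSETS = {
    "embedding": np.array([-40.0, -40.0, -30.0]),
    "bone": np.array([8.0, 0.0, 20.0]),
    "implant": np.array([0.0, 0.0, 70.0]),
    "actuator": np.array([0.0, 0.0, 110.0]),
}


@dataclass
class TrackedSequence:
    """Marker point-cloud time series for the four rigid bodies.

    ``frames[body]`` has shape (n_frames, n_markers, 3) in mm.
    ``analysis_points`` maps the protocol landmarks a-g to frame indices:
    a = time-zero reference; (b, d, f) = valley of the final cycle of
    blocks 1-3 (block ends); (c, e, g) = the paired final-cycle peaks.
    ``ground_truth`` records every pose and deformation used to generate
    the data so estimators can be validated against it.
    """

    frames: dict
    times: np.ndarray
    frame_rate_hz: float
    analysis_points: dict
    block_slices: list
    ground_truth: dict

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def bodies(self) -> list:
        return list(self.frames)


def _check_layout(name: str, layout: np.ndarray) -> None:
    layout = np.asarray(layout, dtype=float)
    if layout.ndim != 2 or layout.shape[1] != 3 or layout.shape[0] < 4:
        raise ValueError(f"{name}: need >= 4 markers with 3 coordinates")
    centered = layout - layout.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 3:
        raise ValueError(f"{name}: marker layout is coplanar/degenerate; "
                         "pose would be unidentifiable")


def _ramp(frac_of_block: np.ndarray, hold_frac: float) -> np.ndarray:
    """Linear ramp reaching 1 at ``hold_frac`` of the block, then holding.

    Plastic settling is modeled as saturating before the final load cycle,
    so block-end landmarks see the full per-block increment.
    """
    return np.clip(frac_of_block / hold_frac, 0.0, 1.0)


def simulate_tracking_sequence(
    protocol: LoadProtocol | None = None,
    implant_subsidence_mm: Sequence[float] = (0.0, 0.0, 0.0),
    implant_tilt_deg: Sequence[float] = (0.0, 0.0, 0.0),
    bone_elastic_amplitude_um: Sequence[float] = (40.0, 60.0, 80.0),
    bone_plastic_drift_um: Sequence[float] = (10.0, 15.0, 20.0),
    marker_layouts: dict | None = None,
    noise_sd_um: float = 4.9,
    frame_rate_hz: float = 30.0,
    seed: int | None = 0,
    global_motion: Callable[[float], RigidTransform] | None = None,
    implant_motion: Callable[[float], RigidTransform] | None = None,
    actuator_gain_mm_per_n: float = 1e-3,
) -> TrackedSequence:
    """Generate a marker sequence for one cyclic-loading experiment.

    Per frame, marker positions are the rigid transform of each body's
    layout by its pose, plus (bone and implant bodies) a compressive
    deformation translation phase-locked to the load, plus iid Gaussian
    noise of ``noise_sd_um`` per coordinate.  The implant body rides on the
    bone, so its prescribed subsidence/tilt are exactly its motion relative
    to the bone body.  ``implant_subsidence_mm`` and ``implant_tilt_deg``
    give cumulative values reached at the end of each block (ramped within
    the block, saturating before the final cycle); alternatively
    ``implant_motion`` prescribes the full relative pose trajectory.
    ``global_motion``, if given, is a gauge transform applied to every body
    (e.g. rig drift); the embedding markers carry it, allowing downstream
    rigid-body correction to remove it.
    """
    protocol = protocol or LoadProtocol()
    layouts = {k: np.asarray(v, dtype=float)
               for k, v in (marker_layouts or DEFAULT_LAYOUTS).items()}
    for name in ("embedding", "bone", "implant", "actuator"):
        if name not in layouts:
            raise ValueError(f"missing marker layout for body '{name}'")
        _check_layout(name, layouts[name])

    n_blocks = len(protocol.blocks)
    for arr, label in ((implant_subsidence_mm, "implant_subsidence_mm"),
                       (implant_tilt_deg, "implant_tilt_deg"),
                       (bone_elastic_amplitude_um, "bone_elastic_amplitude"),
                       (bone_plastic_drift_um, "bone_plastic_drift")):
        if len(arr) != n_blocks:
            raise ValueError(f"{label} must have one entry per load block")

    fpc = frame_rate_hz / protocol.frequency_hz  # frames per load cycle
    block_frames = [int(round(c * fpc)) for _, c in protocol.blocks]
    n_frames = 1 + sum(block_frames)  # frame 0 = time-zero reference
    times = np.arange(n_frames) / frame_rate_hz

    load = np.full(n_frames, protocol.valley_force_n)
    elastic = np.zeros(n_frames)        # um, compressive, load-locked
    drift = np.zeros(n_frames)          # um, cumulative plastic
    subsidence = np.zeros(n_frames)     # mm, cumulative implant vs bone
    tilt = np.zeros(n_frames)           # deg, cumulative coronal
    block_slices = []
    analysis = {"a": 0}
    start = 1
    cum_drift = cum_sub = cum_tilt = 0.0
    letters = [("b", "c"), ("d", "e"), ("f", "g")]
    for k, ((peak, cycles), nf) in enumerate(zip(protocol.blocks,
                                                 block_frames)):
        idx = np.arange(nf)
        t_block = (idx + 1) / frame_rate_hz
        phase = 2 * np.pi * protocol.frequency_hz * t_block
        frac_load = (1 - np.cos(phase)) / 2
        sl = slice(start, start + nf)
        load[sl] = protocol.valley_force_n \
            + (peak - protocol.valley_force_n) * frac_load
        hold = max((nf - fpc) / nf, 1e-9)
        ramp = _ramp((idx + 1) / nf, hold)
        elastic[sl] = bone_elastic_amplitude_um[k] * frac_load
        drift[sl] = cum_drift + bone_plastic_drift_um[k] * ramp
        subsidence[sl] = cum_sub + (implant_subsidence_mm[k] - cum_sub) * ramp
        tilt[sl] = cum_tilt + (implant_tilt_deg[k] - cum_tilt) * ramp
        cum_drift += bone_plastic_drift_um[k]
        cum_sub = implant_subsidence_mm[k]
        cum_tilt = implant_tilt_deg[k]
        if k < len(letters):
            # final cycle spans the last fpc+1 frames; its opening valley
            # and mid-cycle peak are the analysis landmarks
            valley = start + nf - 1 - int(round(fpc))
            peak_f = start + nf - 1 - int(round(fpc / 2))
            analysis[letters[k][0]] = valley
            analysis[letters[k][1]] = peak_f
        block_slices.append(sl)
        start += nf

    # bone deformation: compressive translation along -z (um -> mm)
    bone_def = np.zeros((n_frames, 3))
    bone_def[:, 2] = -(elastic + drift) * 1e-3

    rel_poses = []
    for i in range(n_frames):
        if implant_motion is not None:
            rel = implant_motion(times[i])
        else:
            rot = Rotation.from_euler("y", tilt[i], degrees=True).as_matrix()
            rel = RigidTransform(rot, np.array([0.0, 0.0, -subsidence[i]]))
        rel_poses.append(rel)

    frames: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for body, layout in layouts.items():
        base = layout + DEFAULT_BODY_OFFSETS.get(body, 0.0)
        pts = np.empty((n_frames, len(layout), 3))
        for i in range(n_frames):
            if body == "embedding":
                p = base
            elif body == "bone":
                p = base + bone_def[i]
            elif body == "implant":
                centroid = base.mean(axis=0)
                p = rel_poses[i].apply(base - centroid) + centroid \
                    + bone_def[i]
            else:  # actuator follows the applied load
                p = base + np.array(
                    [0.0, 0.0, -actuator_gain_mm_per_n
                     * (load[i] - protocol.valley_force_n)])
            if global_motion is not None:
                p = global_motion(times[i]).apply(p)
            pts[i] = p
        if noise_sd_um > 0:
            pts = pts + rng.normal(0.0, noise_sd_um * 1e-3, size=pts.shape)
        frames[body] = pts

    ground_truth = {
        "load_n": load,
        "elastic_um": elastic,
        "drift_um": drift,
        "subsidence_mm": subsidence,
        "tilt_deg": tilt,
        "bone_deformation_mm": bone_def,
        "protocol": protocol,
        "noise_sd_um": noise_sd_um,
        "implant_subsidence_mm": tuple(implant_subsidence_mm),
        "implant_tilt_deg": tuple(implant_tilt_deg),
        "bone_elastic_amplitude_um": tuple(bone_elastic_amplitude_um),
        "bone_plastic_drift_um": tuple(bone_plastic_drift_um),
    }
    return TrackedSequence(frames, times, frame_rate_hz, analysis,
                           block_slices, ground_truth)
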