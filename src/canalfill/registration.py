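"""2D-3D rigid registration of the bone model to AP/ML radiographs and
implant pose correction.

The validation chain mirrors postoperative verification of a preoperative
plan: simulated parallel-projection radiographs of the implanted state are
registered against the preoperative 3D model, the implant pose is
re-estimated from its silhouette on both views, and the postoperative fill
ratios are recomputed with the corrected pose.

Dissimilarity is one minus the normalized cross-correlation of
Gaussian-smoothed gradient-magnitude images, summed over the two views —
invariant to projection intensity scaling.  Optimization is derivative-free
(Powell line searches, coarse-to-fine smoothing) over the 6-DOF pose with
seeded multi-starts; Powell handles the nearly flat axial-rotation
direction of the quasi-axisymmetric bone far better than a simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .core import Radiograph2D, RigidTransform, VoxelVolume
from .morphometry import FillRatios, ResectionPlane, compute_vfr
from .phantom import ImplantSpec, simulate_radiograph
from .planning import ImplantPlacement

_SMOOTH_SIGMA = 1.5


def pose_from_params(params: np.ndarray) -> RigidTransform:
    """6-vector (tx, ty, tz mm, rx, ry, rz deg) -> rigid transform."""
    return RigidTransform.from_params(*params[:3], *params[3:])


def params_from_pose(pose: RigidTransform) -> np.ndarray:
    rx, ry, rz = Rotation.from_matrix(pose.rotation).as_euler("xyz",
                                                              degrees=True)
    return np.array([*pose.translation, rx, ry, rz])


def transform_volume(volume: VoxelVolume,
                     pose: RigidTransform) -> VoxelVolume:
    """Resample a volume under a rigid transform about its center
    (linear interpolation)."""
    if len(set(volume.spacing)) != 1:
        raise ValueError("registration assumes isotropic spacing")
    sp = volume.spacing[0]
    center = (np.array(volume.shape) - 1) / 2
    rinv = pose.rotation.T
    offset = center - rinv @ (center + pose.translation / sp)
    grid = ndimage.affine_transform(volume.grid.astype(np.float32), rinv,
                                    offset=offset, order=1, mode="constant",
                                    cval=float(volume.grid.min()))
    return volume.like(grid)


def _feature_image(pixels: np.ndarray,
                   sigma: float = _SMOOTH_SIGMA) -> np.ndarray:
    gx, gy = np.gradient(pixels.astype(np.float64))
    mag = np.hypot(gx, gy)
    return ndimage.gaussian_filter(mag, sigma)


def _ncc(a: np.ndarray, b: np.ndarray,
         include: np.ndarray | None = None) -> float:
    if include is not None:
        a = a[include]
        b = b[include]
        if a.size == 0:
            return 0.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def metal_exclusion_mask(pixels: np.ndarray, threshold: float,
                         dilate: int = 3) -> np.ndarray:
    """Pixels dominated by implant metal (above ``threshold``), dilated so
    the metal's gradient skirt is excluded from bone registration too."""
    mask = pixels > threshold
    if dilate > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=dilate)
    return mask


@dataclass
class RegistrationResult:
    pose: RigidTransform
    residual: float
    converged: bool
    n_evaluations: int


def register_bone(volume: VoxelVolume, rad_ap: Radiograph2D,
                  rad_ml: Radiograph2D,
                  initial: RigidTransform | None = None,
                  n_starts: int = 3, seed: int = 0,
                  maxiter: int = 20,
                  residual_threshold: float = 0.1,
                  exclude_ap: np.ndarray | None = None,
                  exclude_ml: np.ndarray | None = None) -> RegistrationResult:
    """Recover the rigid pose of the bone in the radiograph frame.

    The initial pose must be within the capture range of the optimizer
    (about +/-10 mm and +/-15 deg of truth).  Optimization is
    coarse-to-fine: a heavily smoothed gradient image first (wide capture
    basin), then the sharp one for precision.  ``exclude_ap``/``exclude_ml``
    mask pixels to ignore (e.g. implant metal on postoperative images; see
    :func:`metal_exclusion_mask`).  Non-convergence (residual above
    ``residual_threshold``) is flagged, and the best pose found is still
    returned.
    """
    evals = [0]

    def downsample2(img: np.ndarray) -> np.ndarray:
        return ndimage.zoom(np.asarray(img, dtype=np.float32), 0.5, order=1)

    # pyramid: (volume, target AP, target ML, include AP, include ML,
    #           gradient sigma, Powell iteration cap)
    coarse_vol = VoxelVolume(downsample2(volume.grid),
                             tuple(2 * s for s in volume.spacing),
                             volume.origin)
    stages = []
    for scale, sigma, iters in ((2, 2.0, maxiter), (1, _SMOOTH_SIGMA, 4)):
        if scale == 2:
            vol_s = coarse_vol
            ap_s, ml_s = downsample2(rad_ap.pixels), downsample2(
                rad_ml.pixels)
            inc_ap = None if exclude_ap is None else \
                downsample2(exclude_ap.astype(np.float32)) < 0.25
            inc_ml = None if exclude_ml is None else \
                downsample2(exclude_ml.astype(np.float32)) < 0.25
        else:
            vol_s = volume
            ap_s, ml_s = rad_ap.pixels, rad_ml.pixels
            inc_ap = None if exclude_ap is None else ~exclude_ap
            inc_ml = None if exclude_ml is None else ~exclude_ml
        stages.append((vol_s, _feature_image(ap_s, sigma),
                       _feature_image(ml_s, sigma), inc_ap, inc_ml, sigma,
                       iters))

    def make_loss(stage):
        vol_s, t_ap, t_ml, inc_ap, inc_ml, sigma, _ = stage

        def loss(params: np.ndarray) -> float:
            evals[0] += 1
            moved = transform_volume(vol_s, pose_from_params(params))
            ap = _feature_image(simulate_radiograph(moved, "AP").pixels,
                                sigma)
            ml = _feature_image(simulate_radiograph(moved, "ML").pixels,
                                sigma)
            return 2.0 - _ncc(ap, t_ap, inc_ap) - _ncc(ml, t_ml, inc_ml)

        return loss

    x0 = params_from_pose(initial) if initial is not None else np.zeros(6)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        start = x0 if s == 0 else x0 + rng.normal(0, [1, 1, 1, 2, 2, 2])
        x = start
        for stage in stages:
            res = optimize.minimize(make_loss(stage), x, method="Powell",
                                    options={"xtol": 1e-3, "ftol": 1e-9,
                                             "maxiter": stage[-1]})
            x = res.x
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-4:
            break
    pose = pose_from_params(best.x)
    return RegistrationResult(pose, float(best.fun),
                              bool(best.fun < residual_threshold), evals[0])


# ---------------------------------------------------------------------------
# Implant pose correction
# ---------------------------------------------------------------------------


@dataclass
class PoseDeviation:
    """Planned-to-implanted pose deviation, decomposed in a fixed order:
    varus/valgus (coronal, about +y) first, then axial rotation (about
    +z), then a residual out-of-plane rotation (about +x), then
    translation.  The order is fixed because Euler-order changes the
    numbers; :meth:`compose` round-trips the full transform."""

    varus_valgus_deg: float
    axial_rotation_deg: float
    residual_rotation_deg: float
    translation_mm: np.ndarray

    @classmethod
    def from_transform(cls, delta: RigidTransform) -> "PoseDeviation":
        vv, ax, res = Rotation.from_matrix(delta.rotation).as_euler(
            "yzx", degrees=True)
        return cls(float(vv), float(ax), float(res),
                   np.asarray(delta.translation, dtype=float))

    def compose(self) -> RigidTransform:
        rot = Rotation.from_euler(
            "yzx", [self.varus_valgus_deg, self.axial_rotation_deg,
                    self.residual_rotation_deg], degrees=True).as_matrix()
        return RigidTransform(rot, self.translation_mm)

    def is_zero(self, atol_mm: float = 1e-9, atol_deg: float = 1e-9) -> bool:
        return (np.linalg.norm(self.translation_mm) < atol_mm
                and abs(self.varus_valgus_deg) < atol_deg
                and abs(self.axial_rotation_deg) < atol_deg
                and abs(self.residual_rotation_deg) < atol_deg)


class ImplantProjector:
    """Renders smoothed implant silhouettes on the AP and ML views for a
    trial pose, on the lattice of a reference volume.

    The in/out test is a linear ramp of about one voxel width rather than
    a hard threshold, so the silhouettes — and hence the matching loss —
    vary continuously with pose instead of jumping at voxel-center
    crossings."""

    def __init__(self, spec: ImplantSpec, volume: VoxelVolume):
        self.spec = spec
        self.volume = volume
        x, y, z = volume.meshgrid()
        self._pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
        self._ramp = 0.7 * float(volume.spacing[0])

    def mask(self, pose: RigidTransform) -> np.ndarray:
        return self.soft_mask(pose) >= 0.5

    def soft_mask(self, pose: RigidTransform) -> np.ndarray:
        local = pose.inverse().apply(self._pts)
        lz = local[:, 2]
        r = np.hypot(local[:, 0], local[:, 1])
        w = self._ramp
        radial = np.clip((self.spec.radius_at(lz) - r) / w + 0.5, 0.0, 1.0)
        axial = np.clip(np.minimum(lz, self.spec.total_length - lz) / w
                        + 0.5, 0.0, 1.0)
        return (radial * axial).reshape(self.volume.shape)

    def silhouettes(self, pose: RigidTransform) -> tuple[np.ndarray,
                                                         np.ndarray]:
        m = self.soft_mask(pose)
        ap = ndimage.gaussian_filter(m.max(axis=1), _SMOOTH_SIGMA)
        ml = ndimage.gaussian_filter(m.max(axis=0), _SMOOTH_SIGMA)
        return ap, ml


def implant_silhouettes_from_radiographs(
        rad_ap: Radiograph2D, rad_ml: Radiograph2D,
        bone_volume: VoxelVolume, bone_pose: RigidTransform,
        threshold: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Extract the implant silhouette from postoperative radiographs by
    subtracting the registered bone's own projection; the residual above
    ``threshold`` is the metal silhouette."""
    moved = transform_volume(bone_volume, bone_pose)
    ap_bone = simulate_radiograph(moved, "AP").pixels
    ml_bone = simulate_radiograph(moved, "ML").pixels
    sil_ap = (rad_ap.pixels - ap_bone) > threshold
    sil_ml = (rad_ml.pixels - ml_bone) > threshold
    return (ndimage.gaussian_filter(sil_ap.astype(float), _SMOOTH_SIGMA),
            ndimage.gaussian_filter(sil_ml.astype(float), _SMOOTH_SIGMA))


def correct_implant_pose(
        planned: ImplantPlacement, bone_registration: RegistrationResult,
        target_sil_ap: np.ndarray, target_sil_ml: np.ndarray,
        volume: VoxelVolume, n_starts: int = 2, seed: int = 0,
        maxiter: int = 20) -> tuple[ImplantPlacement, PoseDeviation]:
    """Re-estimate the implant pose from its radiograph silhouettes.

    The optimization runs in the radiograph frame, starting from the
    planned pose carried through the registered bone pose; the deviation is
    corrected_pose o planned_pose^-1 expressed in the bone frame and
    decomposed into varus/valgus, axial rotation and translation.
    Registration failure propagates.
    """
    if not bone_registration.converged:
        raise ValueError("bone registration did not converge; implant "
                         "correction would be unreliable")
    bone_pose = bone_registration.pose
    projector = ImplantProjector(planned.spec, volume)
    pose0 = bone_pose.compose(planned.pose)
    # parametrize the update as rotation about the implant's mid-axis
    # point plus translation: decouples tilt from shift, which are a
    # near-degenerate diagonal valley when rotating about the world origin.
    # rotation about the implant's own axis is not searched: the stem and
    # cup are solids of revolution, so it is invisible in any silhouette.
    center = pose0.apply(np.array([0.0, 0.0, planned.spec.total_length / 2]))

    def update(params: np.ndarray) -> RigidTransform:
        rot = Rotation.from_euler("xy", params[3:], degrees=True).as_matrix()
        t = params[:3] + center - rot @ center
        return RigidTransform(rot, t).compose(pose0)

    def loss(params: np.ndarray) -> float:
        ap, ml = projector.silhouettes(update(params))
        return 2.0 - _ncc(ap, target_sil_ap) - _ncc(ml, target_sil_ml)

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        start = np.zeros(5) if s == 0 else rng.normal(0, [0.5, 0.5, 0.5,
                                                          1, 1])
        res = optimize.minimize(loss, start, method="Powell",
                                options={"xtol": 1e-3, "ftol": 1e-9,
                                         "maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-5:
            break

    corrected_world = update(best.x)
    corrected_bone = bone_pose.inverse().compose(corrected_world)
    delta = corrected_bone.compose(planned.pose.inverse())
    deviation = PoseDeviation.from_transform(delta)
    corrected = ImplantPlacement(planned.spec, corrected_bone)
    return corrected, deviation


def compute_postop_vfr(corrected: ImplantPlacement, canal_mask: np.ndarray,
                       plane: ResectionPlane, volume: VoxelVolume,
                       cortical_mask: np.ndarray | None = None) -> float:
    """Postoperative volumetric fill ratio at the corrected pose — the
    same congruent-voxelization computation as the preoperative one."""
    return compute_vfr(canal_mask, corrected.spec, corrected.pose, plane,
                       volume, cortical_mask=cortical_mask)
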