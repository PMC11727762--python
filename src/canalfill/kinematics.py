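"""Rigid-body kinematics from tracked marker point clouds.

The chain mirrors standard optical-metrology practice: fit the embedding
(fixture) body's rigid pose per frame and invert it to express all bodies
in the fixed embedding frame; then extract, at the protocol's analysis
points a-g,

* implant subsidence and coronal tilt relative to the bone body at the end
  of each load block (deltas a->b, a->d, a->f),
* bone micromotion as the hysteresis width of the final load cycle
  (deltas b->c, d->e, f->g), and
* total bone deformation from the time-zero reference to each block end.

Poses are least-squares rigid fits (Kabsch: SVD of the cross-covariance
with reflection correction).  Bone deformation metrics use the marker-
cloud centroid, the natural low-noise point-cloud statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import RigidTransform
from .phantom import TrackedSequence

MM_TO_UM = 1e3


@dataclass
class PoseFit:
    pose: RigidTransform
    rms_mm: float


def estimate_rigid_pose(reference: np.ndarray,
                        current: np.ndarray) -> PoseFit:
    """Least-squares rigid transform mapping ``reference`` onto
    ``current`` (corresponding rows), via SVD of the cross-covariance with
    reflection correction.  Degenerate (collinear) point sets are rejected
    because their pose is unidentifiable.
    """
    ref = np.asarray(reference, dtype=float)
    cur = np.asarray(current, dtype=float)
    if ref.shape != cur.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 corresponding points")
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-9) < 2:
        raise ValueError("collinear/degenerate point set: rigid pose "
                         "unidentifiable")
    cur_c = cur - cur.mean(axis=0)
    h = ref_c.T @ cur_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cur.mean(axis=0) - rot @ ref.mean(axis=0)
    pose = RigidTransform(rot, t)
    rms = float(np.sqrt(np.mean(np.sum(
        (pose.apply(ref) - cur) ** 2, axis=1))))
    return PoseFit(pose, rms)


def correct_rigid_motion(seq: TrackedSequence) -> TrackedSequence:
    """Express all bodies in the embedding frame.

    Per frame, the rigid pose of the embedding markers relative to the
    first frame is fitted, inverted, and applied to every body; embedding
    markers become stationary up to noise.  Applying the correction twice
    is idempotent up to numerical tolerance.
    """
    if "embedding" not in seq.frames:
        raise ValueError("sequence has no embedding body; rigid-body "
                         "correction impossible")
    emb = seq.frames["embedding"]
    ref = emb[0]
    out = {body: np.empty_like(pts) for body, pts in seq.frames.items()}
    for i in range(seq.n_frames):
        inv = estimate_rigid_pose(ref, emb[i]).pose.inverse()
        for body, pts in seq.frames.items():
            out[body][i] = inv.apply(pts[i])
    return TrackedSequence(out, seq.times, seq.frame_rate_hz,
                           seq.analysis_points, seq.block_slices,
                           seq.ground_truth)


# ---------------------------------------------------------------------------
# Outcome metrics
# ---------------------------------------------------------------------------


@dataclass
class StabilityMetrics:
    """Implant subsidence (mm, positive = distal migration) and coronal
    tilt (deg) relative to the bone at each block end (a->b, a->d, a->f)."""

    s_implant_mm: dict
    alpha_implant_deg: dict


@dataclass
class BoneLoadingMetrics:
    """Bone micromotion (hysteresis width, um) within the final cycle of
    each block, and total bone deformation (um) from the time-zero
    reference to each block end."""

    s_bone_hw_um: dict
    s_bone_tot_um: dict


def _relative_implant_pose(seq: TrackedSequence, i_ref: int,
                           i_cur: int) -> tuple[RigidTransform, np.ndarray]:
    bone = estimate_rigid_pose(seq.frames["bone"][i_ref],
                               seq.frames["bone"][i_cur]).pose
    imp = estimate_rigid_pose(seq.frames["implant"][i_ref],
                              seq.frames["implant"][i_cur]).pose
    rel = bone.inverse().compose(imp)
    centroid_ref = seq.frames["implant"][i_ref].mean(axis=0)
    return rel, centroid_ref


def coronal_tilt_deg(rotation: np.ndarray) -> float:
    """Coronal-plane (about +y) component of a rotation, degrees."""
    return float(Rotation.from_matrix(rotation).as_euler(
        "yzx", degrees=True)[0])


def implant_stability(seq: TrackedSequence,
                      blocks=("220", "520", "820")) -> StabilityMetrics:
    """Implant pose change relative to the bone body at the block-end
    analysis points b, d, f versus the reference a.

    Subsidence is the displacement of the implant centroid along the bone
    frame's -z axis (positive distal); tilt is the coronal-plane rotation
    component.
    """
    ap = seq.analysis_points
    needed = ["a", "b", "d", "f"]
    if any(k not in ap for k in needed):
        raise ValueError(f"analysis points {needed} must all be defined")
    s, alpha = {}, {}
    for name, point in zip(blocks, ("b", "d", "f")):
        rel, c0 = _relative_implant_pose(seq, ap["a"], ap[point])
        disp = rel.apply(c0) - c0
        s[name] = float(-disp[2])
        alpha[name] = coronal_tilt_deg(rel.rotation)
    return StabilityMetrics(s, alpha)


def bone_loading(seq: TrackedSequence, blocks=("220", "520", "820"),
                 component: str = "magnitude") -> BoneLoadingMetrics:
    """Bone centroid displacement metrics, in um.

    Hysteresis width: valley-to-peak displacement within the final cycle
    of each block (b->c, d->e, f->g).  Total deformation: reference-to-
    block-end displacement (a->b, a->d, a->f).  ``component`` selects the
    3D ``magnitude`` (default) or the along-axis ``axial`` (|z|)
    displacement.
    """
    ap = seq.analysis_points
    pairs_hw = [("b", "c"), ("d", "e"), ("f", "g")]
    needed = {p for pair in pairs_hw for p in pair} | {"a"}
    if any(k not in ap for k in needed):
        raise ValueError("analysis points a-g must all be defined")
    if component not in ("magnitude", "axial"):
        raise ValueError("component must be 'magnitude' or 'axial'")

    def centroid(i: int) -> np.ndarray:
        return seq.frames["bone"][i].mean(axis=0)

    def norm(v: np.ndarray) -> float:
        if component == "axial":
            return float(abs(v[2]))
        return float(np.linalg.norm(v))

    hw, tot = {}, {}
    for name, (valley, peak) in zip(blocks, pairs_hw):
        hw[name] = norm(centroid(ap[peak]) - centroid(ap[valley])) * MM_TO_UM
        tot[name] = norm(centroid(ap[valley]) - centroid(ap["a"])) * MM_TO_UM
    return BoneLoadingMetrics(hw, tot)


def find_analysis_points(seq: TrackedSequence) -> dict:
    """Recover the a-g frame indices from the actuator body's
    load-synchronous displacement (for sequences lacking the sidecar).

    The actuator tracks the applied force, so within each block the final
    valley/peak pair is located from its centroid z trace.
    """
    act_z = seq.frames["actuator"].mean(axis=1)[:, 2]
    fpc = int(round(seq.frame_rate_hz
                    * 1.0 / seq.ground_truth["protocol"].frequency_hz)) \
        if seq.ground_truth else None
    points = {"a": 0}
    letters = [("b", "c"), ("d", "e"), ("f", "g")]
    for k, sl in enumerate(seq.block_slices[:3]):
        seg = act_z[sl]
        n = len(seg)
        if fpc is None or fpc >= n:
            raise ValueError("cannot locate final cycle within block")
        base = n - fpc - 1
        final = seg[base:]
        valley = int(np.argmax(final)) + base + sl.start
        peak = int(np.argmin(final)) + base + sl.start
        points[letters[k][0]] = min(valley, peak)
        points[letters[k][1]] = max(valley, peak)
    return points
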