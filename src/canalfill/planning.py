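"""Virtual implant selection inside a segmented canal and specimen
grouping by fill ratio.

The planner inserts each catalog entry along the shaft axis, centered on
the canal, with the cup seated at the resection plane, checks for cortical
perforation, and evaluates the volumetric fill ratio.  ``best_fit`` keeps
the largest-volume admissible component; ``target_ratio`` keeps the
admissible component whose fill ratio is closest to the requested value,
which is how low/high fill-ratio groups are constructed deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import LabelMasks, RigidTransform, VoxelVolume
from .morphometry import (FillRatios, PerforationError, ResectionPlane,
                          compute_vfr)
from .phantom import ImplantSpec, voxelize_implant

#: Fill-ratio threshold separating low from high groups (low: vfr < 0.72;
#: a ratio of exactly 0.72 is assigned to the high group).
FILL_RATIO_THRESHOLD = 0.72


class GroupLabel(Enum):
    Standard_low = "Standard_low"
    Standard_high = "Standard_high"
    SS_low = "SS_low"
    SS_high = "SS_high"


@dataclass
class ImplantPlacement:
    """A catalog component with its 6-DOF pose in the bone frame and the
    fill ratios it achieves."""

    spec: ImplantSpec
    pose: RigidTransform
    fill_ratios: FillRatios | None = None

    def vfr(self) -> float:
        if self.fill_ratios is None or np.isnan(self.fill_ratios.vfr_3d):
            raise ValueError("fill ratios not computed for this placement")
        return self.fill_ratios.vfr_3d


def default_catalog() -> list[ImplantSpec]:
    """A graded short/standard stem catalog.

    Diameters step in 1 mm increments; short stems are 35 mm, standard
    60 mm, each with a matching metaphyseal cup line.  The range is chosen
    so phantom cohorts can realize fill ratios from roughly 0.5 to 1.0.
    """
    catalog = []
    for stem_type, length in (("short", 35.0), ("standard", 60.0)):
        for d_prox in (6.0, 7.0, 8.0, 9.0):
            for d_cup in (10.0, 12.0, 14.0):
                catalog.append(ImplantSpec(
                    stem_type=stem_type, stem_length=length,
                    proximal_diameter=d_prox,
                    distal_diameter=max(d_prox - 1.0, 2.0),
                    cup_diameter=d_cup, cup_height=10.0))
    return catalog


def _nominal_pose(spec: ImplantSpec, canal_mask: np.ndarray,
                  volume: VoxelVolume, plane: ResectionPlane,
                  proud_mm: float = 0.0) -> RigidTransform:
    """Axis-aligned insertion: centered on the distal canal, cup top at the
    resection plane (optionally ``proud_mm`` above it)."""
    idx = np.argwhere(canal_mask)
    if idx.size == 0:
        raise ValueError("empty canal mask")
    xc = volume.coords(0)
    yc = volume.coords(1)
    # center on the distal third of the canal, where the stem must track
    z_idx = idx[:, 2]
    distal = idx[z_idx <= np.percentile(z_idx, 33)]
    cx = float(xc[distal[:, 0]].mean())
    cy = float(yc[distal[:, 1]].mean())
    z_top = plane.z_at_axis() + proud_mm
    return RigidTransform(np.eye(3),
                          np.array([cx, cy, z_top - spec.total_length]))


def evaluate_placement(spec: ImplantSpec, canal_mask: np.ndarray,
                       masks: LabelMasks, volume: VoxelVolume,
                       plane: ResectionPlane,
                       proud_offsets=(0.0, 1.0, 2.0)) -> ImplantPlacement:
    """Place one catalog entry, resolving perforation by small proximal
    shifts; raises :class:`PerforationError` if none succeeds."""
    last_err: PerforationError | None = None
    for proud in proud_offsets:
        pose = _nominal_pose(spec, canal_mask, volume, plane, proud)
        try:
            vfr = compute_vfr(canal_mask, spec, pose, plane, volume,
                              cortical_mask=masks.cortical)
        except PerforationError as err:
            last_err = err
            continue
        fr = FillRatios(vfr, np.nan, np.nan)
        return ImplantPlacement(spec, pose, fr)
    raise last_err if last_err is not None else ValueError(
        "placement failed without perforation report")


def fit_implant(canal_mask: np.ndarray, masks: LabelMasks,
                volume: VoxelVolume, plane: ResectionPlane,
                catalog: list[ImplantSpec] | None = None,
                mode: str = "best_fit",
                target_ratio: float | None = None,
                stem_type: str | None = None) -> ImplantPlacement:
    """Select a component from the catalog.

    ``best_fit``: the largest-volume entry admitting a non-perforating
    pose.  ``target_ratio``: the entry whose achieved fill ratio is closest
    to ``target_ratio`` without perforation.  Ties break toward the shorter
    stem (less invasive).  The result does not depend on catalog order.
    """
    catalog = catalog if catalog is not None else default_catalog()
    if not catalog:
        raise ValueError("catalog is empty")
    if stem_type is not None:
        catalog = [s for s in catalog if s.stem_type == stem_type]
        if not catalog:
            raise ValueError(f"no '{stem_type}' entries in catalog")
    if mode == "target_ratio" and target_ratio is None:
        raise ValueError("target_ratio mode needs a target value")

    placements: list[ImplantPlacement] = []
    failures: list[tuple[ImplantSpec, PerforationError]] = []
    for spec in catalog:
        try:
            placements.append(evaluate_placement(spec, canal_mask, masks,
                                                 volume, plane))
        except PerforationError as err:
            failures.append((spec, err))
    if not placements:
        smallest = min(failures, key=lambda f: f[0].analytic_volume())
        raise PerforationError(smallest[1].n_voxels)

    if mode == "best_fit":
        key = lambda p: (p.spec.analytic_volume(), -p.spec.stem_length)
        return max(placements, key=key)
    if mode == "target_ratio":
        key = lambda p: (-abs(p.vfr() - target_ratio), -p.spec.stem_length)
        return max(placements, key=key)
    raise ValueError("mode must be 'best_fit' or 'target_ratio'")


def assign_group(placement: ImplantPlacement,
                 threshold: float = FILL_RATIO_THRESHOLD) -> GroupLabel:
    """Map (stem type, fill ratio) to one of the four study groups."""
    low = placement.vfr() < threshold
    if placement.spec.stem_type == "standard":
        return GroupLabel.Standard_low if low else GroupLabel.Standard_high
    return GroupLabel.SS_low if low else GroupLabel.SS_high
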