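"""Readers and writers for the pipeline's on-disk formats.

Volumes go to MetaImage (.mhd/.raw) or NIfTI (.nii.gz) via SimpleITK;
label masks are unsigned-8-bit volumes in the same formats; implant
surfaces are binary STL via trimesh; radiographs are 16-bit TIFF; tracking
sequences are tidy CSV (frame, time_s, body, marker_id, x_mm, y_mm, z_mm)
with a JSON sidecar holding analysis-point indices and ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile
import trimesh

from .core import LabelMasks, Radiograph2D, VoxelVolume
from .phantom import TrackedSequence

_LABEL_VALUES = {"background": 0, "canal": 1, "trabecular": 2, "cortical": 3}


def _to_sitk(grid: np.ndarray, volume: VoxelVolume) -> sitk.Image:
    # SimpleITK expects (z, y, x) memory order
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    return img


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a grayscale volume as .mhd/.raw or .nii.gz by extension."""
    path = Path(path)
    sitk.WriteImage(_to_sitk(volume.grid.astype(np.float32), volume),
                    str(path))
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    img = sitk.ReadImage(str(path))
    grid = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelVolume(grid, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_masks(masks: LabelMasks, volume: VoxelVolume,
                path: str | Path) -> Path:
    labels = np.zeros(masks.shape, dtype=np.uint8)
    for name, value in _LABEL_VALUES.items():
        if value:
            labels[getattr(masks, name)] = value
    sitk.WriteImage(_to_sitk(labels, volume), str(Path(path)))
    return Path(path)


def read_masks(path: str | Path) -> LabelMasks:
    img = sitk.ReadImage(str(path))
    labels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return LabelMasks(cortical=labels == _LABEL_VALUES["cortical"],
                      trabecular=labels == _LABEL_VALUES["trabecular"],
                      canal=labels == _LABEL_VALUES["canal"],
                      background=labels == _LABEL_VALUES["background"])


def write_stl(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    path = Path(path)
    mesh.export(str(path))
    return path


def write_radiograph(rad: Radiograph2D, path: str | Path) -> Path:
    """16-bit TIFF; intensities rescaled to the full range, with the scale
    recorded in the TIFF description for round-tripping."""
    path = Path(path)
    lo, hi = float(rad.pixels.min()), float(rad.pixels.max())
    scale = (hi - lo) or 1.0
    data = np.round((rad.pixels - lo) / scale * 65535).astype(np.uint16)
    meta = {"view": rad.view, "spacing": list(rad.spacing),
            "lo": lo, "hi": hi, "direction": list(rad.direction)}
    tifffile.imwrite(path, data, description=json.dumps(meta))
    return path


def read_radiograph(path: str | Path) -> Radiograph2D:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    pixels = data.astype(np.float64) / 65535 * (meta["hi"] - meta["lo"]) \
        + meta["lo"]
    return Radiograph2D(pixels, tuple(meta["spacing"]), meta["view"],
                        tuple(meta["direction"]))


def write_tracking(seq: TrackedSequence, csv_path: str | Path,
                   sidecar_path: str | Path | None = None) -> Path:
    csv_path = Path(csv_path)
    rows = []
    for body, pts in seq.frames.items():
        n_frames, n_markers, _ = pts.shape
        frame_idx = np.repeat(np.arange(n_frames), n_markers)
        marker_idx = np.tile(np.arange(n_markers), n_frames)
        flat = pts.reshape(-1, 3)
        rows.append(pd.DataFrame({
            "frame": frame_idx, "time_s": seq.times[frame_idx],
            "body": body, "marker_id": marker_idx,
            "x_mm": flat[:, 0], "y_mm": flat[:, 1], "z_mm": flat[:, 2]}))
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False)

    sidecar_path = Path(sidecar_path) if sidecar_path \
        else csv_path.with_suffix(".json")
    gt = {}
    for key, val in seq.ground_truth.items():
        if isinstance(val, np.ndarray):
            gt[key] = val.tolist()
        elif hasattr(val, "__dict__"):
            gt[key] = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(val).items()}
        else:
            gt[key] = list(val) if isinstance(val, tuple) else val
    sidecar = {"frame_rate_hz": seq.frame_rate_hz,
               "analysis_points": seq.analysis_points,
               "block_slices": [[s.start, s.stop] for s in seq.block_slices],
               "ground_truth": gt}
    sidecar_path.write_text(json.dumps(sidecar))
    return csv_path


def read_tracking(csv_path: str | Path,
                  sidecar_path: str | Path | None = None) -> TrackedSequence:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path \
        else csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    frames = {}
    times = None
    for body, sub in df.groupby("body", sort=False):
        sub = sub.sort_values(["frame", "marker_id"])
        n_frames = sub["frame"].nunique()
        n_markers = sub["marker_id"].nunique()
        frames[body] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy().reshape(
            n_frames, n_markers, 3)
        if times is None:
            times = sub.drop_duplicates("frame")["time_s"].to_numpy()
    return TrackedSequence(
        frames, times, meta["frame_rate_hz"], meta["analysis_points"],
        [slice(a, b) for a, b in meta["block_slices"]],
        meta.get("ground_truth", {}))
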