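"""File formats: TIFF videos, OPD maps, CSV tables, YAML configs, JSON
metrics, model checkpoints, and config hashing for provenance.

Conventions
-----------
* Hologram videos are multi-page 16-bit grayscale TIFFs.  Intensities are
  stored as ``round(I * HOLOGRAM_SCALE)`` (documented in the TIFF
  description), giving ~4.8 decimal digits of dynamic range — far below the
  synthetic noise floor.
* OPD maps are multi-page 32-bit float TIFFs; the description notes that
  values are optical path delays in nm.
* Ground truth, detections and tracks are plain CSVs with fixed headers.
* All configs are YAML mappings of dataclass fields; ``config_hash`` is the
  SHA-256 of the canonical JSON rendering, used for provenance stamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .holosim import GroundTruthRecord
from .segtrack import CellTrack, DetectionRecord, ProjectionSet

__all__ = [
    "HOLOGRAM_SCALE",
    "write_video_tiff",
    "read_video_tiff",
    "write_opd_tiff",
    "read_opd_tiff",
    "write_truth_csv",
    "read_truth_csv",
    "detections_to_frame",
    "tracks_to_frame",
    "write_detections_csv",
    "write_tracks_csv",
    "write_projection_set",
    "read_projection_set",
    "write_yaml",
    "read_yaml",
    "dataclass_to_dict",
    "write_metrics_json",
    "config_hash",
    "save_model",
    "load_model",
]

#: Fixed gain applied when quantizing hologram intensities to 16 bits.
HOLOGRAM_SCALE = 10000.0

TRUTH_COLUMNS = ["frame", "cell_id", "row", "col", "rot_x", "rot_y", "rot_z", "label"]
DETECTION_COLUMNS = [
    "frame", "cell_id", "row", "col", "area", "ecc",
    "major", "minor", "circularity", "size", "kept",
]


def write_video_tiff(frames: np.ndarray, path) -> None:
    """Write a (T, H, W) float video as a multi-page 16-bit TIFF."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3:
        raise ValueError("frames must be a (T, H, W) array")
    quantized = np.clip(np.round(frames * HOLOGRAM_SCALE), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path, quantized, photometric="minisblack",
        description=json.dumps({"scale": HOLOGRAM_SCALE, "quantity": "intensity"}),
    )


def read_video_tiff(path) -> np.ndarray:
    """Read a hologram video TIFF back to float intensities (T, H, W)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.float64) / HOLOGRAM_SCALE


def write_opd_tiff(opd: np.ndarray, path) -> None:
    """Write one or more OPD maps (nm) as a 32-bit float multi-page TIFF."""
    arr = np.asarray(opd, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("opd must be a 2-D map or a (T, H, W) stack")
    tifffile.imwrite(
        path, arr, photometric="minisblack",
        description=json.dumps({"units": "nm", "quantity": "optical path delay"}),
    )


def read_opd_tiff(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.float64)


def write_truth_csv(records: list[GroundTruthRecord], path) -> None:
    rows = [
        {
            "frame": r.frame_index,
            "cell_id": r.cell_id,
            "row": r.centroid[0],
            "col": r.centroid[1],
            "rot_x": r.orientation[0],
            "rot_y": r.orientation[1],
            "rot_z": r.orientation[2],
            "label": r.class_label,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _detection_row(det: DetectionRecord, cell_id: int, kept: bool) -> dict:
    return {
        "frame": det.frame_index,
        "cell_id": cell_id,
        "row": det.centroid[0],
        "col": det.centroid[1],
        "area": det.area,
        "ecc": det.eccentricity,
        "major": det.major_axis_length,
        "minor": det.minor_axis_length,
        "circularity": det.circularity,
        "size": det.equivalent_diameter,
        "kept": int(kept),
    }


def detections_to_frame(
    detections: list[DetectionRecord], kept: list[bool] | None = None
) -> pd.DataFrame:
    """Detections table; ``cell_id`` is -1 (no track identity yet)."""
    if kept is None:
        kept = [True] * len(detections)
    rows = [_detection_row(d, -1, k) for d, k in zip(detections, kept)]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def tracks_to_frame(tracks: list[CellTrack]) -> pd.DataFrame:
    rows = [_detection_row(d, t.cell_id, True) for t in tracks for d in t.detections]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def write_detections_csv(detections, path, kept=None) -> None:
    detections_to_frame(detections, kept).to_csv(path, index=False)


def write_tracks_csv(tracks, path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def write_projection_set(projset: ProjectionSet, root) -> Path:
    """Write one cell's crops as ``<root>/cell_<id>/`` with per-frame TIFFs
    and an ``index.json`` (cell id, optional label, frame list)."""
    cell_dir = Path(root) / f"cell_{projset.cell_id:05d}"
    cell_dir.mkdir(parents=True, exist_ok=True)
    for frame_idx, crop in zip(projset.frame_indices, projset.crops):
        write_video_tiff(crop[None], cell_dir / f"frame_{frame_idx:05d}.tif")
    index = {
        "cell_id": projset.cell_id,
        "label": projset.label,
        "frames": list(map(int, projset.frame_indices)),
        "pad_size": projset.pad_size,
    }
    (cell_dir / "index.json").write_text(json.dumps(index, indent=2, sort_keys=True))
    return cell_dir


def read_projection_set(cell_dir) -> ProjectionSet:
    cell_dir = Path(cell_dir)
    index = json.loads((cell_dir / "index.json").read_text())
    crops = np.stack(
        [read_video_tiff(cell_dir / f"frame_{f:05d}.tif")[0] for f in index["frames"]]
    )
    return ProjectionSet(
        cell_id=index["cell_id"],
        crops=crops,
        frame_indices=index["frames"],
        pad_size=index["pad_size"],
        label=index["label"],
    )


def dataclass_to_dict(obj) -> dict:
    """Dataclass -> plain dict with JSON/YAML-safe scalar values."""
    if not dataclasses.is_dataclass(obj):
        raise TypeError(f"{type(obj).__name__} is not a dataclass")
    def clean(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        if isinstance(v, (list, dict, str, int, float, bool)) or v is None:
            return v
        return v
    return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}


def write_yaml(data, path) -> None:
    if dataclasses.is_dataclass(data) and not isinstance(data, type):
        data = dataclass_to_dict(data)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_yaml(path) -> dict:
    loaded = yaml.safe_load(Path(path).read_text())
    return {} if loaded is None else loaded


def write_metrics_json(metrics: dict, path) -> None:
    def default(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        raise TypeError(f"not JSON-serializable: {type(v).__name__}")
    Path(path).write_text(json.dumps(metrics, indent=2, sort_keys=True, default=default))


def config_hash(config) -> str:
    """SHA-256 of the canonical JSON rendering of a config (dataclass or
    mapping); stamped into run outputs for provenance."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclass_to_dict(config)
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def save_model(model, path) -> None:
    """Checkpoint a FusionModel: architecture JSON + weight arrays (npz)."""
    from .fusionnet import FusionModel  # local import avoids a cycle

    if not isinstance(model, FusionModel):
        raise TypeError("save_model expects a FusionModel")
    meta = {
        "n_views": model.n_views,
        "n_classes": model.n_classes,
        "share_weights": model.share_weights,
        "backbone": dataclass_to_dict(model.backbone_config),
    }
    weights = {f"w{i:04d}": p.value for i, p in enumerate(model.parameters())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **weights)


def load_model(path):
    from .fusionnet import BackboneConfig, FusionModel

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        backbone = meta["backbone"]
        backbone["block_channels"] = tuple(backbone["block_channels"])
        backbone["block_strides"] = tuple(backbone["block_strides"])
        model = FusionModel(
            meta["n_views"],
            BackboneConfig(**backbone),
            n_classes=meta["n_classes"],
            share_weights=meta["share_weights"],
        )
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"w{i:04d}"]
    return model
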