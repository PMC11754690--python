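"""End-to-end pipeline runner: simulate -> reconstruct -> detect/track ->
export projections -> train -> evaluate, with every stage's output written
to a run directory together with provenance (config hash, seed).

Stage outputs are files on disk so a run is inspectable and restartable.
Any stage failure raises :class:`PipelineError` carrying the stage name and
a machine-readable error code.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as hio
from .fusionnet import FusionModel, TrainConfig, evaluate, make_splits, train
from .holosim import FlowScene, simulate_video
from .optics import OpticalConfig
from .types import HologramFrame
from .phantoms import default_phantom_sampler
from .reconstruct import hologram_to_opd, locate_carrier, stability_maps
from .segtrack import (
    FilterCriteria,
    TrackCriteria,
    detect_cells,
    extract_projection_sets,
    filter_detections,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("holoflow")


class PipelineError(RuntimeError):
    """A stage failure with a stable, machine-readable identity."""

    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run depends on.

    A persisted RunConfig (plus the software version) fully determines every
    stage's output: the global ``seed`` reseeds simulation, splits and
    training, and all stage settings are explicit fields.
    """

    out_dir: str = "run"
    seed: int = 0
    log_level: str = "INFO"
    scene: FlowScene = field(default_factory=FlowScene)
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    track_criteria: TrackCriteria = field(default_factory=TrackCriteria)
    min_projections: int = 1
    k_views: int = 2
    train_config: TrainConfig = field(default_factory=TrainConfig)
    center_crop: int | None = 96

    def stamped(self) -> dict:
        """Provenance record: config dict plus its hash and seed."""
        cfg = {
            f.name: (hio.dataclass_to_dict(getattr(self, f.name))
                     if dataclasses.is_dataclass(getattr(self, f.name))
                     else getattr(self, f.name))
            for f in dataclasses.fields(self)
        }
        return {"config": cfg, "config_hash": hio.config_hash(cfg), "seed": self.seed}


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Outputs: ``video.tif`` + ``truth.csv`` + ``config.yaml`` (simulate),
    ``opd.tif`` + ``stability.json`` (reconstruct), ``detections.csv`` +
    ``tracks.csv`` (segtrack), ``projections/`` (export), ``model.npz`` +
    ``history.csv`` + ``metrics.json`` (train/evaluate), and
    ``provenance.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_metrics_json(config.stamped(), out / "provenance.json")
    hio.write_yaml(config.stamped()["config"], out / "config.yaml")

    # --- simulate ---------------------------------------------------------
    try:
        scene = replace(config.scene, seed=config.seed)
        optics = config.optics.snap_carrier(scene.frame_shape)
        video, truth = simulate_video(scene, default_phantom_sampler(), optics)
        hio.write_video_tiff(video, out / "video.tif")
        hio.write_truth_csv(truth, out / "truth.csv")
        logger.info("simulate: %d frames, %d truth records", video.shape[0], len(truth))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("simulate", "internal", str(exc)) from exc

    # --- reconstruct ------------------------------------------------------
    try:
        mean_frame = video.mean(axis=0)
        peak = locate_carrier(mean_frame)
        opd_stack = np.stack(
            [
                hologram_to_opd(
                    frame,
                    optics.wavelength,
                    background=mean_frame,
                    peak=peak,
                    positive_bias=True,
                ).opd
                for frame in video
            ]
        )
        hio.write_opd_tiff(opd_stack, out / "opd.tif")
        stability = stability_maps(opd_stack)
        hio.write_metrics_json(
            {
                "mean_temporal_std_nm": stability.mean_temporal_std,
                "mean_spatial_std_nm": stability.mean_spatial_std,
            },
            out / "stability.json",
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("reconstruct", "internal", str(exc)) from exc

    # --- detect / track / export projections ------------------------------
    try:
        projsets, background, tracks = extract_projection_sets(
            video,
            fringe_period=1.0 / optics.carrier_frequency,
            filter_criteria=config.filter_criteria,
            track_criteria=config.track_criteria,
            min_projections=config.min_projections,
        )
        detections, kept = [], []
        for i, frame in enumerate(video):
            found = detect_cells(
                HologramFrame(intensity=frame, frame_index=i),
                background,
                fringe_period=1.0 / optics.carrier_frequency,
            )
            passed = {id(d) for d in filter_detections(found, config.filter_criteria)}
            detections.extend(found)
            kept.extend(id(d) in passed for d in found)
        hio.write_detections_csv(detections, out / "detections.csv", kept)
        hio.write_tracks_csv(tracks, out / "tracks.csv")
        truth_df = hio.read_truth_csv(out / "truth.csv")
        proj_dir = out / "projections"
        labeled = []
        for ps in projsets:
            label = _majority_label(ps, tracks, truth_df)
            ps.label = label
            hio.write_projection_set(ps, proj_dir)
            labeled.append(ps)
        logger.info("segtrack: %d tracks, %d projection sets", len(tracks), len(labeled))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("segtrack", "internal", str(exc)) from exc

    # --- train / evaluate --------------------------------------------------
    usable = [ps for ps in labeled if ps.label is not None and len(ps.frame_indices) >= config.k_views]
    skipped = len(labeled) - len(usable)
    if skipped:
        logger.info("train: excluding %d cells with < %d projections or no label", skipped, config.k_views)
    if not usable:
        raise PipelineError("train", "empty-dataset", "empty dataset: no usable projection sets")
    labels = np.array([ps.label for ps in usable])
    if np.unique(labels).size < 2:
        raise PipelineError("train", "empty-dataset", "empty dataset: fewer than 2 classes present")
    x = _stack_views(usable, config.k_views, config.center_crop)
    try:
        n_folds = min(5, int(np.min(np.bincount(labels))))
        n_folds = max(n_folds, 2)
        split = make_splits(labels, fold=config.seed % n_folds, n_folds=n_folds)
        model = FusionModel(config.k_views, seed=config.seed)
        cfg = replace(config.train_config, seed=config.seed)
        history = train(
            model, x[split.train], labels[split.train], cfg,
            x_val=x[split.val] if len(split.val) else None,
            y_val=labels[split.val] if len(split.val) else None,
        )
        history.to_csv(out / "history.csv", index=False)
        hio.save_model(model, out / "model.npz")
        eval_idx = split.test if len(split.test) else split.train
        result = evaluate(model, x[eval_idx], labels[eval_idx])
        hio.write_metrics_json(
            {
                "accuracy": result["accuracy"],
                "per_class_recall": result["per_class_recall"],
                "n": result["n"],
                "config_hash": hio.config_hash(config.stamped()["config"]),
            },
            out / "metrics.json",
        )
        np.savetxt(out / "confusion.csv", result["confusion"], fmt="%d", delimiter=",")
        logger.info("evaluate: accuracy %.3f on %d cells", result["accuracy"], result["n"])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("train", "internal", str(exc)) from exc
    return out


def _majority_label(projset, tracks, truth_df, radius: float = 40.0):
    """Label a projection set by matching its track's detections to the
    nearest ground-truth centroid in each frame (majority vote)."""
    track = next((t for t in tracks if t.cell_id == projset.cell_id), None)
    if track is None:
        return None
    votes: list[int] = []
    for det in track.detections:
        sub = truth_df[truth_df["frame"] == det.frame_index]
        if sub.empty:
            continue
        d2 = (sub["row"] - det.centroid[0]) ** 2 + (sub["col"] - det.centroid[1]) ** 2
        j = d2.idxmin()
        if float(d2.loc[j]) <= radius**2:
            votes.append(int(sub.loc[j, "label"]))
    if not votes:
        return None
    return int(np.bincount(votes).argmax())


def _stack_views(projsets, k: int, center_crop: int | None) -> np.ndarray:
    """Stack the first ``k`` crops of each projection set (frame order) into
    a standardized (N, k, 1, H, W) float32 tensor."""
    crops = np.stack([ps.crops[:k] for ps in projsets]).astype(np.float32)
    if center_crop is not None and center_crop < crops.shape[-1]:
        lo = (crops.shape[-1] - center_crop) // 2
        crops = crops[..., lo : lo + center_crop, lo : lo + center_crop]
    mean = crops.mean(axis=(2, 3), keepdims=True)
    std = crops.std(axis=(2, 3), keepdims=True)
    crops = (crops - mean) / np.maximum(std, 1e-6)
    return crops[:, :, None, :, :]
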