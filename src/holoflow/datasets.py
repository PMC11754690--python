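"""Per-cell multi-projection datasets for classifier training.

For classification experiments the full flow-video pipeline (simulate,
detect, track, crop) is bypassed: each cell is rendered directly into the
standard crop geometry at a sequence of orientations, exactly as a tracked
cell would appear after cropping.  This keeps dataset generation fast and
gives every cell a complete, balanced set of projections.

A *rolling* cell rotates about the flow axis by a fixed increment between
consecutive projections, so successive crops show genuinely different views
of the same cell.  A *non-rolling* cell keeps one fixed (random) orientation
and its projections differ only by sensor noise and sub-crop position — the
control condition in which extra views carry almost no new information.

Each projection is stored in two domains derived from the *same* synthetic
measurement: the raw off-axis hologram crop, and the OPD map reconstructed
from that hologram (demodulation, unwrapping, background zeroing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .optics import OpticalConfig
from .phantoms import PhantomSampler, default_phantom_sampler, render_projection
from .reconstruct import demodulate_exact, phase_to_opd, unwrap_phase, zero_background
from .holosim import synthesize_hologram

__all__ = ["ProjectionDatasetConfig", "ProjectionDataset", "make_projection_dataset"]


@dataclass(frozen=True)
class ProjectionDatasetConfig:
    """Geometry and acquisition settings of a projection dataset.

    ``rolling_rate`` is the rotation increment between consecutive
    projections, in radians, about the flow (row) axis.  ``center_jitter``
    is the maximum whole-pixel offset of the cell from the crop center,
    drawn uniformly per projection, mimicking imperfect crop centering.
    """

    n_per_class: int = 150
    n_classes: int = 3
    n_projections: int = 5
    crop_size: int = 134
    rolling: bool = True
    rolling_rate: float = 0.35
    center_jitter: int = 3
    supersample: int = 2
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_classes < 1 or self.n_projections < 1:
            raise ValueError("n_per_class, n_classes and n_projections must be >= 1")
        if self.crop_size < 8:
            raise ValueError("crop_size must be >= 8")
        if self.center_jitter < 0:
            raise ValueError("center_jitter must be >= 0")


@dataclass
class ProjectionDataset:
    """Stacked projections of ``n_cells`` cells in both domains.

    ``holograms`` and ``opd`` have shape (n_cells, n_projections, H, W);
    ``labels`` has shape (n_cells,).  Rows are grouped by cell, never mix
    cells, and are deterministic functions of the config seed.
    """

    holograms: np.ndarray
    opd: np.ndarray
    labels: np.ndarray
    config: ProjectionDatasetConfig

    @property
    def n_cells(self) -> int:
        return int(self.labels.shape[0])

    def views(self, domain: str, k: int, center_crop: int | None = None) -> np.ndarray:
        """Select ``k`` projections per cell, evenly spread over the
        available ones, and standardize each image to zero mean and unit
        variance.  ``center_crop`` optionally trims the (cell-free) crop
        margin to a smaller centered square before standardization, which
        speeds up training without touching the cell.  Returns
        (n_cells, k, 1, H, W) float32."""
        if domain not in ("hologram", "opd"):
            raise ValueError(f"domain must be 'hologram' or 'opd', got {domain!r}")
        p = self.config.n_projections
        if not (1 <= k <= p):
            raise ValueError(f"k must lie in [1, {p}], got {k}")
        idx = np.unique(np.round(np.linspace(0, p - 1, k)).astype(int))
        if idx.size < k:  # degenerate only when k > p, already excluded
            idx = np.arange(k)
        stack = (self.holograms if domain == "hologram" else self.opd)[:, idx]
        if center_crop is not None:
            side = stack.shape[-1]
            if not (0 < center_crop <= side):
                raise ValueError(f"center_crop must lie in (0, {side}]")
            lo = (side - center_crop) // 2
            stack = stack[..., lo : lo + center_crop, lo : lo + center_crop]
        x = stack.astype(np.float32)
        mean = x.mean(axis=(2, 3), keepdims=True)
        std = x.std(axis=(2, 3), keepdims=True)
        x = (x - mean) / np.maximum(std, 1e-6)
        return x[:, :, None, :, :]

    def early_fusion_views(
        self,
        k: int,
        domains: tuple[str, ...] = ("hologram", "opd"),
        center_crop: int | None = None,
    ) -> np.ndarray:
        """Stack several domains as input channels of the same view (the
        early-fusion ablation).  Returns (n_cells, k, C, H, W) float32."""
        parts = [self.views(d, k, center_crop) for d in domains]
        return np.concatenate(parts, axis=2)


def _reconstruct_opd(hologram, optics: OpticalConfig) -> np.ndarray:
    """Hologram crop -> OPD map in nm (the same steps the analysis pipeline
    applies to tracked crops, with the carrier known by construction)."""
    wavefront = demodulate_exact(hologram, optics.fringe)
    phase = unwrap_phase(wavefront.phase)
    opd_map = phase_to_opd(phase, optics.wavelength, optics.pixel_pitch)
    return zero_background(opd_map).opd


def make_projection_dataset(
    config: ProjectionDatasetConfig = ProjectionDatasetConfig(),
    optics: OpticalConfig = OpticalConfig(),
    sampler: PhantomSampler | None = None,
) -> ProjectionDataset:
    """Render a labeled multi-projection dataset (deterministic per seed).

    For every cell: draw a phantom and a uniformly random initial
    orientation; render ``n_projections`` projections (rotating the cell
    between projections when ``rolling``); synthesize the off-axis hologram
    crop of each projection with sensor noise; and reconstruct the OPD map
    from that hologram.  The carrier is snapped to the crop's FFT grid, as
    the simulator does for full frames.
    """
    sampler = sampler or default_phantom_sampler()
    rng = np.random.default_rng(config.seed)
    shape = (config.crop_size, config.crop_size)
    optics = replace(optics, noise_sigma=config.noise_sigma).snap_carrier(shape)

    n_cells = config.n_per_class * config.n_classes
    holograms = np.empty((n_cells, config.n_projections) + shape, dtype=np.float32)
    opd = np.empty_like(holograms)
    labels = np.empty(n_cells, dtype=np.int64)

    roll = Rotation.from_rotvec([config.rolling_rate, 0.0, 0.0])
    i = 0
    for label in range(config.n_classes):
        for _ in range(config.n_per_class):
            phantom = sampler.sample(label, rng)
            orientation = sampler.random_orientation(rng)
            for t in range(config.n_projections):
                opd_nm, amplitude = render_projection(
                    phantom,
                    orientation,
                    pixel_pitch=optics.pixel_pitch,
                    shape=shape,
                    supersample=config.supersample,
                )
                if config.center_jitter:
                    dy, dx = rng.integers(
                        -config.center_jitter, config.center_jitter + 1, size=2
                    )
                    opd_nm = np.roll(opd_nm, (dy, dx), axis=(0, 1))
                    amplitude = np.roll(amplitude, (dy, dx), axis=(0, 1))
                holo = synthesize_hologram(opd_nm, amplitude, optics, seed=rng)
                holograms[i, t] = holo.intensity
                opd[i, t] = _reconstruct_opd(holo, optics)
                if config.rolling:
                    orientation = roll * orientation
            labels[i] = label
            i += 1
    return ProjectionDataset(holograms=holograms, opd=opd, labels=labels, config=config)
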