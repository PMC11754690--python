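"""Synthesis of off-axis holograms and flowing-cell hologram videos.

The camera intensity of an off-axis hologram is modeled as the interference
of the sample field S (amplitude ``A``, phase ``phi = 2*pi*OPD/lambda``) with
a tilted plane reference beam of amplitude R:

    I(x, y) = R^2 + A^2 + 2*R*A*cos(2*pi*(fx*x + fy*y) + phi)

where (fx, fy) is the fringe carrier in cycles/pixel, x the column and y the
row index.  Additive Gaussian noise (a fraction of the mean intensity)
models camera noise; cells are assumed in focus, so no diffraction
propagation is applied.

``simulate_video`` composes many cells into a flowing scene: each cell
advances along the flow axis (columns) by a fixed displacement per frame,
jitters perpendicular to it, and rolls (rotates about the flow axis) between
frames, so successive frames show different angular projections of the same
cell -- the physical effect that multi-view classification exploits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .optics import FringeSpec, OpticalConfig
from .phantoms import CellPhantom, PhantomSampler, render_projection, required_grid_size
from .types import HologramFrame, OPDMap

__all__ = [
    "FlowScene",
    "GroundTruthRecord",
    "synthesize_hologram",
    "synthesize_from_wavefront",
    "pupil_filter",
    "imaged_field",
    "imaged_opd",
    "simulate_video",
]

logger = logging.getLogger(__name__)


def _carrier_phase(shape: tuple[int, int], fringe: FringeSpec) -> np.ndarray:
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    return 2.0 * np.pi * (fringe.fx * x + fringe.fy * y)


def pupil_filter(field: np.ndarray, cutoff: float) -> np.ndarray:
    """Apply a circular coherent pupil of radius ``cutoff`` (cycles/pixel).

    This is the coherent transfer function of a finite-NA objective: spatial
    frequencies of the complex field beyond the cutoff are removed.  The
    returned field is exactly band-limited, which also makes the hologram's
    autocorrelation (DC) lobe exactly band-limited to twice the cutoff.
    """
    field = np.asarray(field, dtype=np.complex128)
    fy = np.fft.fftfreq(field.shape[0])[:, None]
    fx = np.fft.fftfreq(field.shape[1])[None, :]
    mask = fy**2 + fx**2 <= cutoff**2
    return np.fft.ifft2(np.fft.fft2(field) * mask)


def imaged_field(opd, amplitude, optics: OpticalConfig) -> np.ndarray:
    """The complex sample field as seen through the imaging system.

    Builds ``amplitude * exp(i * 2*pi * OPD / wavelength)`` and applies the
    pupil.  This is the ground-truth field that a perfect reconstruction of
    the synthesized hologram recovers.
    """
    opd_nm = opd.opd if isinstance(opd, OPDMap) else np.asarray(opd, dtype=np.float64)
    amp = np.broadcast_to(np.asarray(amplitude, dtype=np.float64), opd_nm.shape)
    field = amp * np.exp(2j * np.pi * opd_nm / optics.wavelength)
    if optics.na_cutoff is not None:
        field = pupil_filter(field, optics.na_cutoff)
    return field


def imaged_opd(opd, amplitude, optics: OpticalConfig) -> OPDMap:
    """Ground-truth OPD after the imaging system (phase of the imaged field,
    scaled by wavelength / 2*pi).  Valid while the pupil-filtered phase stays
    within one 2*pi interval, which holds for the default phantoms."""
    field = imaged_field(opd, amplitude, optics)
    return OPDMap(
        opd=np.angle(field) * optics.wavelength / (2.0 * np.pi),
        wavelength=optics.wavelength,
        pixel_pitch=optics.pixel_pitch,
    )


def synthesize_from_wavefront(
    field: np.ndarray,
    fringe: FringeSpec,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    pixel_pitch: float = float("nan"),
    frame_index: int = 0,
) -> HologramFrame:
    """Interfere a complex sample field with a tilted plane reference beam."""
    field = np.asarray(field, dtype=np.complex128)
    carrier = _carrier_phase(field.shape, fringe)
    r = fringe.reference_amplitude
    amp = np.abs(field)
    intensity = r**2 + amp**2 + 2.0 * r * amp * np.cos(carrier + np.angle(field))
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        intensity = intensity + rng.normal(
            0.0, noise_sigma * float(intensity.mean()), size=intensity.shape
        )
        np.clip(intensity, 0.0, None, out=intensity)
    return HologramFrame(intensity=intensity, frame_index=frame_index, pixel_pitch=pixel_pitch)


def synthesize_hologram(
    opd,
    amplitude: np.ndarray | float = 1.0,
    optics: OpticalConfig = OpticalConfig(),
    seed: int | np.random.Generator | None = None,
    frame_index: int = 0,
) -> HologramFrame:
    """Form the off-axis hologram of an OPD map.

    Parameters
    ----------
    opd : OPDMap or 2-D array
        Optical path delay in nm (arrays are interpreted in nm at the
        configured wavelength).
    amplitude : 2-D array or scalar
        Amplitude transmission of the sample, same shape as ``opd``.
    optics : OpticalConfig
        Carrier, wavelength, reference amplitude and noise level.
    seed : int, Generator or None
        Noise source; only used when ``optics.noise_sigma > 0``.
    """
    opd_nm = opd.opd if isinstance(opd, OPDMap) else np.asarray(opd, dtype=np.float64)
    amp = np.broadcast_to(np.asarray(amplitude, dtype=np.float64), opd_nm.shape)
    if amp.shape != opd_nm.shape:
        raise ValueError("opd and amplitude must have the same shape")
    field = imaged_field(opd_nm, amp, optics)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return synthesize_from_wavefront(
        field,
        optics.fringe,
        noise_sigma=optics.noise_sigma,
        rng=rng,
        pixel_pitch=optics.pixel_pitch,
        frame_index=frame_index,
    )


# ---------------------------------------------------------------------------
# Flow scene simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowScene:
    """Geometry and dynamics of a flowing-cell recording.

    The flow axis is the column axis; rows are the perpendicular axis.
    ``rolling_rate`` is the rotation (radians/frame) about the flow axis,
    which is how a cell rolling on the channel bottom presents successive
    angular views to the camera.  The first ``empty_frame_fraction`` of the
    video contains no cells so that frame averaging yields a meaningful
    background estimate.
    """

    frame_shape: tuple[int, int] = (320, 512)
    n_frames: int = 30
    flow_displacement_per_frame: float = 40.0
    perpendicular_jitter_sigma: float = 2.0
    rolling_rate: float = 0.35
    cell_spawn_rate: float = 0.2
    seed: int = 0
    empty_frame_fraction: float = 0.1
    max_cell_density: float = 0.15

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.flow_displacement_per_frame <= 0:
            raise ValueError("flow_displacement_per_frame must be > 0")
        if self.perpendicular_jitter_sigma < 0 or self.cell_spawn_rate < 0:
            raise ValueError("jitter sigma and spawn rate must be >= 0")


@dataclass
class GroundTruthRecord:
    """Per-frame ground truth for one rendered cell instance."""

    frame_index: int
    cell_id: int
    centroid: tuple[float, float]  # (row, col), pixels
    orientation: tuple[float, float, float]  # intrinsic xyz Euler angles, rad
    class_label: int


@dataclass
class _ActiveCell:
    cell_id: int
    phantom: CellPhantom
    orientation: Rotation
    row: float
    col: float
    extent_px: float


def simulate_video(
    scene: FlowScene,
    phantom_sampler: PhantomSampler,
    optics: OpticalConfig = OpticalConfig(),
    supersample: int = 2,
) -> tuple[np.ndarray, list[GroundTruthRecord]]:
    """Render a hologram video of cells flowing and rolling through the field.

    Returns ``(video, truth)`` where ``video`` is a float array of shape
    ``(n_frames, rows, cols)`` and ``truth`` lists one
    :class:`GroundTruthRecord` per cell per frame in which any part of the
    cell is inside the field of view.  Output is a deterministic function of
    ``scene.seed``.
    """
    rng = np.random.default_rng(scene.seed)
    h, w = scene.frame_shape
    labels = phantom_sampler.class_labels
    roll_axis = np.array([1.0, 0.0, 0.0])  # flow (column) axis

    first_spawn = int(math.ceil(scene.empty_frame_fraction * scene.n_frames))
    cells: list[_ActiveCell] = []
    next_id = 0
    video = np.empty((scene.n_frames, h, w), dtype=np.float64)
    truth: list[GroundTruthRecord] = []
    n_overlap = 0

    for f in range(scene.n_frames):
        # advance existing cells
        for cell in cells:
            cell.col += scene.flow_displacement_per_frame
            cell.row += rng.normal(0.0, scene.perpendicular_jitter_sigma)
            cell.orientation = (
                Rotation.from_rotvec(scene.rolling_rate * roll_axis) * cell.orientation
            )
        cells = [c for c in cells if c.col - c.extent_px < w]

        # spawn new cells at the upstream (left) edge
        if f >= first_spawn:
            for _ in range(rng.poisson(scene.cell_spawn_rate)):
                label = labels[rng.integers(len(labels))]
                phantom = phantom_sampler.sample(label, rng)
                extent_px = phantom.max_extent / optics.pixel_pitch
                row = float(rng.uniform(extent_px + 2, h - extent_px - 2))
                col = float(rng.uniform(-extent_px, scene.flow_displacement_per_frame))
                cells.append(
                    _ActiveCell(
                        cell_id=next_id,
                        phantom=phantom,
                        orientation=phantom_sampler.random_orientation(rng),
                        row=row,
                        col=col,
                        extent_px=extent_px,
                    )
                )
                next_id += 1

        # composite OPD and amplitude canvases
        opd = np.zeros((h, w), dtype=np.float64)
        amp = np.ones((h, w), dtype=np.float64)
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                if math.hypot(a.row - b.row, a.col - b.col) < a.extent_px + b.extent_px:
                    n_overlap += 1
        for cell in cells:
            patch_opd, patch_amp = render_projection(
                cell.phantom,
                cell.orientation,
                optics.pixel_pitch,
                supersample=supersample,
            )
            ph, pw = patch_opd.shape
            r0 = int(round(cell.row)) - ph // 2
            c0 = int(round(cell.col)) - pw // 2
            rr0, cc0 = max(r0, 0), max(c0, 0)
            rr1, cc1 = min(r0 + ph, h), min(c0 + pw, w)
            if rr1 <= rr0 or cc1 <= cc0:
                continue  # fully outside
            sl_frame = (slice(rr0, rr1), slice(cc0, cc1))
            sl_patch = (slice(rr0 - r0, rr1 - r0), slice(cc0 - c0, cc1 - c0))
            opd[sl_frame] += patch_opd[sl_patch]
            amp[sl_frame] *= patch_amp[sl_patch]
            euler = tuple(cell.orientation.as_euler("xyz"))
            truth.append(
                GroundTruthRecord(
                    frame_index=f,
                    cell_id=cell.cell_id,
                    # centroid is the pasted patch center (positions are
                    # quantized to whole pixels when compositing)
                    centroid=(float(round(cell.row)), float(round(cell.col))),
                    orientation=(float(euler[0]), float(euler[1]), float(euler[2])),
                    class_label=cell.phantom.class_label,
                )
            )

        video[f] = synthesize_hologram(opd, amp, optics, seed=rng, frame_index=f).intensity

    if n_overlap > scene.max_cell_density * scene.n_frames:
        logger.warning(
            "simulate_video: %d overlapping cell pairs across %d frames; detection "
            "criteria assume isolated cells",
            n_overlap,
            scene.n_frames,
        )
    return video, truth
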