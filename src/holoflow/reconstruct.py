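"""Off-axis hologram reconstruction: Fourier demodulation to a complex
wavefront, background compensation, phase unwrapping, and conversion to
optical path delay.

The reconstruction chain mirrors standard off-axis holographic processing:

1. Fourier-transform the hologram and locate one of the two cross-correlation
   terms (the spectral lobe sitting on the fringe carrier).
2. Window the spectrum around that term, recenter it on the carrier bin, and
   inverse transform -- the result is the complex object wavefront, modulo a
   sub-bin carrier tilt.
3. Divide by a background wavefront extracted the same way from a cell-free
   frame; this cancels system aberrations and the residual carrier tilt.
4. Unwrap the phase and scale by wavelength / (2*pi) to obtain the OPD in nm.

All spectral radii (windows, exclusion zones) are expressed in cycles/pixel
so they are independent of frame shape.  Phase unwrapping uses the
reliability-ordered 2-D unwrapper from scikit-image, which is deterministic
and satisfies the mod-2*pi congruence postcondition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap_2d

from .optics import FringeSpec
from .types import ComplexWavefront, HologramFrame, OPDMap

__all__ = [
    "SpectralPeak",
    "StabilityMetrics",
    "locate_carrier",
    "extract_wavefront",
    "demodulate_exact",
    "compensate_background",
    "unwrap_phase",
    "phase_to_opd",
    "zero_background",
    "hologram_to_opd",
    "stability_maps",
]

#: Default radius (cycles/pixel) of the spectral zone around DC excluded from
#: carrier search and window placement.
DEFAULT_DC_EXCLUSION = 0.08


@dataclass(frozen=True)
class SpectralPeak:
    """Location of a cross-correlation term in the spectrum.

    ``coords`` are bin offsets (d_row, d_col) relative to the DC bin of the
    fftshifted spectrum; ``freq`` is the same location in cycles/pixel
    (f_row, f_col).  The conjugate term sits at the negated location.
    """

    coords: tuple[int, int]
    freq: tuple[float, float]
    magnitude: float

    @property
    def freq_radius(self) -> float:
        """Distance from DC in cycles/pixel."""
        return float(np.hypot(*self.freq))

    def conjugate(self) -> "SpectralPeak":
        return SpectralPeak(
            (-self.coords[0], -self.coords[1]),
            (-self.freq[0], -self.freq[1]),
            self.magnitude,
        )


def _intensity(hologram) -> np.ndarray:
    if isinstance(hologram, HologramFrame):
        return hologram.intensity
    return np.asarray(hologram, dtype=np.float64)


def _freq_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """fftshifted frequency coordinates (cycles/pixel) of each spectral bin."""
    fy = np.fft.fftshift(np.fft.fftfreq(shape[0]))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(shape[1]))[None, :]
    return fy, fx


def locate_carrier(hologram, dc_exclusion: float = DEFAULT_DC_EXCLUSION) -> SpectralPeak:
    """Find the off-axis carrier: the strongest spectral peak outside DC.

    The search is restricted to one half-plane (positive row frequencies,
    plus positive column frequencies on the zero row) so that of the two
    conjugate cross-correlation terms a unique one is always selected.
    Raises ``ValueError("no carrier detected")`` if no peak rises above a
    small fraction of the DC magnitude.
    """
    img = _intensity(hologram)
    h, w = img.shape
    spec = np.fft.fftshift(np.fft.fft2(img))
    mag = np.abs(spec)
    fy, fx = _freq_grids(img.shape)
    allowed = (fy > 0) | ((fy == 0) & (fx > 0))
    allowed &= fy**2 + fx**2 > dc_exclusion**2
    masked = np.where(allowed, mag, 0.0)
    idx = np.unravel_index(int(np.argmax(masked)), mag.shape)
    peak_mag = float(mag[idx])
    dc_mag = float(mag[h // 2, w // 2])
    if dc_mag <= 0 or peak_mag < 1e-3 * dc_mag:
        raise ValueError("no carrier detected")
    return SpectralPeak(
        coords=(int(idx[0] - h // 2), int(idx[1] - w // 2)),
        freq=(float(fy[idx[0], 0]), float(fx[0, idx[1]])),
        magnitude=peak_mag,
    )


def extract_wavefront(
    hologram,
    peak: SpectralPeak,
    window_radius: float | None = None,
    dc_exclusion: float = DEFAULT_DC_EXCLUSION,
) -> ComplexWavefront:
    """Demodulate one cross-correlation term into a complex wavefront.

    A circular spectral window of ``window_radius`` cycles/pixel (default:
    half the carrier's distance from DC, the largest band guaranteed free of
    DC contamination for an arbitrary object) is applied around the peak; the
    windowed spectrum is recentered on the carrier bin and inverse
    transformed.  Any sub-bin carrier tilt remains in the phase and is
    removed by background division.
    """
    img = _intensity(hologram)
    dist = peak.freq_radius
    if window_radius is None:
        window_radius = dist / 2.0
    if window_radius <= 0:
        raise ValueError("window_radius must be > 0")
    if window_radius + dc_exclusion > dist:
        raise ValueError(
            f"window of radius {window_radius:.3f} cycles/px around the carrier at "
            f"{dist:.3f} cycles/px overlaps the DC exclusion zone "
            f"(radius {dc_exclusion:.3f}); shrink the window"
        )
    if abs(peak.freq[0]) + window_radius > 0.5 or abs(peak.freq[1]) + window_radius > 0.5:
        raise ValueError("carrier window does not fit inside the spectrum")
    spec = np.fft.fftshift(np.fft.fft2(img))
    fy, fx = _freq_grids(img.shape)
    mask = (fy - peak.freq[0]) ** 2 + (fx - peak.freq[1]) ** 2 <= window_radius**2
    windowed = np.where(mask, spec, 0.0)
    recentered = np.roll(windowed, (-peak.coords[0], -peak.coords[1]), axis=(0, 1))
    field = np.fft.ifft2(np.fft.ifftshift(recentered))
    pitch = hologram.pixel_pitch if isinstance(hologram, HologramFrame) else float("nan")
    return ComplexWavefront(field=field, background_compensated=False, pixel_pitch=pitch)


def demodulate_exact(
    hologram,
    fringe: FringeSpec,
    window_radius: float | None = None,
) -> ComplexWavefront:
    """Demodulate with an exactly known (possibly sub-bin) carrier.

    Multiplies the hologram by the conjugate carrier wave before low-pass
    windowing, so no residual tilt is left even when the carrier does not
    fall on an integer spectral bin.  Used where the carrier is known by
    construction (simulation, re-fringing); recorded data goes through
    :func:`locate_carrier` / :func:`extract_wavefront` instead.
    """
    img = _intensity(hologram)
    h, w = img.shape
    y, x = np.mgrid[0:h, 0:w]
    demod = img * np.exp(-2j * np.pi * (fringe.fx * x + fringe.fy * y))
    if window_radius is None:
        window_radius = fringe.carrier_frequency / 2.0
    spec = np.fft.fftshift(np.fft.fft2(demod))
    fy, fx = _freq_grids(img.shape)
    mask = fy**2 + fx**2 <= window_radius**2
    field = np.fft.ifft2(np.fft.ifftshift(np.where(mask, spec, 0.0)))
    pitch = hologram.pixel_pitch if isinstance(hologram, HologramFrame) else float("nan")
    return ComplexWavefront(field=field, background_compensated=False, pixel_pitch=pitch)


def compensate_background(
    wavefront: ComplexWavefront,
    background: ComplexWavefront,
    magnitude_floor: float = 1e-6,
) -> ComplexWavefront:
    """Pointwise division by a cell-free background wavefront.

    Cancels shared aberrations (and residual carrier tilt).  The background
    magnitude must stay above ``magnitude_floor`` times its maximum
    everywhere; otherwise the division would amplify noise without bound.
    """
    if wavefront.shape != background.shape:
        raise ValueError(
            f"shape mismatch: wavefront {wavefront.shape} vs background {background.shape}"
        )
    bmag = np.abs(background.field)
    floor = magnitude_floor * float(bmag.max())
    if float(bmag.max()) <= 0.0 or float(bmag.min()) < floor:
        raise ValueError("background magnitude falls below the regularization floor")
    return ComplexWavefront(
        field=wavefront.field / background.field,
        background_compensated=True,
        pixel_pitch=wavefront.pixel_pitch,
    )


def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """Unwrap a 2-D phase map (values treated modulo 2*pi).

    The output is congruent to the input modulo 2*pi at every pixel and is
    continuous for smooth underlying phase surfaces.  Reliability-ordered
    unwrapping: deterministic for a given input.
    """
    wrapped = np.asarray(wrapped, dtype=np.float64)
    if not np.all(np.isfinite(wrapped)):
        raise ValueError("phase map must be finite")
    return np.asarray(_unwrap_2d(wrapped), dtype=np.float64)


def phase_to_opd(
    phase: np.ndarray | float, wavelength: float, pixel_pitch: float = float("nan")
) -> OPDMap:
    """Scale an unwrapped phase map (radians) to OPD in nm:
    ``opd = phase * wavelength / (2*pi)``."""
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    opd = np.atleast_2d(np.asarray(phase, dtype=np.float64)) * wavelength / (2.0 * np.pi)
    return OPDMap(opd=opd, wavelength=wavelength, pixel_pitch=pixel_pitch)


def zero_background(opd: OPDMap, border: int = 8) -> OPDMap:
    """Shift an OPD map so the cell-free border ring sits at 0 (median)."""
    m = opd.opd
    if min(m.shape) <= 2 * border:
        raise ValueError("map too small for the requested border ring")
    ring = np.ones(m.shape, dtype=bool)
    ring[border:-border, border:-border] = False
    return OPDMap(
        opd=m - float(np.median(m[ring])),
        wavelength=opd.wavelength,
        pixel_pitch=opd.pixel_pitch,
    )


def hologram_to_opd(
    hologram,
    wavelength: float,
    background=None,
    peak: SpectralPeak | None = None,
    window_radius: float | None = None,
    dc_exclusion: float = DEFAULT_DC_EXCLUSION,
    conjugate: bool = False,
    border: int = 8,
    positive_bias: bool = False,
) -> OPDMap:
    """Full reconstruction chain: hologram -> OPD map in nm.

    ``background`` may be a cell-free :class:`HologramFrame` (demodulated at
    the same carrier bin and divided out) or ``None``.  ``conjugate=True``
    reconstructs from the opposite cross-correlation term, which negates the
    recovered phase.  ``positive_bias=True`` resolves the inherent conjugate
    sign ambiguity by assuming the object is optically denser than the
    medium (true for cells): if the reconstructed map integrates negative,
    it is negated.
    """
    if peak is None:
        src = background if background is not None else hologram
        peak = locate_carrier(src, dc_exclusion)
    if conjugate:
        peak = peak.conjugate()
    wf = extract_wavefront(hologram, peak, window_radius, dc_exclusion)
    if background is not None:
        bg = extract_wavefront(background, peak, window_radius, dc_exclusion)
        wf = compensate_background(wf, bg)
    phase = unwrap_phase(np.angle(wf.field))
    opd = phase_to_opd(phase, wavelength, pixel_pitch=wf.pixel_pitch)
    opd = zero_background(opd, border=border)
    if positive_bias and float(opd.opd.sum()) < 0:
        opd = OPDMap(opd=-opd.opd, wavelength=opd.wavelength, pixel_pitch=opd.pixel_pitch)
    return opd


@dataclass
class StabilityMetrics:
    """Temporal and spatial OPD stability of a reconstruction series.

    ``temporal_std_map`` is the per-pixel standard deviation across frames
    (its mean is the temporal stability figure); ``spatial_std_series`` is
    the per-frame standard deviation across pixels (its mean is the spatial
    stability figure).  Population (ddof=0) convention.
    """

    temporal_std_map: np.ndarray
    spatial_std_series: np.ndarray
    mean_temporal_std: float
    mean_spatial_std: float


def stability_maps(opd_series) -> StabilityMetrics:
    """Stability metrics of an ordered OPD-map series (>= 2 frames)."""
    maps = [
        m.opd if isinstance(m, OPDMap) else np.asarray(m, dtype=np.float64)
        for m in opd_series
    ]
    if len(maps) < 2:
        raise ValueError("stability requires at least 2 frames")
    if any(m.shape != maps[0].shape for m in maps):
        raise ValueError("all OPD maps must share one shape")
    stack = np.stack(maps)
    temporal = stack.std(axis=0, ddof=0)
    spatial = stack.std(axis=(1, 2), ddof=0)
    return StabilityMetrics(
        temporal_std_map=temporal,
        spatial_std_series=spatial,
        mean_temporal_std=float(temporal.mean()),
        mean_spatial_std=float(spatial.mean()),
    )
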