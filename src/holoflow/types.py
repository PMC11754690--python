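"""Core array containers shared across the pipeline.

``HologramFrame`` is what the camera records, ``ComplexWavefront`` is what
Fourier demodulation recovers from it, and ``OPDMap`` is the physical
quantity of interest: the optical path delay, per pixel, i.e. the product of
cell thickness and the difference between the cell's integral refractive
index and that of the surrounding medium, expressed in nanometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HologramFrame", "ComplexWavefront", "OPDMap"]


@dataclass
class HologramFrame:
    """One recorded off-axis hologram: a real, non-negative intensity image."""

    intensity: np.ndarray
    frame_index: int = 0
    pixel_pitch: float = float("nan")

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be a 2-D image")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("hologram intensity must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape  # type: ignore[return-value]


@dataclass
class ComplexWavefront:
    """Complex object field demodulated from one cross-correlation term."""

    field: np.ndarray
    background_compensated: bool = False
    pixel_pitch: float = float("nan")

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=np.complex128)
        if self.field.ndim != 2:
            raise ValueError("wavefront field must be a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.field.shape  # type: ignore[return-value]

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase in (-pi, pi]."""
        return np.angle(self.field)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.field)


@dataclass
class OPDMap:
    """Optical path delay image in nanometers."""

    opd: np.ndarray
    wavelength: float
    pixel_pitch: float = float("nan")

    def __post_init__(self) -> None:
        self.opd = np.asarray(self.opd, dtype=np.float64)
        if self.opd.ndim != 2:
            raise ValueError("OPD map must be 2-D")
        if not np.all(np.isfinite(self.opd)):
            raise ValueError("OPD map must be finite")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.opd.shape  # type: ignore[return-value]
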