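"""Optical configuration for off-axis hologram formation.

An off-axis hologram is the interference of a sample beam S and a tilted
reference beam R on the camera.  The tilt puts the object information on a
spatial fringe carrier; ``carrier_frequency`` (cycles/pixel) and
``fringe_angle`` (degrees, direction of the fringe normal) describe that
carrier in camera coordinates.  ``x`` is the column axis and ``y`` the row
axis throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["OpticalConfig", "FringeSpec", "HENE_WAVELENGTH_NM"]

#: Helium-neon laser line, nm.  Used as the default illumination wavelength.
HENE_WAVELENGTH_NM = 632.8


@dataclass(frozen=True)
class FringeSpec:
    """Carrier parameters of an off-axis fringe pattern.

    Parameters
    ----------
    carrier_frequency : float
        Spatial frequency of the fringes in cycles/pixel.  Must lie strictly
        between 0 and the Nyquist limit 0.5 so the cross-correlation terms
        are resolvable in the spectrum.
    fringe_angle : float
        Direction of the fringe normal (the carrier wave vector), degrees.
    reference_amplitude : float
        Amplitude of the reference beam relative to unit sample illumination.
    """

    carrier_frequency: float
    fringe_angle: float = 0.0
    reference_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.carrier_frequency < 0.5):
            raise ValueError(
                "carrier_frequency must lie in (0, 0.5) cycles/pixel (below "
                f"Nyquist); got {self.carrier_frequency}"
            )
        if self.reference_amplitude < 0:
            raise ValueError("reference_amplitude must be >= 0")

    @property
    def fx(self) -> float:
        """Carrier frequency along the column (x) axis, cycles/pixel."""
        return self.carrier_frequency * math.cos(math.radians(self.fringe_angle))

    @property
    def fy(self) -> float:
        """Carrier frequency along the row (y) axis, cycles/pixel."""
        return self.carrier_frequency * math.sin(math.radians(self.fringe_angle))

    def snap(self, frame_shape: tuple[int, int]) -> "FringeSpec":
        """Snap the carrier onto the FFT grid of ``frame_shape`` (see
        :meth:`OpticalConfig.snap_carrier`): the snapped fringe pattern is
        exactly periodic over the frame, so a finite synthetic frame shows no
        spectral leakage.  Moves the carrier by at most half a bin."""
        h, w = frame_shape
        fy = round(self.fy * h) / h
        fx = round(self.fx * w) / w
        return FringeSpec(
            carrier_frequency=math.hypot(fx, fy),
            fringe_angle=math.degrees(math.atan2(fy, fx)),
            reference_amplitude=self.reference_amplitude,
        )


@dataclass(frozen=True)
class OpticalConfig:
    """Full optical description of the simulated interferometric microscope.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in nm (default: the He-Ne line).
    pixel_pitch : float
        Size of one camera pixel projected into the object plane, um/pixel.
    carrier_frequency, fringe_angle, reference_amplitude :
        See :class:`FringeSpec`.
    noise_sigma : float
        Standard deviation of additive Gaussian intensity noise, expressed
        as a fraction of the mean hologram intensity.
    na_cutoff : float or None
        Coherent cutoff frequency of the imaging system (circular pupil), in
        cycles/pixel.  The sample field is low-pass filtered at this radius
        before interference, which is what a finite-NA objective does to the
        coherent field.  ``None`` disables pupil filtering.  For valid
        off-axis separation the carrier must satisfy
        ``carrier_frequency >= 3 * na_cutoff`` (object lobe of width
        ``na_cutoff`` clear of the autocorrelation lobe of width
        ``2 * na_cutoff``).
    """

    wavelength: float = HENE_WAVELENGTH_NM
    pixel_pitch: float = 0.16
    carrier_frequency: float = 0.35
    fringe_angle: float = 45.0
    reference_amplitude: float = 1.0
    noise_sigma: float = 0.0
    na_cutoff: float | None = 0.11

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if not (0.0 < self.carrier_frequency < 0.5):
            raise ValueError(
                "carrier_frequency must lie in (0, 0.5) cycles/pixel (below "
                f"Nyquist); got {self.carrier_frequency}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.na_cutoff is not None and not (0 < self.na_cutoff < 0.5):
            raise ValueError("na_cutoff must lie in (0, 0.5) cycles/pixel or be None")

    @property
    def fringe(self) -> FringeSpec:
        return FringeSpec(
            carrier_frequency=self.carrier_frequency,
            fringe_angle=self.fringe_angle,
            reference_amplitude=self.reference_amplitude,
        )

    @property
    def fx(self) -> float:
        return self.fringe.fx

    @property
    def fy(self) -> float:
        return self.fringe.fy

    def snap_carrier(self, frame_shape: tuple[int, int]) -> "OpticalConfig":
        """Snap the carrier onto the FFT grid of ``frame_shape``.

        Returns a config whose carrier components are integer multiples of
        1/rows and 1/cols, so the fringe pattern is exactly periodic over the
        frame.  Simulations use this to avoid spectral leakage that a finite
        synthetic frame would otherwise introduce; it leaves the carrier
        within half a spectral bin of the requested one.
        """
        h, w = frame_shape
        fy = round(self.fy * h) / h
        fx = round(self.fx * w) / w
        freq = math.hypot(fx, fy)
        angle = math.degrees(math.atan2(fy, fx))
        return OpticalConfig(
            wavelength=self.wavelength,
            pixel_pitch=self.pixel_pitch,
            carrier_frequency=freq,
            fringe_angle=angle,
            reference_amplitude=self.reference_amplitude,
            noise_sigma=self.noise_sigma,
            na_cutoff=self.na_cutoff,
        )

    def with_fringe(self, fringe: FringeSpec) -> "OpticalConfig":
        """Return a copy carrying a new fringe carrier."""
        return OpticalConfig(
            wavelength=self.wavelength,
            pixel_pitch=self.pixel_pitch,
            carrier_frequency=fringe.carrier_frequency,
            fringe_angle=fringe.fringe_angle,
            reference_amplitude=fringe.reference_amplitude,
            noise_sigma=self.noise_sigma,
            na_cutoff=self.na_cutoff,
        )
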