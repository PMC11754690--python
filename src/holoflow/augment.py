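"""Fringe-carrier augmentation: re-synthesize a hologram of the same cell at
a new fringe frequency and direction.

A classifier trained on raw off-axis holograms must not key on the fringe
carrier, which varies with interferometer alignment.  ``refringe``
demodulates a cell hologram to its complex wavefront and interferes it again
with a reference beam at a different carrier, producing a new hologram of
the identical object.  Training on such augmentations makes the network
insensitive to fringe frequency and direction; the object's OPD and
amplitude are preserved exactly (up to the spectral band common to the two
carriers), so the class label never changes.
"""

from __future__ import annotations

import numpy as np

from .holosim import synthesize_from_wavefront
from .optics import FringeSpec, OpticalConfig
from .reconstruct import demodulate_exact, extract_wavefront, locate_carrier
from .types import HologramFrame

__all__ = ["refringe", "sample_fringe_specs"]


def refringe(
    hologram,
    new: FringeSpec,
    original: FringeSpec | OpticalConfig | None = None,
    window_radius: float | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    snap_carrier: bool = True,
) -> HologramFrame:
    """Re-synthesize ``hologram`` on a new fringe carrier.

    If the original carrier is known (``original``), demodulation is exact
    (no residual tilt even for off-bin carriers); otherwise the carrier is
    located from the spectrum.  The new hologram's object amplitude and phase
    equal the demodulated ones, band-limited to the demodulation window.
    With ``snap_carrier`` (default) the new carrier is moved onto the FFT
    grid of the crop (at most half a bin), which keeps the synthetic fringe
    pattern periodic over the finite crop and hence leakage-free.
    """
    shape = hologram.shape if isinstance(hologram, HologramFrame) else np.asarray(hologram).shape
    if snap_carrier:
        new = new.snap(shape)
    if original is not None:
        fringe = original.fringe if isinstance(original, OpticalConfig) else original
        wavefront = demodulate_exact(hologram, fringe, window_radius)
    else:
        peak = locate_carrier(hologram)
        wavefront = extract_wavefront(hologram, peak, window_radius)
    frame_index = hologram.frame_index if isinstance(hologram, HologramFrame) else 0
    pitch = hologram.pixel_pitch if isinstance(hologram, HologramFrame) else float("nan")
    return synthesize_from_wavefront(
        wavefront.field,
        new,
        noise_sigma=noise_sigma,
        rng=rng,
        pixel_pitch=pitch,
        frame_index=frame_index,
    )


def sample_fringe_specs(
    n: int,
    freq_range: tuple[float, float] = (0.2, 0.38),
    angle_range: tuple[float, float] = (0.0, 360.0),
    reference_amplitude: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> list[FringeSpec]:
    """Draw ``n`` fringe specs uniformly over the given frequency and angle
    ranges (deterministic for a fixed seed)."""
    if not (0.0 < freq_range[0] <= freq_range[1] < 0.5):
        raise ValueError("freq_range must lie within (0, 0.5) and be ordered")
    if not (0.0 <= angle_range[0] <= angle_range[1] <= 360.0):
        raise ValueError("angle_range must lie within [0, 360] and be ordered")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = rng.uniform(freq_range[0], freq_range[1], size=n)
    angles = rng.uniform(angle_range[0], angle_range[1], size=n)
    return [
        FringeSpec(carrier_frequency=float(f), fringe_angle=float(a),
                   reference_amplitude=reference_amplitude)
        for f, a in zip(freqs, angles)
    ]
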