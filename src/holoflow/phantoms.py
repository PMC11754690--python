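"""Cell phantoms: piecewise-constant refractive-index objects and their
projections.

A phantom is an ellipsoidal cell body with an optional co-aligned ellipsoidal
nucleus and spherical cytoplasmic granules.  Because the refractive-index
model is piecewise constant and built from quadric shapes, the projection
along the optical axis (z) has a closed form: the chord length of a ray
through each component.  The optical path delay at a pixel is

    OPD(x, y) = sum_k  dn_k * L_k(x, y)

where ``L_k`` is the chord length of component k at (x, y) and ``dn_k`` its
refractive-index difference (the nucleus and granule values are *excess*
differences on top of the cytoplasm, so components add).  Absorbing
components additionally attenuate the transmitted amplitude with a
Beer-Lambert factor.

Analytic chords make the renderer its own oracle: a homogeneous sphere of
radius r and index difference dn has peak OPD exactly 2*r*dn (in length
units), and the integral of the projection equals dn times the component
volume regardless of orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "CellPhantom",
    "PhantomSampler",
    "default_phantom_sampler",
    "render_opd_projection",
    "render_projection",
    "required_grid_size",
]

from .types import OPDMap


@dataclass
class CellPhantom:
    """A single cell as a piecewise-constant phase (and absorption) object.

    Lengths are in micrometers; refractive-index differences are
    dimensionless.  The body is an ellipsoid with semi-axes
    ``(elongation * radius, radius, radius)`` along its own x/y/z axes; the
    nucleus shares the body's axes and elongation.  ``delta_n_nucleus`` and
    ``granule_delta_n`` are excess values relative to the cytoplasm.
    """

    class_label: int
    radius: float
    delta_n_cytoplasm: float
    elongation: float = 1.0
    nucleus_radius: float = 0.0
    delta_n_nucleus: float = 0.0
    granule_positions: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3), dtype=np.float64)
    )
    granule_radius: float = 0.5
    granule_delta_n: float = 0.0
    amplitude_absorption: float = 0.0
    granule_absorption: float = 0.0

    def __post_init__(self) -> None:
        self.granule_positions = np.atleast_2d(
            np.asarray(self.granule_positions, dtype=np.float64)
        )
        if self.granule_positions.size == 0:
            self.granule_positions = np.zeros((0, 3), dtype=np.float64)
        if self.granule_positions.shape[1:] != (3,):
            raise ValueError("granule_positions must have shape (n, 3)")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.elongation <= 0:
            raise ValueError("elongation must be > 0")
        if not (0 <= self.nucleus_radius <= self.radius):
            raise ValueError("nucleus_radius must lie in [0, radius]")
        for name in ("delta_n_cytoplasm", "delta_n_nucleus", "granule_delta_n"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("amplitude_absorption", "granule_absorption"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def granule_count(self) -> int:
        return int(self.granule_positions.shape[0])

    @property
    def max_extent(self) -> float:
        """Radius of the smallest sphere containing the phantom, um."""
        body = self.elongation * self.radius
        if self.granule_count:
            gran = float(
                np.max(np.linalg.norm(self.granule_positions, axis=1))
                + self.granule_radius
            )
            return max(body, gran)
        return body


def required_grid_size(phantom: CellPhantom, pixel_pitch: float, margin: int = 4) -> int:
    """Smallest square grid (pixels) that contains the phantom projection."""
    return int(math.ceil(2.0 * phantom.max_extent / pixel_pitch)) + margin


def _as_matrix(orientation) -> np.ndarray:
    if orientation is None:
        return np.eye(3)
    if isinstance(orientation, Rotation):
        return orientation.as_matrix()
    mat = np.asarray(orientation, dtype=np.float64)
    if mat.shape != (3, 3):
        raise ValueError("orientation must be a scipy Rotation or a 3x3 matrix")
    return mat


def _ellipsoid_chords(
    x: np.ndarray,
    y: np.ndarray,
    semiaxes: Sequence[float],
    rot: np.ndarray,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Chord length along z of an arbitrarily rotated ellipsoid, per (x, y)."""
    d = np.diag([1.0 / s**2 for s in semiaxes])
    m = rot @ d @ rot.T
    vx = x - center[0]
    vy = y - center[1]
    vz = -center[2]
    a = m[2, 2]
    b = 2.0 * (m[2, 0] * vx + m[2, 1] * vy + m[2, 2] * vz)
    c = (
        m[0, 0] * vx**2
        + 2.0 * m[0, 1] * vx * vy
        + m[1, 1] * vy**2
        + 2.0 * (m[0, 2] * vx + m[1, 2] * vy) * vz
        + m[2, 2] * vz**2
        - 1.0
    )
    disc = b**2 - 4.0 * a * c
    np.clip(disc, 0.0, None, out=disc)
    return np.sqrt(disc) / a


def _sphere_chords(x: np.ndarray, y: np.ndarray, radius: float, cx: float, cy: float) -> np.ndarray:
    d2 = radius**2 - (x - cx) ** 2 - (y - cy) ** 2
    np.clip(d2, 0.0, None, out=d2)
    return 2.0 * np.sqrt(d2)


def render_projection(
    phantom: CellPhantom,
    orientation=None,
    pixel_pitch: float = 0.16,
    shape: tuple[int, int] | None = None,
    supersample: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Project a phantom along the optical axis.

    Returns ``(opd_nm, amplitude)``: the optical path delay map in nm and the
    amplitude transmission map in [0, 1], both of the requested ``shape``
    (default: the smallest even square that contains the cell).  The grid is
    supersampled ``supersample`` times per axis and block-averaged, which
    antialiases the component rims.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be > 0")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    n_req = required_grid_size(phantom, pixel_pitch)
    if shape is None:
        side = n_req + (n_req % 2)
        shape = (side, side)
    if min(shape) < n_req:
        raise ValueError(
            f"grid {shape} too small for phantom of extent "
            f"{phantom.max_extent:.2f} um at {pixel_pitch} um/pixel: "
            f"need at least {n_req} pixels per side"
        )
    rot = _as_matrix(orientation)
    h, w = shape
    s = supersample
    fine_pitch = pixel_pitch / s
    yy = (np.arange(h * s) - (h * s - 1) / 2.0) * fine_pitch
    xx = (np.arange(w * s) - (w * s - 1) / 2.0) * fine_pitch
    x, y = np.meshgrid(xx, yy)

    body_axes = (phantom.elongation * phantom.radius, phantom.radius, phantom.radius)
    l_body = _ellipsoid_chords(x, y, body_axes, rot)

    opd_um = phantom.delta_n_cytoplasm * l_body
    if phantom.nucleus_radius > 0 and phantom.delta_n_nucleus != 0:
        nuc_axes = (
            phantom.elongation * phantom.nucleus_radius,
            phantom.nucleus_radius,
            phantom.nucleus_radius,
        )
        opd_um = opd_um + phantom.delta_n_nucleus * _ellipsoid_chords(x, y, nuc_axes, rot)

    l_gran = None
    if phantom.granule_count:
        lab_pos = phantom.granule_positions @ rot.T
        l_gran = np.zeros_like(l_body)
        for gx, gy, _gz in lab_pos:
            l_gran += _sphere_chords(x, y, phantom.granule_radius, gx, gy)
        if phantom.granule_delta_n != 0:
            opd_um = opd_um + phantom.granule_delta_n * l_gran

    attenuation = np.zeros_like(l_body)
    if phantom.amplitude_absorption > 0:
        a = min(phantom.amplitude_absorption, 1.0 - 1e-9)
        alpha = -math.log1p(-a) / (2.0 * phantom.radius)
        attenuation += alpha * l_body
    if phantom.granule_absorption > 0 and l_gran is not None:
        a = min(phantom.granule_absorption, 1.0 - 1e-9)
        alpha = -math.log1p(-a) / (2.0 * phantom.granule_radius)
        attenuation += alpha * l_gran
    amplitude = np.exp(-attenuation)

    opd_nm = 1000.0 * opd_um
    if s > 1:
        opd_nm = opd_nm.reshape(h, s, w, s).mean(axis=(1, 3))
        amplitude = amplitude.reshape(h, s, w, s).mean(axis=(1, 3))
    return opd_nm, amplitude


def render_opd_projection(
    phantom: CellPhantom,
    orientation=None,
    pixel_pitch: float = 0.16,
    shape: tuple[int, int] | None = None,
    supersample: int = 4,
    wavelength: float = 632.8,
) -> OPDMap:
    """Render only the OPD projection of a phantom (see
    :func:`render_projection`)."""
    opd_nm, _ = render_projection(
        phantom, orientation, pixel_pitch, shape=shape, supersample=supersample
    )
    return OPDMap(opd=opd_nm, wavelength=wavelength, pixel_pitch=pixel_pitch)


# ---------------------------------------------------------------------------
# Class-conditional phantom sampling
# ---------------------------------------------------------------------------

#: The three default synthetic classes.  They are designed so that single-view
#: classification is ambiguous but multiple rolled views (and amplitude
#: information) resolve it:
#:
#: * class 0 -- small homogeneous cell, no granules.
#: * class 1 -- round nucleated cell with absorbing granules; its peak OPD
#:   matches class 0 (the larger radius is compensated by a lower index
#:   difference), so the phase profile alone separates 0 from 1 only through
#:   the outline size, while the granules carry a mostly-amplitude signature.
#: * class 2 -- elongated (prolate) version of class 1 whose index
#:   differences are scaled so the end-on projection matches class 1; only a
#:   view off the long axis reveals the elongation.
DEFAULT_CLASS_NAMES = {0: "small-homogeneous", 1: "round-granular", 2: "elongated-granular"}


class PhantomSampler:
    """Class-conditional phantom distribution.

    ``params`` maps class label -> dict of distribution parameters (see
    :func:`default_phantom_sampler` for the default three classes).  Sampling
    is driven by a caller-supplied :class:`numpy.random.Generator`, so a
    fixed generator state yields identical phantoms.
    """

    def __init__(self, params: dict[int, dict]) -> None:
        if not params:
            raise ValueError("at least one class required")
        self.params = params

    @property
    def class_labels(self) -> list[int]:
        return sorted(self.params)

    def sample(self, label: int, rng: np.random.Generator) -> CellPhantom:
        if label not in self.params:
            raise KeyError(f"unknown class label {label}")
        p = self.params[label]
        radius = float(
            np.clip(
                rng.normal(p["radius_mean"], p["radius_sd"]),
                0.6 * p["radius_mean"],
                1.4 * p["radius_mean"],
            )
        )
        n_gran = int(p.get("granule_count", 0))
        if n_gran:
            # uniform inside a ball of 0.75 * radius, stretched with the body
            u = rng.normal(size=(n_gran, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            r = 0.75 * radius * rng.uniform(size=(n_gran, 1)) ** (1.0 / 3.0)
            pos = u * r
            pos[:, 0] *= p.get("elongation", 1.0)
        else:
            pos = np.zeros((0, 3))
        return CellPhantom(
            class_label=label,
            radius=radius,
            elongation=p.get("elongation", 1.0),
            delta_n_cytoplasm=p["delta_n_cytoplasm"],
            nucleus_radius=p.get("nucleus_fraction", 0.0) * radius,
            delta_n_nucleus=p.get("delta_n_nucleus", 0.0),
            granule_positions=pos,
            granule_radius=p.get("granule_radius", 0.5),
            granule_delta_n=p.get("granule_delta_n", 0.0),
            amplitude_absorption=p.get("amplitude_absorption", 0.0),
            granule_absorption=p.get("granule_absorption", 0.0),
        )

    def random_orientation(self, rng: np.random.Generator) -> Rotation:
        return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))


def default_phantom_sampler() -> PhantomSampler:
    """The three default synthetic classes (see module notes above)."""
    common = dict(
        nucleus_fraction=0.55,
        granule_radius=0.5,
        granule_delta_n=0.002,
        granule_absorption=0.55,
        amplitude_absorption=0.04,
    )
    params = {
        0: dict(
            radius_mean=3.7,
            radius_sd=0.30,
            delta_n_cytoplasm=0.0325,
            nucleus_fraction=0.55,
            delta_n_nucleus=0.010,
            amplitude_absorption=0.04,
        ),
        1: dict(
            common,
            radius_mean=4.0,
            radius_sd=0.30,
            delta_n_cytoplasm=0.030,
            delta_n_nucleus=0.010,
            granule_count=10,
        ),
        2: dict(
            common,
            radius_mean=4.0,
            radius_sd=0.30,
            elongation=1.5,
            delta_n_cytoplasm=0.020,
            delta_n_nucleus=0.0067,
            granule_count=10,
        ),
    }
    return PhantomSampler(params)
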