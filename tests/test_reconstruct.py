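import numpy as np
import pytest

from holoflow import (
    OpticalConfig,
    compensate_background,
    default_phantom_sampler,
    demodulate_exact,
    extract_wavefront,
    hologram_to_opd,
    imaged_opd,
    locate_carrier,
    phase_to_opd,
    render_projection,
    stability_maps,
    synthesize_hologram,
    unwrap_phase,
    zero_background,
)
from holoflow.types import OPDMap


def round_trip(shape=(128, 128), noise_sigma=0.0, seed=0):
    """Synthesize a hologram of a known cell and reconstruct it; returns
    (reconstructed OPD, ground-truth OPD after the imaging pupil)."""
    optics = OpticalConfig(noise_sigma=noise_sigma).snap_carrier(shape)
    phantom = default_phantom_sampler().sample(1, np.random.default_rng(seed))
    opd, amp = render_projection(
        phantom, pixel_pitch=optics.pixel_pitch, shape=shape, supersample=2
    )
    holo = synthesize_hologram(opd, amp, optics, seed=seed)
    background = synthesize_hologram(
        np.zeros(shape), 1.0, optics, seed=seed + 1
    )
    truth = zero_background(imaged_opd(opd, amp, optics))
    rec = hologram_to_opd(
        holo, optics.wavelength, background=background, positive_bias=True
    )
    return rec.opd, truth.opd


def test_round_trip_noiseless_subnanometer():
    rec, truth = round_trip(noise_sigma=0.0)
    rmse = float(np.sqrt(np.mean((rec - truth) ** 2)))
    assert rmse < 1.0  # nm


def test_round_trip_with_noise_under_5nm():
    rec, truth = round_trip(noise_sigma=0.01)
    rmse = float(np.sqrt(np.mean((rec - truth) ** 2)))
    assert rmse < 5.0  # nm


def test_phase_to_opd_formula_exact():
    # phase of exactly 2*pi at wavelength lambda is an OPD of exactly lambda
    out = phase_to_opd(2.0 * np.pi, 632.8)
    assert float(out.opd[0, 0]) == 632.8
    assert phase_to_opd(np.pi, 500.0).opd[0, 0] == pytest.approx(250.0, rel=1e-15)
    with pytest.raises(ValueError, match="wavelength"):
        phase_to_opd(1.0, 0.0)


def test_unwrap_linear_ramp():
    y, x = np.mgrid[0:128, 0:128]
    true_phase = 0.35 * x + 0.1 * y
    wrapped = np.angle(np.exp(1j * true_phase))
    unwrapped = unwrap_phase(wrapped)
    resid = unwrapped - true_phase
    resid -= resid.mean()  # unwrapping is defined up to a 2*pi offset
    assert np.abs(resid).max() < 1e-6
    # congruence postcondition
    assert np.allclose(np.angle(np.exp(1j * (unwrapped - wrapped))), 0.0, atol=1e-9)


def test_unwrap_rejects_nonfinite():
    bad = np.zeros((8, 8))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        unwrap_phase(bad)


def test_conjugate_reconstruction_antisymmetric():
    shape = (128, 128)
    optics = OpticalConfig().snap_carrier(shape)
    phantom = default_phantom_sampler().sample(0, np.random.default_rng(2))
    opd, amp = render_projection(
        phantom, pixel_pitch=optics.pixel_pitch, shape=shape, supersample=2
    )
    holo = synthesize_hologram(opd, amp, optics, seed=0)
    background = synthesize_hologram(np.zeros(shape), 1.0, optics, seed=1)
    plus = hologram_to_opd(holo, optics.wavelength, background=background)
    minus = hologram_to_opd(holo, optics.wavelength, background=background, conjugate=True)
    rmse = float(np.sqrt(np.mean((plus.opd + minus.opd) ** 2)))
    assert rmse < 1.0  # nm


def test_positive_bias_resolves_sign():
    shape = (128, 128)
    optics = OpticalConfig().snap_carrier(shape)
    phantom = default_phantom_sampler().sample(0, np.random.default_rng(2))
    opd, amp = render_projection(
        phantom, pixel_pitch=optics.pixel_pitch, shape=shape, supersample=2
    )
    holo = synthesize_hologram(opd, amp, optics, seed=0)
    bg = synthesize_hologram(np.zeros(shape), 1.0, optics, seed=1)
    a = hologram_to_opd(holo, optics.wavelength, background=bg, positive_bias=True)
    b = hologram_to_opd(
        holo, optics.wavelength, background=bg, conjugate=True, positive_bias=True
    )
    assert a.opd.sum() > 0 and b.opd.sum() > 0
    np.testing.assert_allclose(a.opd, b.opd, atol=1.0)


def test_locate_carrier_finds_pure_cosine():
    shape = (128, 128)
    fy, fx = 20 / 128, 28 / 128
    y, x = np.mgrid[0:128, 0:128]
    img = 2.0 + np.cos(2 * np.pi * (fx * x + fy * y))
    peak = locate_carrier(img)
    assert peak.freq == pytest.approx((fy, fx))
    assert peak.coords == (20, 28)
    conj = peak.conjugate()
    assert conj.coords == (-20, -28)


def test_locate_carrier_rejects_flat_image():
    with pytest.raises(ValueError, match="no carrier detected"):
        locate_carrier(np.ones((64, 64)))


def test_extract_wavefront_window_validation():
    shape = (128, 128)
    optics = OpticalConfig().snap_carrier(shape)
    holo = synthesize_hologram(np.zeros(shape), 1.0, optics, seed=0)
    peak = locate_carrier(holo.intensity)
    with pytest.raises(ValueError, match="window_radius"):
        extract_wavefront(holo, peak, window_radius=0.0)
    with pytest.raises(ValueError, match="overlaps the DC exclusion"):
        extract_wavefront(holo, peak, window_radius=0.4)


def test_demodulate_exact_matches_extract_on_grid_carrier():
    shape = (128, 128)
    optics = OpticalConfig().snap_carrier(shape)
    phantom = default_phantom_sampler().sample(0, np.random.default_rng(1))
    opd, amp = render_projection(
        phantom, pixel_pitch=optics.pixel_pitch, shape=shape, supersample=2
    )
    holo = synthesize_hologram(opd, amp, optics, seed=0)
    a = demodulate_exact(holo, optics.fringe)
    b = extract_wavefront(holo, locate_carrier(holo))
    np.testing.assert_allclose(a.field, b.field, atol=1e-8)


def test_compensate_background_validation():
    shape = (32, 32)
    optics = OpticalConfig().snap_carrier(shape)
    holo = synthesize_hologram(np.zeros(shape), 1.0, optics, seed=0)
    wf = demodulate_exact(holo, optics.fringe)
    small = demodulate_exact(
        synthesize_hologram(np.zeros((16, 16)), 1.0, OpticalConfig().snap_carrier((16, 16)), seed=0),
        OpticalConfig().snap_carrier((16, 16)).fringe,
    )
    with pytest.raises(ValueError, match="shape mismatch"):
        compensate_background(wf, small)
    from holoflow.types import ComplexWavefront

    zero_bg = ComplexWavefront(field=np.zeros(shape, complex), background_compensated=False)
    with pytest.raises(ValueError, match="floor"):
        compensate_background(wf, zero_bg)


def test_zero_background_median_ring():
    m = np.full((64, 64), 7.0)
    m[20:40, 20:40] += 100.0
    out = zero_background(OPDMap(opd=m, wavelength=632.8))
    assert out.opd[0, 0] == pytest.approx(0.0)
    assert out.opd[30, 30] == pytest.approx(100.0)
    with pytest.raises(ValueError, match="too small"):
        zero_background(OPDMap(opd=np.zeros((10, 10)), wavelength=632.8))


def test_stability_maps_match_numpy():
    rng = np.random.default_rng(0)
    stack = rng.normal(size=(6, 16, 16))
    s = stability_maps(stack)
    np.testing.assert_allclose(s.temporal_std_map, stack.std(axis=0))
    np.testing.assert_allclose(s.spatial_std_series, stack.std(axis=(1, 2)))
    assert s.mean_temporal_std == pytest.approx(stack.std(axis=0).mean())
    with pytest.raises(ValueError, match="at least 2"):
        stability_maps(stack[:1])
    with pytest.raises(ValueError, match="share one shape"):
        stability_maps([stack[0], stack[1][:8]])
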