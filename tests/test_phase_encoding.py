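"""Glyph generation, hologram encoding/demodulation, input-field synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from vecspeckle.phase_encoding import (
    Hologram,
    PhaseTarget,
    demodulate_hologram,
    encode_hologram,
    generate_glyph,
    synthesize_input_field,
)


def _wrapped_rms(err: np.ndarray) -> float:
    """RMS phase error after removing the global constant offset."""
    err = err - np.angle(np.exp(1j * err).mean())
    return float(np.sqrt(np.mean(np.angle(np.exp(1j * err)) ** 2)))


class TestGlyphs:
    @pytest.mark.parametrize("style", ["digit-like", "blobs", "rings"])
    def test_deterministic_normalized_and_supported(self, style):
        a = generate_glyph(style, 32, seed=7)
        b = generate_glyph(style, 32, seed=7)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 1
        assert 0.05 <= np.mean(a > 0.1) <= 0.40

    def test_different_seeds_differ(self):
        a = generate_glyph("digit-like", 64, seed=1)
        b = generate_glyph("digit-like", 64, seed=2)
        assert np.abs(a - b).max() > 0.1

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            generate_glyph("stripes", 32, seed=0)
        with pytest.raises(ValueError):
            generate_glyph("blobs", 8, seed=0)


class TestPhaseTarget:
    def test_single_mode_shares_phase_maps(self):
        g = generate_glyph("blobs", 32, seed=3)
        t = PhaseTarget(g)
        np.testing.assert_array_equal(t.delta1, t.delta2)
        np.testing.assert_allclose(t.delta1, np.pi * g)

    def test_dual_mode_requires_second_glyph(self):
        g = generate_glyph("blobs", 32, seed=3)
        with pytest.raises(ValueError):
            PhaseTarget(g, mode="dual")
        t = PhaseTarget(g, generate_glyph("blobs", 32, seed=4), mode="dual")
        assert t.labels().shape == (2, 32, 32)
        assert np.abs(t.delta1 - t.delta2).max() > 0


class TestEncode:
    def test_zero_phase_peak_transmittance(self):
        # at the pixel where both carriers have zero phase, t = 1 + 1/2 + 1/2
        t = PhaseTarget(np.zeros((64, 64)))
        holo = encode_hologram(t, f0=8, gamma=1.0)
        assert holo.transmittance[0, 0] == pytest.approx(2.0)

    def test_pi_phase_cancels_one_carrier(self):
        g = np.ones((64, 64))
        t = PhaseTarget(g, np.zeros((64, 64)), phase_scale=np.pi, mode="dual")
        holo = encode_hologram(t, f0=8, gamma=1.0)
        # cos(0 + pi) = -1 on the x carrier, cos(0) = +1 on the y carrier
        assert holo.transmittance[0, 0] == pytest.approx(1.0)

    def test_matches_direct_evaluation(self, rng):
        g1 = ndimage.gaussian_filter(rng.random((48, 48)), 3)
        g2 = ndimage.gaussian_filter(rng.random((48, 48)), 3)
        g1, g2 = g1 / g1.max(), g2 / g2.max()
        t = PhaseTarget(g1, g2, mode="dual")
        f0, gamma = 8.0, 0.8
        holo = encode_hologram(t, f0=f0, gamma=gamma)
        x = np.arange(48)[None, :] / 48
        y = np.arange(48)[:, None] / 48
        direct = (
            1
            + gamma / 2 * np.cos(2 * np.pi * f0 * x + np.pi * g1)
            + gamma / 2 * np.cos(2 * np.pi * f0 * y + np.pi * g2)
        )
        assert np.abs(holo.transmittance - direct).max() < 1e-12

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(gamma=st.floats(0.05, 1.0), f0=st.floats(8.0, 16.0), seed=st.integers(0, 50))
    def test_transmittance_bounds(self, gamma, f0, seed):
        g = ndimage.gaussian_filter(np.random.default_rng(seed).random((32, 32)), 3)
        holo = encode_hologram(PhaseTarget(g / g.max()), f0=f0, gamma=gamma)
        assert holo.transmittance.min() >= 1 - gamma - 1e-9
        assert holo.transmittance.max() <= 1 + gamma + 1e-9

    def test_rejects_low_carrier_and_bad_gamma(self):
        g = generate_glyph("blobs", 32, seed=5)
        with pytest.raises(ValueError):
            encode_hologram(PhaseTarget(g), f0=2.0)
        with pytest.raises(ValueError):
            encode_hologram(PhaseTarget(g), f0=8.0, gamma=0.0)


class TestDemodulate:
    def test_constant_phases_recovered(self):
        H = 128
        t = PhaseTarget(np.full((H, H), 1.0 / np.pi), np.full((H, H), 2.0 / np.pi), mode="dual")
        holo = encode_hologram(t, f0=16, gamma=1.0)
        d1, d2 = demodulate_hologram(holo)
        for rec, true in ((d1, 1.0), (d2, 2.0)):
            err = rec - true
            assert _wrapped_rms(err) < 1e-6
            assert np.ptp(np.angle(np.exp(1j * (rec - true)))) < 1e-6

    def test_smooth_roundtrip_rms(self, rng):
        # Gaussian-filtered noise targets (sigma = 4 px, 128 x 128) hard-limited
        # below f0/2 = 8 cycles so the bandlimited round-trip contract applies
        fr = np.hypot(np.fft.fftfreq(128)[:, None], np.fft.fftfreq(128)[None, :]) * 128
        maps = []
        for _ in range(2):
            g = ndimage.gaussian_filter(rng.standard_normal((128, 128)), 4)
            g = np.fft.ifft2(np.fft.fft2(g) * (fr <= 7.5)).real
            g = (g - g.min()) / np.ptp(g)
            maps.append(g)
        t = PhaseTarget(maps[0], maps[1], mode="dual")
        holo = encode_hologram(t, f0=16, gamma=1.0)
        d1, d2 = demodulate_hologram(holo)
        assert _wrapped_rms(d1 - t.delta1) < 0.05
        assert _wrapped_rms(d2 - t.delta2) < 0.05

    def test_zero_modulation_rejected(self):
        holo = Hologram(np.ones((32, 32)), carrier_frequency=8, modulation_depth=0.0)
        with pytest.raises(ValueError):
            demodulate_hologram(holo)


class TestInputField:
    def test_scalar_mode_has_no_y_component(self):
        g = generate_glyph("digit-like", 32, seed=9)
        f = synthesize_input_field(PhaseTarget(g), polarization="scalar")
        assert np.abs(f.ey).max() == 0.0
        np.testing.assert_allclose(np.abs(f.ex), 1.0)

    def test_vector_hv_zero_phase_normalization(self):
        t = PhaseTarget(np.zeros((16, 16)))
        f = synthesize_input_field(t, basis="HV")
        np.testing.assert_allclose(f.ex, 1 / np.sqrt(2))
        np.testing.assert_allclose(f.ey, 1 / np.sqrt(2))
        assert f.power == pytest.approx(16 * 16)

    def test_circular_equal_phases_reduce_to_single_component(self):
        g = generate_glyph("blobs", 32, seed=10)
        t = PhaseTarget(g)
        f_circ = synthesize_input_field(t, basis="circular")
        f_hv = synthesize_input_field(t, basis="HV")
        # equal phases on L and R interfere into pure x polarization
        np.testing.assert_allclose(f_circ.ex, np.exp(1j * t.delta1), atol=1e-12)
        np.testing.assert_allclose(np.abs(f_circ.ey), 0, atol=1e-12)
        assert abs(f_circ.power - f_hv.power) < 1e-12 * f_hv.power

    @pytest.mark.parametrize("basis", ["HV", "circular"])
    @pytest.mark.parametrize("polarization", ["vector", "scalar"])
    def test_power_conservation(self, basis, polarization):
        g1 = generate_glyph("digit-like", 32, seed=20)
        g2 = generate_glyph("digit-like", 32, seed=21)
        t = PhaseTarget(g1, g2, mode="dual")
        f = synthesize_input_field(t, basis=basis, polarization=polarization)
        assert f.power == pytest.approx(32 * 32, rel=1e-10)

    def test_unknown_basis_rejected(self):
        t = PhaseTarget(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            synthesize_input_field(t, basis="diagonal")
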