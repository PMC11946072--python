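"""Vector-transmission-matrix and layered-medium physics."""

import dataclasses

import numpy as np
import pytest

from vecspeckle.fields import JonesField
from vecspeckle.phase_encoding import PhaseTarget, generate_glyph, synthesize_input_field
from vecspeckle.scattering import (
    drift_medium,
    effective_vtm,
    propagate,
    record_speckle,
    sample_dense_vtm,
    sample_layered_medium,
)
from vecspeckle.training import pcc


def _random_field(rng, n, bandlimit=None):
    def comp():
        f = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        if bandlimit is not None:
            fr = np.hypot(np.fft.fftfreq(n)[:, None], np.fft.fftfreq(n)[None, :])
            f = np.fft.ifft2(np.fft.fft2(f) * (fr <= bandlimit))
        return f

    return JonesField(comp(), comp())


class TestDenseVTM:
    def test_isotropic_limit_zero_cross_blocks(self):
        m = sample_dense_vtm(12, coupling=0.0, seed=1)
        assert np.abs(m.t12).max() == 0.0
        assert np.abs(m.t21).max() == 0.0

    def test_isotropic_medium_keeps_polarizations_independent(self, rng):
        m = sample_dense_vtm(12, coupling=0.0, seed=2)
        f = JonesField(rng.standard_normal((12, 12)) + 0j, np.zeros((12, 12)))
        out = propagate(f, m)
        assert np.abs(out.ey).max() == 0.0

    def test_ballistic_only_is_identity(self, rng):
        m = sample_dense_vtm(10, coupling=0.3, ballistic_fraction=1.0, transmissivity=1.0, seed=3)
        f = _random_field(rng, 10)
        out = propagate(f, m)
        np.testing.assert_allclose(out.ex, f.ex, atol=1e-12)
        np.testing.assert_allclose(out.ey, f.ey, atol=1e-12)

    def test_ensemble_power_expectation(self, rng):
        # mean transmitted power over the medium ensemble approaches eta * P_in
        f = _random_field(rng, 16)
        ratios = []
        for seed in range(200):
            m = sample_dense_vtm(16, coupling=0.5, ballistic_fraction=0.0,
                                 transmissivity=1.0, seed=seed)
            ratios.append(propagate(f, m).power / f.power)
        assert 0.9 <= np.mean(ratios) <= 1.1

    def test_deterministic_given_seed(self):
        a = sample_dense_vtm(8, seed=5)
        b = sample_dense_vtm(8, seed=5)
        np.testing.assert_array_equal(a.t11, b.t11)
        np.testing.assert_array_equal(a.t12, b.t12)

    def test_grid_cap_enforced(self):
        with pytest.raises(ValueError, match="layered"):
            sample_dense_vtm(64, seed=0)


class TestLayeredMedium:
    def test_single_isotropic_screen_preserves_amplitude(self, rng):
        m = sample_layered_medium(16, n_layers=1, coupling=0.0, layer_spacing=0.0, seed=1)
        f = _random_field(rng, 16)
        out = propagate(f, m)
        np.testing.assert_allclose(np.abs(out.ex), np.abs(f.ex), atol=1e-10)
        np.testing.assert_allclose(np.abs(out.ey), np.abs(f.ey), atol=1e-10)

    def test_screens_are_unitary(self):
        m = sample_layered_medium(8, n_layers=3, coupling=0.8, seed=2)
        for i in range(3):
            j = m.screen(i)
            prod = np.einsum("...ij,...kj->...ik", j, j.conj())
            np.testing.assert_allclose(prod, np.broadcast_to(np.eye(2), prod.shape), atol=1e-12)

    def test_power_conserved_for_bandlimited_input(self, rng):
        m = sample_layered_medium(32, n_layers=6, coupling=0.5, seed=3)
        f = _random_field(rng, 32, bandlimit=0.25)
        ratio = propagate(f, m).power / f.power
        assert 0.99 <= ratio <= 1.0 + 1e-9

    def test_more_layers_decorrelate_from_identity(self):
        # correlation between the output intensity and the unscattered (L=0)
        # intensity strictly decreases with depth (averaged over seeds);
        # an amplitude-structured input makes the reference non-degenerate
        g = generate_glyph("digit-like", 32, seed=4)
        f = JonesField(g.astype(complex), np.zeros_like(g, dtype=complex))
        ref = f.intensity
        means = []
        for n_layers in (1, 3, 6):
            cors = []
            for seed in range(20):
                m = sample_layered_medium(32, n_layers=n_layers, coupling=0.5, seed=seed)
                cors.append(pcc(propagate(f, m).intensity, ref))
            means.append(np.mean(cors))
        assert means[0] > means[1] > means[2]


class TestPropagation:
    @pytest.mark.parametrize("kind", ["dense", "layered"])
    def test_linearity(self, kind, rng):
        n = 12
        if kind == "dense":
            medium = sample_dense_vtm(n, coupling=0.5, seed=7)
        else:
            medium = sample_layered_medium(n, n_layers=3, coupling=0.5, seed=7)
        f1, f2 = _random_field(rng, n), _random_field(rng, n)
        a, b = 0.7 - 0.2j, -1.1 + 0.5j
        combined = propagate(a * f1 + b * f2, medium)
        separate = a * propagate(f1, medium) + b * propagate(f2, medium)
        np.testing.assert_allclose(combined.ex, separate.ex, atol=1e-10)
        np.testing.assert_allclose(combined.ey, separate.ey, atol=1e-10)

    def test_grid_mismatch_rejected(self, rng):
        m = sample_dense_vtm(8, seed=0)
        with pytest.raises(ValueError, match="grid"):
            propagate(_random_field(rng, 16), m)


class TestEffectiveVTM:
    def test_reproduces_layered_propagation(self, rng):
        m = sample_layered_medium(8, n_layers=3, coupling=0.5, seed=9)
        dense = effective_vtm(m)
        for _ in range(5):
            f = _random_field(rng, 8)
            a = propagate(f, m)
            b = propagate(f, dense)
            assert np.abs(a.ex - b.ex).max() < 1e-8
            assert np.abs(a.ey - b.ey).max() < 1e-8

    def test_no_layers_gives_identity(self, rng):
        m = sample_layered_medium(6, n_layers=0, seed=1)
        dense = effective_vtm(m)
        n = 36
        np.testing.assert_allclose(dense.t11, np.eye(n), atol=1e-12)
        np.testing.assert_allclose(dense.t22, np.eye(n), atol=1e-12)
        np.testing.assert_allclose(dense.t12, 0, atol=1e-12)

    def test_isotropic_layers_have_no_cross_blocks(self):
        m = sample_layered_medium(8, n_layers=4, coupling=0.0, seed=2)
        dense = effective_vtm(m)
        assert np.abs(dense.t12).max() < 1e-10
        assert np.abs(dense.t21).max() < 1e-10

    def test_large_grid_rejected(self):
        m = sample_layered_medium(32, n_layers=1, seed=0)
        with pytest.raises(ValueError):
            effective_vtm(m)


class TestDrift:
    def test_zero_rate_is_identity(self):
        m = sample_dense_vtm(8, seed=1)
        assert drift_medium(m, 0.0) is m

    def test_full_rate_gives_independent_medium(self):
        # speckle correlation after a rate-1 step matches that between
        # unrelated media (both near zero)
        g = generate_glyph("blobs", 16, seed=0)
        f = synthesize_input_field(PhaseTarget(g))
        cor_drift, cor_fresh = [], []
        for seed in range(50):
            m0 = sample_dense_vtm(16, ballistic_fraction=0.0, seed=seed)
            i0 = propagate(f, m0).intensity
            m1 = drift_medium(m0, 1.0)
            cor_drift.append(pcc(i0, propagate(f, m1).intensity))
            m2 = sample_dense_vtm(16, ballistic_fraction=0.0, seed=10_000 + seed)
            cor_fresh.append(pcc(i0, propagate(f, m2).intensity))
        assert abs(np.mean(cor_drift) - np.mean(cor_fresh)) < 0.1

    @pytest.mark.parametrize("kind", ["dense", "layered"])
    def test_decorrelation_is_monotone(self, kind):
        from scipy.stats import spearmanr

        g = generate_glyph("blobs", 16, seed=1)
        f = synthesize_input_field(PhaseTarget(g))
        n_steps, n_real = 8, 30
        curves = np.zeros((n_real, n_steps + 1))
        for r in range(n_real):
            if kind == "dense":
                m = sample_dense_vtm(16, ballistic_fraction=0.1, seed=r)
            else:
                m = sample_layered_medium(16, n_layers=3, coupling=0.5, seed=r)
            i0 = propagate(f, m).intensity
            curves[r, 0] = 1.0
            for t in range(1, n_steps + 1):
                m = drift_medium(m, 0.1)
                curves[r, t] = pcc(i0, propagate(f, m).intensity)
        mean_curve = curves.mean(axis=0)
        rho = spearmanr(np.arange(n_steps + 1), mean_curve).statistic
        assert rho < -0.9

    def test_drift_preserves_statistics(self):
        # repeated drift leaves block variance at its stationary value
        m = sample_dense_vtm(12, coupling=0.4, ballistic_fraction=0.2, seed=3)
        v0 = np.var(m.diffuse["xx"])
        for _ in range(5):
            m = drift_medium(m, 0.5)
        assert np.var(m.diffuse["xx"]) == pytest.approx(v0, rel=0.2)


class TestCamera:
    def test_uniform_field_normalizes_to_one(self):
        f = JonesField(np.ones((8, 8)), np.zeros((8, 8)))
        rec = record_speckle(f)
        np.testing.assert_allclose(rec.intensity, 1.0)

    def test_intensity_is_sum_of_component_intensities(self, rng):
        f = _random_field(rng, 16)
        fx = JonesField(f.ex, np.zeros_like(f.ex))
        fy = JonesField(np.zeros_like(f.ey), f.ey)
        total = fx.intensity + fy.intensity
        np.testing.assert_allclose(f.intensity, total, atol=1e-12)

    def test_fully_developed_speckle_contrast(self, rng):
        # single-polarization diffuse output: exponential intensity, contrast 1
        contrasts = []
        g = generate_glyph("blobs", 32, seed=5)
        f = synthesize_input_field(PhaseTarget(g), polarization="scalar")
        for seed in range(10):
            m = sample_dense_vtm(32, coupling=0.0, ballistic_fraction=0.0, seed=seed)
            i = propagate(f, m).intensity
            contrasts.append(i.std() / i.mean())
        assert 0.85 <= np.mean(contrasts) <= 1.15

    def test_quantization_levels(self, rng):
        f = _random_field(rng, 16)
        rec = record_speckle(f, quantize=2)
        # renormalized 2-bit frame: at most 4 distinct levels
        assert len(np.unique(rec.intensity)) <= 4

    def test_shot_noise_reproducible(self, rng):
        f = _random_field(rng, 16)
        a = record_speckle(f, noise=100.0, seed=4)
        b = record_speckle(f, noise=100.0, seed=4)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        c = record_speckle(f, noise=100.0, seed=5)
        assert np.abs(a.intensity - c.intensity).max() > 0
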