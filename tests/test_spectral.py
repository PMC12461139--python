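"""Spectral decomposition identity, directed-term oracles, band integration."""

import numpy as np
import pytest

import dyadcausal.var as dv
from dyadcausal.spectral import (
    CausalSpectrum,
    band_integrate,
    causal_spectrum,
    decompose,
)

FS = 10.17


def bivariate_geweke_oracle(A1, sigma, omegas):
    """Directed spectra of a bivariate VAR(1) with diagonal Sigma, evaluated
    directly from the closed-form 2x2 transfer function (independent of the
    state-space code path)."""
    f12, f21 = [], []
    for w in omegas:
        H = np.linalg.inv(np.eye(2) - A1 * np.exp(-1j * w))
        s11 = (abs(H[0, 0]) ** 2 * sigma[0, 0]
               + abs(H[0, 1]) ** 2 * sigma[1, 1])
        s22 = (abs(H[1, 1]) ** 2 * sigma[1, 1]
               + abs(H[1, 0]) ** 2 * sigma[0, 0])
        f12.append(np.log(s22 / (abs(H[1, 1]) ** 2 * sigma[1, 1])))
        f21.append(np.log(s11 / (abs(H[0, 0]) ** 2 * sigma[0, 0])))
    return np.array(f12), np.array(f21)


def random_bivariate_var1(rng):
    while True:
        A1 = rng.uniform(-0.9, 0.9, size=(2, 2))
        if np.max(np.abs(np.linalg.eigvals(A1))) < 0.95:
            break
    sigma = np.diag(rng.uniform(0.5, 2.0, size=2))
    return dv.VARModel(coeffs=A1[None], sigma=sigma, order=1, n_effective=100)


class TestDecomposition:
    def test_three_way_identity_random_models(self, rng):
        grid = dv.FrequencyGrid.linspace(FS, 129)
        worst = 0.0
        for dim, order in [(4, 1), (4, 2), (6, 1), (6, 2)]:
            for _ in range(10):
                model = dv.random_stable_var(dim, order, rng)
                dec = decompose(dv.var_to_state_space(model, fs=FS), grid,
                                n_model=dim // 2)
                worst = max(worst, dec.identity_residual())
        assert worst < 1e-8

    def test_independent_blocks_zero_coupling(self):
        coeffs = np.zeros((1, 4, 4))
        coeffs[0, :2, :2] = [[0.5, 0.1], [0.0, 0.4]]
        coeffs[0, 2:, 2:] = [[0.3, 0.0], [0.2, 0.6]]
        sigma = np.eye(4)
        sigma[0, 1] = sigma[1, 0] = 0.3
        sigma[2, 3] = sigma[3, 2] = -0.2
        model = dv.VARModel(coeffs=coeffs, sigma=sigma, order=1,
                            n_effective=100)
        grid = dv.FrequencyGrid.linspace(FS, 65)
        dec = decompose(dv.var_to_state_space(model, fs=FS), grid, n_model=2,
                        sigma_ridge=0.0)
        for arr in (dec.f_total, dec.f_m_to_i, dec.f_i_to_m, dec.f_inst):
            assert np.abs(arr).max() < 1e-10

    def test_bivariate_closed_form_oracle(self, rng):
        grid = dv.FrequencyGrid.linspace(FS, 129)
        worst = 0.0
        for _ in range(20):
            model = random_bivariate_var1(rng)
            dec = decompose(dv.var_to_state_space(model, fs=FS), grid,
                            n_model=1, sigma_ridge=0.0)
            f12, f21 = bivariate_geweke_oracle(model.coeffs[0], model.sigma,
                                               grid.omega)
            worst = max(worst,
                        np.abs(dec.f_m_to_i - f12).max(),
                        np.abs(dec.f_i_to_m - f21).max())
        assert worst < 1e-5

    def test_directed_terms_nonnegative(self, rng):
        grid = dv.FrequencyGrid.linspace(FS, 65)
        for _ in range(20):
            model = dv.random_stable_var(4, 2, rng)
            dec = decompose(dv.var_to_state_space(model, fs=FS), grid,
                            n_model=2)
            assert dec.f_m_to_i.min() > -1e-6
            assert dec.f_i_to_m.min() > -1e-6
            clamped = dec.clamped()
            assert clamped.f_m_to_i.min() >= 0.0

    def test_invalid_block_split_rejected(self, rng):
        model = dv.random_stable_var(4, 1, rng)
        grid = dv.FrequencyGrid.linspace(FS, 65)
        with pytest.raises(ValueError, match="n_model"):
            decompose(dv.var_to_state_space(model, fs=FS), grid, n_model=4)


class TestCausalSpectrum:
    def test_symmetric_system_zero_causality(self):
        # swapping the two channels leaves the model invariant
        coeffs = np.array([[[0.4, 0.2], [0.2, 0.4]]])
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        model = dv.VARModel(coeffs=coeffs, sigma=sigma, order=1,
                            n_effective=100)
        grid = dv.FrequencyGrid.linspace(FS, 65)
        cs = causal_spectrum(decompose(dv.var_to_state_space(model, fs=FS),
                                       grid, n_model=1))
        assert np.abs(cs.c).max() < 1e-10

    def test_relabelling_negates_c_exactly(self, rng):
        model = dv.random_stable_var(4, 2, rng)
        grid = dv.FrequencyGrid.linspace(FS, 65)
        perm = [2, 3, 0, 1]
        swapped = dv.VARModel(
            coeffs=model.coeffs[:, perm][:, :, perm],
            sigma=model.sigma[np.ix_(perm, perm)],
            order=2, n_effective=model.n_effective)
        c1 = causal_spectrum(decompose(dv.var_to_state_space(model, fs=FS),
                                       grid, n_model=2)).c
        c2 = causal_spectrum(decompose(dv.var_to_state_space(swapped, fs=FS),
                                       grid, n_model=2)).c
        np.testing.assert_allclose(c2, -c1, atol=1e-12)

    def test_unidirectional_coupling_positive_at_peak(self):
        model = dv.VARModel(coeffs=np.array([[[0.9, 0.0], [0.16, 0.8]]]),
                            sigma=np.eye(2), order=1, n_effective=100)
        grid = dv.FrequencyGrid.linspace(FS, 129)
        dec = decompose(dv.var_to_state_space(model, fs=FS), grid, n_model=1)
        cs = causal_spectrum(dec)
        assert cs.c[np.argmax(dec.f_m_to_i)] > 0
        assert np.abs(dec.f_i_to_m).max() < 1e-10   # no reverse path


class TestBandIntegrate:
    def flat_spectrum(self, c, n=513):
        grid = dv.FrequencyGrid.linspace(FS, n)
        arr = np.full(len(grid), float(c))
        return CausalSpectrum(grid=grid, c=arr, f_m_to_i=np.maximum(arr, 0),
                              f_i_to_m=np.maximum(-arr, 0))

    def test_zero_integrand(self):
        assert band_integrate(self.flat_spectrum(0.0), use_mask=False).value == 0.0

    def test_constant_integrand_arithmetic(self):
        c = 1.7
        f1, f2 = 0.008, 0.08
        out = band_integrate(self.flat_spectrum(c), (f1, f2), use_mask=False)
        w1, w2 = 2 * np.pi * f1 / FS, 2 * np.pi * f2 / FS
        assert out.value == pytest.approx(c * (w2 - w1) / (4 * np.pi))
        assert out.intensity == pytest.approx(abs(out.value))

    def test_grid_refinement_converges(self, rng):
        model = dv.random_stable_var(4, 2, rng)
        vals = {}
        for n in (513, 1025):
            grid = dv.FrequencyGrid.linspace(FS, n)
            cs = causal_spectrum(decompose(
                dv.var_to_state_space(model, fs=FS), grid, n_model=2))
            vals[n] = band_integrate(cs, (0.5, 4.0), use_mask=False).value
        assert vals[1025] == pytest.approx(vals[513], rel=1e-4, abs=1e-12)

    def test_mask_required_when_requested(self):
        with pytest.raises(ValueError, match="mask"):
            band_integrate(self.flat_spectrum(1.0), use_mask=True)

    def test_all_false_masks_give_exact_zero(self):
        cs = self.flat_spectrum(1.0)
        masked = CausalSpectrum(
            grid=cs.grid, c=cs.c, f_m_to_i=cs.f_m_to_i, f_i_to_m=cs.f_i_to_m,
            mask_m_to_i=np.zeros(len(cs.grid), bool),
            mask_i_to_m=np.zeros(len(cs.grid), bool))
        assert band_integrate(masked, use_mask=True).value == 0.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            band_integrate(self.flat_spectrum(1.0), (0.08, 0.008),
                           use_mask=False)
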