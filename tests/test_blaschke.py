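"""Adaptive Blaschke transform: kernels, selection, recursion, spectrum."""

import numpy as np
import pytest

from ebmd.blaschke import (
    AnalyticSignal,
    BlaschkeDecomposer,
    DiskDictionary,
    analytic_extension,
    blaschke_factor,
    blaschke_mono_component,
    blaschke_spectrum,
    blaschke_transform,
    partial_reconstruction,
    quasi_periodicity_score,
    residual_update,
    select_parameter,
    szego_kernel,
    unit_circle_grid,
)


class TestAnalyticExtension:
    def test_real_part_round_trip(self, rng):
        x = rng.standard_normal(300)
        a = analytic_extension(x, 100.0)
        np.testing.assert_allclose(a.samples.real, x, atol=1e-10)

    def test_cosine_gives_complex_exponential(self):
        n = 256
        t = np.arange(n)
        x = np.cos(2 * np.pi * t / n)
        a = analytic_extension(x, 1.0)
        np.testing.assert_allclose(a.samples, np.exp(2j * np.pi * t / n), atol=1e-10)

    def test_constant_passthrough(self):
        a = analytic_extension(np.full(64, 3.5), 10.0)
        np.testing.assert_allclose(a.samples, np.full(64, 3.5 + 0j), atol=1e-12)

    def test_negative_frequencies_vanish(self, rng):
        x = rng.standard_normal(128)
        spec = np.fft.fft(analytic_extension(x, 1.0).samples)
        assert np.max(np.abs(spec[65:])) < 1e-9 * np.max(np.abs(spec))

    @pytest.mark.parametrize("bad", [np.full(4, 1.0), np.array([1.0, np.nan] * 8)])
    def test_input_validation(self, bad):
        with pytest.raises(ValueError):
            analytic_extension(bad, 1.0)


class TestSzegoKernel:
    def test_zero_parameter_is_constant_one(self, grid256):
        np.testing.assert_allclose(szego_kernel(0.0, grid256), np.ones(256))

    def test_closed_form_hand_value(self):
        val = szego_kernel(0.5, np.array([1.0 + 0j]))[0]
        assert val == pytest.approx(np.sqrt(0.75) / 0.5, abs=1e-12)
        assert val == pytest.approx(1.7320508, abs=1e-6)

    def test_unit_norm_on_fine_grid(self):
        grid = unit_circle_grid(4096)
        kern = szego_kernel(0.3 + 0.2j, grid)
        assert np.mean(np.abs(kern) ** 2) == pytest.approx(1.0, abs=1e-4)

    def test_discrete_normalization_exact(self, grid256):
        kern = szego_kernel(0.8j, grid256, normalize="discrete")
        assert np.mean(np.abs(kern) ** 2) == pytest.approx(1.0, abs=1e-14)

    def test_outside_disk_rejected(self, grid256):
        with pytest.raises(ValueError):
            szego_kernel(1.0, grid256)


class TestMonoComponent:
    def test_first_order_with_zero_parameter_is_one(self, grid256):
        b1 = blaschke_mono_component([0.0, 0.3], 1, grid256)
        np.testing.assert_allclose(b1, np.ones(256), atol=1e-12)

    def test_all_zero_parameters_give_powers(self, grid256):
        params = np.zeros(5)
        for n in range(1, 6):
            bn = blaschke_mono_component(params, n, grid256)
            np.testing.assert_allclose(bn, grid256 ** (n - 1), atol=1e-10)

    def test_blaschke_factors_unimodular(self, rng):
        grid = unit_circle_grid(128)
        for _ in range(10):
            a = 0.95 * np.sqrt(rng.uniform()) * np.exp(2j * np.pi * rng.uniform())
            np.testing.assert_allclose(
                np.abs(blaschke_factor(a, grid)), np.ones(128), atol=1e-10)

    def test_orthonormality(self, rng):
        n = 2048
        grid = unit_circle_grid(n)
        params = 0.7 * np.sqrt(rng.uniform(size=6)) * np.exp(
            2j * np.pi * rng.uniform(size=6))
        comps = [blaschke_mono_component(params, k, grid) for k in range(1, 7)]
        gram = np.array([[np.mean(u * np.conj(v)) for v in comps] for u in comps])
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-6)


class TestQuasiPeriodicityScore:
    def test_matches_direct_autocorrelation_summation(self, rng):
        for _ in range(5):
            for x in (rng.standard_normal(64),
                      rng.standard_normal(64) + 1j * rng.standard_normal(64)):
                lags = [np.sum(x[m:] * np.conj(x[: x.size - m])) / x.size
                        for m in range(1, x.size)]
                direct = abs(np.sum(lags)) / x.size
                assert quasi_periodicity_score(x) == pytest.approx(direct, abs=1e-12)

    def test_zero_and_sign_flip(self, rng):
        assert quasi_periodicity_score(np.zeros(32)) == 0.0
        x = rng.standard_normal(100)
        assert quasi_periodicity_score(x) == pytest.approx(
            quasi_periodicity_score(-x), abs=1e-15)

    def test_periodic_component_beats_white_noise(self):
        # equal-energy comparison over 100 seeds; the mono-component keeps its
        # autocorrelation coherent across lags, noise cancels
        grid = unit_circle_grid(512)
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = 0.5 * np.exp(2j * np.pi * r.uniform())
            periodic = szego_kernel(a, grid).real
            periodic /= np.sqrt(np.mean(periodic**2))
            noise = r.standard_normal(512)
            noise /= np.sqrt(np.mean(noise**2))
            wins += quasi_periodicity_score(periodic) > quasi_periodicity_score(noise)
        assert wins == 100


class TestSelectParameter:
    def test_single_atom_dictionary(self, rng):
        d = DiskDictionary(np.array([0.4 + 0.1j]))
        x = rng.standard_normal(128)
        assert select_parameter(analytic_extension(x, 1.0), d) == 0.4 + 0.1j

    def test_agrees_with_exhaustive_scan_oracle(self, rng):
        d = DiskDictionary.polar(radii=(0.2, 0.5, 0.8), phase_count=8)
        grid = unit_circle_grid(256)
        for _ in range(10):
            f = analytic_extension(rng.standard_normal(256), 1.0)
            got = select_parameter(f, d)
            scores = []
            for a in d.atoms:
                kern = szego_kernel(complex(a), grid, normalize="discrete")
                c = np.mean(f.samples * np.conj(kern))
                scores.append(quasi_periodicity_score(c * kern))
            want = complex(d.atoms[int(np.argmax(scores))])
            assert got == want

    def test_planted_atom_recovery(self):
        # single-radius dictionary (plus origin): the planted kernel's
        # projection dominates every same-radius competitor
        d = DiskDictionary.polar(radii=(0.3,), phase_count=8)
        grid = unit_circle_grid(512)
        for seed, idx in enumerate([1, 3, 5, 8]):
            a_star = complex(d.atoms[idx])
            r = np.random.default_rng(seed)
            x = 2.0 * szego_kernel(a_star, grid, normalize="discrete").real
            x = x + 0.01 * np.sqrt(np.mean(x**2)) * r.standard_normal(512)
            assert select_parameter(analytic_extension(x, 1.0), d) == a_star

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            DiskDictionary(np.array([], dtype=complex))


class TestResidualUpdate:
    def test_exact_one_term_representation(self, grid256):
        kern = szego_kernel(0.3 + 0.4j, grid256, normalize="discrete")
        coeff, f_next = residual_update(kern, 0.3 + 0.4j)
        assert coeff == pytest.approx(1.0, abs=1e-10)
        assert np.max(np.abs(f_next)) < 1e-10

    def test_orthogonal_input_passes_through(self, grid256):
        # z is orthogonal to the constant kernel e_0
        coeff, f_next = residual_update(grid256.astype(complex), 0.0)
        assert abs(coeff) < 1e-14
        assert np.mean(np.abs(f_next) ** 2) == pytest.approx(1.0, rel=1e-12)

    def test_energy_conservation(self, rng):
        f = rng.standard_normal(256) + 1j * rng.standard_normal(256)
        coeff, f_next = residual_update(f, 0.4j)
        lhs = np.mean(np.abs(f) ** 2)
        rhs = abs(coeff) ** 2 + np.mean(np.abs(f_next) ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-12)


def _bandlimited(rng, n, top):
    spec = np.zeros(n, dtype=complex)
    spec[1:top] = rng.standard_normal(top - 1) + 1j * rng.standard_normal(top - 1)
    spec[0] = rng.standard_normal()
    x = np.fft.ifft(spec + np.conj(np.roll(spec[::-1], 1)))
    return np.real(x)


class TestTransform:
    def test_fourier_limit_coefficients(self, rng):
        n, k = 1024, 32
        for _ in range(3):
            x = _bandlimited(rng, n, k)
            d = blaschke_transform(x, 1.0, max_order=k,
                                   dictionary=DiskDictionary.fourier())
            f_one_sided = np.fft.fft(analytic_extension(x, 1.0).samples) / n
            err = np.abs(d.coeffs - f_one_sided[:k])
            assert np.max(err) <= 1e-8 * np.max(np.abs(f_one_sided[:k]))
            recon = d.components.sum(axis=0) + d.residual
            rel = np.linalg.norm(recon - d.analytic) / np.linalg.norm(d.analytic)
            assert rel <= 1e-8

    def test_zero_signal_gives_zero_coefficients(self):
        d = blaschke_transform(np.zeros(128), 1.0, max_order=8,
                               dictionary=DiskDictionary.fourier())
        np.testing.assert_allclose(d.coeffs, 0.0)
        np.testing.assert_allclose(d.spectrum, 0.0)

    def test_residual_energy_non_increasing_in_order(self, rng):
        x = rng.standard_normal(256)
        d = DiskDictionary.polar(radii=(0.3, 0.6), phase_count=8)
        e = [np.mean(np.abs(blaschke_transform(x, 1.0, max_order=k,
                                               dictionary=d).residual) ** 2)
             for k in (4, 8, 16)]
        assert e[0] >= e[1] >= e[2]

    def test_per_order_energy_conservation(self, rng):
        x = rng.standard_normal(300)
        d = blaschke_transform(x, 1.0, max_order=20,
                               dictionary=DiskDictionary.polar(
                                   radii=(0.2, 0.5, 0.8), phase_count=8))
        # ||f_1||^2 = sum |c_k|^2 + ||f_{K+1}||^2 telescoped
        total = np.mean(np.abs(d.analytic) ** 2)
        parts = np.sum(np.abs(d.coeffs) ** 2) + np.mean(np.abs(d.residual) ** 2)
        assert parts == pytest.approx(total, rel=1e-10)

    def test_max_order_clamped_with_warning(self, rng):
        x = rng.standard_normal(64)
        with pytest.warns(UserWarning, match="clamp"):
            d = blaschke_transform(x, 1.0, max_order=999,
                                   dictionary=DiskDictionary.fourier())
        assert d.order == 32

    def test_reconstruction_with_adaptive_dictionary(self, rng):
        x = rng.standard_normal(256)
        d = blaschke_transform(x, 1.0, max_order=64,
                               dictionary=DiskDictionary.polar(
                                   radii=(0.2, 0.5), phase_count=8))
        recon = d.components.sum(axis=0) + d.residual
        rel = np.linalg.norm(recon - d.analytic) / np.linalg.norm(d.analytic)
        assert rel <= 1e-6


class TestSpectrumAndPartial:
    def test_fourier_limit_spectrum_is_power(self, rng):
        n, k = 512, 16
        x = _bandlimited(rng, n, k)
        d = blaschke_transform(x, 1.0, max_order=k,
                               dictionary=DiskDictionary.fourier())
        f_one_sided = np.fft.fft(analytic_extension(x, 1.0).samples) / n
        np.testing.assert_allclose(blaschke_spectrum(d),
                                   np.abs(f_one_sided[:k]) ** 2, rtol=1e-8)

    def test_spectrum_nonnegative_and_bounded_by_power(self, rng):
        x = rng.standard_normal(256)
        d = blaschke_transform(x, 1.0, max_order=32,
                               dictionary=DiskDictionary.polar(
                                   radii=(0.3,), phase_count=8))
        bs = blaschke_spectrum(d)
        assert np.all(bs >= 0)
        assert bs.sum() <= np.mean(np.abs(d.analytic) ** 2) + 1e-10

    def test_planted_component_concentrates_in_first_order(self, grid256):
        kern = szego_kernel(0.5j, grid256, normalize="discrete")
        x = (3.0 * kern).real
        d = blaschke_transform(x, 1.0, max_order=8,
                               dictionary=DiskDictionary(np.array([0.5j, 0.2])))
        bs = blaschke_spectrum(d)
        assert bs[0] / bs.sum() >= 0.99

    def test_partial_reconstruction_additivity(self, rng):
        x = rng.standard_normal(256)
        d = blaschke_transform(x, 1.0, max_order=16,
                               dictionary=DiskDictionary.polar(
                                   radii=(0.4,), phase_count=8))
        full = partial_reconstruction(d, (1, 16))
        split = partial_reconstruction(d, (1, 7)) + partial_reconstruction(d, (8, 16))
        np.testing.assert_allclose(split, full, atol=1e-10)
        np.testing.assert_allclose(
            full, np.real(d.components.sum(axis=0)), atol=1e-12)

    def test_fourier_limit_partial_selects_modes(self, rng):
        n, k = 512, 16
        x = _bandlimited(rng, n, k)
        d = blaschke_transform(x, 1.0, max_order=k,
                               dictionary=DiskDictionary.fourier())
        got = partial_reconstruction(d, (3, 5))
        spec = np.fft.fft(analytic_extension(x, 1.0).samples)
        mask = np.zeros(n)
        mask[2:5] = 1.0
        want = np.real(np.fft.ifft(spec * mask))
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_out_of_range_interval(self, rng):
        x = rng.standard_normal(128)
        d = blaschke_transform(x, 1.0, max_order=8,
                               dictionary=DiskDictionary.fourier())
        with pytest.raises(IndexError):
            partial_reconstruction(d, (0, 8))
        with pytest.raises(IndexError):
            partial_reconstruction(d, (1, 9))


class TestDecomposerEstimator:
    def test_fit_transform_api(self, rng):
        x = rng.standard_normal(256)
        est = BlaschkeDecomposer(max_order=8, radii=(), sample_rate=10.0)
        assert est.get_params()["max_order"] == 8
        est.set_params(max_order=16)
        mat = est.fit(x).transform()
        assert mat.shape == (16, 256)
        np.testing.assert_allclose(mat.sum(axis=0) + est.residual_.real, x,
                                   atol=1e-8)

    def test_unfitted_transform_raises(self):
        with pytest.raises(RuntimeError):
            BlaschkeDecomposer().transform()

    def test_invalid_param_rejected(self):
        with pytest.raises(ValueError):
            BlaschkeDecomposer().set_params(bogus=1)
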