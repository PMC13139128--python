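"""Savitzky-Golay filtering, MSC, SNV and correlation screening."""

import numpy as np
import pytest

from leafspec.datasets import SpectraMatrix
from leafspec.preprocess import (SGKernel, msc, pearson_by_wavelength,
                                 second_derivative, sg_smooth, snv)


def _spectra(values, wl=None):
    values = np.atleast_2d(np.asarray(values, float))
    wl = np.arange(values.shape[1], dtype=float) if wl is None else wl
    return SpectraMatrix(values, wl)


def _polyfit_oracle(x, half_width, order, deriv):
    """Brute-force per-window least-squares polynomial fit (truncated at the
    edges), evaluated (or differentiated) at the window centre."""
    m = len(x)
    out = np.empty(m)
    t = np.arange(m, dtype=float)
    for k in range(m):
        lo, hi = max(0, k - half_width), min(m, k + half_width + 1)
        coef = np.polynomial.polynomial.polyfit(t[lo:hi] - t[k], x[lo:hi], order)
        out[k] = coef[deriv] * (1 if deriv == 0 else 2)
    return out


class TestSGSmooth:
    def test_constant_spectrum_unchanged(self):
        X = _spectra(np.full((2, 40), 0.37))
        out = sg_smooth(X, SGKernel(7, 2, 0))
        np.testing.assert_allclose(out.reflectance, 0.37, atol=1e-12)

    def test_quadratic_reproduced_exactly(self):
        t = np.arange(60.0)
        q = 0.3 * t ** 2 - 2.0 * t + 5.0
        out = sg_smooth(_spectra(q), SGKernel(7, 2, 0))
        np.testing.assert_allclose(out.reflectance[0], q, atol=1e-8)

    def test_matches_per_window_polyfit_oracle_everywhere(self):
        rng = np.random.default_rng(1)
        x = np.sin(np.linspace(0, 6, 80)) + 0.1 * rng.standard_normal(80)
        out = sg_smooth(_spectra(x), SGKernel(7, 2, 0)).reflectance[0]
        oracle = _polyfit_oracle(x, 7, 2, 0)
        np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_window_wider_than_spectrum_rejected(self):
        with pytest.raises(ValueError, match="wider"):
            sg_smooth(_spectra(np.ones(9)), SGKernel(7, 2, 0))


class TestSecondDerivative:
    def test_linear_spectrum_gives_zero(self):
        t = np.arange(50.0)
        out = second_derivative(_spectra(2.0 * t + 1.0), SGKernel(7, 2, 2))
        np.testing.assert_allclose(out.reflectance, 0.0, atol=1e-9)

    def test_quadratic_gives_constant_2a(self):
        t = np.arange(50.0)
        out = second_derivative(_spectra(0.4 * t ** 2), SGKernel(7, 2, 2))
        np.testing.assert_allclose(out.reflectance, 0.8, atol=1e-8)

    def test_cubic_matches_analytic_second_derivative(self):
        wl = np.arange(400.0, 500.0, 1.0)
        x = 1e-6 * wl ** 3
        out = second_derivative(_spectra(x, wl), SGKernel(7, 3, 2)).reflectance[0]
        np.testing.assert_allclose(out[7:-7], 6e-6 * wl[7:-7], atol=1e-6)

    def test_grid_spacing_scales_result(self):
        # same quadratic sampled at 2 nm spacing: d2/dlambda2 must not change
        wl = np.arange(400.0, 500.0, 2.0)
        x = 0.001 * (wl - 450) ** 2
        out = second_derivative(_spectra(x, wl), SGKernel(5, 2, 2)).reflectance[0]
        np.testing.assert_allclose(out, 0.002, atol=1e-9)

    def test_nonuniform_grid_rejected(self):
        wl = np.array([400.0, 401.0, 403.0, 404.0, 405.0, 406.0, 407.0,
                       408.0, 409.0, 410.0, 411.0, 412.0, 413.0, 414.0, 415.0])
        with pytest.raises(ValueError, match="uniform"):
            second_derivative(_spectra(np.ones(15), wl), SGKernel(3, 2, 2))

    def test_chained_sg_then_sd_equals_single_sd_on_smooth_input(self):
        wl = np.arange(400.0, 480.0, 1.0)
        x = 0.002 * (wl - 440) ** 2 + 0.1
        X = _spectra(x, wl)
        chained = second_derivative(sg_smooth(X, SGKernel(7, 2, 0)),
                                    SGKernel(7, 2, 2)).reflectance
        single = second_derivative(X, SGKernel(7, 2, 2)).reflectance
        np.testing.assert_allclose(chained, single, atol=1e-6)


class TestMSC:
    def test_sample_equal_to_reference_unchanged(self):
        rng = np.random.default_rng(0)
        ref = 0.3 + 0.1 * rng.random(30)
        X = _spectra(np.vstack([ref, ref]))
        out, model = msc(X, reference=ref)
        np.testing.assert_allclose(out.reflectance[0], ref, atol=1e-12)
        np.testing.assert_allclose(model.slopes, 1.0, atol=1e-12)
        np.testing.assert_allclose(model.offsets, 0.0, atol=1e-12)

    def test_affine_scatter_inverted_exactly(self):
        rng = np.random.default_rng(1)
        ref = 0.3 + 0.1 * rng.random(30)
        X = _spectra(2.0 * ref + 0.5)
        out, _ = msc(X, reference=ref)
        np.testing.assert_allclose(out.reflectance[0], ref, atol=1e-9)

    def test_scatter_perturbed_set_recovers_reference_shape(self):
        rng = np.random.default_rng(2)
        ref = 0.3 + 0.2 * np.sin(np.linspace(0, 3, 50))
        rows = [a * ref + b + 0.001 * rng.standard_normal(50)
                for a, b in zip(1 + 0.2 * rng.standard_normal(12),
                                0.05 * rng.standard_normal(12))]
        out, _ = msc(_spectra(np.vstack(rows)), reference=ref)
        for row in out.reflectance:
            assert np.corrcoef(row, ref)[0, 1] >= 0.999

    def test_msc_idempotent_with_fixed_reference(self):
        rng = np.random.default_rng(3)
        ref = 0.3 + 0.1 * rng.random(25)
        X = _spectra(np.vstack([1.5 * ref + 0.2, 0.7 * ref - 0.1]))
        once, _ = msc(X, reference=ref)
        twice, _ = msc(once, reference=ref)
        np.testing.assert_allclose(once.reflectance, twice.reflectance, atol=1e-9)

    def test_constant_sample_raises_with_id(self):
        X = SpectraMatrix(np.vstack([np.linspace(0, 1, 20), np.full(20, 0.5)]),
                          np.arange(20.0), ["good", "flatliner"])
        with pytest.raises(ValueError, match="flatliner"):
            msc(X, reference=np.linspace(0, 1, 20))


class TestSNV:
    def test_hand_example_with_n_minus_1_denominator(self):
        out = snv(_spectra([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.reflectance[0], [-1.0, 0.0, 1.0],
                                   atol=1e-12)

    def test_rows_are_standardized(self):
        rng = np.random.default_rng(4)
        out = snv(_spectra(rng.random((6, 40))))
        np.testing.assert_allclose(out.reflectance.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.reflectance.std(axis=1, ddof=1), 1,
                                   atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        X = _spectra(rng.random((4, 30)))
        np.testing.assert_allclose(snv(snv(X)).reflectance,
                                   snv(X).reflectance, atol=1e-12)

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (0.5, 1.0), (3.0, -0.7)])
    def test_invariant_to_per_sample_affine_transform(self, a, b):
        rng = np.random.default_rng(6)
        X = rng.random((3, 30))
        np.testing.assert_allclose(snv(_spectra(a * X + b)).reflectance,
                                   snv(_spectra(X)).reflectance, atol=1e-9)

    def test_constant_row_raises(self):
        with pytest.raises(ValueError, match="constant"):
            snv(_spectra(np.full((1, 10), 0.3)))


class TestPearsonScreen:
    def test_perfectly_correlated_and_anticorrelated_columns(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = _spectra(np.column_stack([y, -y, np.ones(4)]))
        r = pearson_by_wavelength(X, y)
        np.testing.assert_allclose(r[:2], [1.0, -1.0], atol=1e-12)
        assert r[2] == 0.0                       # zero-variance column

    def test_five_point_hand_example(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 4, 5, 4, 5])
        X = _spectra(x.reshape(-1, 1), wl=np.array([500.0]))
        r = pearson_by_wavelength(X, y)
        assert abs(r[0] - 0.7746) < 1e-3
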