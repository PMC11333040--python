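"""Normalization, q-band averaging and Gaussian-approximation MSD."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from efws.core import DomainError, EfwsError, ElasticScan
from efws.preprocess import gaussian_msd, normalize_to_base, sum_over_q
from efws.synth import simulate_water_scan


def _scan_from_kernel(temperatures, q_values, intensities, normalized=False):
    return ElasticScan(
        sample_id="s",
        component="protein",
        state="hydrated",
        hydration_h=0.4,
        resolution_time=1000.0,
        temperatures=temperatures,
        q_values=q_values,
        intensities=intensities,
        normalized=normalized,
    )


class TestNormalizeToBase:
    def test_base_window_values_near_one(self, water_model, temperatures, q_values):
        scan = simulate_water_scan(water_model, 40.0, temperatures, q_values)
        norm = normalize_to_base(scan)
        base = norm.intensities[norm.temperatures <= 20.0]
        assert np.allclose(base.mean(axis=0), 1.0, atol=1e-12)

    def test_scale_invariance(self, water_model, temperatures, q_values):
        scan = simulate_water_scan(water_model, 40.0, temperatures, q_values)
        scaled = _scan_from_kernel(
            temperatures, q_values, 37.5 * scan.intensities
        )
        a = normalize_to_base(scan).intensities
        b = normalize_to_base(scaled).intensities
        assert np.allclose(a, b, rtol=1e-12)

    def test_high_temperature_value_matches_closed_form(
        self, water_model, q_values
    ):
        # at high T the relaxation is much faster than the window, so the
        # normalized kernel is the EISF times the Debye-Waller ratio to the
        # base-window mean
        T = np.concatenate([np.arange(10.0, 21.0, 2.0), [300.0]])
        scan = simulate_water_scan(water_model, 1000.0, T, q_values)
        norm = normalize_to_base(scan)
        q2 = q_values**2
        dw = np.exp(-np.outer(water_model.vib_slope * T, q2) / 6.0)
        expected = water_model.eisf_a0 * dw[-1] / dw[:-1].mean(axis=0)
        assert np.allclose(norm.intensities[-1], expected, atol=1e-8)

    def test_empty_base_window_rejected(self, water_model, q_values):
        scan = simulate_water_scan(
            water_model, 40.0, np.arange(100.0, 300.0, 2.0), q_values
        )
        with pytest.raises(EfwsError):
            normalize_to_base(scan)

    def test_zero_base_mean_rejected(self):
        T = np.array([10.0, 20.0, 30.0])
        q = np.array([0.5, 1.0])
        scan = _scan_from_kernel(T, q, np.zeros((3, 2)))
        with pytest.raises(DomainError):
            normalize_to_base(scan)


class TestSumOverQ:
    def test_constant_in_q_equals_any_column(self, temperatures):
        q = np.array([0.5, 0.9, 1.3, 1.7])
        col = np.exp(-temperatures / 300.0)
        scan = _scan_from_kernel(
            temperatures, q, np.tile(col[:, None], (1, 4)), normalized=True
        )
        series = sum_over_q(scan)
        assert np.allclose(series.values, col, rtol=1e-12)

    @given(c=st.floats(0.1, 10.0))
    def test_commutes_with_scalar_rescaling(self, c):
        T = np.arange(10.0, 100.0, 10.0)
        q = np.array([0.5, 0.9, 1.3])
        base = np.exp(-np.outer(T / 500.0, q**2))
        a = sum_over_q(_scan_from_kernel(T, q, base))
        b = sum_over_q(_scan_from_kernel(T, q, c * base))
        assert np.allclose(c * a.values, b.values, rtol=1e-12)

    def test_closed_interval_band_selection(self, temperatures):
        q = np.array([0.45, 0.9, 1.75, 2.0])
        scan = _scan_from_kernel(
            temperatures, q, np.ones((temperatures.size, 4)), normalized=True
        )
        series = sum_over_q(scan, q_range=(0.45, 1.75))
        assert series.q_range == (0.45, 1.75)
        with pytest.raises(EfwsError):
            sum_over_q(scan, q_range=(1.8, 1.9))


class TestGaussianMSD:
    def test_exact_inversion_of_gaussian_kernel(self, temperatures, q_values):
        msd_true = 0.3
        kernel = np.exp(
            -np.outer(np.full(temperatures.size, msd_true), q_values**2) / 6.0
        )
        scan = _scan_from_kernel(temperatures, q_values, kernel, normalized=True)
        series = gaussian_msd(scan)
        assert np.allclose(series.msd, msd_true, atol=1e-10)
        assert np.allclose(series.r_squared, 1.0, atol=1e-10)

    def test_unit_intensity_gives_zero_msd(self, temperatures, q_values):
        scan = _scan_from_kernel(
            temperatures, q_values,
            np.ones((temperatures.size, q_values.size)), normalized=True,
        )
        assert np.allclose(gaussian_msd(scan).msd, 0.0, atol=1e-12)

    def test_water_scan_low_t_recovers_vibrational_msd(
        self, water_model, q_values
    ):
        # far below the onset the kernel is pure Debye-Waller; after base
        # normalization the MSD is referenced to the base-window mean T
        T = np.arange(10.0, 120.0, 2.0)
        scan = simulate_water_scan(water_model, 1000.0, T, q_values)
        series = gaussian_msd(normalize_to_base(scan))
        t_base = T[T <= 20.0].mean()
        expected = water_model.vib_slope * (T - t_base)
        # increments are exact; the absolute level carries a ~2e-6 offset
        # from the log of the base-window mean not being exactly quadratic
        # in q (log-sum-exp curvature)
        assert np.allclose(np.diff(series.msd), np.diff(expected), atol=1e-10)
        assert np.allclose(series.msd, expected, atol=1e-5)

    def test_free_intercept_absorbs_q_independent_factor(
        self, temperatures, q_values
    ):
        msd_true = 0.25
        kernel = 0.8 * np.exp(
            -np.outer(np.full(temperatures.size, msd_true), q_values**2) / 6.0
        )
        scan = _scan_from_kernel(temperatures, q_values, kernel, normalized=True)
        assert np.allclose(gaussian_msd(scan).msd, msd_true, atol=1e-10)

    def test_nonpositive_intensity_flags_temperature(self, q_values):
        T = np.array([10.0, 20.0, 30.0])
        kernel = np.ones((3, q_values.size))
        kernel[1, 3] = 0.0
        scan = _scan_from_kernel(T, q_values, kernel, normalized=True)
        series = gaussian_msd(scan)
        assert np.isnan(series.msd[1])
        assert np.isfinite(series.msd[[0, 2]]).all()

    def test_requires_normalized_scan(self, temperatures, q_values):
        scan = _scan_from_kernel(
            temperatures, q_values,
            np.ones((temperatures.size, q_values.size)),
        )
        with pytest.raises(EfwsError):
            gaussian_msd(scan)
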