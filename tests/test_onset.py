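"""Difference curves, onset detectors and the bootstrap interval."""

import numpy as np
import pytest

from efws.core import DifferenceSeries, EfwsError, NoOnsetError, SummedSeries
from efws.onset import bootstrap_onset, detect_onset, difference_curve
from efws.preprocess import normalize_to_base, sum_over_q
from efws.synth import simulate_protein_scan, simulate_water_scan


def _series(t, v):
    return SummedSeries(temperatures=np.asarray(t, float),
                        values=np.asarray(v, float), q_range=(0.45, 1.75))


def _diff(t, v):
    return DifferenceSeries(temperatures=np.asarray(t, float),
                            values=np.asarray(v, float), kind="intensity")


def _piecewise(t, breakpoint=210.0, slope=0.002):
    return np.where(t > breakpoint, slope * (t - breakpoint), 0.0)


class TestDifferenceCurve:
    def test_identical_series_give_zero(self):
        t = np.arange(10.0, 300.0, 2.0)
        v = np.exp(-t / 300.0)
        d = difference_curve(_series(t, v), _series(t, v))
        assert np.allclose(d.values, 0.0, atol=1e-15)

    def test_intensity_sign_convention_dry_minus_hydrated(self):
        t = np.arange(10.0, 300.0, 2.0)
        dry = _series(t, np.ones_like(t))
        hyd = _series(t, 1.0 - _piecewise(t))
        d = difference_curve(hyd, dry)
        assert d.kind == "intensity"
        assert np.all(d.values >= 0)
        assert d.values[-1] > 0

    def test_mismatched_grids_resolve_to_coarser(self):
        t_fine = np.arange(10.0, 300.0 + 1e-9, 2.0)
        t_coarse = np.arange(10.0, 300.0 + 1e-9, 5.0)
        d = difference_curve(
            _series(t_fine, np.ones_like(t_fine)),
            _series(t_coarse, np.ones_like(t_coarse)),
        )
        assert np.allclose(np.diff(d.temperatures), 5.0)

    def test_small_overlap_rejected(self):
        a = _series(np.arange(10.0, 40.0, 2.0), np.ones(15))
        b = _series(np.arange(30.0, 100.0, 2.0), np.ones(35))
        with pytest.raises(EfwsError, match="overlap"):
            difference_curve(a, b)

    def test_mixed_kind_rejected(self, protein_model, temperatures, q_values):
        from efws.preprocess import gaussian_msd

        scan = normalize_to_base(
            simulate_protein_scan(protein_model, 0.4, 1000.0, temperatures, q_values)
        )
        with pytest.raises(EfwsError):
            difference_curve(gaussian_msd(scan), sum_over_q(scan))


class TestBilinearDetector:
    def test_recovers_exact_piecewise_breakpoint(self):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        result = detect_onset(_diff(t, _piecewise(t)))
        assert result.t_on == pytest.approx(210.0, abs=2.0)
        assert result.sse < 1e-20

    @pytest.mark.parametrize("breakpoint", [195.0, 224.0, 251.0])
    def test_breakpoint_within_one_grid_step(self, breakpoint):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        result = detect_onset(_diff(t, _piecewise(t, breakpoint=breakpoint)))
        assert result.t_on == pytest.approx(breakpoint, abs=2.0)

    def test_equivariant_under_affine_rescaling(self):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        rng = np.random.default_rng(0)
        y = _piecewise(t) + 1e-4 * rng.standard_normal(t.size)
        a = detect_onset(_diff(t, y))
        b = detect_onset(_diff(t, 3.7 * y + 0.42))
        assert a.t_on == pytest.approx(b.t_on, abs=1e-6)

    def test_pure_noise_yields_no_onset(self):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        rng = np.random.default_rng(11)
        with pytest.raises(NoOnsetError):
            detect_onset(_diff(t, 1e-3 * rng.standard_normal(t.size)))

    def test_identically_zero_yields_no_onset(self):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        with pytest.raises(NoOnsetError):
            detect_onset(_diff(t, np.zeros_like(t)))

    def test_t_on_strictly_inside_range(self):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        result = detect_onset(_diff(t, _piecewise(t)))
        assert t[0] < result.t_on < t[-1]

    def test_protein_study_onset_matches_generator_tg(
        self, protein_model, temperatures, q_values
    ):
        for dt in (10.0, 1000.0):
            hyd = simulate_protein_scan(
                protein_model, 0.4, dt, temperatures, q_values
            )
            dry = simulate_protein_scan(
                protein_model, 0.4, dt, temperatures, q_values, state="dry"
            )
            d = difference_curve(
                sum_over_q(normalize_to_base(hyd)),
                sum_over_q(normalize_to_base(dry)),
            )
            result = detect_onset(d)
            assert result.t_on == pytest.approx(228.0, abs=3.0)

    def test_protein_onset_resolution_invariant_water_onset_not(
        self, protein_model, water_model, temperatures, q_values
    ):
        # the decoupling signature at detector level
        protein_onsets, water_onsets = [], []
        for dt in (1000.0, 40.0, 10.0):
            for model, sim, out in (
                (protein_model, simulate_protein_scan, protein_onsets),
                (water_model, simulate_water_scan, water_onsets),
            ):
                if sim is simulate_protein_scan:
                    hyd = sim(model, 0.4, dt, temperatures, q_values)
                    dry = sim(model, 0.4, dt, temperatures, q_values, state="dry")
                else:
                    hyd = sim(model, dt, temperatures, q_values)
                    dry = sim(model, dt, temperatures, q_values, state="dry")
                d = difference_curve(
                    sum_over_q(normalize_to_base(hyd)),
                    sum_over_q(normalize_to_base(dry)),
                )
                out.append(detect_onset(d).t_on)
        assert max(protein_onsets) - min(protein_onsets) < 3.0
        assert water_onsets[0] < water_onsets[1] < water_onsets[2]


class TestThresholdDetector:
    def test_first_sustained_exceedance(self):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        rng = np.random.default_rng(5)
        y = _piecewise(t, breakpoint=230.0) + 1e-4 * rng.standard_normal(t.size)
        result = detect_onset(_diff(t, y), method="threshold")
        assert result.method == "threshold"
        assert result.t_on == pytest.approx(230.0, abs=6.0)

    def test_flat_noise_yields_no_onset(self):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        rng = np.random.default_rng(7)
        with pytest.raises(NoOnsetError):
            detect_onset(_diff(t, 1e-3 * rng.standard_normal(t.size)),
                         method="threshold")


class TestBootstrap:
    def test_noiseless_piecewise_input_gives_zero_width(self):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        d = _diff(t, _piecewise(t))
        lo, hi = bootstrap_onset(d, n_boot=100, seed=0)
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_fixed_seed_reproduces_interval(self):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        rng = np.random.default_rng(3)
        d = _diff(t, _piecewise(t) + 2e-4 * rng.standard_normal(t.size))
        a = bootstrap_onset(d, n_boot=200, seed=9)
        b = bootstrap_onset(d, n_boot=200, seed=9)
        assert a == b

    def test_small_n_boot_warns(self):
        t = np.arange(150.0, 300.0 + 1e-9, 2.0)
        d = _diff(t, _piecewise(t))
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_onset(d, n_boot=50, seed=0)
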