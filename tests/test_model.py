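"""Arctangent model layer: closed forms, fitting, maxima."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vesselmech as vm
from vesselmech.errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterDomainError,
)

from conftest import random_valid_params

GRID = np.array(vm.PAPER_PRESSURE_GRID)

params_st = st.builds(
    vm.ArctanParams,
    Am=st.floats(10, 5000),
    P0=st.floats(-100, 400),
    P1=st.floats(1, 500),
)


class TestAreaAt:
    def test_half_area_at_p0(self):
        p = vm.ArctanParams(100, 100, 50)
        assert vm.area_at(p, 100) == pytest.approx(50.0)

    def test_upper_asymptote(self):
        p = vm.ArctanParams(100, 0, 1)
        assert vm.area_at(p, 1e6) == pytest.approx(100.0, abs=1e-4)

    def test_closed_form_value(self):
        # frozen from independent evaluation of Am*(1/2 + arctan(20/58.6)/pi)
        p = vm.ArctanParams(3313, 100, 58.6)
        assert vm.area_at(p, 120) == pytest.approx(2003.3456164757072, rel=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterDomainError):
            vm.ArctanParams(-1, 100, 50)
        with pytest.raises(ParameterDomainError):
            vm.ArctanParams(100, 100, 0)
        with pytest.raises(ParameterDomainError):
            vm.ArctanParams(100, np.inf, 50)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(params_st, st.floats(-500, 800), st.floats(0.1, 100))
    def test_strictly_increasing_and_bounded(self, p, pressure, dp):
        a1, a2 = vm.area_at(p, pressure), vm.area_at(p, pressure + dp)
        assert 0 < a1 < p.Am
        assert a2 > a1

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(params_st)
    def test_normalization_limits(self, p):
        assert vm.area_at(p, -1e6) <= 1e-3 * p.Am
        assert vm.area_at(p, 1e6) >= p.Am * (1 - 1e-3)


class TestComplianceAt:
    def test_peak_value_closed_form(self):
        p = vm.ArctanParams(3313, 100, 58.6)
        assert vm.compliance_at(p, 100) == pytest.approx(3313 / (np.pi * 58.6))
        assert vm.compliance_at(p, 100) == pytest.approx(18.0, abs=0.01)

    def test_symmetric_about_p0(self):
        p = vm.ArctanParams(100, 100, 50)
        assert vm.compliance_at(p, 130) == pytest.approx(vm.compliance_at(p, 70))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(params_st)
    def test_half_peak_at_p0_plus_p1(self, p):
        assert vm.compliance_at(p, p.P0 + p.P1) == pytest.approx(
            0.5 * vm.compliance_at(p, p.P0)
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(params_st, st.floats(-200, 500))
    def test_matches_area_derivative(self, p, pressure):
        """Central finite difference of A matches C to 1e-6 relative."""
        h = 1e-3
        fd = (vm.area_at(p, pressure + h) - vm.area_at(p, pressure - h)) / (2 * h)
        assert fd == pytest.approx(vm.compliance_at(p, pressure), rel=1e-6)

    def test_numeric_argmax_is_p0(self, rng):
        for p in random_valid_params(rng, 10):
            grid = np.arange(p.P0 - 50, p.P0 + 50, 0.01)
            c = vm.compliance_at(p, grid)
            assert abs(grid[np.argmax(c)] - p.P0) <= 0.011


class TestDistensibilityAt:
    def test_at_p0_independent_of_am(self):
        for am in (10.0, 100.0, 5000.0):
            p = vm.ArctanParams(am, 100, 58.6)
            assert vm.distensibility_at(p, 100) == pytest.approx(2 / (np.pi * 58.6))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(params_st, st.floats(-200, 500))
    def test_identity_d_times_a_equals_c(self, p, pressure):
        da = vm.distensibility_at(p, pressure) * vm.area_at(p, pressure)
        assert da == pytest.approx(vm.compliance_at(p, pressure), rel=1e-12)

    def test_argmax_matches_grid_search_oracle(self):
        """Dense brute-force grid search locates the same maximum."""
        p = vm.ArctanParams(100, 100, 50)
        grid = np.arange(15, 300.0001, 0.001)
        d = vm.distensibility_at(p, grid)
        i = int(np.argmax(d))
        sm = vm.summary_metrics(p, (15, 300))
        assert sm.pressure_at_max_distensibility == pytest.approx(grid[i], abs=0.01)
        assert sm.max_distensibility == pytest.approx(d[i], rel=1e-8)
        # frozen oracle values
        assert sm.pressure_at_max_distensibility == pytest.approx(78.55, abs=0.1)
        assert sm.max_distensibility == pytest.approx(0.014492, rel=1e-3)


class TestFitArctangent:
    def test_noise_free_exact_recovery(self):
        true = vm.ArctanParams(1000, 110, 40)
        areas = vm.area_at(true, GRID)
        fit = vm.fit_arctangent(GRID, areas)
        assert fit.converged
        assert fit.params.Am == pytest.approx(true.Am, rel=1e-6)
        assert fit.params.P0 == pytest.approx(true.P0, rel=1e-6)
        assert fit.params.P1 == pytest.approx(true.P1, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_randomized_recovery(self, rng):
        """Exact recovery holds across randomized truths on the 10-point grid."""
        for _ in range(20):
            true = vm.ArctanParams(
                rng.uniform(50, 4000), rng.uniform(40, 200), rng.uniform(10, 150)
            )
            fit = vm.fit_arctangent(GRID, vm.area_at(true, GRID))
            for got, want in [
                (fit.params.Am, true.Am),
                (fit.params.P0, true.P0),
                (fit.params.P1, true.P1),
            ]:
                assert got == pytest.approx(want, rel=1e-6)

    def test_noisy_recovery_within_ten_percent(self):
        true = vm.ArctanParams(1000, 110, 40)
        rng = np.random.default_rng(5)
        areas = vm.area_at(true, GRID) * (1 + rng.normal(0, 0.02, GRID.size)) ** 2
        fit = vm.fit_arctangent(GRID, areas)
        assert fit.params.Am == pytest.approx(1000, rel=0.10)

    def test_too_few_points_rejected(self):
        true = vm.ArctanParams(1000, 110, 40)
        with pytest.raises(InsufficientDataError):
            vm.fit_arctangent(GRID[:4], vm.area_at(true, GRID[:4]))

    def test_constant_areas_degenerate(self):
        with pytest.raises(DegenerateDataError):
            vm.fit_arctangent(GRID, np.full(GRID.size, 50.0))

    def test_truncation_does_not_move_noise_free_params(self):
        true = vm.ArctanParams(800, 120, 45)
        areas = vm.area_at(true, GRID)
        full = vm.fit_arctangent(GRID, areas)
        for cut in (1, 2, 3, 4, 5):  # down to 5 surviving points
            fit = vm.fit_arctangent(GRID[:-cut], areas[:-cut])
            assert fit.params.Am == pytest.approx(full.params.Am, rel=1e-3)
            assert fit.params.P0 == pytest.approx(full.params.P0, rel=1e-3)
            assert fit.params.P1 == pytest.approx(full.params.P1, rel=1e-3)


class TestSummaryMetrics:
    def test_closed_form_maxima(self):
        p = vm.ArctanParams(3313, 100, 58.6)
        sm = vm.summary_metrics(p, (15, 300))
        assert sm.max_area == 3313
        assert sm.max_compliance == pytest.approx(18.0, abs=0.01)
        assert sm.pressure_at_max_compliance == pytest.approx(100.0)

    def test_p0_outside_range_clipped(self):
        p = vm.ArctanParams(100, 350, 50)
        sm = vm.summary_metrics(p, (15, 300))
        assert sm.pressure_at_max_compliance == 300.0
        assert sm.max_compliance == pytest.approx(vm.compliance_at(p, 300))

    def test_doubling_p1_halves_max_compliance(self):
        a = vm.summary_metrics(vm.ArctanParams(100, 100, 50)).max_compliance
        b = vm.summary_metrics(vm.ArctanParams(100, 100, 100)).max_compliance
        assert a == pytest.approx(2 * b)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            vm.summary_metrics(vm.ArctanParams(100, 100, 50), (300, 15))
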