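"""Forward simulator: grids, bio-optical components, shallow-water limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import reefsbi as rb
from reefsbi.forward_model import Rrs_to_rrs, rrs_to_Rrs
from reefsbi.optics_data import default_benthic_spectrum, pure_water_absorption


class TestWavelengthGrid:
    @pytest.mark.parametrize(
        "start,stop,step,n",
        [(400, 700, 5, 61), (400, 400, 5, 1), (400, 710, 5, 63), (400, 705, 5, 62)],
    )
    def test_inclusive_count(self, start, stop, step, n):
        g = rb.make_wavelength_grid(start, stop, step)
        assert len(g) == n
        assert g.values[0] == start and g.values[-1] == stop

    def test_non_divisible_range_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            rb.make_wavelength_grid(400, 702, 5)

    def test_decreasing_wavelengths_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            rb.WavelengthGrid(np.array([500.0, 450.0]))


class TestParameterVector:
    def test_roundtrip(self, typical_theta):
        assert rb.ParameterVector.from_array(typical_theta.to_array()) == typical_theta

    @pytest.mark.parametrize(
        "field,value",
        [("phytoplankton", 8.0), ("cdom440", 3.0), ("minerals", 31.0),
         ("depth", 25.0), ("depth", 0.05), ("wind", -1.0), ("phytoplankton", 0.0)],
    )
    def test_out_of_range_rejected(self, typical_theta, field, value):
        kwargs = {n: getattr(typical_theta, n) for n in rb.PARAM_NAMES}
        kwargs[field] = value
        with pytest.raises(ValueError):
            rb.ParameterVector(**kwargs)


class TestIOPs:
    def test_pure_water_limit(self, grid):
        # all constituents -> 0 recovers the pure-water coefficients
        theta = np.array([1e-12, 1e-12, 1e-12, 5.0, 5.0])
        a = rb.total_absorption(theta, grid)
        np.testing.assert_allclose(a, pure_water_absorption(grid), rtol=1e-6)

    def test_cdom_anchored_at_440(self, grid, typical_theta):
        a_with = rb.total_absorption(typical_theta, grid)
        theta0 = np.array([typical_theta.phytoplankton, 1e-300,
                           typical_theta.minerals, 6.0, 5.0])
        a_without = rb.total_absorption(theta0, grid)
        i440 = int(np.argmax(grid.values == 440.0))
        assert a_with[i440] - a_without[i440] == pytest.approx(typical_theta.cdom440)

    def test_mineral_absorption_linear_in_concentration(self, grid):
        base = np.array([1e-300, 1e-300, 2.0, 5.0, 5.0])
        double = base.copy()
        double[2] = 4.0
        aw = pure_water_absorption(grid)
        np.testing.assert_allclose(
            rb.total_absorption(double, grid) - aw,
            2.0 * (rb.total_absorption(base, grid) - aw),
            rtol=1e-12,
        )

    def test_cdom_does_not_scatter(self, grid, typical_theta):
        theta2 = np.array([typical_theta.phytoplankton, 2.0,
                           typical_theta.minerals, 6.0, 5.0])
        np.testing.assert_array_equal(
            rb.total_backscatter(typical_theta, grid),
            rb.total_backscatter(theta2, grid),
        )

    def test_mineral_backscatter_linear(self, grid):
        from reefsbi.optics_data import pure_water_backscatter

        base = np.array([1e-300, 0.0, 3.0, 5.0, 5.0])
        double = base.copy()
        double[2] = 6.0
        bbw_ph = rb.total_backscatter(np.array([1e-300, 0.0, 1e-300, 5.0, 5.0]), grid)
        np.testing.assert_allclose(
            rb.total_backscatter(double, grid) - bbw_ph,
            2.0 * (rb.total_backscatter(base, grid) - bbw_ph),
            rtol=1e-9,
        )

    def test_grid_outside_water_table_rejected(self, typical_theta):
        g = rb.make_wavelength_grid(300, 400, 5)
        with pytest.raises(ValueError, match="pure-water table"):
            rb.total_absorption(typical_theta, g)


class TestSimulateRrs:
    def test_deep_limit_drops_bottom_term(self, grid, simulator):
        """At 1000 m the output equals the optically deep closed form."""
        theta_deep = np.array([0.3, 0.05, 0.5, 0.0, 1000.0])
        rrs = Rrs_to_rrs(rb.simulate_rrs(theta_deep, simulator.benthic, grid).values)
        iops = rb.forward_model.compute_iops(theta_deep, grid)
        u = iops.u
        deep_closed_form = (0.084 + 0.170 * u) * u
        np.testing.assert_allclose(rrs, deep_closed_form, atol=1e-10)

    def test_zero_depth_limit_is_benthic_albedo(self, grid, simulator):
        theta0 = np.array([0.3, 0.05, 0.5, 0.0, 0.0])
        rrs = Rrs_to_rrs(rb.simulate_rrs(theta0, simulator.benthic, grid).values)
        np.testing.assert_allclose(rrs, simulator.benthic.rho / np.pi, atol=1e-10)

    def test_wind_adds_flat_glint(self, grid, simulator):
        t1 = np.array([0.3, 0.05, 0.5, 2.0, 5.0])
        t2 = np.array([0.3, 0.05, 0.5, 9.0, 5.0])
        diff = (rb.simulate_rrs(t2, simulator.benthic, grid).values
                - rb.simulate_rrs(t1, simulator.benthic, grid).values)
        np.testing.assert_allclose(diff, 2e-5 * 7.0, rtol=1e-9)

    def test_deterministic(self, simulator, typical_theta):
        a = simulator(typical_theta).values
        b = simulator(typical_theta).values
        np.testing.assert_array_equal(a, b)

    def test_cdom_darkens_blue_over_deep_water(self, grid, simulator):
        i440 = int(np.argmax(grid.values == 440.0))
        lo = np.array([0.3, 0.05, 0.5, 5.0, 1000.0])
        hi = np.array([0.3, 0.50, 0.5, 5.0, 1000.0])
        r_lo = rb.simulate_rrs(lo, simulator.benthic, grid).values[i440]
        r_hi = rb.simulate_rrs(hi, simulator.benthic, grid).values[i440]
        assert r_hi < r_lo

    def test_minerals_brighten_green_over_deep_water(self, grid, simulator):
        i560 = int(np.argmax(grid.values == 560.0))
        lo = np.array([0.3, 0.05, 0.5, 5.0, 1000.0])
        hi = np.array([0.3, 0.05, 5.0, 5.0, 1000.0])
        r_lo = rb.simulate_rrs(lo, simulator.benthic, grid).values[i560]
        r_hi = rb.simulate_rrs(hi, simulator.benthic, grid).values[i560]
        assert r_hi > r_lo

    def test_grid_mismatch_rejected(self, simulator, typical_theta):
        other = rb.make_wavelength_grid(400, 705, 5)
        with pytest.raises(ValueError, match="grid"):
            rb.simulate_rrs(typical_theta, simulator.benthic, other)

    def test_negative_depth_rejected(self, grid, simulator):
        with pytest.raises(ValueError, match="depth"):
            rb.simulate_rrs(np.array([0.3, 0.05, 0.5, 5.0, -1.0]),
                            simulator.benthic, grid)

    def test_batch_matches_scalar_path(self, simulator, priors):
        thetas = rb.sample_prior(priors, 20, seed=3)
        batch = simulator.simulate_batch(thetas)
        rows = np.stack([simulator(t).values for t in thetas])
        np.testing.assert_allclose(batch, rows, rtol=1e-12)


class TestRrsConversion:
    @pytest.mark.parametrize(
        "rrs,expected",
        [(0.0, 0.0), (0.01, 0.005076142131979695), (0.1, 0.058823529411764705)],
    )
    def test_known_values(self, rrs, expected):
        assert rrs_to_Rrs(rrs) == pytest.approx(expected, rel=1e-12)

    def test_pole_rejected(self):
        with pytest.raises(ValueError, match="non-physical"):
            rrs_to_Rrs(0.7)

    @given(st.floats(min_value=0.0, max_value=0.6))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_and_monotonicity(self, rrs):
        Rrs = rrs_to_Rrs(rrs)
        assert Rrs_to_rrs(Rrs) == pytest.approx(rrs, rel=1e-12, abs=1e-15)
        eps = 1e-6
        assert rrs_to_Rrs(rrs + eps) > Rrs  # strictly increasing


def test_default_benthic_spectrum_shape(grid):
    """Brown-coral-like: darker blue than red, values within [0, 1]."""
    b = default_benthic_spectrum(grid)
    assert np.all(b.rho >= 0) and np.all(b.rho <= 1)
    assert b.rho[0] < b.rho[-1]
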