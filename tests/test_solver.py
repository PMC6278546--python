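"""Finite-volume transport solver: interface model, stepping, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twaspme as tp
from twaspme.solver import (
    Field,
    SolverError,
    SolverSettings,
    column_system,
    interface_flux,
    simulate,
)


class TestInterfaceFlux:
    def test_partition_equilibrium_gives_zero_flux(self):
        assert interface_flux(1e-6, 301 * 1e-6, 301, 1000) == pytest.approx(0.0)

    def test_clean_coating_inward_flux(self):
        assert interface_flux(6.41e-7, 0.0, 301, 1000) == pytest.approx(6.41e-4)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=0, max_value=1e-3),
        st.floats(min_value=0, max_value=1.0),
        st.floats(min_value=1.0, max_value=1e6),
    )
    def test_outward_flux_is_negated_inward(self, ca, cf, kd):
        inward = interface_flux(ca, cf, kd, 1000)
        outward = -interface_flux(ca, cf, kd, 1000)
        assert outward == pytest.approx(-inward)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            interface_flux(1e-6, 0.0, 0.0, 1000)


class TestAdvance:
    def test_uniform_field_with_no_flux_boundaries_is_stationary(
        self, benzene, car_pdms
    ):
        system = column_system(
            5e-3, 100e-6, 20, benzene, car_pdms, open_dirichlet=False
        )
        fld = Field(values=np.full(system.n_unknowns, 2e-7))
        out = system.advance(fld, 500.0, 0.0)
        assert out.values == pytest.approx(fld.values, rel=1e-12)

    def test_air_column_at_boundary_concentration_is_steady(self, benzene):
        c0 = 0.641e-6
        system = column_system(10e-3, 155e-6, 30, benzene, None)
        fld = Field(values=np.full(system.n_unknowns, c0))
        out = system.advance(fld, 100.0, c0)
        assert out.values == pytest.approx(np.full_like(out.values, c0), rel=1e-12)

    def test_discrete_conservation_per_step(self, benzene, car_pdms):
        """Backward-Euler: stored-amount change equals Δt × boundary influx."""
        system = column_system(2e-3, 100e-6, 30, benzene, car_pdms)
        fld = system.new_field()
        dt, c0 = 50.0, 1e-6
        for _ in range(5):
            new = system.advance(fld, dt, c0)
            change = system.stored_amount(new.values) - system.stored_amount(
                fld.values
            )
            influx = dt * system.boundary_influx_rate(new.values, c0)
            assert change == pytest.approx(influx, rel=1e-9)
            fld = new

    def test_nonpositive_dt_rejected(self, benzene):
        system = column_system(1e-3, 1e-4, 5, benzene, None)
        with pytest.raises(SolverError):
            system.advance(system.new_field(), 0.0, 1e-6)


class TestSimulate:
    @pytest.fixture()
    def quick_run(self, benzene, car_pdms, fast_resolution):
        dev = tp.build_device("needle_24ga", 10e-3)
        prog = tp.ConcentrationProgram.constant(0.641e-6)
        return simulate(
            dev,
            car_pdms,
            benzene,
            prog,
            SolverSettings(dt_max=500.0),
            t_end=20_000,
            resolution=fast_resolution,
        )

    def test_monotone_uptake_under_constant_concentration(self, quick_run):
        series = quick_run.series
        assert np.all(np.diff(series.n_extracted) >= 0)
        rec = series.recovery_pct[1:]
        assert np.all(np.diff(rec) <= 1e-9)

    def test_mass_balance(self, quick_run):
        assert quick_run.mass_balance_residual < 1e-3

    def test_starts_from_zero(self, quick_run):
        series = quick_run.series
        assert series.t[0] == 0.0
        assert series.n_extracted[0] == 0.0
        assert np.all(series.n_extracted >= 0)

    def test_deterministic_outputs(self, benzene, pdms, fast_resolution):
        dev = tp.build_device("needle_24ga", 10e-3)
        prog = tp.ConcentrationProgram.constant(0.641e-6)
        kw = dict(t_end=5_000, resolution=fast_resolution)
        a = simulate(dev, pdms, benzene, prog, **kw)
        b = simulate(dev, pdms, benzene, prog, **kw)
        assert np.array_equal(a.series.n_extracted, b.series.n_extracted)
        assert np.array_equal(a.final_field.values, b.final_field.values)

    def test_interface_modes_agree_for_large_flux_coefficient(
        self, benzene, pdms, fast_resolution
    ):
        """Penalty flux at k = 1000 m/s matches the equilibrium-partition
        limit: a further increase of k does not affect the result."""
        dev = tp.build_device("needle_24ga", 10e-3)
        prog = tp.ConcentrationProgram.constant(0.641e-6)
        recs = []
        for mode in ("penalty_flux", "equilibrium_partition"):
            res = simulate(
                dev,
                pdms,
                benzene,
                prog,
                SolverSettings(interface_mode=mode),
                t_end=10_000,
                resolution=fast_resolution,
            )
            recs.append(res.recovery_at(10_000))
        assert abs(recs[0] - recs[1]) < 0.2

    def test_breakpoints_refine_the_step(self, benzene, car_pdms, fast_resolution):
        """A concentration drop mid-run is resolved, not stepped over."""
        prog = tp.ConcentrationProgram.from_breakpoints(
            [(0, 1.176e-6), (4_000, 1.176e-6), (4_500, 0.1176e-6), (10_000, 0.1176e-6)]
        )
        dev = tp.build_device("needle_24ga", 10e-3)
        res = simulate(
            dev, car_pdms, benzene, prog, t_end=10_000, resolution=fast_resolution
        )
        assert res.mass_balance_residual < 1e-3
        # uptake rate drops sharply after the concentration drop
        series = res.series
        rate = np.diff(series.n_extracted) / np.diff(series.t)
        before = rate[np.searchsorted(series.t[1:], 4_000) - 1]
        after = rate[-1]
        assert after < 0.5 * before

    def test_invalid_t_end(self, benzene, car_pdms):
        dev = tp.build_device("needle_24ga", 10e-3)
        prog = tp.ConcentrationProgram.constant(1e-6)
        with pytest.raises(ValueError):
            simulate(dev, car_pdms, benzene, prog, t_end=0.0)
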