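"""Concentration programs, the ideal TWA model, and derived metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twaspme.materials import BUILTIN_ANALYTES, BUILTIN_COATINGS, derive_porous
from twaspme.scenarios import (
    ConcentrationProgram,
    ProfileReport,
    extracted_amount,
    ideal_uptake,
    profile_metrics,
    recovery,
)
from twaspme.solver import Field, column_system

WORST_CASE = ConcentrationProgram.from_breakpoints(
    [(0, 1.176e-6), (49_000, 1.176e-6), (51_000, 0.1176e-6), (100_000, 0.1176e-6)]
)


class TestConcentrationProgram:
    def test_constant_program_twa(self):
        prog = ConcentrationProgram.constant(0.641e-6)
        for t in (1.0, 1e3, 1e5):
            assert prog.twa(t) == pytest.approx(0.641e-6)

    def test_worst_case_twa_at_end(self):
        # (1.176·49000 + 0.6468·2000 + 0.1176·49000) / 100000
        assert WORST_CASE.twa(100_000) == pytest.approx(0.6468e-6, rel=1e-9)

    def test_worst_case_twa_on_plateau(self):
        assert WORST_CASE.twa(49_000) == pytest.approx(1.176e-6, rel=1e-12)

    def test_ramp_is_linear_between_breakpoints(self):
        assert WORST_CASE.value(50_000) == pytest.approx(
            (1.176e-6 + 0.1176e-6) / 2
        )

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            WORST_CASE.twa(0.0)

    def test_decreasing_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationProgram.from_breakpoints([(0, 1e-6), (0, 2e-6)])

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=1e5),
                st.floats(min_value=0, max_value=1e-5),
            ),
            min_size=1,
            max_size=6,
            unique_by=lambda p: round(p[0], 6),
        ),
        st.floats(min_value=1.0, max_value=2e5),
    )
    def test_twa_bounded_by_program_range(self, points, t):
        points = sorted(points)
        prog = ConcentrationProgram.from_breakpoints(points)
        cs = prog.concentrations
        twa = prog.twa(t)
        assert min(cs) - 1e-20 <= twa <= max(cs) + 1e-20


class TestIdealModel:
    def test_benzene_24ga_amount(self):
        n = ideal_uptake(0.641e-6, 8.8e-6, math.pi * 155e-6**2, 1e5, 0.01)
        assert n == pytest.approx(4.26e-12, rel=2e-3)

    def test_zero_time(self):
        assert ideal_uptake(1e-6, 8.8e-6, 1e-7, 0.0, 0.01) == 0.0

    def test_23ga_z40_is_100_pg_of_benzene(self):
        """The detection-limit estimate: ~100 pg at 23 ga, Z = 40 mm."""
        n = ideal_uptake(0.641e-6, 8.8e-6, math.pi * 170e-6**2, 1e5, 0.04)
        assert n == pytest.approx(1.28e-12, rel=2e-3)
        assert n * 78.0 * 1e12 == pytest.approx(100.0, rel=0.01)  # pg

    def test_linear_in_each_argument(self):
        base = ideal_uptake(1e-6, 8.8e-6, 1e-7, 1e4, 0.01)
        assert ideal_uptake(2e-6, 8.8e-6, 1e-7, 1e4, 0.01) == pytest.approx(2 * base)
        assert ideal_uptake(1e-6, 8.8e-6, 1e-7, 1e4, 0.02) == pytest.approx(base / 2)

    def test_zero_retraction_rejected(self):
        with pytest.raises(ValueError):
            ideal_uptake(1e-6, 8.8e-6, 1e-7, 1e4, 0.0)


class TestRecovery:
    @pytest.mark.parametrize(
        "n,n_ideal,expected",
        [(3.28e-12, 4.26e-12, 77.0), (0.0, 1e-12, 0.0), (2e-12, 2e-12, 100.0)],
    )
    def test_values(self, n, n_ideal, expected):
        assert recovery(n, n_ideal) == pytest.approx(expected, abs=0.1)

    def test_undefined_for_zero_ideal(self):
        with pytest.raises(ValueError):
            recovery(1e-12, 0.0)


class TestExtractedAmount:
    def test_adsorptive_uniform_field(self, benzene, car_pdms):
        system = column_system(1e-3, 100e-6, 10, benzene, car_pdms)
        c = 1e-6
        fld = Field(values=np.full(system.n_unknowns, c))
        porous = derive_porous(car_pdms, benzene)
        volume = math.pi * 100e-6**2 * 1e-3
        assert extracted_amount(fld, system) == pytest.approx(
            porous.R * c * volume, rel=1e-12
        )

    def test_absorptive_uniform_field(self, benzene, pdms):
        system = column_system(1e-3, 100e-6, 10, benzene, pdms)
        cf = 3e-4
        fld = Field(values=np.full(system.n_unknowns, cf))
        volume = math.pi * 100e-6**2 * 1e-3
        assert extracted_amount(fld, system) == pytest.approx(cf * volume, rel=1e-12)

    def test_zero_field(self, benzene, car_pdms):
        system = column_system(1e-3, 100e-6, 10, benzene, car_pdms)
        assert extracted_amount(Field(values=np.zeros(system.n_unknowns)), system) == 0


class TestProfileMetrics:
    @staticmethod
    def _uniform_profile(n=20, length=10e-3, loading=5.0):
        edges = np.linspace(0, length, n + 1)
        return ProfileReport(
            z_lo=edges[:-1],
            z_hi=edges[1:],
            loading=np.full(n, loading),
            bin_volume=np.full(n, 1e-12),
            air_z=np.array([]),
            air_concentration=np.array([]),
        )

    def test_uniform_profile(self):
        metrics = profile_metrics(self._uniform_profile(), tip_window=1e-3)
        assert metrics["tip_fraction"] == pytest.approx(10.0, rel=1e-9)
        assert metrics["tip_to_end_ratio"] == pytest.approx(1.0)

    def test_tip_window_fractional_overlap(self):
        metrics = profile_metrics(self._uniform_profile(n=4), tip_window=1.25e-3)
        assert metrics["tip_fraction"] == pytest.approx(12.5, rel=1e-9)

    def test_window_beyond_coating_rejected(self):
        with pytest.raises(ValueError):
            profile_metrics(self._uniform_profile(), tip_window=20e-3)
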