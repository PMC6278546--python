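"""Closed-form reference solutions used to verify the transport solver.

None of these call the finite-volume code: each is an independent
analytic result for a limiting configuration that the solver can be
driven into, so agreement is evidence and disagreement is a bug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .materials import BUILTIN_ANALYTES, BUILTIN_COATINGS, derive_porous
from .solver import SolverSettings, column_system

__all__ = [
    "OracleResult",
    "steady_channel_rate",
    "retarded_semi_infinite_uptake",
    "check_steady_channel",
    "check_retarded_slab",
    "run_validation",
]


@dataclass(frozen=True)
class OracleResult:
    scenario: str
    analytic: float
    simulated: float

    @property
    def rel_error(self) -> float:
        return abs(self.simulated - self.analytic) / abs(self.analytic)

    def passed(self, tol: float = 0.01) -> bool:
        return self.rel_error <= tol


def steady_channel_rate(C0: float, D: float, A: float, Z: float) -> float:
    """Steady molar flow through a stagnant air channel with a perfect sink.

    ``C0·D·A/Z`` — the time derivative of the ideal TWA uptake model.
    """
    if Z <= 0:
        raise ValueError("Z must be > 0")
    return C0 * D * A / Z


def retarded_semi_infinite_uptake(C0: float, D_e: float, R: float, t: float) -> float:
    """Amount stored per unit area in a retarded half-space, mol·m⁻².

    For ``R·∂c/∂t = D_e·∂²c/∂z²`` on z > 0 with surface concentration C0
    and zero initial condition, the stored amount per exposed area is
    ``2·C0·sqrt(R·D_e·t/π)``.
    """
    if min(C0, D_e, R) <= 0 or t < 0:
        raise ValueError("C0, D_e, R must be > 0 and t >= 0")
    return 2.0 * C0 * math.sqrt(R * D_e * t / math.pi)


# ---------------------------------------------------------------------------
# Solver-vs-oracle drivers (used by tests and the `validate` CLI command).


def check_steady_channel(
    n_cells: int = 60, t_end: float = 60_000.0
) -> OracleResult:
    """Empty-tube flux: air column, C0 at the opening, sink plane at depth Z."""
    analyte = BUILTIN_ANALYTES["benzene"]
    C0, Z, radius = 0.641e-6, 0.01, 155e-6
    settings = SolverSettings(dt_max=500.0, output_interval=t_end)
    system = column_system(
        Z, radius, n_cells, analyte, None, settings, rear_dirichlet=0.0
    )
    fld = system.new_field()
    t, dt = 0.0, settings.dt_init
    while t < t_end - 1e-9:
        step = min(dt, t_end - t)
        fld = system.advance(fld, step, C0)
        t += step
        dt = min(dt * settings.dt_growth, settings.dt_max)
    # outflow through the rear sink plane at late time
    idx, coef, diag, fixed = system._bnd[-1]
    out_rate = float(np.sum(diag * fld.values[idx] - coef * fixed))
    area = math.pi * radius**2
    return OracleResult(
        scenario="steady_channel_rate",
        analytic=steady_channel_rate(C0, analyte.D_air, area, Z),
        simulated=out_rate,
    )


def check_retarded_slab(
    n_cells: int = 400, t_end: float = 10.0
) -> OracleResult:
    """Early-time uptake of a deep adsorptive slab vs the half-space form.

    The slab is long enough that the penetration depth sqrt(D_e·t/R) stays
    below 20% of its length over the comparison window.
    """
    analyte = BUILTIN_ANALYTES["benzene"]
    coating = BUILTIN_COATINGS["car_pdms"]
    porous = derive_porous(coating, analyte)
    C0, radius = 1e-6, 100e-6
    length = 25.0 * math.sqrt(porous.D_e * t_end / porous.R)
    settings = SolverSettings(dt_init=t_end / 2000, dt_max=t_end / 200)
    system = column_system(length, radius, n_cells, analyte, coating, settings)
    fld = system.new_field()
    t, dt = 0.0, settings.dt_init
    while t < t_end - 1e-12:
        step = min(dt, t_end - t)
        fld = system.advance(fld, step, C0)
        t += step
        dt = min(dt * settings.dt_growth, settings.dt_max)
    area = math.pi * radius**2
    stored_per_area = system.stored_amount(fld.values) / area
    return OracleResult(
        scenario="retarded_semi_infinite_uptake",
        analytic=retarded_semi_infinite_uptake(C0, porous.D_e, porous.R, t_end),
        simulated=stored_per_area,
    )


def run_validation(tol: float = 0.01) -> dict:
    """Run all oracle checks; returns a JSON-serializable report."""
    results = [check_steady_channel(), check_retarded_slab()]
    return {
        "tolerance": tol,
        "passed": all(r.passed(tol) for r in results),
        "checks": [
            {
                "scenario": r.scenario,
                "analytic": r.analytic,
                "simulated": r.simulated,
                "rel_error": r.rel_error,
                "passed": r.passed(tol),
            }
            for r in results
        ],
    }
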