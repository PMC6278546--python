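"""Boundary-concentration programs, the ideal uptake model, and metrics.

The quantification reference for TWA sampling by a retracted fiber is the
steady-state form of Fick's first law for a stagnant air column of length
``Z`` and cross-section ``A`` terminated by a perfect ("zero-sink")
absorber::

    n_ideal(t) = C̄(t) · A · D · t / Z

where ``C̄(t)`` is the time-weighted-average concentration at the opening
over ``[0, t]``.  The *recovery* of a simulated (or real) sampler is the
extracted amount expressed as a percentage of ``n_ideal`` — the accuracy
metric for the whole technique, since practitioners invert this formula
to obtain C̄ from the measured ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import MEMBRANE_COATING, POROUS_COATING

__all__ = [
    "ConcentrationProgram",
    "UptakeSeries",
    "ProfileReport",
    "ideal_uptake",
    "recovery",
    "extracted_amount",
    "coating_profile",
    "profile_metrics",
]


@dataclass(frozen=True)
class ConcentrationProgram:
    """Piecewise-linear boundary concentration C(t) at the sampler opening.

    Linear interpolation between breakpoints, constant extrapolation
    beyond the first/last breakpoint.
    """

    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size == 0 or t.size != c.size:
            raise ValueError("need matching, non-empty times and concentrations")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def constant(cls, c0: float) -> "ConcentrationProgram":
        return cls(times=(0.0,), concentrations=(c0,))

    @classmethod
    def from_breakpoints(
        cls, points: Sequence[tuple[float, float]]
    ) -> "ConcentrationProgram":
        ts, cs = zip(*points)
        return cls(times=tuple(ts), concentrations=tuple(cs))

    def value(self, t: float | np.ndarray) -> float | np.ndarray:
        return np.interp(t, self.times, self.concentrations)

    def twa(self, t: float) -> float:
        """Time-weighted-average concentration over [0, t], mol·m⁻³.

        Exact trapezoidal integration of the piecewise-linear program.
        """
        if t <= 0:
            raise ValueError("TWA requires t > 0")
        knots = np.asarray(self.times, dtype=float)
        inner = knots[(knots > 0.0) & (knots < t)]
        grid = np.concatenate(([0.0], inner, [t]))
        vals = self.value(grid)
        return float(np.trapezoid(vals, grid) / t)

    @property
    def max_breakpoint_time(self) -> float:
        return self.times[-1]


def ideal_uptake(C_twa: float, D: float, A: float, t: float, Z: float) -> float:
    """Zero-sink ideal extracted amount n = C̄·A·D·t/Z, mol."""
    if Z <= 0:
        raise ValueError("the retracted-sampler model requires Z > 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    return C_twa * A * D * t / Z


def recovery(n: float, n_ideal: float) -> float:
    """Extracted amount as a percentage of the ideal amount."""
    if n_ideal <= 0:
        raise ValueError("recovery undefined for n_ideal <= 0")
    return 100.0 * n / n_ideal


@dataclass
class UptakeSeries:
    """Time series of a simulated sampling run.

    Amounts in mol; ``recovery_pct`` is NaN where ``n_ideal`` is zero
    (t = 0 of a run, or a program that starts at zero concentration).
    """

    t: np.ndarray
    n_extracted: np.ndarray
    n_air: np.ndarray
    n_ideal: np.ndarray

    @property
    def recovery_pct(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.n_ideal > 0, 100.0 * self.n_extracted / self.n_ideal, np.nan
            )

    def at(self, t: float) -> dict[str, float]:
        """The output sample closest to time t (must match within 0.5 s)."""
        i = int(np.argmin(np.abs(self.t - t)))
        if abs(self.t[i] - t) > 0.5:
            raise ValueError(f"no output sample near t={t:g} s")
        return {
            "t": float(self.t[i]),
            "n_extracted": float(self.n_extracted[i]),
            "n_air": float(self.n_air[i]),
            "n_ideal": float(self.n_ideal[i]),
            "recovery_pct": float(self.recovery_pct[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "n_extracted_mol": self.n_extracted,
                "n_air_mol": self.n_air,
                "n_ideal_mol": self.n_ideal,
                "recovery_pct": self.recovery_pct,
            }
        )


# ---------------------------------------------------------------------------
# Field-based metrics.  ``system`` is a solver TransportSystem (duck-typed
# here to avoid a circular import): it exposes grid, storage coefficients,
# and the open-cell index map.


def extracted_amount(field, system) -> float:
    """Total analyte held by the coating, mol.

    Absorptive membrane: ∫ C_f dV.  Adsorptive porous bed: ∫ (ε + K_d)·c dV
    — pore air plus adsorbed phase, via the storage coefficient.
    """
    g = system.grid
    coating = (g.region == POROUS_COATING) | (g.region == MEMBRANE_COATING)
    idx = system.cell_index[coating]
    return float(
        np.sum(field.values[idx] * system.storage[idx] * g.volume[coating])
    )


def air_amount(field, system) -> float:
    """Analyte held in the free air of the tube, mol."""
    g = system.grid
    air = g.region == 0  # FREE_AIR
    idx = system.cell_index[air]
    return float(np.sum(field.values[idx] * g.volume[air]))


@dataclass
class ProfileReport:
    """Axial loading profile of the coating plus the air-path profile.

    ``loading`` is the total analyte per coating volume in each axial bin
    (mol·m⁻³): C_f for a membrane, (ε + K_d)·c for a porous bed.  Bins run
    from the coating tip (nearest the opening) rearward.
    """

    z_lo: np.ndarray  # bin start, m from the coating tip
    z_hi: np.ndarray
    loading: np.ndarray  # mol·m⁻³ of coating
    bin_volume: np.ndarray  # m³
    air_z: np.ndarray  # axial positions along the diffusion path, m
    air_concentration: np.ndarray  # mol·m⁻³


def coating_profile(field, system) -> ProfileReport:
    """Bin the final field into per-axial-cell coating loadings."""
    g = system.grid
    coating = (g.region == POROUS_COATING) | (g.region == MEMBRANE_COATING)
    rows = np.flatnonzero(coating.any(axis=1))
    if rows.size == 0:
        raise ValueError("device has no coating cells")
    z0 = g.geom.Z
    z_lo = g.z_faces[rows] - z0
    z_hi = g.z_faces[rows + 1] - z0
    loading = np.empty(rows.size)
    vol = np.empty(rows.size)
    for k, i in enumerate(rows):
        cols = coating[i]
        idx = system.cell_index[i, cols]
        v = g.volume[i, cols]
        vol[k] = v.sum()
        loading[k] = np.sum(field.values[idx] * system.storage[idx] * v) / vol[k]

    air = g.region == 0
    arows = np.flatnonzero(air.any(axis=1))
    air_c = np.empty(arows.size)
    for k, i in enumerate(arows):
        cols = air[i]
        idx = system.cell_index[i, cols]
        v = g.volume[i, cols]
        air_c[k] = np.sum(field.values[idx] * v) / v.sum()
    return ProfileReport(
        z_lo=z_lo,
        z_hi=z_hi,
        loading=loading,
        bin_volume=vol,
        air_z=g.z_centers[arows],
        air_concentration=air_c,
    )


def profile_metrics(profile: ProfileReport, tip_window: float = 1e-3) -> dict:
    """Tip-heaviness statistics of a coating loading profile.

    ``tip_fraction``: percentage of the total extracted amount held within
    ``tip_window`` of the coating tip (fractional cell overlap included).
    ``tip_to_end_ratio``: loading concentration of the first axial bin over
    the last one.
    """
    if profile.loading.size == 0:
        raise ValueError("empty profile")
    span = profile.z_hi[-1]
    if tip_window > span * (1 + 1e-9):
        raise ValueError("tip_window exceeds the coating length")
    amounts = profile.loading * profile.bin_volume
    dz = profile.z_hi - profile.z_lo
    overlap = np.clip((tip_window - profile.z_lo) / dz, 0.0, 1.0)
    total = amounts.sum()
    tip_fraction = 100.0 * float(np.sum(amounts * overlap) / total)
    ratio = float(profile.loading[0] / profile.loading[-1])
    return {"tip_fraction": tip_fraction, "tip_to_end_ratio": ratio}
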