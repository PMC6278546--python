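"""Analytes, fiber coatings, and derived porous-media transport parameters.

Adsorptive SPME coatings (Car/PDMS, PDMS/DVB) are beds of porous sorbent
particles.  Transport through them is molecular diffusion in the pore air,
slowed by porosity/tortuosity and by linear adsorption onto the particle
surface.  The governing storage coefficient (retardation factor) is
``R = ε + K_d``: a unit volume of coating holds ``ε·c`` mol in pore air and
``ρ_b·K_p·c = K_d·c`` mol adsorbed when the pore-air concentration is ``c``.
The coating bulk density ρ_b cancels out of R because the mass-based
partition constant is defined as ``K_p = K_d / ρ_b``.

Absorptive coatings (plain PDMS) are homogeneous liquid membranes: analyte
dissolves and diffuses with the membrane diffusivity, and exchanges with
air at the coating surface through a partition-flux boundary condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "MaterialError",
    "Analyte",
    "CoatingSpec",
    "PorousDerived",
    "intra_particle_porosity",
    "total_porosity",
    "tortuosity_from_porosity",
    "effective_diffusivity",
    "retardation_factor",
    "derive_porous",
    "BUILTIN_ANALYTES",
    "BUILTIN_COATINGS",
    "get_analyte",
    "get_coating",
    "load_registry",
]


class MaterialError(ValueError):
    """Invalid material definition or out-of-range porous-media input."""


@dataclass(frozen=True)
class Analyte:
    """A volatile organic compound with its gas-phase properties.

    Attributes
    ----------
    name : str
    D_air : float
        Gas-phase molecular diffusion coefficient, m²·s⁻¹.
    molar_mass : float
        g·mol⁻¹.
    """

    name: str
    D_air: float
    molar_mass: float

    def __post_init__(self) -> None:
        if self.D_air <= 0:
            raise MaterialError(f"{self.name}: D_air must be > 0")
        if self.molar_mass <= 0:
            raise MaterialError(f"{self.name}: molar_mass must be > 0")


@dataclass(frozen=True)
class CoatingSpec:
    """A fiber coating: sorption mechanism, partitioning, particle data.

    Attributes
    ----------
    mechanism : {"adsorptive", "absorptive"}
        Porous particle bed vs homogeneous liquid membrane.
    K_d : mapping analyte name -> dimensionless coating/air distribution
        constant.
    D_membrane : float or None
        Diffusivity of analyte inside an absorptive membrane, m²·s⁻¹.
    particle_pore_volume, particle_specific_volume : float
        mL·g⁻¹ (adsorptive coatings only).
    particle_freefall_density : float
        kg·m⁻³, density of the loose sorbent particles.
    inter_particle_porosity : float
        Void fraction between packed particles.
    outer_radius : float
        Coating outer radius on the standard fiber, m.
    """

    name: str
    mechanism: str
    K_d: Mapping[str, float] = field(default_factory=dict)
    D_membrane: float | None = None
    particle_pore_volume: float | None = None
    particle_specific_volume: float | None = None
    particle_freefall_density: float | None = None
    inter_particle_porosity: float | None = None
    outer_radius: float = 145e-6

    def __post_init__(self) -> None:
        if self.mechanism not in ("adsorptive", "absorptive"):
            raise MaterialError(
                f"{self.name}: mechanism must be adsorptive or absorptive"
            )
        for analyte, kd in self.K_d.items():
            if kd <= 0:
                raise MaterialError(f"{self.name}: K_d[{analyte}] must be > 0")
        if self.mechanism == "absorptive":
            if self.D_membrane is None or self.D_membrane <= 0:
                raise MaterialError(
                    f"{self.name}: absorptive coating requires D_membrane > 0"
                )
        if self.inter_particle_porosity is not None and not (
            0 <= self.inter_particle_porosity < 1
        ):
            raise MaterialError(f"{self.name}: inter_particle_porosity not in [0,1)")

    def kd_for(self, analyte: Analyte | str) -> float:
        name = analyte if isinstance(analyte, str) else analyte.name
        try:
            return float(self.K_d[name])
        except KeyError:
            raise MaterialError(
                f"coating {self.name!r} has no distribution constant for {name!r}"
            ) from None


@dataclass(frozen=True)
class PorousDerived:
    """Porous-media parameters derived for one (coating, analyte) pair."""

    eps_intra: float
    eps_total: float
    tau: float
    rho_b: float  # kg·m⁻³, reporting only: cancels from transport
    K_p: float  # m³·kg⁻¹, = K_d / rho_b
    D_e: float  # m²·s⁻¹
    R: float  # dimensionless, = eps_total + K_d


def intra_particle_porosity(pore_volume: float, specific_volume: float) -> float:
    """Pore volume fraction of a sorbent particle.

    Both arguments in mL·g⁻¹: total pore volume per gram divided by total
    volume of one gram of material.
    """
    if specific_volume <= 0:
        raise MaterialError("specific_volume must be > 0")
    if pore_volume < 0 or pore_volume > specific_volume:
        raise MaterialError("need 0 <= pore_volume <= specific_volume")
    return pore_volume / specific_volume


def total_porosity(eps_intra: float, eps_inter: float) -> float:
    """Total coating porosity from intra- and inter-particle porosities.

    The inter-particle voids occupy ``eps_inter`` of the coating; the
    remaining particle fraction contributes its own internal porosity:
    ``eps = eps_inter + (1 - eps_inter) * eps_intra``.
    """
    if not (0 <= eps_intra < 1) or not (0 <= eps_inter < 1):
        raise MaterialError("porosities must lie in [0, 1)")
    return eps_inter + (1.0 - eps_inter) * eps_intra


def tortuosity_from_porosity(eps: float) -> float:
    """Tortuosity model ``τ = ε + 1.5·(1 − ε)``; τ = 1 for a fully open medium."""
    if not (0 < eps <= 1):
        raise MaterialError("porosity must lie in (0, 1]")
    return eps + 1.5 * (1.0 - eps)


def effective_diffusivity(eps: float, D_pore: float, tau: float) -> float:
    """Effective diffusivity ``D_e = ε·D_p/τ`` of a porous bed (superficial basis)."""
    if not (0 < eps <= 1):
        raise MaterialError("porosity must lie in (0, 1]")
    if D_pore <= 0:
        raise MaterialError("D_pore must be > 0")
    if tau < 1:
        raise MaterialError("tortuosity must be >= 1")
    return eps * D_pore / tau


def retardation_factor(eps: float, K_d: float) -> float:
    """Storage coefficient ``R = ε + K_d`` of a linearly adsorbing porous bed."""
    if not (0 < eps < 1):
        raise MaterialError("porosity must lie in (0, 1)")
    if K_d < 0:
        raise MaterialError("K_d must be >= 0")
    return eps + K_d


def derive_porous(coating: CoatingSpec, analyte: Analyte) -> PorousDerived:
    """All porous-media transport parameters for one coating/analyte pair."""
    if coating.mechanism != "adsorptive":
        raise MaterialError(f"{coating.name} is not an adsorptive coating")
    if None in (
        coating.particle_pore_volume,
        coating.particle_specific_volume,
        coating.particle_freefall_density,
        coating.inter_particle_porosity,
    ):
        raise MaterialError(f"{coating.name}: incomplete particle data")
    eps_intra = intra_particle_porosity(
        coating.particle_pore_volume, coating.particle_specific_volume
    )
    eps = total_porosity(eps_intra, coating.inter_particle_porosity)
    tau = tortuosity_from_porosity(eps)
    kd = coating.kd_for(analyte)
    # pore air diffuses with the free-air coefficient (macro-pore regime)
    d_e = effective_diffusivity(eps, analyte.D_air, tau)
    rho_b = coating.particle_freefall_density * (1.0 - coating.inter_particle_porosity)
    return PorousDerived(
        eps_intra=eps_intra,
        eps_total=eps,
        tau=tau,
        rho_b=rho_b,
        K_p=kd / rho_b,
        D_e=d_e,
        R=retardation_factor(eps, kd),
    )


# ---------------------------------------------------------------------------
# Built-in registry: common VOCs and commercial SPME coatings at 298 K, 1 atm.

BUILTIN_ANALYTES: dict[str, Analyte] = {
    "benzene": Analyte("benzene", D_air=8.8e-6, molar_mass=78.11),
    "toluene": Analyte("toluene", D_air=8.7e-6, molar_mass=92.14),
    "acetone": Analyte("acetone", D_air=12.4e-6, molar_mass=58.08),
    "dichloromethane": Analyte("dichloromethane", D_air=10.1e-6, molar_mass=84.93),
}

BUILTIN_COATINGS: dict[str, CoatingSpec] = {
    # 85 µm Carboxen/PDMS on a 130 µm core: fiber O.D. 290 µm
    "car_pdms": CoatingSpec(
        name="car_pdms",
        mechanism="adsorptive",
        K_d={
            "benzene": 150_000.0,
            "toluene": 288_000.0,
            "acetone": 71_000.0,
            "dichloromethane": 72_000.0,
        },
        particle_pore_volume=0.78,
        particle_specific_volume=2.13,
        particle_freefall_density=470.0,
        inter_particle_porosity=0.50,
        outer_radius=145e-6,
    ),
    # 65 µm PDMS/DVB: fiber O.D. 270 µm
    "pdms_dvb": CoatingSpec(
        name="pdms_dvb",
        mechanism="adsorptive",
        K_d={"benzene": 8_300.0},
        particle_pore_volume=1.54,
        particle_specific_volume=2.78,
        particle_freefall_density=360.0,
        inter_particle_porosity=0.50,
        outer_radius=135e-6,
    ),
    # homogeneous PDMS liquid membrane, modeled in the same fiber envelope
    "pdms": CoatingSpec(
        name="pdms",
        mechanism="absorptive",
        K_d={"benzene": 301.0},
        D_membrane=1e-10,
        outer_radius=145e-6,
    ),
}


def get_analyte(name_or_obj: str | Analyte) -> Analyte:
    if isinstance(name_or_obj, Analyte):
        return name_or_obj
    try:
        return BUILTIN_ANALYTES[name_or_obj]
    except KeyError:
        raise MaterialError(f"unknown analyte {name_or_obj!r}") from None


def get_coating(name_or_obj: str | CoatingSpec) -> CoatingSpec:
    if isinstance(name_or_obj, CoatingSpec):
        return name_or_obj
    try:
        return BUILTIN_COATINGS[name_or_obj]
    except KeyError:
        raise MaterialError(f"unknown coating {name_or_obj!r}") from None


def load_registry(path) -> tuple[dict[str, Analyte], dict[str, CoatingSpec]]:
    """Load a user material registry (YAML) mirroring the built-in schema."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    analytes = {
        name: Analyte(name=name, **spec)
        for name, spec in (doc.get("analytes") or {}).items()
    }
    coatings = {
        name: CoatingSpec(name=name, **spec)
        for name, spec in (doc.get("coatings") or {}).items()
    }
    return analytes, coatings
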