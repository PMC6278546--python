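# Methods

## Physical model

The sampler interior is treated as a 2D axisymmetric domain: the air
column between the opening plane and the fiber tip, the coating annulus,
the thin air gap between coating and tube wall, and an air space behind
the coating ending at a closed no-flux face.  Transport everywhere is
pure molecular diffusion (no advection; the column is stagnant by
design), `s·∂c/∂t = ∇·(D∇c)`.

**Adsorptive coatings** (Carboxen/PDMS, PDMS/DVB) are porous particle
beds.  The dependent variable is the pore-air concentration; adsorption
is linear (Henry regime), giving storage coefficient `R = ε + K_d`.  The
decomposition of K_d into a mass-based constant K_p = K_d/ρ_b and a bulk
density cancels identically; a unit test asserts that changing ρ_b leaves
all transport parameters bit-identical, so the proprietary packing
density of the commercial coatings is immaterial.  The effective
diffusivity is `D_e = ε·D/τ` with the porosity-derived tortuosity
`τ = ε + 1.5(1 − ε)`; pore diffusion uses the free-air coefficient
(macro-pore, non-Knudsen regime).  Total porosity composes inter- and
intra-particle porosities as `ε = ε_inter + (1 − ε_inter)·ε_intra` — the
rule that reproduces both published coating porosities (0.685, 0.775)
from the particle pore data (0.78/2.13 and 1.54/2.78 mL·g⁻¹) with
ε_inter = 0.50.  Deriving from the unrounded particle volumes gives
ε = 0.6831 and τ = 1.1584 for Car/PDMS (published values round the
intra-particle porosity to 0.37 first, giving 0.685/1.1575); the
difference is < 0.1% in D_e.

**The absorptive coating** (plain PDMS) is a homogeneous membrane with
internal diffusivity 10⁻¹⁰ m²·s⁻¹.  Its surface exchanges with air via
the two-film partition flux `J = k(C_a − C_f/K_d)`.  With the default
k = 1000 m·s⁻¹ the interfacial resistance is negligible; an
`equilibrium_partition` mode removes the 1/k term entirely and changes
recoveries by < 0.01 pp, confirming k is not load-bearing.

**Boundary conditions.**  Dirichlet C(t) exactly on the opening plane
(no external boundary-layer resistance — the device sits in well-mixed
air); no-flux on the tube wall, symmetry axis, fiber core, and rear end.
C(t) is piecewise linear with constant extrapolation, and the running
time-weighted average C̄(t) (exact trapezoidal integral) feeds the ideal
model, so recovery is well-defined for variable-concentration programs.

## Geometry defaults

Preset bore radii: 155 µm (24 ga), 170 µm (23 ga), 375 µm (liner,
78.5 mm long); stepped liner = liner with a 170-µm-radius section from
the opening to 2 mm before the fiber tip.  Fiber core radius 65 µm;
coating outer radius 145 µm (Car/PDMS, PDMS — 85 µm film) or 135 µm
(PDMS/DVB — 65 µm film).

Two dimensions are not published and are set here as package defaults:
**coating length 10 mm** (the standard commercial film length) and a
**2 mm air gap behind the coating** before the closed end (the rear face
is exposed to air).  For needles the tube is sized to exactly hold
column + coating + gap; liners have fixed 78.5 mm length and the rear gap
is the remaining space.  An acceptance test varies the coating length
between 7.5 and 15 mm and verifies the headline Car/PDMS recovery moves
by < 2 pp, so these assumptions are not decisive for adsorptive
coatings.  They do set the absolute capacity of the PDMS membrane
(its late-time recovery scales with coating volume) — see Limitations.

## Numerics

Conservative finite-volume discretization on a structured tensor grid
whose faces conform to every material interface, so no cell straddles
regions.  Face conductances are series/harmonic combinations of
half-cell resistances (`d/D` per side, plus `1/k` and the K_d partition
factor on membrane faces).  Axial faces within each band follow a cosine
distribution: target spacing 0.25 mm, refined automatically toward the
opening, the fiber tip, bore steps, and the coating rear.  Radial
defaults: 4 cells in the core column, 10 across the coating annulus,
~30 µm cells across the wall gap (minimum 3).  The default 24 ga grid
has 1336 unknowns.

Time stepping is backward Euler (unconditionally stable for the stiff
R ≈ 1.5×10⁵ retardation), Δt growing geometrically from 1 s by ×1.2 to a
250 s cap, clipped to land on the 1000-s output grid and reset to 1 s at
program breakpoints so concentration ramps are resolved.  One sparse LU
factorization per distinct Δt, reused across steps.  Crank–Nicolson is
available as a flag; it changes 100,000-s recoveries by < 0.1 pp.

The scheme conserves mass by construction: summing the discrete
equations telescopes interior fluxes, so the change in stored amount
equals the time-integrated boundary influx to solver precision.  Each
run reports its worst mass-balance residual (typically 10⁻¹⁰; the
acceptance gate is 10⁻³).  Concentrations are never clipped; a field
more negative than 10⁻⁶ of its own scale aborts the run.  Refining the
default grid ×2 in r, z and halving Δt moves the headline recoveries by
< 0.1 pp (< 0.5 pp gate).

## Verification strategy

Independent closed forms, never computed through the solver:

* **Steady channel**: an air column with a perfect sink at depth Z must
  carry `C₀·D·A/Z`; the solver agrees to 10⁻¹³ relative.
* **Retarded half-space**: early-time uptake of a deep adsorptive slab
  is `2·C₀·√(R·D_e·t/π)` per unit area; a 1D-configured solver run
  agrees within 0.1% while the penetration depth is ≪ slab length.
* **Zero-sink limit**: multiplying the pore diffusivity by 1000 makes
  the Car/PDMS fiber an ideal sink; the simulated uptake then tracks the
  ideal model within 5% over 10,000–100,000 s.

The `twaspme validate` command runs these and emits a pass/fail report.

## Known limitations

* The model is 2D axisymmetric: the fiber is assumed coaxial, and
  needle-wall sorption, temperature/humidity effects, and any advection
  at the opening are out of scope.  Adsorption is linear; saturating
  isotherms (relevant at high concentrations) are not modeled.
* The absorptive-membrane early-time transient is sensitive to the
  unpublished PDMS fiber envelope (film thickness/length fix its
  capacity); simulated PDMS recoveries at 10³–10⁴ s run a few pp above
  the published curve while matching at 10⁵ s.
* The tip-to-end loading ratio of a strongly retarded coating
  (Car/PDMS, ratio ~10²–10³) depends exponentially on the assumed
  coating length and the rear-bin size; only its order of magnitude is
  meaningful.  The near-unity PDMS/DVB ratio is robust.
* Output is sampled on a fixed 1000-s grid; quantities at earlier times
  need a smaller `output_interval`.
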