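"""Axisymmetric sampler geometries and their finite-volume grids.

A TWA-SPME sampler is a tube (protecting needle or glass liner) open at
one end.  The coated fiber sits coaxially inside, retracted a depth ``Z``
behind the opening plane.  Coordinates: ``z`` runs from the opening plane
(z = 0) into the tube, ``r`` from the axis outward.  The computational
domain is the open interior: the air column in front of the fiber, the
coating annulus, the thin air gap between coating and wall, and an air
space behind the coating ending at a closed (no-flux) rear face.

The grid is a structured tensor-product mesh whose faces conform to all
material interfaces (fiber core, coating outer surface, bore steps, fiber
tip plane), so no cell straddles two regions.  Axial faces are clustered
toward band boundaries with a cosine distribution to resolve the steep
gradients at the opening and at the fiber tip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryError",
    "GridError",
    "FREE_AIR",
    "POROUS_COATING",
    "MEMBRANE_COATING",
    "SOLID_CORE",
    "SOLID_WALL",
    "DeviceGeometry",
    "GridResolution",
    "Grid",
    "build_device",
    "generate_grid",
]


class GeometryError(ValueError):
    """Inconsistent device geometry (fiber does not fit, Z too large, ...)."""


class GridError(ValueError):
    """Discretization request that cannot resolve the geometry."""


# cell region codes
FREE_AIR = 0
POROUS_COATING = 1
MEMBRANE_COATING = 2
SOLID_CORE = 3
SOLID_WALL = 4

_PRESET_BORE = {
    "needle_24ga": 155e-6,  # I.D. 310 µm
    "needle_23ga": 170e-6,  # I.D. 340 µm
    "liner": 375e-6,  # I.D. 0.75 mm
}
_LINER_LENGTH = 78.5e-3


@dataclass(frozen=True)
class DeviceGeometry:
    """One sampler configuration.

    ``bore_segments`` is a piecewise-constant radius profile: a tuple of
    ``(z_start, z_end, radius)`` covering ``[0, tube_length)``.  The fiber
    coating occupies ``z in [Z, Z + coating_length)`` radially between
    ``fiber_core_radius`` and ``coating_outer_radius``; behind it lies
    ``rear_gap_length`` of open air, then the closed rear end.
    """

    kind: str
    bore_segments: tuple[tuple[float, float, float], ...]
    tube_length: float
    Z: float
    fiber_core_radius: float = 65e-6
    coating_outer_radius: float = 145e-6
    coating_length: float = 10e-3
    rear_gap_length: float = 2e-3

    def __post_init__(self) -> None:
        if self.Z < 0:
            raise GeometryError("Z must be >= 0")
        for name in ("tube_length", "coating_length", "rear_gap_length",
                     "fiber_core_radius", "coating_outer_radius"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if self.fiber_core_radius >= self.coating_outer_radius:
            raise GeometryError("fiber core must be thinner than the coating")
        end = self.Z + self.coating_length + self.rear_gap_length
        if end > self.tube_length * (1 + 1e-12):
            raise GeometryError(
                f"Z={self.Z:g} m leaves no room for coating and rear gap in a "
                f"{self.tube_length:g} m tube"
            )
        z0_seen = 0.0
        for z0, z1, r in self.bore_segments:
            if abs(z0 - z0_seen) > 1e-15 or z1 <= z0 or r <= 0:
                raise GeometryError("bore_segments must tile [0, tube_length)")
            z0_seen = z1
        if abs(z0_seen - self.tube_length) > 1e-12:
            raise GeometryError("bore_segments must cover the full tube length")
        lo, hi = self.Z, self.Z + self.coating_length
        for z0, z1, r in self.bore_segments:
            if z1 > lo + 1e-15 and z0 < hi - 1e-15:
                if self.coating_outer_radius >= r:
                    raise GeometryError(
                        f"fiber (O.D. {2*self.coating_outer_radius:g} m) does not "
                        f"fit the bore (I.D. {2*r:g} m) at z={z0:g}"
                    )

    @property
    def domain_length(self) -> float:
        """Axial extent of the open domain (opening to closed rear face), m."""
        return self.Z + self.coating_length + self.rear_gap_length

    def bore_radius(self, z: float) -> float:
        for z0, z1, r in self.bore_segments:
            if z0 <= z < z1 or (z1 == self.tube_length and z == z1):
                return r
        raise GeometryError(f"z={z:g} outside the tube")

    @property
    def opening_area(self) -> float:
        """Internal cross-section area at the opening plane, m² (A of the ideal model)."""
        return math.pi * self.bore_segments[0][2] ** 2


def build_device(
    kind: str,
    Z: float,
    *,
    coating_outer_radius: float = 145e-6,
    overrides: dict | None = None,
) -> DeviceGeometry:
    """Construct a preset sampler geometry.

    Presets: ``needle_24ga`` (bore radius 155 µm), ``needle_23ga`` (170 µm),
    ``liner`` (375 µm, 78.5 mm long), ``stepped_liner`` (liner whose first
    section, from the opening to 2 mm before the fiber tip, is narrowed to
    the 23 ga radius of 170 µm).  ``custom`` requires ``bore_radius`` (and
    optionally ``tube_length``) in overrides.

    Needle tubes are sized to exactly hold the air column, coating, and
    rear gap; liners have a fixed physical length and their rear gap is
    whatever space remains behind the coating.
    """
    ov = dict(overrides or {})
    core = ov.pop("fiber_core_radius", 65e-6)
    coat_r = ov.pop("coating_outer_radius", coating_outer_radius)
    coat_len = ov.pop("coating_length", 10e-3)
    rear = ov.pop("rear_gap_length", 2e-3)
    if kind in _PRESET_BORE or kind == "custom":
        if kind == "custom":
            try:
                bore = ov.pop("bore_radius")
            except KeyError:
                raise GeometryError("custom geometry requires bore_radius") from None
        else:
            bore = ov.pop("bore_radius", _PRESET_BORE[kind])
        if kind == "liner":
            tube = ov.pop("tube_length", _LINER_LENGTH)
            rear = ov.pop("rear_gap_length", tube - Z - coat_len)
            if rear <= 0:
                raise GeometryError("Z too large: no rear space left in the liner")
        else:
            tube = ov.pop("tube_length", Z + coat_len + rear)
        segments = ((0.0, tube, bore),)
    elif kind == "stepped_liner":
        tube = ov.pop("tube_length", _LINER_LENGTH)
        narrow_r = ov.pop("narrow_radius", 170e-6)
        wide_r = ov.pop("bore_radius", _PRESET_BORE["liner"])
        standoff = ov.pop("narrow_standoff", 2e-3)
        step_z = Z - standoff
        if step_z <= 0:
            raise GeometryError("stepped liner needs Z larger than the standoff")
        rear = ov.pop("rear_gap_length", tube - Z - coat_len)
        if rear <= 0:
            raise GeometryError("Z too large: no rear space left in the liner")
        segments = ((0.0, step_z, narrow_r), (step_z, tube, wide_r))
    else:
        raise GeometryError(f"unknown device kind {kind!r}")
    if ov:
        raise GeometryError(f"unknown geometry overrides: {sorted(ov)}")
    return DeviceGeometry(
        kind=kind,
        bore_segments=segments,
        tube_length=tube,
        Z=Z,
        fiber_core_radius=core,
        coating_outer_radius=coat_r,
        coating_length=coat_len,
        rear_gap_length=rear,
    )


@dataclass(frozen=True)
class GridResolution:
    """Discretization policy.

    ``axial_cell_size`` is the target spacing; within each axial band the
    faces follow a cosine distribution, giving finer cells near interfaces
    and at most ~π/2 times the target in the band middle.
    """

    n_radial_core: int = 4
    n_radial_coating: int = 10
    radial_gap_cell: float = 30e-6
    axial_cell_size: float = 0.25e-3
    cluster_axial: bool = True

    def refined(self, factor: float = 2.0) -> "GridResolution":
        """A uniformly refined copy (for grid-convergence studies)."""
        return replace(
            self,
            n_radial_core=int(round(self.n_radial_core * factor)),
            n_radial_coating=int(round(self.n_radial_coating * factor)),
            radial_gap_cell=self.radial_gap_cell / factor,
            axial_cell_size=self.axial_cell_size / factor,
        )


@dataclass
class Grid:
    """Structured axisymmetric finite-volume grid with region labels."""

    geom: DeviceGeometry | None
    r_faces: np.ndarray  # (nr+1,)
    z_faces: np.ndarray  # (nz+1,)
    region: np.ndarray  # (nz, nr) int8
    volume: np.ndarray = field(init=False)  # (nz, nr), m³

    def __post_init__(self) -> None:
        rf, zf = self.r_faces, self.z_faces
        ring = math.pi * (rf[1:] ** 2 - rf[:-1] ** 2)  # annulus areas
        dz = np.diff(zf)
        self.volume = np.outer(dz, ring)

    @property
    def nr(self) -> int:
        return len(self.r_faces) - 1

    @property
    def nz(self) -> int:
        return len(self.z_faces) - 1

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_faces[:-1] + self.r_faces[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_faces[:-1] + self.z_faces[1:])

    @property
    def open_mask(self) -> np.ndarray:
        return self.region < SOLID_CORE

    @property
    def n_open(self) -> int:
        return int(self.open_mask.sum())

    def open_volume(self) -> float:
        return float(self.volume[self.open_mask].sum())

    def analytic_open_volume(self) -> float:
        g = self.geom
        end = g.domain_length
        vol = 0.0
        for z0, z1, r in g.bore_segments:
            lo, hi = max(z0, 0.0), min(z1, end)
            if hi > lo:
                vol += math.pi * r**2 * (hi - lo)
        vol -= math.pi * g.fiber_core_radius**2 * g.coating_length
        return vol


def _band_faces(z0: float, z1: float, target: float, cluster: bool) -> np.ndarray:
    n = max(2, int(math.ceil((z1 - z0) / target)))
    xi = np.linspace(0.0, 1.0, n + 1)
    if cluster:
        xi = 0.5 * (1.0 - np.cos(math.pi * xi))
    return z0 + (z1 - z0) * xi


def generate_grid(
    geom: DeviceGeometry,
    resolution: GridResolution | None = None,
    *,
    mechanism: str = "adsorptive",
) -> Grid:
    """Discretize a device; ``mechanism`` selects the coating region label."""
    res = resolution or GridResolution()
    if res.n_radial_coating < 3:
        raise GridError("need at least 3 radial cells across the coating annulus")
    if res.n_radial_core < 1 or res.radial_gap_cell <= 0 or res.axial_cell_size <= 0:
        raise GridError("resolution parameters must be positive")

    end = geom.domain_length
    core, coat_r = geom.fiber_core_radius, geom.coating_outer_radius
    bores = sorted({r for z0, z1, r in geom.bore_segments if z0 < end})
    r_max = bores[-1]

    # radial faces: conforming at core, coating surface, and every bore radius
    r_faces = [np.linspace(0.0, core, res.n_radial_core + 1)]
    r_faces.append(np.linspace(core, coat_r, res.n_radial_coating + 1)[1:])
    marks = [coat_r] + [r for r in bores if r > coat_r + 1e-15]
    for lo, hi in zip(marks[:-1], marks[1:]):
        n = max(3, int(math.ceil((hi - lo) / res.radial_gap_cell)))
        r_faces.append(np.linspace(lo, hi, n + 1)[1:])
    rf = np.concatenate(r_faces)

    # axial bands: bore steps, fiber tip, coating rear
    cuts = {0.0, end, geom.Z, geom.Z + geom.coating_length}
    for z0, z1, r in geom.bore_segments:
        if 0.0 < z0 < end:
            cuts.add(z0)
    z_cuts = sorted(c for c in cuts if 0.0 <= c <= end)
    zf = np.concatenate(
        [
            _band_faces(a, b, res.axial_cell_size, res.cluster_axial)[:-1]
            for a, b in zip(z_cuts[:-1], z_cuts[1:])
        ]
        + [np.array([end])]
    )

    coat_label = POROUS_COATING if mechanism == "adsorptive" else MEMBRANE_COATING
    nz, nr = len(zf) - 1, len(rf) - 1
    region = np.full((nz, nr), FREE_AIR, dtype=np.int8)
    z_mid = 0.5 * (zf[:-1] + zf[1:])
    r_lo, r_hi = rf[:-1], rf[1:]
    tol = 1e-12
    fiber_band = (z_mid > geom.Z) & (z_mid < geom.Z + geom.coating_length)
    bore_at = np.array([geom.bore_radius(z) for z in z_mid])
    region[r_lo[None, :] >= bore_at[:, None] - tol] = SOLID_WALL
    in_core = r_hi <= core + tol
    in_coat = (r_lo >= core - tol) & (r_hi <= coat_r + tol)
    region[np.ix_(fiber_band, in_core)] = SOLID_CORE
    region[np.ix_(fiber_band, in_coat)] = coat_label

    grid = Grid(geom=geom, r_faces=rf, z_faces=zf, region=region)
    if not math.isclose(grid.open_volume(), grid.analytic_open_volume(), rel_tol=1e-10):
        raise GridError("grid volume does not match the device volume")
    return grid
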