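"""Run configuration: schema validation, unit conversion, orchestration.

A run config is one YAML document naming an analyte, a coating, a device
(kind + retraction depth Z + optional geometry overrides), a boundary
concentration program, and solver/resolution settings.  Dimensioned
values carry unit tags ("10 mm", "0.641 umol/m3"); bare numbers are SI.

``sweep`` configs are the same document with list values for ``analyte``,
``coating``, ``device.kind`` or ``device.Z``; they expand to the cartesian
product of runs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .geometry import DeviceGeometry, GridResolution, build_device
from .materials import Analyte, CoatingSpec, get_analyte, get_coating
from .scenarios import ConcentrationProgram, coating_profile, profile_metrics
from .solver import SolverSettings, simulate
from .units import parse_quantity

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "build_run",
    "expand_sweep",
    "run_from_config",
    "preset_names",
    "preset_path",
]


class ConfigError(ValueError):
    """Schema violation; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field {field!r}: {message}")


_SWEEPABLE = ("analyte", "coating", "device.kind", "device.Z")

_GEOM_LENGTH_OVERRIDES = (
    "coating_length",
    "rear_gap_length",
    "bore_radius",
    "tube_length",
    "fiber_core_radius",
    "coating_outer_radius",
    "narrow_radius",
    "narrow_standoff",
)


@dataclass
class RunConfig:
    """A fully resolved, SI-unit run description."""

    name: str
    analyte: Analyte
    coating: CoatingSpec
    device: DeviceGeometry
    program: ConcentrationProgram
    settings: SolverSettings
    resolution: GridResolution
    t_end: float


def load_config(path) -> dict:
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError("<document>", f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("<document>", "config must be a mapping")
    doc.setdefault("name", path.stem)
    return doc


def _require(doc: dict, field: str, parent: str = ""):
    key = f"{parent}{field}"
    if field not in doc or doc[field] is None:
        raise ConfigError(key, "missing required field")
    return doc[field]


def _analyte_from(value) -> Analyte:
    if isinstance(value, dict):
        try:
            return Analyte(
                name=value["name"],
                D_air=parse_quantity(value["D_air"], "diffusivity"),
                molar_mass=float(value["molar_mass"]),
            )
        except KeyError as exc:
            raise ConfigError(f"analyte.{exc.args[0]}", "missing") from exc
    try:
        return get_analyte(value)
    except Exception as exc:
        raise ConfigError("analyte", str(exc)) from exc


def _coating_from(value) -> CoatingSpec:
    if isinstance(value, dict):
        try:
            return CoatingSpec(**value)
        except Exception as exc:
            raise ConfigError("coating", str(exc)) from exc
    try:
        return get_coating(value)
    except Exception as exc:
        raise ConfigError("coating", str(exc)) from exc


def build_run(doc: dict) -> RunConfig:
    """Validate a config document and resolve it to SI-unit objects."""
    for field in _SWEEPABLE:
        node, _, leaf = field.rpartition(".")
        holder = doc.get("device", {}) if node == "device" else doc
        if isinstance(holder, dict) and isinstance(holder.get(leaf), list):
            raise ConfigError(field, "list values require the sweep command")

    analyte = _analyte_from(_require(doc, "analyte"))
    coating = _coating_from(_require(doc, "coating"))

    dev = _require(doc, "device")
    if not isinstance(dev, dict):
        raise ConfigError("device", "must be a mapping")
    kind = _require(dev, "kind", "device.")
    Z = parse_quantity(_require(dev, "Z", "device."), "length")
    overrides = {}
    for key in _GEOM_LENGTH_OVERRIDES:
        if key in dev:
            overrides[key] = parse_quantity(dev[key], "length")
    unknown = set(dev) - set(_GEOM_LENGTH_OVERRIDES) - {"kind", "Z"}
    if unknown:
        raise ConfigError(f"device.{sorted(unknown)[0]}", "unknown field")
    try:
        device = build_device(
            kind,
            Z,
            coating_outer_radius=overrides.pop(
                "coating_outer_radius", coating.outer_radius
            ),
            overrides=overrides,
        )
    except Exception as exc:
        raise ConfigError("device", str(exc)) from exc

    prog_doc = _require(doc, "program")
    if not isinstance(prog_doc, dict):
        raise ConfigError("program", "must be a mapping")

    def conc(v):
        return parse_quantity(v, "concentration", molar_mass=analyte.molar_mass)

    if "constant" in prog_doc:
        program = ConcentrationProgram.constant(conc(prog_doc["constant"]))
    elif "breakpoints" in prog_doc:
        pts = [
            (parse_quantity(t, "time"), conc(c)) for t, c in prog_doc["breakpoints"]
        ]
        program = ConcentrationProgram.from_breakpoints(pts)
    else:
        raise ConfigError("program", "needs 'constant' or 'breakpoints'")

    t_end = parse_quantity(_require(doc, "t_end"), "time")

    s = doc.get("solver") or {}
    try:
        settings = SolverSettings(
            dt_init=parse_quantity(s.get("dt_init", 1.0), "time"),
            dt_growth=float(s.get("dt_growth", 1.2)),
            dt_max=parse_quantity(s.get("dt_max", 250.0), "time"),
            output_interval=parse_quantity(s.get("output_interval", 1000.0), "time"),
            flux_coefficient=parse_quantity(s.get("flux_coefficient", 1000.0), "speed"),
            interface_mode=s.get("interface_mode", "penalty_flux"),
            scheme=s.get("scheme", "backward_euler"),
        )
    except ValueError as exc:
        raise ConfigError("solver", str(exc)) from exc

    r = doc.get("resolution") or {}
    try:
        resolution = GridResolution(
            n_radial_core=int(r.get("n_radial_core", 4)),
            n_radial_coating=int(r.get("n_radial_coating", 10)),
            radial_gap_cell=parse_quantity(r.get("radial_gap_cell", 30e-6), "length"),
            axial_cell_size=parse_quantity(r.get("axial_cell_size", 0.25e-3), "length"),
        )
    except ValueError as exc:
        raise ConfigError("resolution", str(exc)) from exc

    return RunConfig(
        name=str(doc.get("name", "run")),
        analyte=analyte,
        coating=coating,
        device=device,
        program=program,
        settings=settings,
        resolution=resolution,
        t_end=t_end,
    )


def expand_sweep(doc: dict) -> list[dict]:
    """Expand list-valued sweepable fields to the cartesian product of runs."""
    axes = []
    for field in _SWEEPABLE:
        node, _, leaf = field.rpartition(".")
        holder = doc.get("device", {}) if node == "device" else doc
        value = holder.get(leaf) if isinstance(holder, dict) else None
        if isinstance(value, list):
            axes.append((field, value))
    if not axes:
        return [dict(doc)]
    runs = []
    for combo in itertools.product(*(v for _, v in axes)):
        out = json.loads(json.dumps(doc))  # deep copy of plain YAML data
        tags = []
        for (field, _), value in zip(axes, combo):
            node, _, leaf = field.rpartition(".")
            (out["device"] if node == "device" else out)[leaf] = value
            tags.append(str(value).replace(" ", ""))
        out["name"] = "_".join([str(doc.get("name", "sweep"))] + tags)
        runs.append(out)
    return runs


def run_from_config(
    doc_or_path,
    outdir,
    *,
    t_end: float | None = None,
    resolution: GridResolution | None = None,
) -> dict:
    """Execute one run and write uptake.csv + summary.json to ``outdir``.

    Returns the summary dict.  ``t_end``/``resolution`` override the config
    (used for quick preset checks).
    """
    doc = doc_or_path if isinstance(doc_or_path, dict) else load_config(doc_or_path)
    cfg = build_run(doc)
    if t_end is not None:
        cfg.t_end = t_end
    if resolution is not None:
        cfg.resolution = resolution
    result = simulate(
        cfg.device,
        cfg.coating,
        cfg.analyte,
        cfg.program,
        cfg.settings,
        cfg.t_end,
        resolution=cfg.resolution,
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = result.series.to_frame()
    frame.to_csv(outdir / "uptake.csv", index=False, float_format="%.10e")
    final = result.series.at(cfg.t_end)
    profile = coating_profile(result.final_field, result.system)
    summary = {
        "name": cfg.name,
        "inputs": {
            "analyte": cfg.analyte.name,
            "coating": cfg.coating.name,
            "device_kind": cfg.device.kind,
            "Z_m": cfg.device.Z,
            "tube_length_m": cfg.device.tube_length,
            "coating_length_m": cfg.device.coating_length,
            "rear_gap_length_m": cfg.device.rear_gap_length,
            "opening_area_m2": cfg.device.opening_area,
            "t_end_s": cfg.t_end,
            "n_cells": result.system.n_unknowns,
        },
        "final": final,
        "profile": profile_metrics(profile),
        "mass_balance_residual": result.mass_balance_residual,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


# ---------------------------------------------------------------------------
# Shipped scenario presets


def preset_names() -> list[str]:
    root = resources.files("twaspme") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def preset_path(name: str) -> Path:
    p = resources.files("twaspme") / "presets" / f"{name}.yaml"
    if not p.is_file():
        raise ConfigError("preset", f"unknown preset {name!r}")
    return Path(str(p))
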