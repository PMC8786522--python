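"""Configuration loading, result serialization and run manifests.

Scenario files are YAML (JSON parses too) with a strict schema: unknown
keys are a hard error, every applied default is logged.  Lengths in the
file are millimetres for readability; the in-memory model is SI (metres).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .geometry import (
    BoundarySpec,
    ConfigurationError,
    LayerField,
    LayerMaterial,
    Schedule,
    ScenarioConfig,
    SharedConstants,
    build_grid,
)
from .steady import TemperatureField

__all__ = [
    "load_config",
    "load_preset",
    "list_presets",
    "config_to_dict",
    "config_hash",
    "write_results",
    "RunManifest",
]

log = logging.getLogger("bioheatfd")

_TOP_KEYS = {"name", "mode", "geometry", "layers", "materials", "shared",
             "boundaries", "schedule", "solver"}
_GEOMETRY_KEYS = {"depth_mm", "height_mm", "width_mm", "spacing_mm"}
_MATERIAL_KEYS = {"k", "rho", "c", "qm", "qm_inner", "split_fraction"}
_SHARED_KEYS = {"mb", "cb", "ta", "qe", "he", "tw"}
_BOUNDARY_KEYS = {"surface", "deep", "lateral", "robin_order"}
_SCHEDULE_KEYS = {"output_interval_s", "end_time_s", "reset_interval_s", "reset_action"}
_SOLVER_KEYS = {"initial_condition", "safety_factor"}


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    if not isinstance(block, dict):
        raise ConfigurationError(f"{where} must be a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def _require(block: dict, key: str, where: str):
    if key not in block:
        raise ConfigurationError(f"missing required key {key!r} in {where}")
    return block[key]


def _default(block: dict, key: str, value, where: str):
    if key in block:
        return block[key]
    log.info("config %s.%s defaulted to %r", where, key, value)
    return value


def config_from_dict(raw: dict, name_hint: str = "scenario") -> ScenarioConfig:
    _check_keys(raw, _TOP_KEYS, "top level")
    name = raw.get("name", name_hint)
    mode = _default(raw, "mode", "steady", "top level")

    geo = _require(raw, "geometry", "top level")
    _check_keys(geo, _GEOMETRY_KEYS, "geometry")
    h = float(_require(geo, "spacing_mm", "geometry")) * 1e-3
    grid = build_grid(
        float(_require(geo, "depth_mm", "geometry")) * 1e-3,
        float(_require(geo, "height_mm", "geometry")) * 1e-3,
        float(_require(geo, "width_mm", "geometry")) * 1e-3,
        h,
    )

    lay = _require(raw, "layers", "top level")
    if not isinstance(lay, dict) or not lay:
        raise ConfigurationError("layers must be a non-empty mapping of <name>_mm keys")
    names, thick = [], []
    for key, val in lay.items():
        if not key.endswith("_mm"):
            raise ConfigurationError(
                f"layer key {key!r} must end in '_mm' (thickness in millimetres)"
            )
        names.append(key[:-3])
        thick.append(float(val) * 1e-3)
    layers = LayerField(names=tuple(names), thicknesses=tuple(thick))

    mats_raw = _require(raw, "materials", "top level")
    _check_keys(mats_raw, set(names), "materials")
    materials = {}
    for lname, entry in mats_raw.items():
        _check_keys(entry, _MATERIAL_KEYS, f"materials.{lname}")
        materials[lname] = LayerMaterial(
            k=float(_require(entry, "k", f"materials.{lname}")),
            rho=float(_require(entry, "rho", f"materials.{lname}")),
            c=float(_require(entry, "c", f"materials.{lname}")),
            qm=float(_default(entry, "qm", 0.0, f"materials.{lname}")),
            qm_inner=(float(entry["qm_inner"]) if entry.get("qm_inner") is not None else None),
            split_fraction=float(_default(entry, "split_fraction", 0.5, f"materials.{lname}")),
        )

    sh = _require(raw, "shared", "top level")
    _check_keys(sh, _SHARED_KEYS, "shared")
    shared = SharedConstants(
        mb=float(_require(sh, "mb", "shared")),
        cb=float(_require(sh, "cb", "shared")),
        ta=float(_require(sh, "ta", "shared")),
        qe=float(_default(sh, "qe", 0.0, "shared")),
        he=float(_require(sh, "he", "shared")),
        tw=float(_require(sh, "tw", "shared")),
    )

    bd = raw.get("boundaries", {})
    _check_keys(bd, _BOUNDARY_KEYS, "boundaries")
    boundaries = BoundarySpec(
        surface=_default(bd, "surface", "robin", "boundaries"),
        deep=_default(bd, "deep", "dirichlet", "boundaries"),
        lateral=_default(bd, "lateral", "copy_face", "boundaries"),
        robin_order=int(_default(bd, "robin_order", 2, "boundaries")),
    )

    schedule = None
    if "schedule" in raw:
        sc = raw["schedule"]
        _check_keys(sc, _SCHEDULE_KEYS, "schedule")
        schedule = Schedule(
            output_interval_s=float(_default(sc, "output_interval_s", 120.0, "schedule")),
            end_time_s=float(_default(sc, "end_time_s", 360.0, "schedule")),
            reset_interval_s=float(_default(sc, "reset_interval_s", 120.0, "schedule")),
            reset_action=_default(sc, "reset_action", "clamp_surface_dirichlet", "schedule"),
        )

    sv = raw.get("solver", {})
    _check_keys(sv, _SOLVER_KEYS, "solver")
    return ScenarioConfig(
        grid=grid,
        layers=layers,
        materials=materials,
        shared=shared,
        boundaries=boundaries,
        mode=mode,
        schedule=schedule,
        initial_condition=_default(sv, "initial_condition", "linear_depth", "solver"),
        safety_factor=float(_default(sv, "safety_factor", 0.9, "solver")),
        name=name,
    )


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario file (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return config_from_dict(raw, name_hint=path.stem)


def _presets_dir() -> Path:
    return Path(str(resources.files("bioheatfd").joinpath("data/presets")))


def list_presets() -> list[str]:
    return sorted(p.stem for p in _presets_dir().glob("*.yaml"))


def load_preset(name: str) -> ScenarioConfig:
    """Load a shipped scenario preset (see :func:`list_presets`)."""
    path = _presets_dir() / f"{name}.yaml"
    if not path.exists():
        raise LookupError(f"unknown preset {name!r}; available: {list_presets()}")
    return load_config(path)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def config_to_dict(cfg: ScenarioConfig) -> dict:
    """Canonical plain-dict form of a configuration (for hashing/manifests)."""
    d = {
        "name": cfg.name,
        "mode": cfg.mode,
        "geometry": {
            "h_m": cfg.grid.h, "nx": cfg.grid.nx, "ny": cfg.grid.ny, "nz": cfg.grid.nz,
        },
        "layers": {n: t for n, t in zip(cfg.layers.names, cfg.layers.thicknesses)},
        "materials": {n: asdict(m) for n, m in sorted(cfg.materials.items())},
        "shared": asdict(cfg.shared),
        "boundaries": asdict(cfg.boundaries),
        "schedule": asdict(cfg.schedule) if cfg.schedule else None,
        "solver": {
            "initial_condition": cfg.initial_condition,
            "safety_factor": cfg.safety_factor,
        },
    }
    return d


def config_hash(cfg: ScenarioConfig) -> str:
    payload = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _table_order_key(grid, i, j, k):
    return (i, abs(j) + abs(k), max(abs(j), abs(k)), -j, -k)


def fields_to_long_frame(fields: list[TemperatureField], cfg: ScenarioConfig) -> pd.DataFrame:
    frames = [f.to_frame(cfg) for f in fields]
    return pd.concat(frames, ignore_index=True)


def fields_to_table_frame(fields: list[TemperatureField], cfg: ScenarioConfig) -> pd.DataFrame:
    """Table-style layout: one row per node, ordered centre-out per depth
    plane; transient captures become one column per reading time."""
    g = cfg.grid
    nodes = sorted(g.iter_nodes(), key=lambda n: _table_order_key(g, *n))
    recs = []
    for i, j, k in nodes:
        rec = {"i": i, "j": j, "k": k}
        if len(fields) == 1 and fields[0].time is None:
            rec["T"] = fields[0].at(i, j, k)
        else:
            for f in fields:
                label = f"T_{f.time / 60:g}min" if f.time is not None else "T"
                rec[label] = f.at(i, j, k)
        recs.append(rec)
    return pd.DataFrame.from_records(recs)


def write_results(
    fields: TemperatureField | list[TemperatureField],
    layout: str,
    path: str | Path,
    cfg: ScenarioConfig,
) -> dict:
    """Write captured field(s) as CSV.

    ``layout='long'`` gives one row per (time,) node with coordinates and
    full-precision temperatures; ``layout='table'`` mirrors the published
    table grouping with 2-decimal temperatures.  Returns a manifest entry.
    """
    if isinstance(fields, TemperatureField):
        fields = [fields]
    if not fields:
        raise ValueError("refusing to write an empty field list")
    path = Path(path)
    if layout == "long":
        df = fields_to_long_frame(fields, cfg)
        df.to_csv(path, index=False)
    elif layout == "table":
        df = fields_to_table_frame(fields, cfg)
        df.to_csv(path, index=False, float_format="%.2f")
    else:
        raise ConfigurationError(f"unknown layout {layout!r}")
    return {"path": str(path), "layout": layout, "rows": int(len(df))}


@dataclass
class RunManifest:
    """Provenance record written beside every set of result files."""

    scenario: str
    config_hash: str
    mode: str
    solver_settings: dict
    outputs: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def add_output(self, entry: dict) -> None:
        self.outputs.append(entry)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
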