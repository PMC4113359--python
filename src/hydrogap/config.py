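"""Configuration loading, validation and run outputs.

A single structured YAML config drives every run.  All physical constants
(psychrometric constant, latent heat, radiation conversion, the
Priestley-Taylor coefficient, ...) live in the config with site defaults,
so every otherwise under-specified constant is visible and overridable.
Species parameters and an optional stand inventory are referenced by file
path (tab-separated tables) and resolved relative to the config file.

Outputs are plain CSV with stable column schemas plus a machine-readable
JSON manifest (config echo, master seed, package version) from which a
run can be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from importlib.resources import files as _pkg_files
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .forest import SpeciesTable, load_species_table
from .hydrology import CanopyHydroParams, EnergyParams, SoilParams
from .simulate import SimulationConfig
from .weather import (SEASONS, ClimateParams, ScenarioSpec,
                      SeasonalClimateParams)

__all__ = ["ConfigError", "RunConfig", "load_config", "default_config_path",
           "demo_species_path", "demo_inventory_path", "write_outputs"]

log = logging.getLogger("hydrogap")


class ConfigError(ValueError):
    """A configuration field is missing, mistyped or out of range."""


_CLIMATE_KEYS = {
    "mean_interval", "mean_event_depth", "prescribed_rain",
    "temp_mu", "temp_sigma", "rg_mu_dry", "rg_sigma_dry",
    "rg_mu_wet", "rg_sigma_wet",
}

_PROTOCOL_DEFAULTS = {
    # (init_mode, years): young secondary succession vs old-growth
    # equilibrium protocols
    "YS": ("bare_ground", 60),
    "OG": ("inventory", 1000),
    "custom": (None, None),
}


def default_config_path() -> Path:
    return Path(str(_pkg_files("hydrogap.data") / "default_config.yaml"))


def demo_species_path() -> Path:
    return Path(str(_pkg_files("hydrogap.data") / "species_demo.tsv"))


def demo_inventory_path() -> Path:
    return Path(str(_pkg_files("hydrogap.data") / "inventory_demo.tsv"))


@dataclasses.dataclass
class RunConfig:
    """Validated top-level run configuration."""

    simulation: SimulationConfig
    protocol: str = "YS"
    out_dir: Path | None = None
    source_path: Path | None = None
    raw: dict = dataclasses.field(default_factory=dict)


def _build_dataclass(cls, block: Mapping[str, Any], name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        log.warning("%s: ignoring unknown fields %s", name, sorted(unknown))
    types = {f.name: f.type for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in block.items():
        if k not in fields:
            continue
        # YAML 1.1 reads scientific notation without a sign (2.56e6) as a
        # string; coerce numerics declared as float/int
        if isinstance(v, str) and types[k] in ("float", "int", float, int):
            try:
                v = float(v) if types[k] in ("float", float) else int(v)
            except ValueError:
                raise ConfigError(f"{name}.{k}: expected a number, got {v!r}")
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def _build_climate(block: Mapping[str, Any]) -> ClimateParams:
    seasons = {}
    for tag in SEASONS:
        if tag not in block:
            raise ConfigError(f"climate: missing season block {tag!r}")
        sub = dict(block[tag])
        unknown = set(sub) - _CLIMATE_KEYS
        if unknown:
            log.warning("climate.%s: ignoring unknown fields %s",
                        tag, sorted(unknown))
            for k in unknown:
                sub.pop(k)
        missing = _CLIMATE_KEYS - set(sub)
        if missing:
            raise ConfigError(f"climate.{tag}: missing fields {sorted(missing)}")
        try:
            seasons[tag] = SeasonalClimateParams(season=tag, **sub)
        except ValueError as exc:
            raise ConfigError(f"climate.{tag}: {exc}") from exc
    return ClimateParams(seasons)


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Every parameter block is type- and range-checked on load (the
    dataclass validators run before any simulation starts) and all
    resolved defaults are echoed to the ``hydrogap`` logger.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")

    protocol = raw.get("protocol", "YS")
    if protocol not in _PROTOCOL_DEFAULTS:
        raise ConfigError(
            f"protocol must be one of {sorted(_PROTOCOL_DEFAULTS)}")
    init_mode, proto_years = _PROTOCOL_DEFAULTS[protocol]

    soil = _build_dataclass(SoilParams, raw.get("soil", {}), "soil")
    canopy = _build_dataclass(CanopyHydroParams, raw.get("canopy", {}),
                              "canopy")
    energy = _build_dataclass(EnergyParams, raw.get("constants", {}),
                              "constants")
    if "climate" in raw:
        climate = _build_climate(raw["climate"])
    else:
        from .weather import default_climate
        climate = default_climate()
        log.info("climate: using built-in current-climate defaults")

    species_file = raw.get("species_file")
    species_path = (Path(species_file) if species_file
                    else demo_species_path())
    if not species_path.is_absolute() and species_file:
        species_path = path.parent / species_path
    if not species_path.exists():
        raise ConfigError(f"species_file not found: {species_path}")
    try:
        species = load_species_table(species_path)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    inventory = None
    inv_file = raw.get("inventory_file")
    if inv_file:
        inv_path = Path(inv_file)
        if not inv_path.is_absolute():
            inv_path = path.parent / inv_path
        if not inv_path.exists():
            raise ConfigError(f"inventory_file not found: {inv_path}")
        inventory = pd.read_csv(inv_path, sep="\t", comment="#")
        if "species_id" not in inventory or "dbh_cm" not in inventory:
            raise ConfigError(
                "inventory needs species_id and dbh_cm columns")

    scenario = None
    if "scenario" in raw and raw["scenario"]:
        sc = dict(raw["scenario"])
        if "warming" in sc:
            from .weather import WARMING_2100
            if sc.pop("warming"):
                sc["warming_offsets"] = dict(WARMING_2100)
        if "affected_seasons" in sc:
            sc["affected_seasons"] = tuple(sc["affected_seasons"])
        scenario = _build_dataclass(ScenarioSpec, sc, "scenario")

    years = raw.get("years", proto_years)
    if years is None:
        raise ConfigError("custom protocol requires explicit 'years'")
    if init_mode == "inventory" and inventory is None:
        raise ConfigError("OG protocol requires inventory_file")

    sim_kwargs: dict[str, Any] = dict(
        species=species,
        years=int(years),
        replicates=int(raw.get("replicates", 1)),
        seed=int(raw.get("seed", 0)),
        init_mode=init_mode or raw.get("init_mode", "bare_ground"),
        inventory=inventory,
        grid=tuple(raw.get("grid", (5, 5))),
        climate=climate,
        scenario=scenario,
        soil=soil,
        canopy=canopy,
        energy=energy,
        s0=float(raw.get("s0", 0.5)),
        hydrology_enabled=bool(raw.get("hydrology_enabled", True)),
        cap_interception_by_pet=bool(raw.get("cap_interception_by_pet", True)),
    )
    try:
        sim = SimulationConfig(**sim_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    for name, obj in (("soil", soil), ("canopy", canopy),
                      ("constants", energy)):
        log.info("resolved %s: %s", name, dataclasses.asdict(obj))
    log.info("resolved run: protocol=%s years=%s replicates=%s seed=%s "
             "grid=%s species=%s", protocol, sim.years, sim.replicates,
             sim.seed, sim.grid, species_path)

    out_dir = Path(raw["out_dir"]) if "out_dir" in raw else None
    return RunConfig(simulation=sim, protocol=protocol, out_dir=out_dir,
                     source_path=path, raw=raw)


def config_hash(raw: Mapping[str, Any]) -> str:
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_outputs(results: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  seed: int, raw_config: Mapping[str, Any] | None = None,
                  ) -> list[Path]:
    """Write result tables as CSV plus a reproducibility manifest.

    ``results`` maps a base filename (without extension) to a DataFrame.
    The manifest records the master seed, a config hash/echo and the
    package version; re-running from the same config and seed reproduces
    the outputs byte-identically.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    written = []
    for name, frame in results.items():
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    manifest = {
        "seed": int(seed),
        "version": __version__,
        "config_hash": config_hash(raw_config or {}),
        "config": dict(raw_config or {}),
        "files": [p.name for p in written],
        "columns": {name: list(frame.columns)
                    for name, frame in results.items()},
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(mp)
    return written
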