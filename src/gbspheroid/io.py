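"""Configuration, CSV schemas, and run manifests.

All tables are UTF-8 CSVs with explicit headers and units encoded in
column names (area_mm2, dt_h). Configs are YAML mappings validated
field-by-field before any run; every output directory receives a
manifest sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .estimation import (
    CELL_AREA_COLUMNS,
    CELL_COUNT_COLUMNS,
    SPHEROID_AREA_COLUMNS,
    DataError,
)
from .lattice import Phenotype
from .oxygen import OxygenParams
from .simulate import GrowthRecord, SimulationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "write_record",
    "read_cell_counts",
    "read_cell_areas",
    "read_spheroid_areas",
    "write_manifest",
]

_PathLike = Union[str, Path]


class ConfigError(ValueError):
    """Invalid configuration file; the message names the offending field."""


_SIM_FIELDS = {
    "L_mm": float,
    "cell_size_um": float,
    "tau_h": float,
    "duration_days": float,
    "initial_cells": int,
    "seed": int,
    "age_policy": str,
    "initial_age_mode": str,
    "area_metric": str,
}

_OXY_FIELDS = {
    "D_o_cm2_s": float,
    "alpha_o_nd": float,
    "gamma_o_M_cell_s": float,
    "o_max_M_cm3": float,
    "o_deadly": float,
    "kappa_star_override": float,
}


def config_to_dict(config: SimulationConfig) -> dict:
    d = {name: getattr(config, name) for name in _SIM_FIELDS}
    d["phenotypes"] = [
        {
            "id": p.id,
            "doubling_time_h": p.doubling_time_h,
            "proliferation_depth_r": p.proliferation_depth_r,
        }
        for p in config.phenotypes
    ]
    if config.frequencies is not None:
        d["frequencies"] = list(config.frequencies)
    d["oxygen"] = {
        name: getattr(config.oxygen, name)
        for name in _OXY_FIELDS
        if getattr(config.oxygen, name) is not None
    }
    return d


def _coerce(section: str, name: str, value, typ):
    try:
        return typ(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}.{name}: cannot read {value!r} as {typ.__name__}") from exc


def config_from_dict(data: dict) -> SimulationConfig:
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    known = set(_SIM_FIELDS) | {"phenotypes", "frequencies", "oxygen"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    kwargs = {}
    for name, typ in _SIM_FIELDS.items():
        if name in data:
            kwargs[name] = _coerce("config", name, data[name], typ)
    if "phenotypes" in data:
        phens = []
        for i, p in enumerate(data["phenotypes"]):
            if not isinstance(p, dict):
                raise ConfigError(f"phenotypes[{i}] must be a mapping")
            try:
                phens.append(
                    Phenotype(
                        id=_coerce(f"phenotypes[{i}]", "id", p.get("id", i), int),
                        doubling_time_h=_coerce(
                            f"phenotypes[{i}]", "doubling_time_h",
                            p["doubling_time_h"], float,
                        ),
                        proliferation_depth_r=_coerce(
                            f"phenotypes[{i}]", "proliferation_depth_r",
                            p.get("proliferation_depth_r", 2), int,
                        ),
                    )
                )
            except KeyError as exc:
                raise ConfigError(f"phenotypes[{i}]: missing field {exc}") from exc
            except ValueError as exc:
                raise ConfigError(f"phenotypes[{i}]: {exc}") from exc
        kwargs["phenotypes"] = tuple(phens)
    if "frequencies" in data and data["frequencies"] is not None:
        kwargs["frequencies"] = tuple(
            _coerce("frequencies", str(i), v, float)
            for i, v in enumerate(data["frequencies"])
        )
    if "oxygen" in data:
        oxy = data["oxygen"]
        if not isinstance(oxy, dict):
            raise ConfigError("oxygen must be a mapping")
        unknown = set(oxy) - set(_OXY_FIELDS)
        if unknown:
            raise ConfigError(f"unknown oxygen field(s): {sorted(unknown)}")
        okw = {
            name: _coerce("oxygen", name, oxy[name], typ)
            for name, typ in _OXY_FIELDS.items()
            if name in oxy and oxy[name] is not None
        }
        try:
            kwargs["oxygen"] = OxygenParams(**okw)
        except ValueError as exc:
            raise ConfigError(f"oxygen: {exc}") from exc
    try:
        return SimulationConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: _PathLike) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse YAML config {path}: {exc}") from exc
    return config_from_dict(data or {})


def save_config(config: SimulationConfig, path: _PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def write_record(record: GrowthRecord, path: _PathLike) -> None:
    record.to_frame().to_csv(path, index=False)


def _read_table(path: _PathLike, columns: list, name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise DataError(f"cannot read {name} CSV {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{name} CSV {path} missing column(s) {missing}")
    return df


def read_cell_counts(path: _PathLike) -> pd.DataFrame:
    """cell_counts.csv: line, day, count_per_ml."""
    return _read_table(path, CELL_COUNT_COLUMNS, "cell_counts")


def read_cell_areas(path: _PathLike) -> pd.DataFrame:
    """cell_areas.csv: line, cell_id, area_um2."""
    return _read_table(path, CELL_AREA_COLUMNS, "cell_areas")


def read_spheroid_areas(path: _PathLike) -> pd.DataFrame:
    """spheroid_areas.csv: line, day, replicate, area_mm2."""
    return _read_table(path, SPHEROID_AREA_COLUMNS, "spheroid_areas")


def write_manifest(
    out_dir: _PathLike,
    command: str,
    config: Optional[dict] = None,
    seed: Optional[int] = None,
    outputs: Optional[list] = None,
) -> Path:
    """Write run_manifest.json: command, resolved config, seed, outputs, version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "outputs": [str(o) for o in (outputs or [])],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "package_version": __version__,
    }
    path = out_dir / "run_manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("wrote manifest %s", path)
    return path
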