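"""Configuration files and run logs.

One documented dialect: INI key-value text read with :mod:`configparser`.
Sections used by the pipeline:

* ``[catchment]`` — ``area_km2`` plus one ``cover.<name>`` key per cover;
* ``[parameters]`` — ``<unit>.<parameter> = value`` and
  ``global.snow_temp_threshold``;
* ``[ranges]`` — ``<unit>.<parameter> = low, high`` sampling ranges;
* ``[thresholds]`` — ``q_low``, ``qdiff_all``, ``qdiff_dry``,
  ``percentile``, ``area_km2`` (L/s except the area).

Every CLI run writes a machine-readable JSON run log (seed, config hash,
package versions) next to its outputs.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import platform
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .buckets import GLOBAL_PARAM_FIELDS, UNIT_PARAM_FIELDS, ParameterSet, UnitParameters
from .events import ThresholdSpec
from .series import CatchmentSpec


def _read(path) -> configparser.ConfigParser:
    parser = configparser.ConfigParser()
    parser.optionxform = str  # keys are case-sensitive parameter names
    with open(path, encoding="utf-8") as fh:
        parser.read_file(fh)
    return parser


def read_catchment(path) -> CatchmentSpec:
    cfg = _read(path)["catchment"]
    covers = {
        key.removeprefix("cover."): float(value)
        for key, value in cfg.items()
        if key.startswith("cover.")
    }
    return CatchmentSpec(area_km2=float(cfg["area_km2"]), cover_fractions=covers)


def write_catchment(spec: CatchmentSpec, path) -> None:
    lines = ["[catchment]", f"area_km2 = {spec.area_km2!r}"]
    lines += [f"cover.{name} = {f!r}" for name, f in spec.cover_fractions.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_parameters(path) -> ParameterSet:
    cfg = _read(path)["parameters"]
    units: dict[str, dict[str, float]] = {}
    glob: dict[str, float] = {}
    for key, value in cfg.items():
        scope, param = key.split(".", 1)
        if scope == "global":
            glob[param] = float(value)
        else:
            units.setdefault(scope, {})[param] = float(value)
    return ParameterSet(
        units={u: UnitParameters(**kv) for u, kv in units.items()},
        **glob,
    )


def write_parameters(params: ParameterSet, path) -> None:
    lines = ["[parameters]"]
    for unit, up in params.units.items():
        lines += [f"{unit}.{f} = {getattr(up, f)!r}" for f in UNIT_PARAM_FIELDS]
    for f in GLOBAL_PARAM_FIELDS:
        lines.append(f"global.{f} = {getattr(params, f)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ranges(path) -> dict[str, tuple[float, float]]:
    cfg = _read(path)["ranges"]
    out: dict[str, tuple[float, float]] = {}
    for key, value in cfg.items():
        parts = [p.strip() for p in value.split(",")]
        if len(parts) != 2:
            raise ValueError(f"range for {key!r} must be 'low, high', got {value!r}")
        out[key] = (float(parts[0]), float(parts[1]))
    return out


def read_thresholds(path) -> ThresholdSpec:
    cfg = _read(path)["thresholds"]
    return ThresholdSpec(**{key: float(value) for key, value in cfg.items()})


def write_thresholds(spec: ThresholdSpec, path) -> None:
    lines = ["[thresholds]"]
    for f in ("q_low", "qdiff_all", "qdiff_dry", "percentile", "area_km2"):
        lines.append(f"{f} = {getattr(spec, f)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_run_log(out_dir, command: str, seed: int | None,
                  config_paths: list = ()) -> Path:
    """JSON run log: command, seed, config hashes, versions. Returns its path."""
    digest = {}
    for p in config_paths:
        p = Path(p)
        digest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    log = {
        "command": command,
        "seed": seed,
        "config_sha256": digest,
        "versions": {
            "newtflow": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "platform": platform.platform(),
        },
    }
    out = Path(out_dir) / f"runlog_{command}.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(log, indent=2) + "\n", encoding="utf-8")
    return out
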