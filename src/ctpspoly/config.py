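"""Strict TOML configuration and CSV table I/O.

A run configuration is a TOML document with a ``[params]`` block (the
thermodynamic constants), a ``[conditions]`` block, optional
command-specific blocks (grids, events, noise, seed, output), and a log
level.  Unknown keys are rejected; all defaults are materialized on
load so the echoed config fully specifies the run.

Units are fixed package-wide (μM, s, k_B·T) and named in CSV headers.
Tables are RFC-4180 CSV, UTF-8, '.' decimal.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import Event, EventScript
from .params import Conditions, ThermoParams

#: exact column schema for dose–response curve tables
CURVE_COLUMNS = ["mechanism", "swept", "x_uM", "y", "normalized"]

_PARAM_KEYS = {"K_uf", "K_cf", "K_cp", "K_e", "E_nuc", "k_max",
               "mechanism", "polymerizing"}
_CONDITION_KEYS = {"U", "C", "E_tot"}
_GRID_KEYS = {"E_grid", "C_grid", "E_grid_log10_range", "C_grid_log10_range",
              "n_points"}
_NOISE_KEYS = {"cv", "sd_abs", "seed"}
_ASSAY_KEYS = {"tau_poly", "horizon", "dt_out", "scatter_proxy"}
_FIT_KEYS = {"free", "n_restarts", "jitter_decades", "seed", "datasets"}
_ESTIMATE_KEYS = {"mean_len"}
_TOP_KEYS = {"params", "conditions", "grids", "noise", "assay", "events",
             "fit", "estimate", "log_level"}


class ConfigError(ValueError):
    """Malformed configuration: syntax, unknown key, or wrong type."""


@dataclass
class RunConfig:
    """A fully materialized run configuration."""

    params: ThermoParams
    conditions: Conditions
    grids: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    assay: dict = field(default_factory=dict)
    events: EventScript = field(default_factory=EventScript)
    fit: dict = field(default_factory=dict)
    estimate: dict = field(default_factory=dict)
    log_level: str = "INFO"


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{where}]: {sorted(unknown)}")


def _default_params() -> dict:
    from .estimation import default_params
    return default_params().to_dict()


def parse_config(doc: dict) -> RunConfig:
    """Materialize a parsed TOML mapping into a RunConfig."""
    _check_keys(doc, _TOP_KEYS, "top level")
    raw_params = dict(doc.get("params", {}))
    _check_keys(raw_params, _PARAM_KEYS, "params")
    merged = _default_params() | raw_params
    try:
        params = ThermoParams(**merged)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [params]: {exc}") from exc

    raw_cond = dict(doc.get("conditions", {}))
    _check_keys(raw_cond, _CONDITION_KEYS, "conditions")
    try:
        conditions = Conditions(**raw_cond)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [conditions]: {exc}") from exc

    grids = dict(doc.get("grids", {}))
    _check_keys(grids, _GRID_KEYS, "grids")
    noise = {"cv": 0.05, "sd_abs": 0.05, "seed": 0} | dict(doc.get("noise", {}))
    _check_keys(noise, _NOISE_KEYS, "noise")
    assay = {"tau_poly": 2.0, "horizon": 1200.0, "dt_out": 1.0,
             "scatter_proxy": "mass_x_length"} | dict(doc.get("assay", {}))
    _check_keys(assay, _ASSAY_KEYS, "assay")
    fit = {"free": ["E_nuc", "K_cf", "K_cp"], "n_restarts": 8,
           "jitter_decades": 1.0, "seed": 0, "datasets": []} | dict(doc.get("fit", {}))
    _check_keys(fit, _FIT_KEYS, "fit")
    estimate = dict(doc.get("estimate", {}))
    _check_keys(estimate, _ESTIMATE_KEYS, "estimate")

    raw_events = doc.get("events", [])
    if not isinstance(raw_events, list):
        raise ConfigError("[[events]] must be an array of tables")
    evs = []
    for i, e in enumerate(raw_events):
        _check_keys(dict(e), {"time", "kind", "magnitude"}, f"events[{i}]")
        try:
            evs.append(Event(time=float(e["time"]), kind=e["kind"],
                             magnitude=float(e.get("magnitude", 0.0))))
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"invalid events[{i}]: {exc}") from exc

    log_level = doc.get("log_level", "INFO")
    if log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        raise ConfigError(f"invalid log_level {log_level!r}")
    return RunConfig(params=params, conditions=conditions, grids=grids,
                     noise=noise, assay=assay, events=EventScript(tuple(evs)),
                     fit=fit, estimate=estimate, log_level=log_level)


def load_config(path) -> RunConfig:
    """Strictly parse a TOML run configuration from disk."""
    try:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"TOML syntax error in {path}: {exc}") from exc
    return parse_config(doc)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(float(v)) if isinstance(v, float) else str(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to TOML (the config echo)."""
    lines = [f"log_level = {_toml_value(cfg.log_level)}", ""]
    blocks = [
        ("params", cfg.params.to_dict()),
        ("conditions", cfg.conditions.to_dict()),
        ("grids", cfg.grids),
        ("noise", cfg.noise),
        ("assay", cfg.assay),
        ("fit", cfg.fit),
        ("estimate", cfg.estimate),
    ]
    for name, block in blocks:
        if not block:
            continue
        lines.append(f"[{name}]")
        for k, v in block.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    for e in cfg.events.events:
        lines += ["[[events]]", f"time = {_toml_value(e.time)}",
                  f"kind = {_toml_value(e.kind)}",
                  f"magnitude = {_toml_value(e.magnitude)}", ""]
    return "\n".join(lines)


def write_curve_csv(frame: pd.DataFrame, path) -> None:
    """Write a long-format curve table with the exact package schema."""
    out = frame.reindex(columns=CURVE_COLUMNS)
    out.to_csv(path, index=False)


def resolve_grid(grids: dict, which: str) -> np.ndarray:
    """Build a concentration grid from explicit points or a log10 range."""
    explicit = grids.get(f"{which}_grid")
    if explicit is not None:
        return np.asarray(explicit, dtype=float)
    rng = grids.get(f"{which}_grid_log10_range")
    n = int(grids.get("n_points", 40))
    if rng is not None:
        lo, hi = float(rng[0]), float(rng[1])
        return np.logspace(lo, hi, n)
    if which == "E":
        return np.geomspace(0.05, 10.0, n)
    return np.concatenate([[0.0], np.logspace(-1, 4, n - 1)])
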