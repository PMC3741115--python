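"""TOML configuration: one table per concern, unknown keys are an error."""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

from .params import GridSpec, ParameterError, SimulationParams, StabilityError
from .protocols import ProtocolSpec, get_protocol

__all__ = ["ConfigError", "load_config", "default_config_text"]


class ConfigError(ParameterError):
    """Invalid or inconsistent configuration file."""


_GRID_KEYS = {f.name for f in dataclasses.fields(GridSpec)}
_PHYSICS_KEYS = {f.name for f in dataclasses.fields(SimulationParams)} - {"grid"}
_PROTOCOL_KEYS = {f.name for f in dataclasses.fields(ProtocolSpec)}


def _check_keys(table: dict, allowed: set[str], section: str) -> None:
    unknown = set(table) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")


def load_config(path) -> tuple[SimulationParams, ProtocolSpec]:
    """Read a TOML config and return validated parameters and protocol.

    Sections ``[grid]``, ``[physics]`` and ``[protocol]`` are all optional;
    missing values fall back to the defaults.  A ``[protocol]`` table may
    either name a canned protocol (``name = "A"``) with field overrides, or
    define all fields itself.
    """
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    _check_keys(raw, {"grid", "physics", "protocol"}, "top level")

    grid_tbl = dict(raw.get("grid", {}))
    _check_keys(grid_tbl, _GRID_KEYS, "grid")
    if "shape" in grid_tbl:
        grid_tbl["shape"] = tuple(grid_tbl["shape"])
    try:
        grid = GridSpec(**grid_tbl)

        phys = dict(raw.get("physics", {}))
        _check_keys(phys, _PHYSICS_KEYS, "physics")
        params = SimulationParams(grid=grid, **phys)

        proto_tbl = dict(raw.get("protocol", {}))
        _check_keys(proto_tbl, _PROTOCOL_KEYS | {"name"}, "protocol")
        name = proto_tbl.pop("name", "A")
        protocol = get_protocol(name, **proto_tbl) if name.upper() in "ABCDE" \
            else ProtocolSpec(name=name, **proto_tbl)
    except (ConfigError, StabilityError):
        raise
    except (ParameterError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return params, protocol


def default_config_text() -> str:
    """A complete config with every key at its default value."""
    return """\
# dopadiff simulation configuration (all values shown are the defaults)

[grid]
shape = [64, 64, 64]       # voxels per axis (1 voxel = 1 um^3)
spacing = 1.0              # um
boundary = "periodic"      # or "reflecting"

[physics]
site_density = 2.0e-4      # release sites per um^3 tissue
alpha = 0.23               # extracellular volume fraction
tortuosity = 1.54          # metadata; the engine uses d_eff directly
d_free = 763.0             # um^2/s
d_eff = 322.0              # um^2/s (= d_free / tortuosity^2)
vesicle_volume = 6.5e-20   # L
vesicle_conc = 0.25        # mol/L
quantal_moles = 1.625e-20  # mol per release event
f_tonic = 5.6              # Hz
f_phasic = 15.0            # Hz
pause_rate = 0.0           # Hz
release_prob = 0.5
uptake_rate = 1.5          # 1/s
kd_high = 10.0             # nM
kd_low = 1500.0            # nM
dt = 5.0e-4                # s
seed = 0

[protocol]
name = "A"                 # canned protocols A-E; fields below override
phasic_fraction = 0.5
"""
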