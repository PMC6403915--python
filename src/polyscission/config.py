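"""YAML configuration: model parameters, grid and run options.

Unspecified keys take the reference film defaults (55 um film, lactic
acid repeating unit 90.08 g mol^-1, density 1.2 g cm^-3, pristine
diffusivities 1e-10 / 1e-10 / 1e-8 cm^2 s^-1 for monomer / oligomer /
water).  Unknown keys are an error — no silent typos.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml

from .kinetics import ModelParams
from .solver import GridSpec

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The configuration file is malformed or contains unknown keys."""


PARAM_KEYS = ("kd", "DM0", "Dolig0", "DW0", "Mmon", "rho_pol",
              "CW_surface", "Mn_ref")
GRID_KEYS = ("film_thickness_um", "n_nodes")
OPTION_KEYS = ("rtol", "method", "sealed", "fixed_cw", "well_mixed")


def load_config(path=None):
    """Load a YAML config; returns ``(ModelParams, GridSpec, options)``.

    ``path=None`` (or an empty file) yields all defaults.  The resolved
    parameter set is logged.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(
                f"config must be a mapping, got {type(loaded).__name__}")
        raw = loaded

    unknown = sorted(set(raw) - set(PARAM_KEYS) - set(GRID_KEYS)
                     - set(OPTION_KEYS))
    if unknown:
        raise ConfigError(
            f"unknown config keys: {unknown}; allowed keys are "
            f"{sorted(PARAM_KEYS + GRID_KEYS + OPTION_KEYS)}")

    try:
        params = ModelParams(**{k: raw[k] for k in PARAM_KEYS if k in raw})
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid model parameters: {exc}") from exc

    grid_kwargs = {}
    if "film_thickness_um" in raw:
        thickness = raw["film_thickness_um"]
        if not isinstance(thickness, (int, float)) or thickness <= 0:
            raise ConfigError(
                f"film_thickness_um must be > 0, got {thickness!r}")
        # half-film domain, um -> cm
        grid_kwargs["half_thickness"] = thickness / 2.0 * 1e-4
    if "n_nodes" in raw:
        grid_kwargs["n_nodes"] = raw["n_nodes"]
    try:
        grid = GridSpec(**grid_kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid grid specification: {exc}") from exc

    options = {k: raw[k] for k in OPTION_KEYS if k in raw}
    logger.info("resolved config: params=%s grid=%s options=%s",
                params, grid, options)
    return params, grid, options


def config_echo(params: ModelParams, grid: GridSpec, options: dict,
                version: str) -> str:
    """Plain-text echo of the fully resolved configuration."""
    lines = [f"polyscission {version}", "[params]"]
    lines += [f"{k} = {getattr(params, k)!r}" for k in PARAM_KEYS]
    lines += ["[grid]",
              f"half_thickness_cm = {grid.half_thickness!r}",
              f"n_nodes = {grid.n_nodes}",
              "[options]"]
    lines += [f"{k} = {v!r}" for k, v in sorted(options.items())]
    return "\n".join(lines) + "\n"
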