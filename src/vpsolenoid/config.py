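"""Run configuration: one YAML file fully determines a run.

The schema mirrors the pipeline: ``coil`` (the solenoid design), ``roi``
(where metrics are evaluated), ``solver`` (B1 proxy, engine), ``profile``
(axis sampling), ``optimize`` (grids and selection rule) and ``output``
(formats).  Unknown keys are rejected with their full path so typos fail
loudly; every run writes the fully resolved configuration next to its
outputs so the sweep is reproducible from the output directory alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .geometry import SolenoidSpec
from .metrics import RoiSpec
from .optimize import DEFAULT_RULE
from .solver import B1_PROXIES

__all__ = ["RunConfig", "ConfigError", "load_config", "resolved_dict", "dump_config"]


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


_SCHEMA: dict[str, tuple[str, ...]] = {
    "coil": (
        "winding_diameter_mm",
        "n_turns",
        "winding_length_mm",
        "alpha_deg",
        "beta_deg",
        "current_A",
        "segments_per_turn",
    ),
    "roi": ("radius_mm", "z_half_extent_mm", "grid_spacing_mm"),
    "solver": ("b1_proxy", "engine"),
    "profile": ("n_samples",),
    "optimize": ("alpha_values", "beta_values", "selection_rule"),
    "output": ("formats",),
}

_REQUIRED_SECTIONS = ("coil",)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one run."""

    coil: SolenoidSpec = SolenoidSpec()
    roi: RoiSpec = RoiSpec()
    b1_proxy: str = "magnitude"
    engine: str = "auto"
    profile_n_samples: int = 57
    alpha_values: tuple[float, ...] = tuple(np.arange(0.0, 181.0, 10.0))
    beta_values: tuple[float, ...] = tuple(np.arange(0.0, 181.0, 10.0))
    selection_rule: str = DEFAULT_RULE
    output_formats: tuple[str, ...] = ("csv",)
    overrides: tuple[str, ...] = ()  # CLI overrides applied, for provenance

    def __post_init__(self) -> None:
        if self.b1_proxy not in B1_PROXIES:
            raise ConfigError(
                f"solver.b1_proxy must be one of {B1_PROXIES}, got {self.b1_proxy!r}"
            )
        if self.engine not in ("auto", "numba", "numpy"):
            raise ConfigError(f"solver.engine invalid: {self.engine!r}")
        if self.profile_n_samples < 3 or self.profile_n_samples % 2 == 0:
            raise ConfigError("profile.n_samples must be odd and >= 3")
        bad = set(self.output_formats) - {"csv", "nifti"}
        if bad:
            raise ConfigError(f"output.formats entries not recognised: {sorted(bad)}")


def _check_keys(data: Mapping[str, Any], source: str) -> None:
    unknown = set(data) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"{source}: unknown section(s) {sorted(unknown)}")
    for sec in _REQUIRED_SECTIONS:
        if sec not in data:
            raise ConfigError(f"{source}: missing required section '{sec}'")
    for sec, keys in _SCHEMA.items():
        sub = data.get(sec, {})
        if not isinstance(sub, Mapping):
            raise ConfigError(f"{source}: section '{sec}' must be a mapping")
        extra = set(sub) - set(keys)
        if extra:
            raise ConfigError(
                f"{source}: unknown key(s) {sorted(f'{sec}.{k}' for k in extra)}"
            )


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus flat overrides.

    ``overrides`` uses dotted keys (``"coil.alpha_deg"``); with
    ``path=None`` only defaults and overrides apply.  Raises
    :class:`ConfigError` before anything is written anywhere.
    """
    data: dict[str, Any] = {}
    source = "<defaults>"
    if path is not None:
        source = str(path)
        try:
            loaded = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"{source}: not valid YAML ({exc})") from exc
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"{source}: top level must be a mapping")
        data = {k: dict(v) if isinstance(v, Mapping) else v for k, v in loaded.items()}
        _check_keys(data, source)

    applied = []
    for dotted, value in (overrides or {}).items():
        if value is None:
            continue
        sec, _, key = dotted.partition(".")
        if sec not in _SCHEMA or key not in _SCHEMA[sec]:
            raise ConfigError(f"unknown override key {dotted!r}")
        data.setdefault(sec, {})[key] = value
        applied.append(f"{dotted}={value}")

    def get(sec: str, key: str, default):
        return data.get(sec, {}).get(key, default)

    try:
        coil = SolenoidSpec(
            winding_diameter_mm=float(get("coil", "winding_diameter_mm", 34.0)),
            n_turns=float(get("coil", "n_turns", 3.0)),
            winding_length_mm=float(get("coil", "winding_length_mm", 56.0)),
            alpha_deg=float(get("coil", "alpha_deg", 0.0)),
            beta_deg=float(get("coil", "beta_deg", 0.0)),
            current_a=float(get("coil", "current_A", 1.0)),
            segments_per_turn=int(get("coil", "segments_per_turn", 360)),
        )
        roi = RoiSpec(
            radius_mm=float(get("roi", "radius_mm", 14.0)),
            z_half_extent_mm=float(get("roi", "z_half_extent_mm", 28.0)),
            grid_spacing_mm=float(get("roi", "grid_spacing_mm", 1.0)),
        )
        defaults = RunConfig.__dataclass_fields__
        return RunConfig(
            coil=coil,
            roi=roi,
            b1_proxy=str(get("solver", "b1_proxy", "magnitude")),
            engine=str(get("solver", "engine", "auto")),
            profile_n_samples=int(get("profile", "n_samples", 57)),
            alpha_values=tuple(
                float(v)
                for v in get("optimize", "alpha_values", defaults["alpha_values"].default)
            ),
            beta_values=tuple(
                float(v)
                for v in get("optimize", "beta_values", defaults["beta_values"].default)
            ),
            selection_rule=str(get("optimize", "selection_rule", DEFAULT_RULE)),
            output_formats=tuple(get("output", "formats", ("csv",))),
            overrides=tuple(applied),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"{source}: {exc}") from exc


def resolved_dict(cfg: RunConfig) -> dict[str, Any]:
    """The fully resolved configuration as a plain nested dict."""
    return {
        "coil": {
            "winding_diameter_mm": cfg.coil.winding_diameter_mm,
            "n_turns": cfg.coil.n_turns,
            "winding_length_mm": cfg.coil.winding_length_mm,
            "alpha_deg": cfg.coil.alpha_deg,
            "beta_deg": cfg.coil.beta_deg,
            "current_A": cfg.coil.current_a,
            "segments_per_turn": cfg.coil.segments_per_turn,
        },
        "roi": {
            "radius_mm": cfg.roi.radius_mm,
            "z_half_extent_mm": cfg.roi.z_half_extent_mm,
            "grid_spacing_mm": cfg.roi.grid_spacing_mm,
        },
        "solver": {"b1_proxy": cfg.b1_proxy, "engine": cfg.engine},
        "profile": {"n_samples": cfg.profile_n_samples},
        "optimize": {
            "alpha_values": list(cfg.alpha_values),
            "beta_values": list(cfg.beta_values),
            "selection_rule": cfg.selection_rule,
        },
        "output": {"formats": list(cfg.output_formats)},
        "overrides": list(cfg.overrides),
    }


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration as YAML."""
    Path(path).write_text(
        yaml.safe_dump(resolved_dict(cfg), sort_keys=True, default_flow_style=None)
    )
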