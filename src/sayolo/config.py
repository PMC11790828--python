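"""YAML config loading, defaulting and range validation for the CLI.

Precedence is flags > config file > documented defaults.  Validation
reports every violated bound together with the admissible range (e.g.
a loss ``ratio`` of 2.0 is rejected naming the bound [0.5, 1.5]).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import yaml

from .isd_loss import ConfigError, ISDConfig
from .simulate import LOSS_NAMES, PhantomSpec, SimConfig

__all__ = ["ConfigError", "RunConfig", "validate_config", "load_yaml", "dump_yaml"]


@dataclass
class RunConfig:
    """Resolved, range-checked parameters for one CLI run."""

    loss: ISDConfig = field(default_factory=ISDConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    phantoms: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def to_mapping(self) -> dict[str, Any]:
        out = {
            "loss": asdict(self.loss),
            "sim": asdict(self.sim),
            "phantoms": asdict(self.phantoms),
            "seed": self.seed,
        }
        out["sim"]["isd"] = asdict(self.sim.isd)
        return out


_LOSS_KEYS = {"ratio", "k", "theta", "s", "shape_weight_pairing"}
_SIM_KEYS = {
    "n_targets",
    "n_anchors_per_target",
    "anchor_scatter_radius",
    "aspect_ratios",
    "scales",
    "steps",
    "step_size",
    "loss_names",
    "seed",
    "target_size",
    "grid_spacing",
}
_PHANTOM_KEYS = {
    "image_size",
    "n_images",
    "classes",
    "max_ellipses",
    "background",
    "intensity",
    "noise_sigma",
    "seed",
}


def _section(raw: Mapping[str, Any], name: str, allowed: set[str]) -> dict[str, Any]:
    sect = raw.get(name, {}) or {}
    if not isinstance(sect, Mapping):
        raise ConfigError(f"config section {name!r} must be a mapping")
    unknown = set(sect) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in config section {name!r}: {sorted(unknown)}"
        )
    return dict(sect)


def validate_config(raw: Mapping[str, Any] | None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Normalize, default and range-check a raw config mapping.

    ``overrides`` (typically CLI flags, keyed ``section.key``) take
    precedence over the file values.  An empty mapping yields all
    documented defaults.  Violated bounds raise :class:`ConfigError`
    naming the offending key and the admissible range.
    """
    raw = dict(raw or {})
    known_sections = {"loss", "sim", "phantoms", "seed"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    loss_kw = _section(raw, "loss", _LOSS_KEYS)
    sim_kw = _section(raw, "sim", _SIM_KEYS)
    ph_kw = _section(raw, "phantoms", _PHANTOM_KEYS)
    seed = raw.get("seed", 0)

    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key == "seed":
            seed = value
            continue
        section, _, subkey = key.partition(".")
        target = {"loss": loss_kw, "sim": sim_kw, "phantoms": ph_kw}.get(section)
        if target is None or not subkey:
            raise ConfigError(f"unknown override {key!r}")
        target[subkey] = value

    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")

    try:
        loss = ISDConfig(**loss_kw)
    except ConfigError:
        raise
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc

    sim_kw.setdefault("seed", seed)
    for tuple_key in ("aspect_ratios", "scales", "loss_names"):
        if tuple_key in sim_kw:
            sim_kw[tuple_key] = tuple(sim_kw[tuple_key])
    ph_kw.setdefault("seed", seed)
    if "classes" in ph_kw:
        ph_kw["classes"] = tuple(ph_kw["classes"])
    try:
        sim = SimConfig(isd=loss, **sim_kw)
        phantoms = PhantomSpec(**ph_kw)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    unknown_losses = set(sim.loss_names) - set(LOSS_NAMES)
    if unknown_losses:
        raise ConfigError(f"unknown loss names {sorted(unknown_losses)}")
    return RunConfig(loss=loss, sim=sim, phantoms=phantoms, seed=seed)


def load_yaml(path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return data


def dump_yaml(path, cfg: RunConfig) -> None:
    """Serialize the fully resolved config next to a run's outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_mapping(), fh, sort_keys=True)
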