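"""Structured experiment configuration (YAML) with a strict schema.

A single configuration file describes one experiment: the thermal regime,
the fixed demographic TPCs, optional resident/mutant shapes, numerical
controls for invasion-fitness averaging and canonical-equation
integration, and an optional (sigma_eps, omega) sweep.  Unknown keys are
rejected so that misspelled parameters cannot silently skew results, and
``save(load(f))`` round-trips structurally.

A ``preset:`` key expands to one of the named reference regimes of
:func:`thermoevo.experiments.preset`; any further keys override the
expanded values.

The sine frequency ``omega`` may be written as a float (radians per step)
or as a multiple of pi in string form: ``"pi"``, ``"2pi"``, ``"pi/20"``,
``"13pi/20"``.  It is stored canonically as float radians.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
import re
from dataclasses import dataclass
from typing import Any, Optional

import yaml

from .adaptive import CanonicalConfig
from .competition_tpc import TPCShape
from .demography import CapacityParams, DemographyParams, GrowthParams
from .experiments import SweepSpec
from .invasion import InvasionConfig
from .thermal_env import ThermalRegime

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "parse_omega",
    "load_config",
    "save_config",
    "config_hash",
]


class ConfigError(ValueError):
    """A configuration file violates the schema."""


_PI_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)?\s*\*?\s*pi\s*(?:/\s*(\d+(?:\.\d+)?))?\s*$")


def parse_omega(value: Any) -> float:
    """Parse omega given as a float or a 'pi' string like ``"13pi/20"``."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        m = _PI_RE.match(value)
        if m:
            coef = float(m.group(1)) if m.group(1) else 1.0
            den = float(m.group(2)) if m.group(2) else 1.0
            return coef * math.pi / den
        try:
            return float(value)
        except ValueError:
            pass
    raise ConfigError(
        f"cannot parse omega={value!r}; expected a float or a string like '13pi/20'"
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated, fully-expanded experiment description."""

    thermal: ThermalRegime = ThermalRegime()
    growth: GrowthParams = GrowthParams()
    capacity: CapacityParams = CapacityParams()
    resident: Optional[TPCShape] = None
    mutant: Optional[TPCShape] = None
    invasion: InvasionConfig = InvasionConfig()
    canonical: CanonicalConfig = CanonicalConfig()
    sweep: Optional[SweepSpec] = None
    output_dir: str = "results"
    log_level: str = "INFO"

    @property
    def demography(self) -> DemographyParams:
        return DemographyParams(growth=self.growth, capacity=self.capacity)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "thermal": dataclasses.asdict(self.thermal),
            "growth": dataclasses.asdict(self.growth),
            "capacity": dataclasses.asdict(self.capacity),
            "invasion": dataclasses.asdict(self.invasion),
            "canonical": {
                "E": [list(row) for row in self.canonical.E],
                "step_eta": self.canonical.step_eta,
                "max_iters": self.canonical.max_iters,
                "grad_tol": self.canonical.grad_tol,
            },
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }
        if self.resident is not None:
            d["resident"] = dataclasses.asdict(self.resident)
        if self.mutant is not None:
            d["mutant"] = dataclasses.asdict(self.mutant)
        if self.sweep is not None:
            d["sweep"] = {
                "sigma_eps_grid": list(self.sweep.sigma_eps_grid),
                "omega_grid": list(self.sweep.omega_grid),
                "m": self.sweep.m,
                "tau0": self.sweep.tau0,
                "master_seed": self.sweep.master_seed,
                "continuation": self.sweep.continuation,
                "horizon_L": self.sweep.inv_cfg.horizon_L,
                "burn_in": self.sweep.inv_cfg.burn_in,
            }
        return d


def _build(cls, data: dict, section: str, transforms: dict | None = None):
    if not isinstance(data, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )
    kwargs = dict(data)
    for key, fn in (transforms or {}).items():
        if key in kwargs:
            kwargs[key] = fn(kwargs[key])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


_TOP_KEYS = {
    "preset", "thermal", "growth", "capacity", "resident", "mutant",
    "invasion", "canonical", "sweep", "output_dir", "log_level",
}


def _from_mapping(raw: dict) -> ExperimentConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}"
        )
    if "preset" in raw:
        from .experiments import preset

        base = preset(raw["preset"])
        base_dict = base.to_dict()
        for key, value in raw.items():
            if key == "preset":
                continue
            if isinstance(value, dict) and isinstance(base_dict.get(key), dict):
                base_dict[key] = {**base_dict[key], **value}
            else:
                base_dict[key] = value
        raw = base_dict

    thermal = _build(
        ThermalRegime, raw.get("thermal", {}), "thermal", {"omega": parse_omega}
    )
    growth = _build(GrowthParams, raw.get("growth", {}), "growth")
    capacity = _build(CapacityParams, raw.get("capacity", {}), "capacity")
    invasion = _build(InvasionConfig, raw.get("invasion", {}), "invasion")
    canonical = _build(
        CanonicalConfig,
        raw.get("canonical", {}),
        "canonical",
        {"E": lambda rows: tuple(tuple(float(v) for v in row) for row in rows)},
    )
    resident = (
        _build(TPCShape, raw["resident"], "resident") if raw.get("resident") else None
    )
    mutant = _build(TPCShape, raw["mutant"], "mutant") if raw.get("mutant") else None

    sweep = None
    if raw.get("sweep"):
        sdata = dict(raw["sweep"])
        allowed = {
            "sigma_eps_grid", "omega_grid", "m", "tau0",
            "master_seed", "continuation", "horizon_L", "burn_in",
        }
        unknown = set(sdata) - allowed
        if unknown:
            raise ConfigError(
                f"unknown key(s) {sorted(unknown)} in section 'sweep'; "
                f"allowed: {sorted(allowed)}"
            )
        inv_cfg = InvasionConfig(
            horizon_L=int(sdata.pop("horizon_L", 20_000)),
            burn_in=int(sdata.pop("burn_in", 1000)),
            fd_step=invasion.fd_step,
            noise_seed=invasion.noise_seed,
        )
        try:
            sweep = SweepSpec(
                sigma_eps_grid=tuple(float(v) for v in sdata.pop("sigma_eps_grid")),
                omega_grid=tuple(parse_omega(v) for v in sdata.pop("omega_grid")),
                params=DemographyParams(growth=growth, capacity=capacity),
                inv_cfg=inv_cfg,
                can_cfg=canonical,
                **sdata,
            )
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigError(f"invalid section 'sweep': {exc}") from exc

    return ExperimentConfig(
        thermal=thermal,
        growth=growth,
        capacity=capacity,
        resident=resident,
        mutant=mutant,
        invasion=invasion,
        canonical=canonical,
        sweep=sweep,
        output_dir=str(raw.get("output_dir", "results")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return _from_mapping(raw)


def save_config(cfg: ExperimentConfig, path) -> None:
    """Write a configuration back to YAML (canonical float omega)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable SHA-256 digest of the canonical serialized configuration."""
    payload = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
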