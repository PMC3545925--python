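"""Run configuration: YAML parsing, validation and round-tripping.

With no file (or an empty one) the configuration reproduces the full default
experiment: published cohort parameters and risk coefficients for both sexes,
500 replications per scenario, the factorial ICC grid and the 0.5-step bias
sweeps.  Biases are configured in the units the study quotes (cm for height,
kg for weight) and converted to SI at the boundary.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .cohort import DEFAULT_COHORTS, CohortParameters
from .engine import GridSpecification
from .risk_model import DEFAULT_COEFFICIENTS, RiskCoefficients

__all__ = ["ConfigError", "RunConfiguration", "parse_config", "serialize_config"]


class ConfigError(ValueError):
    """Malformed or out-of-range configuration."""


_GRID_KEYS = {
    "sexes",
    "icc_grid",
    "bias_height_grid_cm",
    "bias_weight_grid_kg",
    "joint_icc_levels",
    "n_reps",
    "base_seed",
}
_TOP_KEYS = _GRID_KEYS | {"out_dir", "verbosity", "cohorts", "coefficients"}
_COHORT_KEYS = {
    "mean_height",
    "sd_height",
    "mean_weight",
    "sd_weight",
    "r_hw",
    "n",
    "reference_incidence",
}
_COEFF_KEYS = {"beta0", "beta1", "beta2"}


@dataclass(frozen=True)
class RunConfiguration:
    grid: GridSpecification = field(default_factory=GridSpecification)
    cohorts: dict[str, CohortParameters] = field(
        default_factory=lambda: dict(DEFAULT_COHORTS)
    )
    coefficients: dict[str, RiskCoefficients] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    out_dir: str = "results"
    verbosity: str = "info"


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown configuration key in {context}: {key!r}")


def parse_config(path: str | Path | None = None) -> RunConfiguration:
    """Load and validate a configuration file; ``None`` gives the defaults."""
    if path is None:
        return RunConfiguration()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed configuration file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    return _from_mapping(raw)


def _from_mapping(raw: dict) -> RunConfiguration:
    _check_keys(raw, _TOP_KEYS, "top level")

    grid_kwargs = {}
    for key in _GRID_KEYS & raw.keys():
        value = raw[key]
        if key in ("sexes", "icc_grid", "bias_height_grid_cm",
                   "bias_weight_grid_kg", "joint_icc_levels"):
            value = tuple(value)
        grid_kwargs[key] = value
    try:
        grid = GridSpecification(**grid_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    cohorts = dict(DEFAULT_COHORTS)
    for sex, overrides in (raw.get("cohorts") or {}).items():
        if sex not in cohorts:
            raise ConfigError(f"unknown sex in cohorts section: {sex!r}")
        _check_keys(overrides, _COHORT_KEYS, f"cohorts.{sex}")
        try:
            cohorts[sex] = replace(cohorts[sex], **overrides)
        except ValueError as exc:
            raise ConfigError(f"cohorts.{sex}: {exc}") from exc

    coefficients = dict(DEFAULT_COEFFICIENTS)
    for sex, overrides in (raw.get("coefficients") or {}).items():
        if sex not in coefficients:
            raise ConfigError(f"unknown sex in coefficients section: {sex!r}")
        _check_keys(overrides, _COEFF_KEYS, f"coefficients.{sex}")
        coefficients[sex] = replace(coefficients[sex], **overrides)

    for sex in grid.sexes:
        if sex not in cohorts:
            raise ConfigError(f"no cohort parameters for sex {sex!r}")

    return RunConfiguration(
        grid=grid,
        cohorts=cohorts,
        coefficients=coefficients,
        out_dir=str(raw.get("out_dir", "results")),
        verbosity=str(raw.get("verbosity", "info")),
    )


def serialize_config(config: RunConfiguration) -> str:
    """YAML representation that :func:`parse_config` reads back unchanged."""
    payload = {
        "sexes": list(config.grid.sexes),
        "icc_grid": list(config.grid.icc_grid),
        "bias_height_grid_cm": list(config.grid.bias_height_grid_cm),
        "bias_weight_grid_kg": list(config.grid.bias_weight_grid_kg),
        "joint_icc_levels": list(config.grid.joint_icc_levels),
        "n_reps": config.grid.n_reps,
        "base_seed": config.grid.base_seed,
        "out_dir": config.out_dir,
        "verbosity": config.verbosity,
        "cohorts": {
            sex: {k: v for k, v in asdict(params).items() if k != "sex"}
            for sex, params in config.cohorts.items()
        },
        "coefficients": {
            sex: {k: getattr(c, k) for k in ("beta0", "beta1", "beta2")}
            for sex, c in config.coefficients.items()
        },
    }
    return yaml.safe_dump(payload, sort_keys=True)


def config_from_yaml(text: str) -> RunConfiguration:
    """Parse a configuration from a YAML string (used for round-tripping)."""
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    return _from_mapping(raw)
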