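"""Run configuration: structured-text (INI) files with per-stage sections.

A run config has four sections::

    [model]        name = colony | turing | lorenz63, plus model parameters
    [likelihood]   mode = bayes | cil | scil, bins M, n_ens, N, metric, ...
    [sampler]      algorithm, steps, seed, step_s, t0, burn_in
    [output]       dir

``validate_config`` fills documented defaults, rejects unknown keys, runs
cross-field checks and collects every error before failing, so a bad file
reports all its problems at once.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError

__all__ = ["RunConfig", "validate_config", "normalize_config", "write_config"]


_MODEL_DEFAULTS: dict[str, dict[str, float | int | str]] = {
    "colony": {
        "alpha": 0.3,
        "sigma_k": 1.5,
        "sigma_s": 2.0,
        "sigma_o": 0.05,
        "r_max": 12.0,
        "n_r": 120,
        "t_max": 10.0,
        "n_times": 10,
    },
    "turing": {
        "a": 0.1,
        "b": 0.9,
        "gamma": 1.0,
        "d_u": 1.0,
        "d_v": 40.0,
        "grid_n": 64,
        "grid_length": 50.0,
        "ic_amplitude": 0.01,
        "dt": 0.15,
        "t_int": 1000.0,
    },
    "lorenz63": {
        "sigma": 10.0,
        "rho": 28.0,
        "beta": 8.0 / 3.0,
        "dt": 0.5,
        "transient": 20.0,
        "epsilon": 1e-3,
    },
}

_LIKELIHOOD_DEFAULTS: dict[str, float | int | str] = {
    "mode": "bayes",
    "m_bins": 10,
    "n_ens": 10,
    "n_per_subset": 10,
    "metric": "L2",
    "data": "",
    "data_seed": 12345,
    "infer": "",
    "n_data": 1,
}

_SAMPLER_DEFAULTS: dict[str, float | int | str] = {
    "algorithm": "adaptive_metropolis",
    "steps": 2000,
    "seed": 0,
    "step_s": 0.01,
    "t0": 200,
    "burn_in": 0.3,
}

_OUTPUT_DEFAULTS: dict[str, str] = {"dir": "out"}

_MODES = {"bayes", "cil", "scil"}
_ALGORITHMS = {"metropolis", "adaptive_metropolis"}


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully defaulted run configuration."""

    model: dict = field(default_factory=dict)
    likelihood: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "model": dict(self.model),
            "likelihood": dict(self.likelihood),
            "sampler": dict(self.sampler),
            "output": dict(self.output),
        }


def _coerce(value: str, default):
    if isinstance(default, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(value)
    if isinstance(default, float):
        return float(value)
    return value


def _merge_section(raw: dict, defaults: dict, section: str, errors: list) -> dict:
    out = dict(defaults)
    for key, value in raw.items():
        if key not in defaults:
            errors.append(f"[{section}] unknown key {key!r}")
            continue
        try:
            out[key] = _coerce(value, defaults[key]) if isinstance(value, str) else value
        except ValueError:
            errors.append(f"[{section}] cannot parse {key} = {value!r}")
    return out


def normalize_config(sections: dict) -> RunConfig:
    """Fill defaults and validate a nested-dict configuration.

    Idempotent: normalising a normalised config is the identity.
    """
    errors: list[str] = []
    known_sections = {"model", "likelihood", "sampler", "output"}
    for name in sections:
        if name not in known_sections and name != "DEFAULT":
            errors.append(f"unknown section [{name}]")

    raw_model = dict(sections.get("model", {}))
    model_name = str(raw_model.pop("name", "")).strip()
    if model_name not in _MODEL_DEFAULTS:
        errors.append(
            f"[model] name must be one of {sorted(_MODEL_DEFAULTS)} (got {model_name!r})"
        )
        model = {"name": model_name}
    else:
        model = _merge_section(raw_model, _MODEL_DEFAULTS[model_name], "model", errors)
        model["name"] = model_name

    likelihood = _merge_section(dict(sections.get("likelihood", {})), _LIKELIHOOD_DEFAULTS, "likelihood", errors)
    sampler = _merge_section(dict(sections.get("sampler", {})), _SAMPLER_DEFAULTS, "sampler", errors)
    output = _merge_section(dict(sections.get("output", {})), _OUTPUT_DEFAULTS, "output", errors)

    # cross-field checks
    if likelihood["mode"] not in _MODES:
        errors.append(f"[likelihood] mode must be one of {sorted(_MODES)}")
    if sampler["algorithm"] not in _ALGORITHMS:
        errors.append(f"[sampler] algorithm must be one of {sorted(_ALGORITHMS)}")
    if likelihood["mode"] in ("cil", "scil"):
        if likelihood["n_ens"] < 3:
            errors.append(
                "[likelihood] n_ens must be at least 3 (a covariance needs "
                ">= 3 subsets; n_ens subsets give n_ens(n_ens-1)/2 realisations)"
            )
        if likelihood["n_per_subset"] < 1:
            errors.append("[likelihood] n_per_subset must be positive")
        if likelihood["m_bins"] < 2:
            errors.append("[likelihood] m_bins must be at least 2")
        if model_name == "colony":
            errors.append("[likelihood] cil/scil modes apply to turing or lorenz63 models")
    if sampler["steps"] < 1:
        errors.append("[sampler] steps must be positive")
    if not 0 <= sampler["burn_in"] < 1:
        errors.append("[sampler] burn_in must lie in [0, 1)")
    if errors:
        raise ConfigError(errors)
    return RunConfig(model=model, likelihood=likelihood, sampler=sampler, output=output)


def validate_config(path: str | Path) -> RunConfig:
    """Parse and normalise an INI config file; raises :class:`ConfigError`
    listing every problem found."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ConfigError([f"cannot read config file {path}"])
    sections = {name: dict(parser[name]) for name in parser.sections()}
    return normalize_config(sections)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    parser = configparser.ConfigParser()
    for name, section in cfg.as_dict().items():
        parser[name] = {k: str(v) for k, v in section.items()}
    with open(path, "w") as fh:
        parser.write(fh)
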