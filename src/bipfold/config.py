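"""Configuration loading and validation.

A run configuration is a flat YAML (or JSON) document with four optional
sections::

    model:           # k, C, coop_policy, volume_um3
    rates:           # any rate-constant field of ParameterSet
    initial_counts:  # bip_total, u0, scj1_total, pore_total, sec63_total
    solver:          # tol, t_max, rtol, atol

Unknown sections or keys are rejected; all violations are collected and
reported together.  An empty file yields the full documented defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .network import CoopPolicy, ModelSpec
from .params import ConfigurationError, ParameterSet

_RATE_KEYS = (
    "k_on", "k_off", "scj1_assist", "k_scj1_on", "k_fold", "k_misfold",
    "k_unfold", "k_agg", "nucleation_factor", "k_disagg", "k_seq",
    "k_pore_on", "k_engage", "k_slide",
)
_COUNT_KEYS = ("bip_total", "u0", "scj1_total", "pore_total", "sec63_total")
_MODEL_KEYS = ("k", "C", "coop_policy", "volume_um3")
_SOLVER_KEYS = ("tol", "t_max", "rtol", "atol")


@dataclass(frozen=True)
class SolverSettings:
    tol: float = 1e-8
    t_max: float = 1e6
    rtol: float = 1e-8
    atol: float = 1e-4


@dataclass(frozen=True)
class RunConfig:
    spec: ModelSpec
    solver: SolverSettings = field(default_factory=SolverSettings)

    def to_dict(self) -> dict:
        return {
            "model": {
                "k": self.spec.k,
                "C": self.spec.C,
                "coop_policy": self.spec.coop_policy.value,
                "volume_um3": self.spec.params.volume_um3,
            },
            "rates": {k: getattr(self.spec.params, k) for k in _RATE_KEYS},
            "initial_counts": {
                k: getattr(self.spec.params, k) for k in _COUNT_KEYS
            },
            "solver": {
                "tol": self.solver.tol, "t_max": self.solver.t_max,
                "rtol": self.solver.rtol, "atol": self.solver.atol,
            },
        }


class ConfigError(ConfigurationError):
    """All schema violations of one document, reported together."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


def _check_number(section: str, key: str, value, problems: list[str]) -> bool:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        problems.append(f"{section}.{key}: expected a number, got {value!r}")
        return False
    return True


def parse_config(doc: dict | None) -> RunConfig:
    """Validate a parsed configuration mapping and build a RunConfig."""
    doc = doc or {}
    problems: list[str] = []
    if not isinstance(doc, dict):
        raise ConfigError(["top level must be a mapping"])
    for section in doc:
        if section not in ("model", "rates", "initial_counts", "solver"):
            problems.append(f"unknown section {section!r}")

    def section(name: str) -> dict:
        sec = doc.get(name) or {}
        if not isinstance(sec, dict):
            problems.append(f"section {name!r} must be a mapping")
            return {}
        return sec

    model = section("model")
    rates = section("rates")
    counts = section("initial_counts")
    solver = section("solver")

    params_kw: dict[str, float] = {}
    for key, value in rates.items():
        if key not in _RATE_KEYS:
            problems.append(f"rates.{key}: unknown rate")
        elif _check_number("rates", key, value, problems):
            if value <= 0:
                problems.append(f"rates.{key}: must be positive, got {value!r}")
            else:
                params_kw[key] = float(value)
    for key, value in counts.items():
        if key not in _COUNT_KEYS:
            problems.append(f"initial_counts.{key}: unknown copy number")
        elif _check_number("initial_counts", key, value, problems):
            if value < 0:
                problems.append(
                    f"initial_counts.{key}: must be non-negative, got {value!r}"
                )
            else:
                params_kw[key] = float(value)

    k, C = 4, 1.0
    policy = CoopPolicy.THRESHOLD
    for key, value in model.items():
        if key not in _MODEL_KEYS:
            problems.append(f"model.{key}: unknown key")
        elif key == "k":
            if value not in (1, 2, 3, 4):
                problems.append(f"model.k: must be 1..4, got {value!r}")
            else:
                k = int(value)
        elif key == "C":
            if _check_number("model", key, value, problems):
                if value < 1:
                    problems.append(f"model.C: must be >= 1, got {value!r}")
                else:
                    C = float(value)
        elif key == "coop_policy":
            try:
                policy = CoopPolicy(value)
            except ValueError:
                valid = ", ".join(p.value for p in CoopPolicy)
                problems.append(f"model.coop_policy: expected one of {valid}")
        elif key == "volume_um3":
            if _check_number("model", key, value, problems):
                if value <= 0:
                    problems.append(f"model.volume_um3: must be positive")
                else:
                    params_kw["volume_um3"] = float(value)

    solver_kw: dict[str, float] = {}
    for key, value in solver.items():
        if key not in _SOLVER_KEYS:
            problems.append(f"solver.{key}: unknown key")
        elif _check_number("solver", key, value, problems):
            if value <= 0:
                problems.append(f"solver.{key}: must be positive, got {value!r}")
            else:
                solver_kw[key] = float(value)

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        spec=ModelSpec(k=k, C=C, params=ParameterSet(**params_kw), coop_policy=policy),
        solver=SolverSettings(**solver_kw),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load, parse and validate a YAML/JSON configuration file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text) if text.strip() else {}
    return parse_config(doc)


def dump_manifest(config: RunConfig, path: str | Path, **extra) -> None:
    """Write a replayable manifest (full config echo plus run metadata)."""
    from . import __version__

    manifest = {"version": __version__, "config": config.to_dict(), **extra}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
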