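"""Structured run configurations (YAML, with JSON as an accepted dialect).

A config file names a subcommand and supplies its model parameters; unknown
keys are rejected with their key path so typos fail loudly.  The seed feeds
every stochastic fixture and is echoed into every output header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]

_SCHEMAS: dict[str, dict] = {
    # subcommand -> {key: (type, default or REQUIRED)}
    "game": {
        "payoff": (list, "REQUIRED"),
        "tol": (float, 1e-9),
    },
    "dynamics": {
        "payoff": (list, "REQUIRED"),
        "phenotypes": (list, None),  # diploid x_ij rows; absent -> haploid
        "start": (list, None),
        "tol": (float, 1e-12),
        "max_iter": (int, 1_000_000),
    },
    "twolocus": {
        "payoff": (list, "REQUIRED"),
        "R": (float, "REQUIRED"),
        "phenotypes": (list, None),  # dense x_ijkl nested lists
        "additive": (bool, False),
        "a": (int, 2),
        "b": (int, 2),
        "mutant": (list, None),
        "tol": (float, 1e-12),
    },
    "modifier": {
        "T": (int, 50),
        "s1": (float, 0.01),
        "s2": (float, 0.015),
        "r": (float, 0.0),
        "mu_res": (float, 0.02),
        "mu_mut": (float, 0.02),
        "constant_environment": (bool, False),
        "grid": (int, 41),
        "grid_max": (float, 0.05),
    },
    "group": {
        "n": (int, "REQUIRED"),
        "m": (float, "REQUIRED"),
        "delta": (float, "REQUIRED"),
        "payoff": (list, "REQUIRED"),
        "y": (float, "REQUIRED"),
        "xhat": (float, "REQUIRED"),
    },
    "sexratio": {
        "resident": (float, "REQUIRED"),
        "mutant": (float, "REQUIRED"),
    },
}

_COMMON = {
    "subcommand": (str, "REQUIRED"),
    "seed": (int, 0),
    "out": (str, None),
    "verbosity": (int, 1),
}

_RANGE_CHECKS = {
    ("twolocus", "R"): lambda v: 0.0 < v <= 0.5 or _fail("R must lie in (0, 0.5]"),
    ("modifier", "T"): lambda v: v >= 1 or _fail("T must be a positive integer"),
    ("modifier", "r"): lambda v: 0.0 <= v <= 0.5 or _fail("r must lie in [0, 0.5]"),
    ("modifier", "mu_res"): lambda v: 0.0 <= v <= 0.5 or _fail("mu_res must lie in [0, 0.5]"),
    ("modifier", "mu_mut"): lambda v: 0.0 <= v <= 0.5 or _fail("mu_mut must lie in [0, 0.5]"),
    ("group", "m"): lambda v: 0.0 < v <= 1.0 or _fail("m must lie in (0, 1]"),
}


def _fail(msg: str):
    raise ValueError(msg)


@dataclass(frozen=True)
class RunConfig:
    subcommand: str
    seed: int
    params: dict
    out: str | None = None
    verbosity: int = 1
    defaults_filled: tuple = field(default_factory=tuple)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration.

    Schema violations report the offending key path; defaults are filled
    and recorded in ``defaults_filled``.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    sub = raw.get("subcommand")
    if sub not in _SCHEMAS:
        raise ValueError(
            f"{path}: subcommand: must be one of {sorted(_SCHEMAS)}, got {sub!r}"
        )
    schema = {**_COMMON, **_SCHEMAS[sub]}
    unknown = set(raw) - set(schema)
    if unknown:
        raise ValueError(f"{path}: unknown keys: {sorted(unknown)}")
    params: dict = {}
    filled: list[str] = []
    for key, (typ, default) in schema.items():
        if key in raw:
            val = raw[key]
            if typ in (int, float) and isinstance(val, (int, float)) and not isinstance(val, bool):
                val = typ(val)
            elif not isinstance(val, typ) and val is not None:
                raise ValueError(f"{path}: {key}: expected {typ.__name__}, got {type(val).__name__}")
        elif default == "REQUIRED":
            raise ValueError(f"{path}: {key}: required key missing")
        else:
            val = default
            filled.append(key)
        check = _RANGE_CHECKS.get((sub, key))
        if check is not None and val is not None:
            check(val)
        params[key] = val
    return RunConfig(
        subcommand=params.pop("subcommand"),
        seed=params.pop("seed"),
        out=params.pop("out"),
        verbosity=params.pop("verbosity"),
        params=params,
        defaults_filled=tuple(sorted(filled)),
    )
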