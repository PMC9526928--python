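"""Run configuration: loading, validation, defaults.

A run config is a flat human-readable YAML mapping.  Only ``alpha`` and
``doses`` are required; everything else defaults to the design's standard
operating point (s=3, m0=12, xi=0.05, max_n=30, cohorts of 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .policy import HistoricalPrior, PolicyConfig, build_pseudo_data
from .scaling import DoseGrid

__all__ = ["RunConfig", "load_config", "ConfigError"]

_KNOWN_KEYS = {
    "alpha", "doses", "scaled_doses", "mode", "offset", "divisor", "s",
    "m0", "xi", "max_n", "cohort_size", "skeleton", "pess", "seed",
    "reps", "scenario", "out", "verbosity", "resolution", "posterior_method",
}


class ConfigError(ValueError):
    """Invalid or malformed run configuration."""


@dataclass
class RunConfig:
    grid: DoseGrid
    policy: PolicyConfig
    hist: Optional[HistoricalPrior] = None
    seed: int = 0
    reps: int = 1000
    scenario_path: Optional[str] = None
    out_path: Optional[str] = None
    verbosity: int = 1


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, applying defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of keys to values")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "alpha" not in raw:
        raise ConfigError("config must set 'alpha' (target toxicity rate)")
    alpha = float(raw["alpha"])
    s = int(raw.get("s", 3))

    try:
        if "scaled_doses" in raw:
            scaled = tuple(float(v) for v in raw["scaled_doses"])
            original = tuple(float(v) for v in raw.get("doses", scaled))
            grid = DoseGrid(original, scaled, alpha, s)
        elif "doses" in raw:
            grid = DoseGrid.from_levels(
                [float(v) for v in raw["doses"]],
                alpha=alpha,
                s=s,
                mode=raw.get("mode", "auto"),
                offset=raw.get("offset"),
                divisor=raw.get("divisor"),
            )
        else:
            raise ConfigError("config must set 'doses' or 'scaled_doses'")
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    if s != 3 and grid.K <= 6:
        warnings.warn(
            f"s={s} with K={grid.K}: s=3 is recommended for K<=6", UserWarning
        )
    elif s != 5 and grid.K >= 7:
        warnings.warn(
            f"s={s} with K={grid.K}: s=5 is recommended for K>=7", UserWarning
        )

    try:
        policy = PolicyConfig(
            alpha=alpha,
            s=s,
            m0=int(raw.get("m0", 12)),
            xi=float(raw.get("xi", 0.05)),
            max_n=int(raw.get("max_n", 30)),
            cohort_size=int(raw.get("cohort_size", 3)),
            posterior_method=str(raw.get("posterior_method", "sequential")),
            resolution=int(raw.get("resolution", 400)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    hist = None
    if "skeleton" in raw:
        skeleton = [float(v) for v in raw["skeleton"]]
        if len(skeleton) != grid.K:
            raise ConfigError("skeleton length must equal the number of doses")
        pess = raw.get("pess")
        if pess is None:
            from .policy import pess_default

            pess = [pess_default(policy.max_n, grid.K)] * grid.K
        elif isinstance(pess, (int, float)):
            pess = [int(pess)] * grid.K
        else:
            pess = [int(v) for v in pess]
        try:
            hist = build_pseudo_data(skeleton, pess)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    sc = raw.get("scenario")
    return RunConfig(
        grid=grid,
        policy=policy,
        hist=hist,
        seed=int(raw.get("seed", 0)),
        reps=int(raw.get("reps", 1000)),
        scenario_path=str(sc) if sc is not None else None,
        out_path=str(raw["out"]) if "out" in raw else None,
        verbosity=int(raw.get("verbosity", 1)),
    )
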