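"""Dose-scale preprocessing for the BSA design.

The design works on doses mapped into the half-open unit interval (0, 1],
partitioned into ``s`` equal subintervals.  A local linear model for the
dose-toxicity curve is fit on whichever subinterval contains the current
dose, so locating doses within the partition is the basic geometric
primitive of the whole method.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseGrid",
    "Subinterval",
    "scale_doses",
    "auto_scale",
    "subinterval_of",
]


class InvalidTransformError(ValueError):
    """A dose transform produced a value outside (0, 1]."""


@dataclass(frozen=True)
class Subinterval:
    """One of the ``s`` equal pieces (v0, v1] tiling (0, 1]."""

    v0: float
    v1: float
    index: int  # 1-based, 1..s

    def __post_init__(self) -> None:
        if not (0.0 <= self.v0 < self.v1 <= 1.0):
            raise ValueError(f"invalid subinterval ({self.v0}, {self.v1}]")

    @property
    def width(self) -> float:
        return self.v1 - self.v0

    def contains(self, x: float, atol: float = 1e-12) -> bool:
        return self.v0 + atol < x <= self.v1 + atol


@dataclass(frozen=True)
class DoseGrid:
    """Candidate doses in original and scaled coordinates.

    Parameters
    ----------
    original_levels : sequence of float
        Doses on their original (or log) scale, strictly increasing.
    scaled_levels : sequence of float
        The same doses mapped into (0, 1], strictly increasing.
    alpha : float
        Target toxicity rate, in (0, 1).
    s : int
        Number of equal subintervals partitioning (0, 1].
    """

    original_levels: tuple
    scaled_levels: tuple
    alpha: float
    s: int = 3

    def __post_init__(self) -> None:
        orig = tuple(float(v) for v in self.original_levels)
        scaled = tuple(float(v) for v in self.scaled_levels)
        object.__setattr__(self, "original_levels", orig)
        object.__setattr__(self, "scaled_levels", scaled)
        if len(orig) != len(scaled):
            raise ValueError("original and scaled level counts differ")
        if len(scaled) == 0:
            raise ValueError("empty dose grid")
        if any(not (0.0 < d <= 1.0) for d in scaled):
            raise InvalidTransformError(
                f"scaled levels must lie in (0, 1], got {scaled}"
            )
        if any(b <= a for a, b in zip(scaled, scaled[1:])):
            raise ValueError("scaled levels must be strictly increasing")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if int(self.s) < 1:
            raise ValueError("s must be a positive integer")
        object.__setattr__(self, "s", int(self.s))

    @property
    def K(self) -> int:
        return len(self.scaled_levels)

    def dose(self, k: int) -> float:
        """Scaled dose for 1-based index ``k``."""
        return self.scaled_levels[k - 1]

    def subinterval(self, k: int) -> Subinterval:
        return subinterval_of(self.dose(k), self.s)

    # ---- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_label": [f"d{k}" for k in range(1, self.K + 1)],
                "original_level": self.original_levels,
                "scaled_level": self.scaled_levels,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "original_levels": list(self.original_levels),
                "scaled_levels": list(self.scaled_levels),
                "alpha": self.alpha,
                "s": self.s,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DoseGrid":
        obj = json.loads(text)
        return cls(
            tuple(obj["original_levels"]),
            tuple(obj["scaled_levels"]),
            float(obj["alpha"]),
            int(obj.get("s", 3)),
        )

    @classmethod
    def from_levels(
        cls,
        levels: Sequence[float],
        alpha: float,
        s: int = 3,
        mode: Literal["linear", "log", "auto"] = "auto",
        offset: float | None = None,
        divisor: float | None = None,
    ) -> "DoseGrid":
        """Build a grid by scaling ``levels`` into (0, 1]."""
        if mode == "auto":
            mode, offset, divisor = auto_scale(levels)
        if offset is None or divisor is None:
            raise ValueError("offset and divisor required unless mode='auto'")
        scaled = scale_doses(levels, mode=mode, offset=offset, divisor=divisor)
        return cls(tuple(levels), tuple(scaled), alpha, s)


def scale_doses(
    levels: Iterable[float],
    mode: Literal["linear", "log"] = "linear",
    offset: float = 0.0,
    divisor: float = 1.0,
) -> list[float]:
    """Map dose levels into (0, 1] by an affine (or log-affine) transform.

    Returns ``(x - offset)/divisor`` for linear mode and
    ``(log x - offset)/divisor`` (natural log) for log mode.  Every output
    must land in (0, 1]; otherwise :class:`InvalidTransformError` is raised
    naming the offending level.
    """
    levels = [float(v) for v in levels]
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")
    if mode == "log":
        if any(v <= 0 for v in levels):
            raise ValueError("log mode requires positive levels")
        vals = [(math.log(v) - offset) / divisor for v in levels]
    elif mode == "linear":
        vals = [(v - offset) / divisor for v in levels]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for lev, x in zip(levels, vals):
        # tolerate float fuzz at the closed upper endpoint
        if not (0.0 < x <= 1.0 + 1e-12):
            raise InvalidTransformError(
                f"level {lev} maps to {x:.6g}, outside (0, 1]"
            )
    return [min(x, 1.0) for x in vals]


def auto_scale(levels: Sequence[float]) -> tuple[str, float, float]:
    """Choose a transform spreading ``levels`` over (0, 1].

    Mode selection follows the spacing of the levels: approximately
    additive spacing selects the linear map, approximately multiplicative
    spacing (more regular on the log scale) selects the natural-log map.
    On the chosen scale the map is ``x -> (x - (min - delta)) / (range + 2*delta)``
    with ``delta = range / (2*(K-1))``, which places K equally spaced levels
    at the midpoints ``(2k-1)/(2K)`` — e.g. 1..5 to 0.1, 0.3, ..., 0.9.
    """
    levels = [float(v) for v in levels]
    if len(set(levels)) < 2:
        raise ValueError("auto_scale needs at least 2 distinct levels")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")

    def spread(vals: list[float]) -> float:
        d = np.diff(vals)
        return float(np.std(d) / np.mean(d))

    mode = "linear"
    if all(v > 0 for v in levels):
        logs = [math.log(v) for v in levels]
        if spread(logs) < spread(levels) - 1e-12:
            mode = "log"
    vals = [math.log(v) for v in levels] if mode == "log" else levels
    lo, hi = vals[0], vals[-1]
    delta = (hi - lo) / (2 * (len(vals) - 1))
    offset = lo - delta
    divisor = (hi - lo) + 2 * delta
    return mode, offset, divisor


def subinterval_of(x: float, s: int) -> Subinterval:
    """Locate the partition piece (v0, v1] containing scaled dose ``x``.

    Uses the ceiling rule ``v0 = (ceil(x*s) - 1)/s``, ``v1 = ceil(x*s)/s``;
    boundary doses ``x = j/s`` belong to the lower subinterval.
    """
    if not (0.0 < x <= 1.0):
        raise ValueError(f"scaled dose must be in (0, 1], got {x}")
    if s < 1:
        raise ValueError("s must be a positive integer")
    # snap float fuzz (e.g. 0.2*3 = 0.6000000000000001) before the ceiling
    j = math.ceil(round(x * s, 12))
    j = min(max(j, 1), s)
    return Subinterval((j - 1) / s, j / s, j)
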