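"""Virtual trials: toxicity scenarios, replicated runs, operating characteristics.

Scenarios carry the true per-dose DLT probabilities; the implied MTD is the
dose whose probability is closest to the target rate (ties toward the lower
dose).  ``run_trial`` draws patient-level Bernoulli outcomes and feeds them
through the transition policy cohort by cohort; replicate sets are seeded
from one root seed via ``numpy.random.SeedSequence`` spawning, so runs are
reproducible and independent across replicates.

The four summary metrics follow the standard dose-finding evaluation: the
percentage of replicates selecting the true MTD (PCS), the percentage of
patients allocated to the MTD (MTD%), the percentage of patients treated
above the MTD (above-MTD%), and the average number of DLTs per trial.
Early-terminated replicates count as incorrect selections and contribute
their enrolled patients to the allocation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .policy import (
    HistoricalPrior,
    PolicyConfig,
    TrialState,
    next_dose,
    select_mtd,
)
from .scaling import DoseGrid

__all__ = [
    "Scenario",
    "TrialResult",
    "OperatingCharacteristics",
    "mtd_index_of",
    "tanh_scenario",
    "random_scenario",
    "random_exact_doses",
    "run_trial",
    "run_replicates",
    "operating_characteristics",
    "synthetic_fixed_scenarios",
]


def mtd_index_of(p: Sequence[float], alpha: float) -> int:
    """1-based index of the dose with toxicity closest to alpha (ties low)."""
    p = np.asarray(p, dtype=float)
    return int(np.argmin(np.abs(p - alpha))) + 1


@dataclass(frozen=True)
class Scenario:
    """True toxicity probabilities on a dose grid."""

    grid: DoseGrid
    p: tuple

    def __post_init__(self) -> None:
        p = tuple(float(v) for v in self.p)
        object.__setattr__(self, "p", p)
        if len(p) != self.grid.K:
            raise ValueError("probability vector length must equal K")
        if any(not (0.0 < v < 1.0) for v in p):
            raise ValueError("toxicity probabilities must be in (0, 1)")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("toxicity probabilities must be strictly increasing")

    @property
    def mtd_index(self) -> int:
        return mtd_index_of(self.p, self.grid.alpha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_index": range(1, self.grid.K + 1),
                "scaled_dose": self.grid.scaled_levels,
                "true_p": self.p,
            }
        )


@dataclass(frozen=True)
class TrialResult:
    """Everything recorded from one simulated trial."""

    selected: Optional[int]  # MTD index, or None if terminated
    path: tuple  # dose index per cohort
    allocations: tuple  # patients per dose, length K
    n_dlt: int
    quick_action_counts: dict

    @property
    def n_enrolled(self) -> int:
        return int(sum(self.allocations))

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "path": list(self.path),
            "allocations": list(self.allocations),
            "n_dlt": self.n_dlt,
            "quick_action_counts": dict(self.quick_action_counts),
        }


@dataclass(frozen=True)
class OperatingCharacteristics:
    pcs: float
    mtd_pct: float
    above_mtd_pct: float
    avg_dlt: float
    n_replicates: int = 0
    n_terminated: int = 0

    def to_dict(self) -> dict:
        return {
            "pcs": self.pcs,
            "mtd_pct": self.mtd_pct,
            "above_mtd_pct": self.above_mtd_pct,
            "avg_dlt": self.avg_dlt,
            "n_replicates": self.n_replicates,
            "n_terminated": self.n_terminated,
        }


def tanh_scenario(original_doses: Sequence[float], grid: DoseGrid) -> Scenario:
    """Toxicity curve Pr(y=1) = [ (tanh(x) + 1) / 2 ]^2 at the original doses."""
    x = np.asarray(original_doses, dtype=float)
    p = ((np.tanh(x) + 1.0) / 2.0) ** 2
    return Scenario(grid, tuple(p))


def random_scenario(
    K: int,
    mtd_position: int,
    alpha: float,
    gap_bounds: tuple = (0.05, 0.3),
    seed: int | np.random.Generator | None = None,
    grid: Optional[DoseGrid] = None,
    max_tries: int = 1000,
) -> Scenario:
    """Pseudo-uniform random scenario with the MTD pinned at one position.

    The MTD's probability is drawn near alpha, its neighbours at gaps
    inside ``gap_bounds``, and the remaining doses extend outward with
    increasing uniform increments; draws violating monotonicity, the (0,1)
    range, or the intended MTD position are rejected and resampled.
    """
    if not (1 <= mtd_position <= K):
        raise ValueError("mtd_position out of range")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if grid is None:
        # rank-based default grid, e.g. 0.1, 0.3, ... for K=5
        scaled = tuple((2 * k - 1) / (2 * K) for k in range(1, K + 1))
        grid = DoseGrid(tuple(range(1, K + 1)), scaled, alpha, 3)
    glo, ghi = gap_bounds
    j = mtd_position - 1
    for _ in range(max_tries):
        p = np.empty(K)
        p[j] = rng.uniform(alpha - 0.05, alpha + 0.05)
        # adjacent doses at a gap inside gap_bounds; remaining doses are
        # sorted uniform draws in the leftover range on each side
        if j >= 1:
            p[j - 1] = p[j] - rng.uniform(glo, ghi)
            if j >= 2:
                if p[j - 1] <= 0.012:
                    continue
                p[: j - 1] = np.sort(rng.uniform(0.001, p[j - 1] - 0.01, size=j - 1))
        if j + 1 < K:
            p[j + 1] = p[j] + rng.uniform(glo, ghi)
            if j + 2 < K:
                if p[j + 1] >= 0.988:
                    continue
                p[j + 2 :] = np.sort(
                    rng.uniform(p[j + 1] + 0.01, 0.999, size=K - j - 2)
                )
        if np.any(p <= 0.0) or np.any(p >= 1.0) or np.any(np.diff(p) <= 0):
            continue
        if mtd_index_of(p, alpha) != mtd_position:
            continue
        return Scenario(grid, tuple(p))
    raise RuntimeError("could not generate a feasible scenario; relax constraints")


def random_exact_doses(
    K: int,
    mtd_position: int,
    location: str,
    alpha: float = 0.3,
    s: int = 3,
    seed: int | np.random.Generator | None = None,
) -> DoseGrid:
    """Random scaled dose levels with the MTD dose pinned by location.

    ``location`` maps to a scaled MTD dose of 0.3 (early), 0.5 (middle) or
    0.7 (late); the other doses avoid the vicinity (d_mtd-0.05, d_mtd+0.05)
    so the MTD stays distinguishable.
    """
    loc_map = {"early": 0.3, "middle": 0.5, "late": 0.7}
    if location not in loc_map:
        raise ValueError("location must be early, middle or late")
    if not (1 <= mtd_position <= K):
        raise ValueError("mtd_position out of range")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = loc_map[location]
    lower = np.sort(rng.uniform(0.01, d - 0.05, size=mtd_position - 1))
    upper = np.sort(rng.uniform(d + 0.05, 1.0, size=K - mtd_position))
    scaled = tuple(lower) + (d,) + tuple(upper)
    return DoseGrid(scaled, scaled, alpha, s)


def synthetic_fixed_scenarios(alpha: float, K: int = 5, s: int = 3) -> list:
    """Synthetic stand-in for a representative fixed-scenario bank.

    Ten deterministic scenarios per target rate with the MTD rotating from
    the lowest to the highest dose, two per position: one with tighter and
    one with wider adjacent gaps.  The MTD sits exactly at ``alpha``; doses
    above approach 0.97 geometrically and doses below decay geometrically,
    keeping adjacent gaps in the conventional (0.05, 0.3) band.  This bank
    is constructed here, not taken from any published scenario table.
    """
    scaled = tuple((2 * k - 1) / (2 * K) for k in range(1, K + 1))
    grid = DoseGrid(tuple(range(1, K + 1)), scaled, alpha, s)
    out = []
    for pos in range(1, K + 1):
        for g in (0.12, 0.22):
            p = [0.0] * K
            p[pos - 1] = alpha
            for i in range(pos, K):
                p[i] = p[i - 1] + g * (0.97 - p[i - 1])
            for i in range(pos - 2, -1, -1):
                p[i] = p[i + 1] * (1.0 - 2.0 * g)
            sc = Scenario(grid, tuple(p))
            assert sc.mtd_index == pos
            out.append(sc)
    return out


def run_trial(
    scenario: Scenario,
    cfg: PolicyConfig,
    hist: Optional[HistoricalPrior] = None,
    seed: int | np.random.Generator | None = None,
    cohort_sizes: Optional[Sequence[int]] = None,
    random_cohort_sizes: bool = False,
) -> TrialResult:
    """Simulate one trial under the policy; deterministic given the seed.

    Cohort sizes come from ``cohort_sizes`` (a schedule) if given, else are
    drawn uniformly from {1,2,3} when ``random_cohort_sizes`` is set, else
    fixed at ``cfg.cohort_size``; the final cohort is capped at the patients
    remaining under ``cfg.max_n``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    state = TrialState(scenario.grid)
    path: list[int] = []
    quick_counts = {"fast-escalation": 0, "wald": 0}
    terminated = False
    i_cohort = 0
    while state.n_enrolled < cfg.max_n:
        dec = next_dose(state, cfg, hist)
        if dec.action == "terminate-toxicity":
            terminated = True
            break
        if dec.rationale == "fast-escalation":
            quick_counts["fast-escalation"] += 1
        elif dec.rationale.startswith("wald"):
            quick_counts["wald"] += 1
        k = dec.next_k
        if cohort_sizes is not None:
            size = cohort_sizes[min(i_cohort, len(cohort_sizes) - 1)]
        elif random_cohort_sizes:
            size = int(rng.integers(1, 4))
        else:
            size = cfg.cohort_size
        size = min(size, cfg.max_n - state.n_enrolled)
        outcomes = (rng.random(size) < scenario.p[k - 1]).astype(int)
        state = state.add_cohort(k, outcomes)
        path.append(k)
        i_cohort += 1
    selected = None if terminated else select_mtd(state, cfg, hist)
    return TrialResult(
        selected=selected,
        path=tuple(path),
        allocations=tuple(int(v) for v in state.m),
        n_dlt=state.n_dlt,
        quick_action_counts=quick_counts,
    )


def run_replicates(
    scenario: Scenario,
    cfg: PolicyConfig,
    reps: int,
    seed: int,
    hist: Optional[HistoricalPrior] = None,
    **trial_kwargs,
) -> list[TrialResult]:
    """Independent replicated trials with spawned per-replicate streams."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(reps)
    return [
        run_trial(scenario, cfg, hist=hist, seed=np.random.default_rng(ss),
                  **trial_kwargs)
        for ss in streams
    ]


def operating_characteristics(
    results: Sequence[TrialResult], scenario: Scenario
) -> OperatingCharacteristics:
    """Aggregate the four dose-finding metrics over replicates."""
    if len(results) == 0:
        raise ValueError("no trial results to summarize")
    mtd = scenario.mtd_index
    R = len(results)
    pcs = 100.0 * sum(r.selected == mtd for r in results) / R
    mtd_fracs = []
    above_fracs = []
    for r in results:
        n = max(r.n_enrolled, 1)
        mtd_fracs.append(r.allocations[mtd - 1] / n)
        above_fracs.append(sum(r.allocations[mtd:]) / n)
    return OperatingCharacteristics(
        pcs=pcs,
        mtd_pct=100.0 * float(np.mean(mtd_fracs)),
        above_mtd_pct=100.0 * float(np.mean(above_fracs)),
        avg_dlt=float(np.mean([r.n_dlt for r in results])),
        n_replicates=R,
        n_terminated=sum(r.selected is None for r in results),
    )
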