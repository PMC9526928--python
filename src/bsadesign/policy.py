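"""Transition policy: from accrued trial data to the next-dose decision.

Decision order per cohort (matching the design's algorithm):

1. *Fast escalation* — until the very first DLT anywhere, escalate one
   level per cohort (when a higher level exists).
2. *Wald quick action* — once the current dose has accumulated ``m0``
   patients, a Wald-type interval for the target rate on the logit scale
   gives a high-confidence move: escalate if the (monotonicity-adjusted)
   observed DLT frequency falls below the interval, de-escalate if above
   it — or terminate the trial for toxicity when that happens at the
   lowest dose.
3. *Bayesian step* — otherwise, compute the posterior mean of theta from
   the data inside the current subinterval and move to whichever of the
   neighbouring doses {k-1, k, k+1} is closest to it.  Dose skipping is
   never allowed.

Historical information (hBSA) enters as per-dose pseudo-observations built
from a skeleton of elicited toxicity probabilities and prior effective
sample sizes; they join the likelihood exactly like real observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .posterior import LocalData, posterior_theta
from .scaling import DoseGrid, subinterval_of

__all__ = [
    "TrialState",
    "PolicyConfig",
    "Decision",
    "HistoricalPrior",
    "pava_adjust",
    "wald_bounds",
    "quick_action",
    "bayes_step",
    "next_dose",
    "select_mtd",
    "build_pseudo_data",
    "pess_default",
    "decision_tree",
    "DecisionNode",
]

Action = Literal["escalate", "stay", "de-escalate", "terminate-toxicity", "complete"]


@dataclass(frozen=True)
class Decision:
    action: Action
    next_k: Optional[int]
    rationale: str  # fast-escalation | wald-escalate | wald-deescalate | wald-terminate | bayes | start
    theta_mean: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "next_k": self.next_k,
            "rationale": self.rationale,
            "theta_mean": self.theta_mean,
        }


@dataclass(frozen=True)
class PolicyConfig:
    """Design parameters of the BSA policy."""

    alpha: float
    s: int = 3
    m0: int = 12
    xi: float = 0.05
    max_n: int = 30
    cohort_size: int = 3
    posterior_method: str = "sequential"
    resolution: int = 400

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.xi < 0.5):
            raise ValueError("xi must be in (0, 0.5)")
        if self.m0 < 1 or self.max_n < 1 or self.s < 1:
            raise ValueError("m0, max_n and s must be positive")


@dataclass(frozen=True)
class TrialState:
    """Accrual history of a trial on a fixed dose grid."""

    grid: DoseGrid
    history: tuple = ()  # of (dose_index k, outcomes tuple)

    def __post_init__(self) -> None:
        hist = tuple((int(k), tuple(int(y) for y in ys)) for k, ys in self.history)
        object.__setattr__(self, "history", hist)
        for k, ys in hist:
            if not (1 <= k <= self.grid.K):
                raise ValueError(f"dose index {k} out of range")
            if any(y not in (0, 1) for y in ys):
                raise ValueError("outcomes must be binary")

    # ---- derived counts -----------------------------------------------
    @property
    def m(self) -> np.ndarray:
        """Patients treated per dose, length K."""
        out = np.zeros(self.grid.K, dtype=int)
        for k, ys in self.history:
            out[k - 1] += len(ys)
        return out

    @property
    def t(self) -> np.ndarray:
        """DLTs observed per dose, length K."""
        out = np.zeros(self.grid.K, dtype=int)
        for k, ys in self.history:
            out[k - 1] += sum(ys)
        return out

    @property
    def n_enrolled(self) -> int:
        return sum(len(ys) for _, ys in self.history)

    @property
    def n_dlt(self) -> int:
        return sum(sum(ys) for _, ys in self.history)

    @property
    def current_k(self) -> Optional[int]:
        return self.history[-1][0] if self.history else None

    @property
    def any_dlt(self) -> bool:
        return self.n_dlt > 0

    def add_cohort(self, k: int, outcomes: Iterable[int]) -> "TrialState":
        return TrialState(self.grid, self.history + ((k, tuple(outcomes)),))

    def observations(self) -> list[tuple]:
        """Flat list of (scaled_dose, outcome) pairs."""
        return [
            (self.grid.dose(k), y) for k, ys in self.history for y in ys
        ]

    # ---- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cohort": range(1, len(self.history) + 1),
                "dose_index": [k for k, _ in self.history],
                "scaled_dose": [self.grid.dose(k) for k, _ in self.history],
                "n_patients": [len(ys) for _, ys in self.history],
                "n_dlt": [sum(ys) for _, ys in self.history],
            }
        )

    @classmethod
    def from_frame(cls, grid: DoseGrid, df: pd.DataFrame) -> "TrialState":
        hist = []
        for _, row in df.sort_values("cohort").iterrows():
            n, t = int(row["n_patients"]), int(row["n_dlt"])
            hist.append((int(row["dose_index"]), (1,) * t + (0,) * (n - t)))
        return cls(grid, tuple(hist))


@dataclass(frozen=True)
class HistoricalPrior:
    """Skeleton-based pseudo-observations for hBSA."""

    skeleton: tuple  # q_1..q_K, strictly increasing in (0,1)
    pess: tuple  # n_01..n_0K, nonnegative integers
    pseudo: tuple  # of (a_k, b_k)

    def pseudo_observations(self, grid: DoseGrid) -> list[tuple]:
        out = []
        for k, (a, b) in enumerate(self.pseudo, start=1):
            out += [(grid.dose(k), 1)] * a + [(grid.dose(k), 0)] * b
        return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_pseudo_data(skeleton: Sequence[float], pess: Sequence[int]) -> HistoricalPrior:
    """Turn skeleton probabilities and PESS into pseudo DLT counts.

    a_k and b_k are the nearest integers to ``n0k*q_k`` and ``n0k*(1-q_k)``
    (half rounds up); their sum may differ from n0k by one.
    """
    q = tuple(float(v) for v in skeleton)
    n0 = tuple(int(v) for v in pess)
    if len(q) != len(n0):
        raise ValueError("skeleton and pess lengths differ")
    if any(not (0.0 < v < 1.0) for v in q) or any(
        b <= a for a, b in zip(q, q[1:])
    ):
        raise ValueError("skeleton must be strictly increasing in (0, 1)")
    if any(v < 0 for v in n0):
        raise ValueError("prior effective sample sizes must be >= 0")
    pseudo = tuple(
        (_round_half_up(n * p), _round_half_up(n * (1 - p)))
        for n, p in zip(n0, q)
    )
    return HistoricalPrior(q, n0, pseudo)


def pess_default(N: int, K: int, rule: str = "largest") -> int:
    """Default prior effective sample size: an integer in [N/(3K), N/(2K)]."""
    if N < 1 or K < 1:
        raise ValueError("N and K must be positive")
    lo = math.ceil(N / (3 * K) - 1e-9)
    hi = math.floor(N / (2 * K) + 1e-9)
    if hi < lo:
        raise ValueError(
            f"no integer in [{N/(3*K):.3g}, {N/(2*K):.3g}]; choose n0 manually"
        )
    return hi if rule == "largest" else lo


def pava_adjust(phat: Sequence[float], m: Sequence[int]) -> np.ndarray:
    """Monotonicity adjustment of observed per-dose DLT frequencies.

    The two-point averaging rule: scanning upward over doses with data,
    whenever a frequency falls below its predecessor both are replaced by
    their mean.  (This is the design's stated adjustment, deliberately
    simpler than full pooled isotonic regression.)
    """
    phat = np.asarray(phat, dtype=float).copy()
    m = np.asarray(m, dtype=int)
    idx = [i for i in range(len(phat)) if m[i] > 0]
    for a, b in zip(idx, idx[1:]):
        if phat[b] < phat[a]:
            avg = (phat[a] + phat[b]) / 2
            phat[a] = phat[b] = avg
    return phat


def wald_bounds(alpha: float, m_k: int, xi: float) -> tuple:
    """Wald-type interval for the target rate, back on the probability scale.

    c = logit(alpha) -/+ z_xi * (m_k*alpha*(1-alpha))**-0.5, returned as
    (expit(c1), expit(c2)).
    """
    if m_k < 1:
        raise ValueError("m_k must be >= 1")
    z = norm.ppf(1 - xi)
    half = z / math.sqrt(m_k * alpha * (1 - alpha))
    c1, c2 = logit(alpha) - half, logit(alpha) + half
    return float(expit(c1)), float(expit(c2))


def quick_action(state: TrialState, cfg: PolicyConfig) -> Optional[Decision]:
    """Frequentist shortcut decisions; ``None`` defers to the Bayesian step."""
    k = state.current_k
    if k is None:
        raise ValueError("quick_action requires at least one completed cohort")
    K = state.grid.K
    if not state.any_dlt and k < K:
        return Decision("escalate", k + 1, "fast-escalation")
    m = state.m
    if state.any_dlt or k == K:
        if m[k - 1] >= cfg.m0:
            t = state.t
            with np.errstate(invalid="ignore", divide="ignore"):
                phat = np.where(m > 0, t / np.maximum(m, 1), np.nan)
            adj = pava_adjust(np.where(np.isnan(phat), 0.0, phat), m)
            p_k = adj[k - 1]
            lower, upper = wald_bounds(cfg.alpha, int(m[k - 1]), cfg.xi)
            if p_k < lower:
                if k < K:
                    return Decision("escalate", k + 1, "wald-escalate")
                return Decision("stay", k, "wald-escalate")
            if p_k > upper:
                if k == 1:
                    return Decision("terminate-toxicity", None, "wald-terminate")
                return Decision("de-escalate", k - 1, "wald-deescalate")
    return None


def bayes_step(
    state: TrialState,
    cfg: PolicyConfig,
    hist: Optional[HistoricalPrior] = None,
) -> Decision:
    """Neighbourhood transition driven by the posterior mean of theta."""
    k = state.current_k
    if k is None:
        raise ValueError("bayes_step requires a current dose")
    grid = state.grid
    sub = subinterval_of(grid.dose(k), cfg.s)
    obs = state.observations()
    if hist is not None:
        obs = hist.pseudo_observations(grid) + obs
    pts = [(x, y) for x, y in obs if sub.contains(x)]
    data = LocalData(tuple(pts), sub.v0, sub.v1, cfg.alpha)
    post = posterior_theta(
        data, resolution=cfg.resolution, method=cfg.posterior_method
    )
    candidates = sorted({max(k - 1, 1), k, min(k + 1, grid.K)})
    # argmin of |d_a - E(theta|D)|; ties break toward the lower dose
    best = min(candidates, key=lambda a: (abs(grid.dose(a) - post.theta_mean), a))
    action: Action = (
        "stay" if best == k else ("escalate" if best > k else "de-escalate")
    )
    return Decision(action, best, "bayes", theta_mean=post.theta_mean)


def next_dose(
    state: TrialState,
    cfg: PolicyConfig,
    hist: Optional[HistoricalPrior] = None,
) -> Decision:
    """Full policy: start at dose 1, then quick actions, then Bayes."""
    if state.current_k is None:
        return Decision("stay", 1, "start")
    qa = quick_action(state, cfg)
    if qa is not None:
        return qa
    return bayes_step(state, cfg, hist)


def select_mtd(
    state: TrialState,
    cfg: PolicyConfig,
    hist: Optional[HistoricalPrior] = None,
) -> Optional[int]:
    """MTD estimate at trial end: the dose the design would assign next.

    Selection is driven by the Bayesian step (the posterior mean of theta),
    not by the frequentist shortcuts, which exist only to expedite
    transitions during accrual.  Returns ``None`` when the trial terminated
    for toxicity (no MTD declared), including when the termination check
    fires on the final state.
    """
    if state.current_k is None:
        return None
    qa = quick_action(state, cfg)
    if qa is not None and qa.action == "terminate-toxicity":
        return None
    return bayes_step(state, cfg, hist).next_k


@dataclass
class DecisionNode:
    """One branch point of a pre-printed decision tree."""

    dose_k: int
    cohort_size: int
    decision: Optional[Decision] = None
    branches: dict = field(default_factory=dict)  # n_dlt -> DecisionNode | leaf dict

    def to_dict(self) -> dict:
        out = {
            "dose": self.dose_k,
            "cohort_size": self.cohort_size,
            "branches": {},
        }
        for ndlt, child in self.branches.items():
            if isinstance(child, DecisionNode):
                out["branches"][str(ndlt)] = child.to_dict()
            else:
                out["branches"][str(ndlt)] = child
        return out

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        lines = [f"{pad}treat cohort of {self.cohort_size} at dose {self.dose_k}:"]
        for ndlt, child in sorted(self.branches.items()):
            if isinstance(child, DecisionNode):
                lines.append(f"{pad}  {ndlt} DLT ->")
                lines.append(child.render(indent + 2))
            else:
                lines.append(f"{pad}  {ndlt} DLT -> {child['label']}")
        return "\n".join(lines)


def decision_tree(
    state: TrialState,
    cfg: PolicyConfig,
    depth: int = 3,
    hist: Optional[HistoricalPrior] = None,
) -> DecisionNode:
    """Enumerate all outcome branches for the next ``depth`` cohorts.

    Each branch fixes the number of DLTs in a cohort (order within a
    cohort does not change any decision) and records the resulting move.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    dec = next_dose(state, cfg, hist)
    if dec.next_k is None:
        raise ValueError("trial already terminated; no tree to build")
    return _expand(state, cfg, hist, dec.next_k, depth)


def _expand(state, cfg, hist, k, depth) -> DecisionNode:
    size = min(cfg.cohort_size, cfg.max_n - state.n_enrolled)
    node = DecisionNode(dose_k=k, cohort_size=size)
    for ndlt in range(size + 1):
        outcomes = (1,) * ndlt + (0,) * (size - ndlt)
        nxt_state = state.add_cohort(k, outcomes)
        dec = next_dose(nxt_state, cfg, hist)
        if dec.action == "terminate-toxicity":
            node.branches[ndlt] = {"label": "terminate for toxicity",
                                   "decision": dec.to_dict()}
        elif depth == 1 or nxt_state.n_enrolled >= cfg.max_n:
            label = f"{dec.action} -> dose {dec.next_k}"
            node.branches[ndlt] = {"label": label, "decision": dec.to_dict()}
        else:
            node.branches[ndlt] = _expand(nxt_state, cfg, hist, dec.next_k,
                                          depth - 1)
    return node
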