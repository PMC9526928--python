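"""Human-readable trial reports with machine-readable JSON twins."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .policy import Decision, TrialState, pava_adjust

__all__ = ["report_trial", "report_dict"]


def report_dict(state: TrialState, decision: Optional[Decision]) -> dict:
    """Numeric content of a trial report as plain data."""
    m = state.m
    t = state.t
    with np.errstate(invalid="ignore"):
        phat = np.where(m > 0, t / np.maximum(m, 1), np.nan)
    adj = pava_adjust(np.where(np.isnan(phat), 0.0, phat), m)
    doses = []
    for k in range(1, state.grid.K + 1):
        doses.append(
            {
                "dose_index": k,
                "scaled_dose": state.grid.dose(k),
                "n_patients": int(m[k - 1]),
                "n_dlt": int(t[k - 1]),
                "phat": None if m[k - 1] == 0 else float(phat[k - 1]),
                "phat_monotone": None if m[k - 1] == 0 else float(adj[k - 1]),
            }
        )
    return {
        "n_enrolled": state.n_enrolled,
        "n_dlt": state.n_dlt,
        "current_dose": state.current_k,
        "doses": doses,
        "decision": decision.to_dict() if decision is not None else None,
    }


def report_trial(state: TrialState, decision: Optional[Decision]) -> str:
    """Render the per-dose table and the pending decision as text."""
    rep = report_dict(state, decision)
    lines = []
    if state.current_k is None:
        lines.append("No data yet: start at dose 1.")
    else:
        lines.append(
            f"Enrolled {rep['n_enrolled']} patients, {rep['n_dlt']} DLTs; "
            f"current dose index {rep['current_dose']}."
        )
    lines.append(f"{'dose':>4} {'scaled':>8} {'n':>4} {'DLT':>4} "
                 f"{'p^':>7} {'p^ mono':>8}")
    for row in rep["doses"]:
        ph = "-" if row["phat"] is None else f"{row['phat']:.3f}"
        pm = "-" if row["phat_monotone"] is None else f"{row['phat_monotone']:.3f}"
        lines.append(
            f"{row['dose_index']:>4} {row['scaled_dose']:>8.3f} "
            f"{row['n_patients']:>4} {row['n_dlt']:>4} {ph:>7} {pm:>8}"
        )
    dec = rep["decision"]
    if dec is not None:
        if dec["action"] == "terminate-toxicity":
            lines.append("Decision: TERMINATE the trial for toxicity (no MTD).")
        else:
            msg = (f"Decision: {dec['action']} -> dose {dec['next_k']} "
                   f"[{dec['rationale']}]")
            if dec["theta_mean"] is not None:
                msg += f", posterior mean of theta = {dec['theta_mean']:.3f}"
            lines.append(msg)
    return "\n".join(lines)
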