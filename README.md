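# bsadesign

Bayesian stochastic approximation (BSA) dose-finding for phase I clinical
trials: a sequential design that estimates the maximum tolerated dose (MTD)
by local Bayesian quantile estimation instead of global curve fitting or
interval rules.

## Who this is for

Trial statisticians designing or simulating phase I dose-escalation studies
with a binary dose-limiting toxicity (DLT) endpoint, a prespecified target
toxicity rate α (typically 0.2 or 0.3), and a small number K of candidate
doses.  The package provides the transition policy (for running a live
trial cohort by cohort), a pre-printable decision tree, a trial simulator
with the standard operating-characteristic metrics, and an extension that
borrows historical information through prior effective sample sizes (hBSA).

## The method

Candidate doses are scaled into (0, 1] and the unit interval is divided
into `s` equal subintervals (default `s = 3`).  Writing π(x) for the
toxicity probability at scaled dose x, the quantity of interest is the
target quantile θ = π⁻¹(α).  On the subinterval (v₀, v₁] containing the
current dose, π is approximated by the line through (θ, α),

    F(x) = α + β(x − θ),   β > 0,

and monotonicity is encoded by the noninformative prior with density
2·I(0 < ρ₀ < ρ₁ < 1) on the endpoint values ρ₀ = F(v₀), ρ₁ = F(v₁).
Observations falling in the current subinterval update the posterior of θ,
and the next cohort is treated at whichever neighbouring dose
(one step down, stay, one step up — no skipping) is closest to E(θ | data):

    a* = argmin { |d_a − E(θ|D_n)| : a = max(k−1,1), k, min(k+1,K) }.

Two frequentist shortcuts bypass the Bayesian step: strict escalation until
the first DLT anywhere, and — once a dose has accumulated m₀ = 12
patients — a Wald-type interval for α on the logit scale,
logit(α) ± z_ξ·{m_k α(1−α)}^(−1/2) with ξ = 0.05, which escalates or
de-escalates with high confidence and terminates the trial for toxicity
when the lowest dose is clearly too toxic.  At the end of accrual the dose
the Bayesian rule would assign next is the MTD estimate.

Two posterior computations are available (`method=` of
`posterior_theta`): a fully analytic sequential recursion in which each
observation contributes its prior-predictive Bernoulli probability
(the default, and what the policy uses), and batch quadrature of the joint
(ρ₀, ρ₁) posterior over the triangle, cross-checked in the test suite
against a Monte-Carlo importance-sampling oracle.  See
`docs/methods.md` for the exact construction and its numerical choices.

## Worked example

Six candidate doses with target rate α = 0.2, scaled by (x + 1.5)/2 to
(0.015, 0.20, 0.405, 0.54, 0.75, 0.96).  After five all-clear cohorts the
trial fast-escalated to the top dose, where the first DLT occurred:

```
$ cat config.yaml
alpha: 0.2
scaled_doses: [0.015, 0.20, 0.405, 0.54, 0.75, 0.96]

$ bsa report --history history.csv --config config.yaml
Enrolled 18 patients, 1 DLTs; current dose index 6.
dose   scaled    n  DLT      p^  p^ mono
   1    0.015    3    0   0.000    0.000
   2    0.200    3    0   0.000    0.000
   3    0.405    3    0   0.000    0.000
   4    0.540    3    0   0.000    0.000
   5    0.750    3    0   0.000    0.000
   6    0.960    3    1   0.333    0.333
Decision: de-escalate -> dose 5 [bayes], posterior mean of theta = 0.728
```

The local model on (2/3, 1] holds six observations (three non-DLT at 0.75,
two non-DLT and one DLT at 0.96); their posterior mean of θ, 0.728, is
closer to dose five (0.75) than to dose six (0.96), so the design steps
down one level.  Replaying the full ten-cohort history gives the search
path 1, 2, 3, 4, 5, 6, 5, 5, 5, 5 and selects dose five as the MTD — the
dose whose true toxicity (0.24 under the example's tanh response curve) is
nearest the 20% target.

The same decisions are available from Python:

```python
from bsadesign import DoseGrid, PolicyConfig, TrialState, next_dose

grid = DoseGrid.from_levels([1, 2, 3, 4, 5], alpha=0.3)
state = TrialState(grid).add_cohort(1, (0, 0, 0))
print(next_dose(state, PolicyConfig(alpha=0.3)))
# Decision(action='escalate', next_k=2, rationale='fast-escalation', theta_mean=None)
```

Simulation of operating characteristics (percent correct selection,
allocation at/above the MTD, expected DLT count) for a five-dose scenario
with true toxicities (0.05, 0.15, 0.3, 0.45, 0.6) and α = 0.3:

```
$ bsa simulate --scenario scenario.csv --config config5.yaml \
      --reps 1000 --seed 7 --out results.json
$ bsa oc --results results.json
{"pcs": 66.3, "mtd_pct": 42.05, "above_mtd_pct": 8.76, "avg_dlt": 6.633,
 "n_replicates": 1000, "n_terminated": 0}
```

Read: 66.3% of 1000 simulated trials selected dose three (the true MTD),
42% of patients were treated at it, 8.8% above it, and a trial incurred
6.6 DLTs on average out of 30 patients.

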