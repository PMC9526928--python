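# Methods

This note records the model, the numerical choices, and the places where
the design space was genuinely open, in enough detail that every number
the package produces can be traced to a decision made here.

## Model

Doses are scaled into (0, 1] and sorted: d₁ < … < d_K.  The unit interval
is partitioned into `s` equal half-open pieces ((j−1)/s, j/s]; the piece
containing the current dose is found by the ceiling rule
v₀ = (⌈x·s⌉ − 1)/s, v₁ = ⌈x·s⌉/s, so a boundary dose x = j/s belongs to
the lower piece.  On the current piece the toxicity curve is approximated
by the line through (θ, α):

    F(x) = α + β(x − θ),   β > 0,

with θ the dose at which toxicity equals the target rate α.  Writing
ρ₀ = F(v₀), ρ₁ = F(v₁), the prior is uniform on the ordered triangle,
density 2·I(0 < ρ₀ < ρ₁ < 1) — monotonicity and nothing else.  For a
given θ the admissible slopes form (0, B(θ)) with

    B(θ) = min( α/(θ − v₀), (1 − α)/(v₁ − θ) ),

each constraint active only on its side of the subinterval.  The induced
prior marginal of θ, restricted to the dose domain, is ∝ B(θ)².

## Posterior computation

`posterior_theta` supports two routes.

**Sequential prior-predictive recursion (default).**  Each observation
(x, y) multiplies the running density of θ by its marginal Bernoulli
probability under the conditional slope prior p(β|θ) ∝ β on (0, B(θ)):

    m(1 | x, θ) = α + (2/3)·B(θ)·(x − θ),        m(0|x,θ) = 1 − m(1|x,θ),

since E[β|θ] = (2/3)B(θ).  Starting from the prior marginal ∝ B(θ)², the
posterior after n observations is the product of n closed-form factors —
no two-dimensional integration, and the update for a new observation is a
single multiplication (the recursion is order-independent).  This route
drives the transition policy.  On the published worked example it
reproduces the five printed posterior means to within 0.005 (relative
error ≤ 1%); see "Fidelity" below.

**Batch joint posterior (`method="grid"`).**  The binomial likelihood is
integrated over β ∈ (0, B(θ)) with the Jacobian factor β of the
(ρ₀, ρ₁) → (β, θ) change of variables, on a midpoint grid (default 400
nodes in β, 3200 in θ).  This is the exact marginal of the joint triangle
model; the test suite verifies it against an importance-sampling oracle
drawing 10⁶ points uniformly from the triangle, and against an
independent two-dimensional quadrature in (ρ₀, ρ₁) coordinates.

**Support of θ.**  Under the unconstrained triangle prior θ has ~θ⁻²
tails, so its mean over the real line diverges logarithmically; any
"cover most of the mass" cutoff would silently determine the estimate.
The support is therefore fixed to the dose domain (0, 1] (default), with
the current subinterval (v₀, v₁] as a stricter option.  With no data both
routes return the same prior push-forward through the same machinery.

**Degenerate cells.**  Grid cells where some F(x) is numerically 0 or 1
against the observed outcome receive zero posterior weight rather than
raising; the sequential factors are clipped away from 0 and 1 before the
logarithm.

**Fidelity to the published worked example.**  The five published
posterior means (0.729, 0.776, 0.760, 0.791, 0.814 after cohorts 6–10)
are reproduced as 0.728, 0.779, 0.764, 0.792, 0.810.  Neither the batch
triangle posterior truncated to (0, 1] (which gives 0.700, 0.749, 0.728,
0.761, 0.787) nor the variant restricted to ρ₀ < α < ρ₁ (0.784, 0.798,
0.784, 0.797, 0.810) matches the published trace; the sequential
recursion above is the closest reconstruction found among some thirty
candidate schemes, is exact at its natural constants (prior exponent 2,
predictive slope factor 2/3), and leaves every published transition
decision unchanged.  The original derivation is not publicly available in
full, so agreement beyond three decimal places is not claimed.

## Transition policy

Order of evaluation per completed cohort, first match wins:

1. **Fast escalation** — if no DLT has occurred anywhere and a higher dose
   exists, move up one level.
2. **Wald shortcut** — if the current dose k holds m_k ≥ m₀ patients
   (m₀ = 12), compare its monotonicity-adjusted DLT frequency with the
   interval expit( logit(α) ∓ z_ξ·{m_k α(1−α)}^(−1/2) ), ξ = 0.05.
   Below the interval: escalate (stay if already at the top dose); above:
   de-escalate, or terminate the trial for toxicity when k = 1.  The
   check applies to the current dose only.
3. **Bayesian step** — every observation whose dose lies in the current
   subinterval (regardless of when it was collected) enters the
   posterior; the next dose is the neighbour in {k−1, k, k+1} closest to
   E(θ|D), ties broken toward the lower dose (safety-first; a tie is
   measure-zero anyway).

The monotonicity adjustment is the design's own two-point rule: scanning
upward, a frequency below its predecessor is replaced, together with the
predecessor, by their average.  This is deliberately *not* full pooled
isotonic regression; with more than one violation the output can remain
non-monotone, exactly as the stated rule implies.  Only the current
dose's adjusted value is consumed.

**MTD selection.**  At the end of accrual the MTD is the dose the
*Bayesian* rule would assign next.  The Wald shortcut is excluded here on
purpose: at typical final states (e.g. 1 DLT among 15 patients at the
settled dose with α = 0.2) the shortcut would recommend the next-higher
dose, contradicting the published example's selection; the shortcuts
exist to speed up transitions, not to define the estimate.  The
toxicity-termination check is still honoured: a trial whose final state
shows the lowest dose clearly too toxic declares no MTD.

**Coherence.**  When consecutive cohorts sit at the same dose, a DLT
cannot trigger escalation and a non-DLT cannot trigger de-escalation:
a "stay" decision means E(θ|D) was inside the midpoint band around the
current dose, and the posterior mean responds monotonically to each
outcome (non-DLT up, DLT down — a tested invariant).  Immediately after
a dose *move* the guarantee does not hold in general: the subinterval
and the neighbour set change, and the previous argmin was capped at one
step, so the estimate may sit beyond the midpoint band before the
outcome arrives.  Simulation puts such boundary steps at roughly 5% of
transitions; the test suite asserts the repeated-dose property
exhaustively and makes no claim about move steps.

## Historical borrowing (hBSA)

Elicited prior toxicity probabilities q₁ < … < q_K (a skeleton) and
per-dose prior effective sample sizes n₀ₖ become pseudo-observations:
aₖ = round(n₀ₖ·qₖ) DLTs and bₖ = round(n₀ₖ·(1−qₖ)) non-DLTs at dose k
(half rounds up; aₖ + bₖ may differ from n₀ₖ by one).  They enter the
likelihood exactly like real observations at that dose.  The default
n₀ₖ for a vague prior is the largest integer in [N/(3K), N/(2K)]
(N the maximum sample size); an empty interval raises with instructions
to choose manually.  All n₀ₖ = 0 reproduces plain BSA decisions
identically (a tested invariant).

## Simulator and scenario generators

Trials draw patient-level Bernoulli outcomes; each replicate has its own
generator spawned from the root seed via `SeedSequence`, so replicate
sets are bitwise reproducible and order-independent.  Cohort sizes are
fixed (default 3), scheduled, or drawn uniformly from {1, 2, 3}; the
final cohort is capped at the patients remaining under max_n = 30.

Metrics over replicates: PCS (percent selecting the true MTD, defined as
argmin |pₖ − α| with ties toward the lower dose), MTD% and above-MTD%
(per-trial allocation fractions, averaged; denominator is patients
actually enrolled), and mean DLT count.  Early-terminated replicates
count as incorrect selections and keep their enrolled patients in the
allocation metrics; their count is reported separately so other
conventions can be tabulated.

**Random scenarios.**  The published evaluation uses a pseudo-uniform
scenario algorithm whose exact construction is not reproduced here.  The
package's generator: p at the MTD ~ U(α−0.05, α+0.05); adjacent gaps
~ U(0.05, 0.3); remaining doses are sorted uniform draws in the leftover
range on each side; draws that break monotonicity, leave (0, 1), or move
the implied MTD are rejected and resampled (cap 1000).  A literal
"increasing increments outward" construction was tried first and is
frequently infeasible below a late MTD, hence the sorted-uniform tails.
This generator is an approximation: comparisons of averaged operating
characteristics against published values are tolerance-based, and in our
measurement it yields somewhat easier scenario banks (average PCS a few
points higher than published for the same design).

**Fixed representative bank.**  The published 20-scenario table lives in
supplementary material that is not distributed here;
`synthetic_fixed_scenarios` provides a deterministic synthetic stand-in
(MTD rotating over all K positions, two adjacent-gap levels 0.12/0.22,
geometric tails toward 0.97 above and toward 0 below).  Operating
characteristics on this bank are *not* comparable to the published
averages scenario-for-scenario; the acceptance-level comparison against
the published 62.5% average records this honestly rather than matching.

**What the simulator does not emulate.**  Accrual times, patient
heterogeneity, dose-outcome latency, and non-monotone toxicity are out of
scope; passing tests say nothing about those aspects of real trials.

## Problem sizes used in the test suite

The worked-example checks are exact replays (30 patients).  Property
suites use 10⁶-draw oracles and a few dozen randomized states.  The
operating-characteristic checks run 500 replicates per fixed scenario
and 100 random scenarios × 50 replicates — large enough that Monte-Carlo
error (≈1–2 percentage points on an average PCS) is well inside the
±3-point bands used, small enough to finish in well under two minutes
each.  The long-run consistency check uses cohort size 1, 300 patients,
200 trials, Wald shortcuts disabled by m₀ = 10⁹, and a coarser posterior
grid (resolution 64), and requires the modal late-path dose to be the
true MTD in ≥90% of trials.

## Known limitations

- The sequential posterior is a reconstruction; see "Fidelity" above.
- Coherence is guaranteed (and asserted) only at repeated doses.
- The pseudo-uniform scenario generator is an approximation, so averaged
  operating characteristics differ from published values by more than
  Monte-Carlo noise.
- The two-point monotonicity rule can leave non-adjacent violations in
  place by design.
- No support for drug combinations, covariates, or non-monotone
  (optimal-biological-dose) settings.
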