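# Methods

## The model

Two social foragers — a *dominant* and a *subordinate* — hold integer
energy reserves x ∈ {0, 1, …, S}. State 0 is death by starvation; S is the
gut/fat ceiling. Time is a sequence of identical periods. At the start of a
period each individual, knowing both reserve levels, commits to one of two
actions for the whole period: **rest** or **forage**.

Each action draws an energetic cost c from a discretized normal
distribution (mean μ_R or μ_F, s.d. σ_R or σ_F, truncated to
[0, c_max]); foraging additionally draws a gain g (mean ν, s.d. ψ,
truncated to [0, g_max]). Predation is the other risk channel: resting
carries per-period predation probability m_R, foraging together m_T,
foraging alone m_A, with m_R ≤ m_T ≤ m_A (group foraging dilutes risk;
lone foraging is most exposed). Reserves update as

    x' = Λ(x − c + g·[forage] − D),     Λ(y) = min(S, max(y, 0)),

where D is the *interference cost*: an extra energetic charge paid **only
by the subordinate**, depending on the realized action pair — D_dUsV is
paid when the dominant does U and the subordinate does V (U, V ∈ {R, F}).
The four costs D_dRsR, D_dFsR, D_dRsF, D_dFsF are the experimental factors;
everything else is identical between the two types.

Fitness is the probability of being alive at a distant horizon. H, the
one-period survival recursion for a focal individual in a live pair, is

    H = (1 − m_focal) · E[ continuation at the chopped next states ],

where the expectation runs over both individuals' cost/gain draws; if the
colleague is predated (probability m_colleague) or starves (lands on 0),
the focal's continuation switches to the *lone-survivor* value function V,
a single-individual rest/forage control problem with risks m_R / m_A, the
same cost/gain distributions, and no interference costs.

## Strategy solution

A strategy profile π assigns each type a forage probability at every pair
state (x_d, x_s), plus lone policies. Given a candidate π, each type's
best response is computed by backward induction: at every state the two
action values are combined through an **error-smoothed choice** — a softmax
at temperature k,

    P(forage) = 1 / (1 + exp((v_rest − v_forage)/k)),

so the better action is chosen with probability near 1 (k = 1e-7 makes
decisions effectively deterministic with exact ties split evenly). Backward
steps are iterated until the induced policy stops changing (*strong
backwards convergence*), which also erases the arbitrary terminal reward; a
state-proportional and an alive-indicator terminal reward give the same
converged policy (verified in the test-suite).

The ESS proxy is the fixed point of damped best-response iteration,

    π ← (1 − λ)·π + λ·BR(π),    λ = 0.1,

i.e. each update is weighted strongly towards the previous candidate.
Damped mixing operates directly on forage probabilities.

### Numerical choices

* **Scale renormalization.** Raw survival-to-horizon values shrink
  geometrically as the horizon recedes, and the paired and lone values
  shrink at different per-period rates. The lone problem is converged first
  as a normalized eigenproblem (per-period survival factor λ_V); the pair
  iteration renormalizes W by its maximum each step and carries the
  lone/paired scale ratio ρ forward analytically. The softmax temperature k
  therefore acts on max-normalized values.
* **Anti-periodicity mixing.** Point-mass cost/gain distributions make the
  state dynamics deterministic, hence periodic, and pure power iteration
  then cycles. A fraction (0.1) of the previous iterate is mixed into every
  normalized value-iteration step; this breaks eigenvalue-modulus ties
  without moving the fixed point.
* **Policy plateau acceptance.** Two effects bound the achievable policy
  resolution: the softmax slope 1/k amplifies ~1e-12 floating-point noise in
  values to ~1e-5 probability wiggle at near-indifferent states, and the
  scale ratio ρ drifts towards its backward-time limit at a per-step rate
  λ_V/λ_W ≈ 1 − O(predation risk), i.e. imperceptibly. Backward iterations
  are accepted once their residual plateaus below 1e-3 with converged value
  surfaces — operationally the same stopping rule as iterating a
  long-but-finite horizon until the policy stops visibly changing.
* **Mixed equilibria and λ annealing.** At states where the ESS is a
  genuinely mixed strategy, the sharp best response flips between 0 and 1 as
  the candidate crosses the indifference probability, so damped iteration
  orbits that probability with amplitude ~λ. When the damping residual
  plateaus above the acceptance floor, λ is quartered (down to 2.5e-4),
  shrinking the orbit until the candidate pins the mixed probability. At
  such states the reported best-response deviation (`br_residual`) is
  inherently O(1); it is reported, never silently enforced.
* **Tolerances and caps.** Backward residual 1e-9 (target), ESS damping
  residual 1e-8 (target), with the plateau floors above; caps 10,000
  backward steps, 5,000 damping iterations; stationary forward iteration to
  L1 < 1e-12 (cap 200,000). All configurable per run.

## Stationary analysis

Given a converged policy, the pair's reserves form a Markov chain on
{1..S}² whose mass leaks through predation and starvation. The *stable
population* conditions on both members being alive: forward iteration with
global renormalization each period, d ← normalize(T·d). Summary statistics
are taken under this conditioned distribution:

* marginal foraging proportions per type and the four paired-behaviour
  proportions p_FF, p_FR, p_RF, p_RR (F/R in dominant-then-subordinate
  order);
* the **synchrony coefficient** (p_RR·p_FF − p_RF·p_FR) /
  (p_RR·p_FF + p_RF·p_FR), +1 for acting only together, −1 for only
  alternating, undefined (NaN) when one behaviour never occurs;
* one-step **behaviour repeat probabilities** per type, conditioned on the
  pair surviving the step;
* the **half-change time** of paired behaviour: the first horizon t at
  which the fraction of surviving pairs that repeated their initial action
  pair through every period drops to ≤ 0.5, linearly interpolated between
  integer horizons (∞-flagged if never, e.g. deterministic immortal
  resters). A crossing time is implemented, taking the "periods until at
  least 50 % changed" reading of this statistic; tracking starts from the
  stationary distribution, not from a burn-in;
* mean reserves per type;
* the **heaviest-individual sojourn**: the mean number of consecutive
  periods with x_d > x_s (resp. x_s > x_d), by the renewal identity
  mean sojourn = π(E)/(per-period exit flux from E), where exiting includes
  ties, reversals and the pair's death. Ties end runs for both types.
* an **independence-of-action statistic**: the stationary-mass-weighted
  disagreement between the focal's smoothed action and the action it would
  take against the colleague collapsed to its conditional-mean state,
  averaged over types. This is a documented stand-in for the S statistic of
  the original independence-of-action analysis, whose closed form is not
  restated in the source this model derives from; the implementation is
  pluggable (`s_statistic(..., method=...)`) so the original formula can be
  dropped in. Qualitatively, 0 = the policy ignores the colleague's state,
  larger = more state-interdependence; quantitative comparison with
  published S values requires the original formula.

## Parameter generation and the factorial experiment

A parameter set derives from six independent uniform(0, 1) draws:

    m_A = exp(−25 r₁)      m_T = m_A(1 − r₃²)     m_R = m_T(1 − r₂²)
    ν = 4 r₆ + 1           μ_F = r₄ ν             μ_R = r₅ μ_F

with fixed S = 40, c_max = 4, g_max = 6, ψ = σ_F = σ_R = √0.5, k = 1e-7,
λ = 0.1. The construction forces m_R ≤ m_T ≤ m_A and μ_R ≤ μ_F ≤ ν. Note
μ_F may exceed c_max (ν ranges up to 5); the cost distribution's support is
clamped to [0, c_max] regardless, so such draws simply concentrate cost
mass at c_max. Distribution bins are integer-centred ([v−½, v+½)), tails
folded into the end bins, then renormalized; gains start at 0 (a forager
may find nothing).

A sweep crosses each parameter set with all 2⁴ = 16 scenarios in which each
interference cost is 0 or 1 state units. The six draws are shared across a
set's sixteen scenarios, so cost effects are compared within parameter sets
— this pairing is what gives the factorial ANOVA its sensitivity.

**Problem sizes.** The desk-scale profile used by the test-suite and the
acceptance script runs S = 20 with 20 parameter sets; the full exploration
profile (S = 40, 1,000 sets) is available behind `--scale full`. Desk scale
preserves every qualitative contrast (the directional effect of each cost,
symmetry, synchrony) while keeping a complete run in minutes; published
full-scale F values are not reproduced quantitatively, and the original
exploration used an unseeded generator, so reproduction is directional by
design.

## Statistical analysis

For each summary statistic, a fully crossed fixed-effects ANOVA over the
four binary costs yields 15 F values (4 main effects, 6 two-way, 4
three-way, 1 four-way; each 1 numerator d.f.). Because the response
distributions violate ANOVA assumptions, critical values are calibrated by
**free permutation**: the response vector is permuted without replacement
against the intact factor design (50,000 times at full scale; 5,000 in the
calibration tests), the 15 F values harvested per permutation, and each
term's critical value set to the 95 % empirical quantile. On a balanced
design the effect-coded model columns are orthogonal, so sequential and
classical sums of squares coincide; with dropped (failed) runs the
sequential decomposition in the natural term order is used. Significant
terms are labelled '+' / '−' when every involved factor's simple effect
(within every combination of the other involved factors) points the same
way, '*' otherwise — an operationalization of "both terms leading to an
increase" for interactions; 'NS' below the critical value.

Null calibration: with i.i.d. noise responses on a balanced 1,600-row
table, each term's 95 % permutation critical F lies near the parametric
F(1, 1584) value 3.85, and the empirical type-I rate against permutation
critical values is ~5 %.

## What the synthetic experiments do and do not show

All inputs are model-generated; there is no field data. The random
parameter sweep probes the *mechanism* — how behaviour-contingent
subordinate costs reshape both players' foraging, synchrony and reserves —
across a broad, reproducible parameter population. Passing tests show the
dynamic-programming machinery is exact (tiny games match exhaustive
enumeration to 1e-12), that the chain analysis is self-consistent, and that
directional cost effects are robust at reduced scale. They do not show that
any particular parameter set describes a real forager, nor reproduce
published full-scale F tables (unseeded originals, 1,000 × 16 runs).

## Known limitations

* Exactly two players and two actions; no within-period switching, no pair
  re-formation after a death, no demographic replacement.
* The interference cost is integer-rounded onto the state grid (the
  factorial uses 0/1 only).
* The independence-of-action statistic is a stand-in (see above).
* `br_residual` is not a convergence guarantee at mixed-equilibrium states
  (see λ annealing above).
* The error-making functional form (softmax) is a documented choice; the
  smoothing acts on max-normalized fitness values.
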