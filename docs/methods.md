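# Methods

## Measurement model

All scoring uses Masters' partial credit model (PCM): for an item with step
thresholds δ₁…δ_m, the probability of category k at ability θ is
exp(Σ_{j≤k}(θ − δ_j)) normalized over k = 0…m, with a common discrimination
across items (a pure Rasch family model — no 2PL/GPCM generalization, no
graded-response or rating-scale variants). The step threshold δ_j is the
ability at which categories j−1 and j are equally likely. Item information
equals the category-score variance at θ and also the derivative of the
expected score, an identity the test suite checks by central differences.
Probabilities are computed with max-subtraction before exponentiation, so
the contract (a normalized probability vector) holds at any finite θ.

## The bundled item bank

The 24-item pool ships with published item difficulties (−2.20 to 2.17
logits) and category counts (2–4 categories, i.e. 1–3 score steps). Only the
overall difficulty and the step count are published, so step thresholds are
generated by a **symmetric-spread rule**: thresholds centred on the item
difficulty with fixed spacing (default 1.0 logit; 1 step → [δ], 2 steps →
[δ∓0.5], 3 steps → [δ−1, δ, δ+1]). This preserves the published difficulty
as the threshold mean; the spacing is a constructor argument for users with
real calibrations. Category scores run 0…n_steps; no per-category weights
are applied. Skip (conditional-path) items carry a route map from answer
category to next item and are excluded from the adaptive pool; the bundled
routing bank's skip items are synthetic demonstrations (flagged as such in
their text), since the real branching questions' calibrations are not
published.

## Person estimation

* **MLE**: safeguarded Newton on the score equation; steps clamped to 1.0
  logit per iteration, estimate confined to ±4.0 logits (`theta_bound`),
  convergence when the proposed step < 1e-5, at most 50 iterations, warm
  start from the previous provisional estimate inside a session.
* **Extreme vectors** (all-minimum / all-maximum) have no finite maximizer
  and are clamped to ±`theta_bound` with `at_bound` set. Clamping was chosen
  over score adjustment or Warm's weighted likelihood for its simple,
  flaggable contract; consequently bounded estimates are included, flagged,
  in all downstream correlations.
* **SEM** = 1/√(total information at θ̂). **Person reliability** defaults to
  the stopping form (1 − SEM)², with (1 − SEM) clipped to [0, 1] before
  squaring so that SEM > 1 yields 0 rather than curving back upward; the
  conventional 1 − SEM²/σ²_θ form is available via
  `reliability_from_sem(..., form="conventional")`. Note the default form is
  far stricter: 0.80 requires SEM ≈ 0.106, i.e. test information ≈ 89 —
  unreachable on a 24-item pool — so in practice the residual rule, not the
  reliability rule, terminates sessions.
* **Fit**: with standardized residuals z_i = (x_i − E_i)/√W_i, outfit MNSQ is
  mean(z_i²) and infit MNSQ is Σ(x_i − E_i)²/ΣW_i; both ≈ 1 under the model.
  Outfit ≥ 2.0 flags a possibly aberrant pattern (careless/random
  responding). Items with information below 1e-12 at the evaluation point
  are dropped from the sums with a warning. Item-level MNSQs pool person
  residuals per item; on simulated cohorts all 24 items fall inside the
  (0.5, 1.5) unidimensionality window.

## Adaptive administration

The first item is drawn uniformly at random from the pool (a deliberate
exposure-spreading choice; information-optimal first items are a known
alternative). Each subsequent item maximizes information at the provisional
ability (0.0 before any response; ties broken by lowest item id). Stopping
rules are OR-combined with precedence:

1. **reliability** ≥ 0.80 (ungated by the minimum-item count),
2. **residual**: mean |Δθ̂| over the last 5 updates < 0.05 logits, allowed
   only after ≥ 5 items (and needing 6 ability values),
3. **pool exhausted / max-items cap**.

Session diagnostics mirror a live administration trace: the residual above
and the Pearson correlation between the last five ability values and their
step numbers (0 by convention for a flat, zero-variance window) — a flat
trend signals convergence. Under these defaults and the bundled bank,
sessions average ≈ 20 of 24 items: late-session ability updates shrink only
like 1/(test information), so the 0.05-logit residual rule fires late. No
rule parameter was adjusted to force shorter tests.

Unanswered pool items can be filled in afterwards with their expected score
at the final ability, rounded half-up and clipped to the category range
(deterministic, documented convention; at a dichotomous item's difficulty
the 0.5 expectation rounds to 1). This recovers a complete response record —
the motivation for imputation in practice is item-level quality reporting
from short sessions.

## Scenario study

One simulated cohort feeds three scoring scenarios: AAI (all 24 items),
RSM (a fresh uniform 12-item subset per person — per-person draws are the
stricter reading of "randomized selection"), and CAT (each person's
pre-simulated responses serve as the answer oracle). CAT final scores use
administered items only by default; `cat_scoring="imputed"` completes the
pool by expected-response imputation and re-estimates, which is the variant
under which CAT accuracy approaches the full form. Raw summation scores are
computed over exactly the items each scenario used; note that per-person RSM
subsets make RSM sums non-comparable across persons, attenuating the
within-RSM sum/estimate correlation (≈ 0.92 at n = 1000) relative to AAI's
(≈ 0.99), though it still exceeds every between-counterpart correlation.

## Synthetic cohorts: what they do and do not emulate

`simulate_cohort` draws abilities i.i.d. N(0, 1) (configurable) and
responses by inverse-CDF sampling at each person's true ability, with one
deterministic substream per person (`default_rng([seed, i])`) so person i is
invariant to cohort size. The generator emulates model-consistent responding
to the pool items only. It does **not** emulate: the negatively skewed,
ceiling-prone ability distributions typical of real satisfaction surveys;
traversal probabilities of the skip items outside the pool (so full-form
"item length" including non-pool items is out of scope); misfitting persons,
missing data, or multidimensionality. Passing tests therefore demonstrate
engine correctness under the model, not robustness to real-data violations.

A consequence worth stating plainly: with symmetric spacing-1.0 thresholds
the pool's expected total information over N(0, 1) abilities is ≈ 7.9
(E[SEM²] ≈ 0.127), which caps the attainable correlation between full-form
MLE estimates and true abilities at ≈ 0.94. Higher values require a more
informative threshold structure (narrower spacing or more categories), not a
different estimator.

## Problem sizes and tolerances

The test suite runs the headline study at 1000 persons (one seeded run), the
estimator-vs-oracle comparison on 500 random response vectors against a
0.001-step likelihood grid on [−6, 6] (agreement within 0.002 required,
interior solutions only), Monte-Carlo fit checks at 500–1000 persons, and
the CAT-vs-RSM ordering check across 50 seeds at 150 persons per seed —
sizes chosen to give sampling error well inside the asserted tolerances
while keeping the suite quick. The acceptance script uses 1000 persons, the
study's published cohort size.
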