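# pcmcat

Adaptive shortening of long patient-experience questionnaires with the Rasch
partial credit model (PCM).

Inpatient-experience surveys such as the UK NHS adult inpatient questionnaire
ask every respondent all 70 questions, which burdens patients and depresses
response rates. `pcmcat` implements the alternative: item-response-theory
computerized adaptive testing (CAT). Given a calibrated item bank, the engine
asks one question at a time, always picking the question that is most
informative about the respondent's current ability estimate, and stops as soon
as the measure is precise or stable enough — typically well before the full
form is exhausted, with little loss of measurement accuracy.

The package is aimed at psychometricians and survey methodologists who want to
simulate, evaluate, or administer PCM-based adaptive questionnaires:

* an item-bank model with file I/O (CSV/JSON), bundled with a 24-item
  inpatient-experience pool (published difficulties and category counts), and
  conditional-path ("skip item") routing metadata;
* PCM category probabilities, score moments, and seeded cohort simulation;
* maximum-likelihood person measurement with standard errors, person
  reliability, infit/outfit mean-square fit statistics, and an aberrant
  response flag (outfit ≥ 2.0);
* a CAT loop (random first item, maximum-information selection,
  reliability/stability stop rules) plus expected-response imputation of the
  items a short session never asked;
* a three-scenario simulation study — answering all items (AAI), a random
  12-item subset (RSM), and CAT — with a correlation/efficiency report.

## Model

For an item with step thresholds δ₁…δ_m (logits), a person at ability θ
scores category k ∈ {0,…,m} with probability

    P(X = k | θ) = exp( Σ_{j≤k} (θ − δ_j) ) / Σ_h exp( Σ_{j≤h} (θ − δ_j) )

(empty sum = 0; all items share one discrimination). Item information is the
score variance at θ; test information adds over items. The person measure θ̂
solves Σᵢ (xᵢ − Eᵢ(θ)) = 0 by safeguarded Newton iteration, with
SEM = 1/√(Σᵢ Wᵢ(θ̂)) and person reliability (1 − SEM)² (the engine's stopping
form; the conventional 1 − SEM²/σ²_θ is available as a switch). A session
stops when reliability reaches 0.80, or when the mean of the last five
ability changes falls below 0.05 logits after at least 5 items, or when the
pool runs out.

## Worked example

Administer one adaptive session to a simulated respondent with true ability
0.8 logits, then run the three-scenario comparison on 100 simulated persons:

```sh
$ pcmcat run --seed 7 --mode oracle --theta 0.8
items administered : 24
stop reason        : pool_exhausted
theta (logits)     : +0.539
SEM (logits)       : 0.354
reliability        : 0.418
outfit MNSQ        : 0.96
```

This respondent's ability trace never settled below the 0.05-logit residual
threshold, so the session used the whole 24-item pool and ended with a
measure of 0.54 ± 0.35 logits; outfit 0.96 ≈ 1 means the response pattern is
model-consistent (values ≥ 2.0 would flag aberrant responding).

```sh
$ pcmcat compare --n 100 --seed 3 --out report/
correlations with true ability:
  cat_est : 0.927
  aai_est : 0.932
  rsm_est : 0.866
mean items administered:
  AAI : 24.00
  RSM : 12.00
  CAT : 20.22
```

CAT matched the full 24-item form's accuracy (r = .93 with the generating
abilities for both) while asking four fewer questions on average, and beat
the random 12-item short form (r = .87) by a wide margin. `report/` holds
the per-person table, the full correlation matrix with means/SDs, and a JSON
run log. Interactive administration (`--mode interactive`) prompts one
question per screen, mirroring a mobile survey flow; skip items are followed
via their route fields (see `pcmcat.route_next_item`).

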