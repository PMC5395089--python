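# Methods

## Trial model

A trial enrolls `n` patients sequentially on `K` arms with immediate
binary outcomes.  Patient *i*'s assignment Δᵢ is drawn from an allocation
rule's probability vector πᵢ = f(d_{i−1}), a deterministic function of the
full history prefix d_{i−1} (assignments and outcomes of patients
1…i−1); the outcome is Bernoulli(p_{Δᵢ}).  The likelihood factorizes into
an outcome part depending only on the per-arm counts and a design part
Πᵢ π_{i,Δᵢ} that carries no information about `p`, so the MLE is the
per-arm responder fraction regardless of the rule.  What the rule *does*
change is the joint law of (n(k), p̂ₖ): whenever the realized arm size is
positively correlated with the arm's estimate,

    Bias(p̂_k) = −Cov(n(k), p̂_k) / E[n(k)]

forces the MLE below the truth.  All estimators and diagnostics in the
package are organized around this identity.

Determinism of the rules is a hard requirement, not a convenience: the
Rao–Blackwellized estimators re-evaluate the rule along permuted
histories, and any hidden randomness would change the conditional
distribution they integrate over.  Rules therefore expose
`initial_state` / `update_state` / `probs_for_state`, with the state a
flat tuple of per-arm success/failure counts (all shipped rules depend on
the prefix only through those counts; the incremental API is what makes
the swap sampler's partial re-walks affordable).

## Allocation rules

**Fixed randomization** (`fr`): constant probabilities, default 1/K.

**Randomized play-the-winner** (`rpw`): a two-arm urn starting with one
ball per arm (configurable); each response adds a same-arm ball, each
failure an opposite-arm ball, and patient *i*'s arm-1 probability is the
urn proportion (1 + S₁ + F₂)/(i + 1).  By default the first two patients
are forced onto different arms so both arms are always occupied and every
estimator is defined: patient 1 is a coin flip, patient 2
deterministically receives the other arm.

*Weighting under the forced split.*  The forced split randomizes the
first-two-patient **pair**; patient 2's conditional assignment
probability given patient 1 is 0/1, but each of the two patients has
marginal probability 1/2 of either arm.  Inverse-probability estimators
must weight those patients by the marginal 1/2: weighting by the
degenerate conditional value 1 silently biases HT by −p_k/(2n) (the arm
that cannot be assigned at step 2 contributes nothing in half the
trials).  Trial histories therefore record the 1/2 weighting vector at
step 2 (`recorded_overrides`), while simulation and the permutation
likelihood keep the true conditional probabilities — in particular,
orderings that put the first two patients on the same arm have
probability zero and never enter the conditioning set.

**Bayesian adaptive randomization** (`bayes_ar`): arm 0 is a control;
each experimental arm k ∈ 1…K carries a Beta(α₀+sₖ, β₀+fₖ) posterior
(default prior Beta(1, 1)).  Experimental arms are weighted by
Pr(p_k > p₀ | data)^{γ_i}, normalized among themselves; the control
receives (1/K)·exp{η_i·(max_k n_k − n₀)}; the full (K+1)-vector is then
renormalized (the two displayed blocks do not otherwise sum to one).
Schedules γ_i = 10(i/n)^{1.75} and η_i = 0.25(i/n): early patients are
split almost evenly, late patients concentrate on the best-looking arm,
and the control is pulled toward the size of the largest experimental arm
to protect the power of the final comparison.  Defaults n = 140 and
K = 3 match the published glioblastoma-style configuration.  The
posterior superiority probability is computed by the closed-form finite
sum over the integer shape parameter, in log space (a seeded Monte Carlo
mode exists solely to cross-validate it); an exact posterior keeps the
rule a pure function of the history, which the permutation estimators
require.  No truncation of extreme allocation probabilities is applied:
the probability of a clearly inferior arm genuinely decays toward zero,
which is exactly the regime where the estimator comparison is
interesting.

## Estimators

Given a history with recorded weights πᵢ (the probability of the arm the
patient actually received):

* **MLE** p̂ₖ = Σ δ y / n(k); NaN (flagged) for unoccupied arms.
* **HT** p̂ₖ = (1/n) Σ δ y / πᵢ; exactly unbiased, support [0, n·max 1/π];
  0 for unoccupied arms.
* **IPW** — the solution of Σ (δ/πᵢ)(y − p) = 0, i.e. the 1/π-weighted
  mean of the arm's outcomes; always in [0, 1], slightly biased in finite
  samples, NaN for unoccupied arms.
* **RBHT** E[p̂_HT | Sₙ], with Sₙ the per-arm patient and responder
  counts.  The conditioning set Ω* is the set of column reorderings of
  the observed (arm, outcome) matrix; each ordering d* is weighted by
  Π π*ᵢ, the product of allocation probabilities recomputed under the
  rule along that ordering.  Unbiasedness is inherited from HT and the
  Rao–Blackwell theorem guarantees no larger variance.  All arms are
  estimated from the same integration pass, so linear contrasts such as
  p̂ₖ − p̂₀ remain unbiased.

Integration back ends:

* `rbht_exhaustive` — enumerate distinct multiset permutations (identical
  columns would otherwise repeat; every distinct ordering of a shared
  column multiset has the same multiplicity n!/Π(repeats)!, so
  enumerating each once leaves the weighted average unchanged).  Refused
  above n = 12 (factorial growth).
* `rbht_rejection` — draw trials under the rule at p_sim (default the
  observed MLE, the efficient choice; any p with full support targets the
  same conditional law because the outcome part of the likelihood is
  constant on Ω*) and keep exact matches of the full per-arm statistic.
* `rbht_mh` — a Metropolis–Hastings chain started at the observed
  history; each step proposes swapping the (arm, outcome) columns of two
  uniformly chosen positions (with replacement; equal or identical picks
  are lazy self-moves) and accepts with min(1, Π π*new/Π π*old) in log
  space.  Orderings the rule cannot produce (−∞ log product) are always
  rejected.  Only positions between the swap points are re-walked.  The
  estimate is the unweighted mean of per-arm HT values over post-burn-in,
  thinned states; its Monte Carlo SE uses 20-batch means to absorb
  autocorrelation.  Defaults M = 10,000, burn-in 1,000, thinning 1,
  validated against the exhaustive back end on small trials.

*Chain length and heavy tails.*  For designs whose allocation probability
for a poor arm decays toward zero, the conditional distribution of HT is
heavy-tailed: the chain occasionally visits an ordering that places one
of that arm's responses at a near-zero-probability position,
contributing a single enormous 1/π term.  The chain mean remains correct
but converges slowly; short chains (M ≈ 2,000) were observed to inflate
the RBHT's empirical MSE by orders of magnitude on such arms, an effect
that disappears at the default M = 10,000.  The batch-means SE reported
with every estimate is the guard rail: treat estimates whose SE is
comparable to the estimate itself as unconverged and lengthen the chain.

## Comparator two-stage designs

* **Futility-stop single-arm design**: 13 patients at stage 1, continue
  to 34 only on ≥ 4 responders, reject the null p₀ = 0.2 when total
  responders exceed 9 (i.e. ≥ 10).  All operating characteristics —
  rejection probability, E[p̂], bias, E[n], Cov(n, p̂) — are exact
  binomial convolutions, and the bias–covariance identity holds to
  machine precision in the enumeration.  The rejection threshold follows
  the convention that the critical count 9 must be exceeded; taken
  literally as "reject on ≥ 9" the design's exact level would be 13.3%,
  contradicting its nominal 10% (the attained level with the implemented
  default is 8.44%).  Stage-1 stops estimate p by x₁/13 — the MLE on the
  patients actually enrolled.
* **Sample-size re-estimation**: two arms of 100; interim
  z₁ = θ̂·√(100/2) with θ̂ = 2[asin√p̂₁ − asin√p̂₂]; if z₁ ∈ (1, 2.74)
  each arm is enlarged to ⌈((1.92+0.84)²/z₁² − 1)·100⌉ (never below the
  100 already enrolled — patients cannot be removed), otherwise the trial
  stops.  Final estimates pool both stages.  Evaluated by vectorized
  simulation; bias and Cov(n_total, p̂₁−p̂₂) carry 20-batch-means SEs.
  The printed resizing constant 1.92 (not the conventional 1.96) and the
  formula's bracketing are both taken as given, with config options
  (`z_alpha`, `grouping`) for the alternatives.  Because the window is
  one-sided in z₁, only trials with a *positive* interim difference
  enlarge; at equal arms this makes Cov(n, p̂₁−p̂₂) positive and the bias
  slightly negative, while across the studied effect range
  (p₁ ∈ (0.45, 0.65) vs p₂ = 0.3) the covariance is negative and the
  bias positive.  No final rejection rule is modelled — only the
  estimation behaviour.

## Simulation and evaluation harness

One root seed per scenario; replicate r uses the substream seeded by
(root, r), so any single trial can be regenerated in isolation.
Conditional simulation matches the full per-arm statistic, not a
coarsening.  The evaluation harness reports per-arm/per-method mean,
bias, MSE and MC SE, plus E[n(k)] and Cov(n(k), p̂ₖ); replicates where an
arm is empty are excluded per-arm with the count reported (the forced
split makes this a non-event for two-arm urn trials).
`bias_covariance_check` estimates both sides of the identity from the
same replicates and flags agreement at three batch-means SEs of the
difference.

## Default problem sizes

Chosen as desk-scale runs whose Monte Carlo SEs are small enough to
resolve the effects under study, and used by the end-to-end tests:
50,000 replicates for the two-arm urn unbiasedness checks (n = 25);
20,000 per grid cell for the sign-structure grid; 100,000 for the
re-estimation design; 5,000 for the variance-reduction comparison
(chain M = 1,000 there — variance margins are wide); 500 replicates of
the 140-patient multi-arm design, with M = 4,000 chain iterations per
replicate in the batch comparison (single-history estimation keeps the
M = 10,000 default).
The scenario grids (`RPW_SCENARIOS`, `BAYES_AR_SCENARIOS`) are documented
reconstructions — the parameter constellations behind the original
figures are not published — so only signs and orderings (which estimator
dominates which) should be compared, not bias magnitudes.

## What the generator does and does not emulate

Simulated trials have immediate binary responses, perfect adherence to
the allocation rule, and no covariates, accrual waves or patient drift.
Passing tests therefore demonstrate the estimators' properties under the
designs' own assumptions; they say nothing about delayed outcomes,
operational unblinding effects, or time-trending populations, all of
which are out of scope.

## Known limitations

* Exhaustive integration is factorial; above n = 12 only the sampling
  back ends apply, and their Monte Carlo error is the user's
  responsibility (watch the reported SEs and acceptance rates).
* The exact beta-superiority sum requires an integer first shape
  parameter (integer prior α); non-integer priors fall back to the
  general log-gamma path and remain exact only up to quadrature of that
  sum.
* IPW and the HT family are undefined/degenerate on arms a rule can
  starve; the multi-arm design's near-zero allocation probabilities make
  IPW unstable by construction, which is visible in its MSE.
* In the shipped multi-arm reconstructions the Rao–Blackwellized
  estimator beats HT (guaranteed) and, on starved arms, IPW — but its
  MSE does not fall below the MLE's, whose negative bias is the price it
  pays instead; run `evaluate` on a scenario of interest before assuming
  either dominates.
* No hypothesis testing, confidence intervals, or type I error control
  for the adaptive designs — estimation only.
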