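"""Point estimators for per-arm response probabilities.

Four estimators of the response probability vector are provided:

* ``mle`` — the per-arm responder fraction.  Under adaptive randomization
  the arm's sample size is positively correlated with its estimate, which
  biases the MLE toward zero.
* ``ht`` — the Horvitz–Thompson-style estimator that divides each observed
  response by the allocation probability actually used and averages over
  the *total* trial size.  It is exactly unbiased but noisy, and can
  exceed 1.
* ``ipw`` — the normalized (inverse-probability-weighted) version of
  ``ht``: a weighted mean of the assigned-arm outcomes, always in [0, 1].
* ``rbht_*`` — the Rao–Blackwellized HT estimator, the conditional
  expectation of ``ht`` given the per-arm patient and responder counts.
  The conditioning set is the set of column reorderings of the trial
  history; each ordering is weighted by the product of the allocation
  probabilities the rule would have produced along it.  Three integration
  strategies are implemented: exhaustive enumeration over multiset
  permutations (small n), rejection sampling from the conditional law, and
  a Metropolis–Hastings chain whose proposal swaps two patients' columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .designs import AllocationRule
from .simulate import simulate_conditional
from .trial import EstimateSet, TrialData, sufficient_stat

__all__ = [
    "MHSettings",
    "mle",
    "ht",
    "ipw",
    "pi_product_log",
    "rbht_exhaustive",
    "rbht_rejection",
    "rbht_mh",
]


@dataclass
class MHSettings:
    """Chain length and thinning for the column-swap sampler."""

    iterations: int = 10_000
    burn_in: int = 1_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.burn_in < 0 or self.burn_in >= self.iterations:
            raise ValueError("burn_in must lie in [0, iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def mle(data: TrialData) -> EstimateSet:
    """Per-arm responder fraction; NaN (flagged) for unoccupied arms."""
    n_k = np.bincount(data.arms, minlength=data.n_arms).astype(float)
    s_k = np.bincount(data.arms, weights=data.outcomes, minlength=data.n_arms)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(n_k > 0, s_k / n_k, np.nan)
    diag = {}
    if np.any(n_k == 0):
        diag["empty_arms"] = np.nonzero(n_k == 0)[0].tolist()
    return EstimateSet("mle", est, diagnostics=diag)


def _ht_values(
    arms: np.ndarray, outcomes: np.ndarray, assigned_probs: np.ndarray, n_arms: int
) -> np.ndarray:
    n = arms.size
    contrib = outcomes / assigned_probs
    return np.bincount(arms, weights=contrib, minlength=n_arms) / n


def ht(data: TrialData) -> EstimateSet:
    """Horvitz–Thompson estimate: (1/n) Σ_i y_i·1{arm_i = k} / π_i."""
    est = _ht_values(data.arms, data.outcomes, data.assigned_probs(), data.n_arms)
    return EstimateSet("ht", est)


def ipw(data: TrialData) -> EstimateSet:
    """Normalized HT: weighted mean of each arm's outcomes with weights 1/π.

    Solves the estimating equation Σ_i (1{arm_i = k}/π_i)(y_i − p_k) = 0,
    so the estimate always lies in [0, 1]; NaN for unoccupied arms.
    """
    pis = data.assigned_probs()
    inv = 1.0 / pis
    num = np.bincount(data.arms, weights=data.outcomes * inv, minlength=data.n_arms)
    den = np.bincount(data.arms, weights=inv, minlength=data.n_arms)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(den > 0, num / den, np.nan)
    return EstimateSet("ipw", est)


# ---------------------------------------------------------------------------
# Rao–Blackwellization machinery
# ---------------------------------------------------------------------------

def _walk_segment(
    rule: AllocationRule,
    state,
    arms: Sequence[int],
    outcomes: Sequence[int],
    start: int,
    stop: int,
):
    """Recompute assigned-arm probabilities for positions [start, stop).

    ``state`` is the rule state after ``start`` patients.  Returns
    ``(log_sum, pis, states)`` where ``pis[t]`` is the probability of the
    arm assigned at position ``start + t`` and ``states[t]`` the state after
    that patient; ``log_sum`` is −inf if any probability is 0.
    """
    log_sum = 0.0
    pis: List[float] = []
    states = []
    for t in range(start, stop):
        arm = arms[t]
        pr = rule.probs_for_state(state, t + 1)
        pa = float(pr[arm])
        if pa <= 0.0:
            return -np.inf, pis, states
        log_sum += math.log(pa)
        pis.append(pa)
        state = rule.update_state(state, arm, outcomes[t])
        states.append(state)
    return log_sum, pis, states


def _recorded_from_mechanism(
    pis: np.ndarray, arms: np.ndarray, overrides: dict
) -> np.ndarray:
    """Patch mechanism probabilities with block-marginal recorded weights."""
    if not overrides:
        return pis
    out = np.array(pis, dtype=float)
    for pos, vec in overrides.items():
        if pos <= len(arms):
            out[pos - 1] = vec[arms[pos - 1]]
    return out


def pi_product_log(
    arms: Sequence[int], outcomes: Sequence[int], rule: AllocationRule
) -> float:
    """Log of the product of assigned-arm probabilities along an ordering.

    The allocation probabilities are recomputed under ``rule`` in the given
    order; the result is −inf when the rule assigns probability 0 somewhere,
    i.e. the ordering is impossible under the design.
    """
    arms = np.asarray(arms, dtype=np.int64)
    outcomes = np.asarray(outcomes, dtype=np.int64)
    log_sum, _, _ = _walk_segment(
        rule, rule.initial_state(), arms, outcomes, 0, arms.size
    )
    return float(log_sum)


def rbht_exhaustive(
    data: TrialData, rule: AllocationRule, max_n: int = 12
) -> EstimateSet:
    """RBHT by exhaustive enumeration of the conditioning set.

    Enumerates every distinct ordering of the trial's (arm, outcome)
    columns, weights each by the product of recomputed allocation
    probabilities, and returns the weighted average of the HT estimate.
    Identical columns would make orderings coincide, but every distinct
    ordering of the shared column multiset has the same multiplicity, so
    enumerating distinct orderings once each leaves the weighted average
    unchanged.  Refuses trials larger than ``max_n`` (factorial growth);
    use the Metropolis–Hastings sampler instead.
    """
    from sympy.utilities.iterables import multiset_permutations

    n, k = data.n, data.n_arms
    if n > max_n:
        raise ValueError(
            f"n = {n} exceeds max_n = {max_n}: exhaustive enumeration is "
            "factorial in n; use rbht_mh"
        )
    columns = list(zip(data.arms.tolist(), data.outcomes.tolist()))
    overrides = rule.recorded_overrides()
    log_weights: List[float] = []
    ht_rows: List[np.ndarray] = []
    n_orderings = 0
    for perm in multiset_permutations(columns):
        n_orderings += 1
        arms = np.fromiter((c[0] for c in perm), dtype=np.int64, count=n)
        outs = np.fromiter((c[1] for c in perm), dtype=np.int64, count=n)
        log_w, pis, _ = _walk_segment(rule, rule.initial_state(), arms, outs, 0, n)
        if log_w == -np.inf:
            continue
        log_weights.append(log_w)
        weights = _recorded_from_mechanism(np.array(pis), arms, overrides)
        ht_rows.append(_ht_values(arms, outs, weights, k))
    if not log_weights:
        raise ValueError("observed history has zero probability under the rule")
    log_w = np.array(log_weights)
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    est = w @ np.vstack(ht_rows)
    return EstimateSet(
        "rbht-exact",
        est,
        diagnostics={"n_orderings": n_orderings, "n_support": len(log_weights)},
    )


def rbht_rejection(
    data: TrialData,
    rule: AllocationRule,
    rng: np.random.Generator,
    n_accept: int = 500,
    budget: int = 1_000_000,
    p_sim: Optional[Sequence[float]] = None,
) -> EstimateSet:
    """RBHT by rejection sampling from the conditional distribution.

    Draws trials under the rule (at ``p_sim``, default the observed MLE)
    and keeps those whose per-arm counts match the observed sufficient
    statistic; the estimate is the unweighted mean of the HT estimates of
    the accepted draws.
    """
    target = sufficient_stat(data)
    accepted, attempts = simulate_conditional(
        rule, target, rng, p_sim=p_sim, n_accept=n_accept, budget=budget
    )
    ht_draws = np.vstack([ht(trial).estimates for trial in accepted])
    m = len(accepted)
    est = ht_draws.mean(axis=0)
    se = ht_draws.std(axis=0, ddof=1) / math.sqrt(m) if m > 1 else np.full(
        data.n_arms, np.nan
    )
    return EstimateSet(
        "rbht-reject",
        est,
        mc_se=se,
        diagnostics={"accepted": m, "attempts": attempts,
                     "acceptance_rate": m / attempts},
    )


def rbht_mh(
    data: TrialData, rule: AllocationRule, settings: Optional[MHSettings] = None
) -> EstimateSet:
    """RBHT by a Metropolis–Hastings chain over column orderings.

    The chain starts at the observed history.  Each step picks two patient
    positions uniformly at random (with replacement; a repeated or
    identical-column pick is a lazy self-move), proposes swapping their
    (arm, outcome) columns, and accepts with probability
    min(1, Π π*(proposed) / Π π*(current)) computed in log space.  Only the
    positions between the two swap points need re-walking, since the rules'
    states depend on the prefix through order-invariant counts.  The
    estimate is the unweighted mean of the per-arm HT values over the
    post-burn-in (thinned) states; the Monte Carlo standard error uses
    batch means to absorb autocorrelation.
    """
    if settings is None:
        settings = MHSettings()
    n, k = data.n, data.n_arms
    rng = np.random.default_rng(settings.seed)
    arms = data.arms.copy()
    outcomes = data.outcomes.copy()

    log_w, pis, states_list = _walk_segment(
        rule, rule.initial_state(), arms, outcomes, 0, n
    )
    if log_w == -np.inf:
        raise ValueError("observed history has zero probability under the rule")
    # states[i] = rule state after i patients (states[0] = empty prefix)
    states = [rule.initial_state()] + states_list
    pis = np.array(pis)
    logpi = np.log(pis)
    overrides = rule.recorded_overrides()
    # recorded weights for HT may differ from the mechanism probabilities
    # at block-randomized positions (forced split)
    rec_pis = _recorded_from_mechanism(pis, arms, overrides)
    # per-arm running sums of y/π for an O(segment) HT update after a swap
    contrib = outcomes / rec_pis
    ht_sums = np.bincount(arms, weights=contrib, minlength=k)

    m = settings.iterations
    trace = np.empty((m, k))
    trace[0] = ht_sums / n
    accepted = 0
    pairs = rng.integers(0, n, size=(m - 1, 2))
    log_u = np.log(rng.random(m - 1))
    for j in range(m - 1):
        i1, i2 = pairs[j]
        if i1 > i2:
            i1, i2 = i2, i1
        if i1 == i2 or (
            arms[i1] == arms[i2] and outcomes[i1] == outcomes[i2]
        ):
            accepted += 1
            trace[j + 1] = trace[j]
            continue
        seg = slice(i1, i2 + 1)
        old_arms_seg = arms[seg].copy()
        arms[i1], arms[i2] = arms[i2], arms[i1]
        outcomes[i1], outcomes[i2] = outcomes[i2], outcomes[i1]
        seg_log, seg_pis, seg_states = _walk_segment(
            rule, states[i1], arms, outcomes, i1, i2 + 1
        )
        old_log = logpi[seg].sum()
        if seg_log != -np.inf and log_u[j] < seg_log - old_log:
            accepted += 1
            ht_sums -= np.bincount(old_arms_seg, weights=contrib[seg], minlength=k)
            pis[seg] = seg_pis
            logpi[seg] = np.log(seg_pis)
            rec_pis[seg] = seg_pis
            for pos, vec in overrides.items():
                if i1 < pos <= i2 + 1:
                    rec_pis[pos - 1] = vec[arms[pos - 1]]
            contrib[seg] = outcomes[seg] / rec_pis[seg]
            ht_sums += np.bincount(arms[seg], weights=contrib[seg], minlength=k)
            # seg_states covers states after patients i1+1 .. i2+1; the last
            # entry equals the old states[i2+1] (same column multiset)
            states[i1 + 1 : i2 + 2] = seg_states
        else:
            arms[i1], arms[i2] = arms[i2], arms[i1]
            outcomes[i1], outcomes[i2] = outcomes[i2], outcomes[i1]
        trace[j + 1] = ht_sums / n

    kept = trace[settings.burn_in :: settings.thin]
    est = kept.mean(axis=0)
    se = _batch_means_se(kept)
    return EstimateSet(
        "rbht-mh",
        est,
        mc_se=se,
        diagnostics={
            "acceptance_rate": accepted / max(m - 1, 1),
            "kept_states": kept.shape[0],
        },
    )


def _batch_means_se(kept: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Autocorrelation-robust SE of the chain mean via batch means."""
    m = kept.shape[0]
    if m < 2 * n_batches:
        return kept.std(axis=0, ddof=1) / math.sqrt(m)
    b = m // n_batches
    batches = kept[: b * n_batches].reshape(n_batches, b, -1).mean(axis=1)
    return batches.std(axis=0, ddof=1) / math.sqrt(n_batches)
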