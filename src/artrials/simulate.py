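"""Trial-history simulation, unconditional and conditional.

Unconditional simulation draws, for each patient in turn, an arm from the
rule's current allocation probabilities and then a Bernoulli outcome from
the assigned arm's true response probability.  Conditional simulation
targets the set of histories sharing a given sufficient statistic (per-arm
patient and responder counts) by rejection: histories are drawn
unconditionally under some response vector and kept only on an exact match.
Which response vector is used does not change the conditional law — the
outcome part of the likelihood is constant on that set — but it changes the
acceptance rate, and the MLE of the observed trial is the efficient choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .designs import AllocationRule
from .trial import SufficientStat, TrialData

__all__ = [
    "ScenarioConfig",
    "ConditionalSamplingError",
    "simulate_trial",
    "simulate_conditional",
    "replicate_rng",
]


class ConditionalSamplingError(RuntimeError):
    """No history matching the target statistic was accepted within budget."""


@dataclass
class ScenarioConfig:
    """One simulation scenario: a design, truth, and sampling settings."""

    rule_spec: dict
    p: Sequence[float]
    n: int
    replications: int = 1000
    seed: int = 0
    methods: Tuple[str, ...] = ("mle", "ht", "ipw")
    mh_iterations: int = 10_000
    mh_burn_in: int = 1_000
    mh_thin: int = 1
    rejection_budget: int = 1_000_000
    scenario_id: str = "scenario"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("response probabilities must lie in [0, 1]")
        if self.n < 1 or self.replications < 1:
            raise ValueError("n and replications must be >= 1")


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent substream for one replicate of a scenario.

    Seeding by (root seed, replicate counter) makes any single replicate
    reproducible in isolation, which matters when tracing an individual
    simulated trial.
    """
    return np.random.default_rng((int(seed), int(replicate)))


def simulate_trial(
    rule: AllocationRule,
    p: Sequence[float],
    n: int,
    rng: np.random.Generator,
) -> TrialData:
    """Simulate one trial of ``n`` patients under ``rule`` and truth ``p``."""
    p = np.asarray(p, dtype=float)
    if p.shape != (rule.n_arms,):
        raise ValueError(
            f"p must have length {rule.n_arms} to match the rule's arm count"
        )
    arms = np.empty(n, dtype=np.int64)
    outcomes = np.empty(n, dtype=np.int64)
    probs = np.empty((n, rule.n_arms))
    state = rule.initial_state()
    u = rng.random((n, 2))
    k_arms = rule.n_arms
    p_list = p.tolist()
    overrides = rule.recorded_overrides()
    for i in range(n):
        pi = rule.probs_for_state(state, i + 1)
        # assignment uses the conditional mechanism probability; the stored
        # weighting vector may be the block-marginal one (forced split)
        probs[i] = overrides.get(i + 1, pi)
        u0 = u[i, 0]
        arm = k_arms - 1  # falls through on rounding of the cumulative sum
        acc = 0.0
        for k in range(k_arms - 1):
            acc += pi[k]
            if u0 < acc:
                arm = k
                break
        outcome = 1 if u[i, 1] < p_list[arm] else 0
        arms[i] = arm
        outcomes[i] = outcome
        state = rule.update_state(state, arm, outcome)
    return TrialData(arms, outcomes, rule.n_arms, probs)


def simulate_conditional(
    rule: AllocationRule,
    target: SufficientStat,
    rng: np.random.Generator,
    p_sim: Optional[Sequence[float]] = None,
    n_accept: int = 500,
    budget: int = 1_000_000,
) -> Tuple[List[TrialData], int]:
    """Rejection-sample histories with sufficient statistic ``target``.

    Draws trials unconditionally under ``p_sim`` (default: the per-arm
    responder fractions implied by ``target``, i.e. the MLE; empty arms get
    1/2) and keeps exact matches on the full per-arm statistic.  Returns the
    accepted histories (possibly fewer than ``n_accept``) and the number of
    attempts consumed.  Raises :class:`ConditionalSamplingError` if nothing
    is accepted within ``budget`` attempts.
    """
    if target.n_arms != rule.n_arms:
        raise ValueError("target statistic arm count does not match the rule")
    n = target.n
    if p_sim is None:
        p_sim = np.array(
            [s / m if m > 0 else 0.5 for m, s in zip(target.n_per_arm, target.s_per_arm)]
        )
    want_n = np.asarray(target.n_per_arm)
    want_s = np.asarray(target.s_per_arm)
    accepted: List[TrialData] = []
    attempts = 0
    while len(accepted) < n_accept and attempts < budget:
        attempts += 1
        trial = simulate_trial(rule, p_sim, n, rng)
        n_k = np.bincount(trial.arms, minlength=rule.n_arms)
        if not np.array_equal(n_k, want_n):
            continue
        s_k = np.bincount(trial.arms, weights=trial.outcomes, minlength=rule.n_arms)
        if np.array_equal(s_k.astype(np.int64), want_s):
            accepted.append(trial)
    if not accepted:
        raise ConditionalSamplingError(
            f"no history matched the target statistic in {attempts} attempts"
        )
    return accepted, attempts
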