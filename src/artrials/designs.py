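"""Allocation rules for response-adaptive randomization.

Every rule is a *pure* function of the trial-history prefix: given the same
prefix and parameters it returns the same probability vector bit for bit.
This is not a stylistic point — the Rao–Blackwellized estimators re-evaluate
the rule along permuted histories, and any hidden randomness inside the rule
would change the conditional distribution they integrate over.

Rules expose a small incremental-state API (``initial_state`` /
``update_state`` / ``probs_for_state``) so that samplers which repeatedly
re-walk partial prefixes (the Metropolis–Hastings column-swap chain) can
recompute only the positions a proposal touches.  All rules shipped here
depend on the prefix only through per-arm success/failure counts, so the
state is a flat tuple of integers.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .trial import TrialData

__all__ = [
    "AllocationRule",
    "FixedRandomization",
    "RandomizedPlayTheWinner",
    "BayesianAdaptiveRandomization",
    "posterior_superiority",
    "gamma_schedule",
    "eta_schedule",
    "rule_from_spec",
]

State = Tuple[int, ...]


class AllocationRule(ABC):
    """Deterministic map from a trial-history prefix to allocation probabilities."""

    n_arms: int

    @abstractmethod
    def initial_state(self) -> State:
        """State summarizing the empty prefix."""

    @abstractmethod
    def update_state(self, state: State, arm: int, outcome: int) -> State:
        """State after appending one (arm, outcome) record to the prefix."""

    @abstractmethod
    def probs_for_state(self, state: State, i: int) -> Tuple[float, ...]:
        """Allocation probabilities for patient ``i`` (1-based) given the
        state of the first ``i - 1`` patients.

        Returns a plain tuple: this is the inner loop of every sampler, and
        avoiding array allocation here is what keeps the permutation
        estimators affordable.
        """

    def alloc_probs(
        self, prefix_arms: Sequence[int], prefix_outcomes: Sequence[int]
    ) -> np.ndarray:
        """Walk a prefix and return the next patient's probability vector."""
        state = self.initial_state()
        for arm, outcome in zip(prefix_arms, prefix_outcomes):
            state = self.update_state(state, int(arm), int(outcome))
        return np.asarray(self.probs_for_state(state, len(prefix_arms) + 1))

    def recorded_overrides(self) -> dict:
        """Positions (1-based) whose *recorded* weighting vector differs
        from the conditional assignment probability.

        The inverse-probability estimators weight each patient by the
        probability of receiving their arm.  When a design assigns a
        patient deterministically as part of a jointly randomized block
        (the forced first-two split), the conditional probability is 0/1
        and the correct weight is the block-marginal probability instead;
        weighting by the degenerate value would bias HT by −p_k/(2n).
        Maps patient index -> replacement probability vector.
        """
        return {}

    def probs_from_trial(self, data: TrialData, recorded: bool = False) -> np.ndarray:
        """Recompute the (n, K) probability matrix along a history.

        With ``recorded=True`` the block-marginal weighting vectors replace
        the conditional ones at the positions of
        :meth:`recorded_overrides`, matching what :func:`simulate_trial`
        stores in the history.
        """
        out = np.empty((data.n, self.n_arms))
        state = self.initial_state()
        overrides = self.recorded_overrides() if recorded else {}
        for i in range(data.n):
            out[i] = overrides.get(i + 1) or self.probs_for_state(state, i + 1)
            state = self.update_state(state, int(data.arms[i]), int(data.outcomes[i]))
        return out


def _count_state_update(state: State, arm: int, outcome: int) -> State:
    """Increment the (success, failure) pair of ``arm`` in a flat count tuple."""
    idx = 2 * arm + (0 if outcome else 1)
    return state[:idx] + (state[idx] + 1,) + state[idx + 1:]


class FixedRandomization(AllocationRule):
    """Constant allocation probabilities (the conventional 1/K split)."""

    def __init__(self, n_arms: int = 2, weights: Optional[Sequence[float]] = None):
        self.n_arms = int(n_arms)
        if weights is None:
            weights = np.full(self.n_arms, 1.0 / self.n_arms)
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (self.n_arms,) or np.any(weights < 0):
            raise ValueError("weights must be a nonnegative length-K vector")
        self._probs = tuple(weights / weights.sum())

    def initial_state(self) -> State:
        return ()

    def update_state(self, state: State, arm: int, outcome: int) -> State:
        return state

    def probs_for_state(self, state: State, i: int) -> Tuple[float, ...]:
        return self._probs


class RandomizedPlayTheWinner(AllocationRule):
    """Two-arm randomized play-the-winner urn.

    The urn starts with ``initial_balls`` balls per arm.  After each
    response a ball of the same arm is added; after each failure a ball of
    the opposite arm.  The allocation probability of arm 1 for patient *i*
    is the urn proportion of arm-1 balls after *i* − 1 patients; with one
    starting ball per arm this is

        (1 + successes on arm 1 + failures on arm 2) / (i + 1).

    ``force_split_first_two`` applies the modification that guarantees both
    arms are occupied: patient 1 is randomized 1/2–1/2 and patient 2
    deterministically receives the other arm (recorded probability 1).
    """

    n_arms = 2

    def __init__(
        self,
        initial_balls: Tuple[int, int] = (1, 1),
        force_split_first_two: bool = True,
    ):
        if len(initial_balls) != 2 or min(initial_balls) < 1:
            raise ValueError("initial_balls must be two counts >= 1")
        self.initial_balls = (int(initial_balls[0]), int(initial_balls[1]))
        self.force_split_first_two = bool(force_split_first_two)

    # state = (s0, f0, s1, f1)
    def initial_state(self) -> State:
        return (0, 0, 0, 0)

    def update_state(self, state: State, arm: int, outcome: int) -> State:
        return _count_state_update(state, arm, outcome)

    def recorded_overrides(self) -> dict:
        # the forced split randomizes the (patient 1, patient 2) pair as a
        # block: each patient's marginal probability of either arm is 1/2,
        # and that is the weight the inverse-probability estimators need
        if self.force_split_first_two:
            return {2: (0.5, 0.5)}
        return {}

    def probs_for_state(self, state: State, i: int) -> Tuple[float, float]:
        s0, f0, s1, f1 = state
        if self.force_split_first_two and i == 2:
            # patient 1's arm is recoverable from the one-patient counts
            return (0.0, 1.0) if (s0 + f0) == 1 else (1.0, 0.0)
        a0, a1 = self.initial_balls
        balls0 = a0 + s0 + f1
        total = a0 + a1 + (i - 1)
        p0 = balls0 / total
        return (p0, 1.0 - p0)


def gamma_schedule(i: int, n: int, coeff: float = 10.0, exponent: float = 1.75) -> float:
    """Sharpening exponent γ_i = coeff·(i/n)^exponent for patient ``i`` of ``n``."""
    if not 1 <= i <= n:
        raise ValueError(f"patient index {i} outside 1..{n}")
    return coeff * (i / n) ** exponent

def eta_schedule(i: int, n: int, coeff: float = 0.25) -> float:
    """Control-balancing rate η_i = coeff·(i/n) for patient ``i`` of ``n``."""
    if not 1 <= i <= n:
        raise ValueError(f"patient index {i} outside 1..{n}")
    return coeff * (i / n)


def _log_beta(a, b):
    return gammaln(a) + gammaln(b) - gammaln(a + b)


# log Γ at integer arguments, precomputed: every beta parameter arising from
# integer counts with an integer prior indexes into this table
_LGAMMA_INT = gammaln(np.arange(2048).astype(float))


def _superiority_exact(a1: float, b1: float, a2: float, b2: float) -> float:
    """Pr(X > Y), X ~ Beta(a1, b1), Y ~ Beta(a2, b2), for integer a1.

    Finite sum over the integer shape parameter, accumulated in log space:
    Pr(X > Y) = Σ_{j=0}^{a1-1} B(a2+j, b1+b2) / [(b1+j) B(1+j, b1) B(a2, b2)].
    """
    j = np.arange(int(round(a1)))
    ints = all(
        abs(v - round(v)) < 1e-12 for v in (b1, a2, b2)
    ) and a2 + a1 + b1 + b2 < 2040
    if ints:
        b1i, a2i, b2i = int(round(b1)), int(round(a2)), int(round(b2))
        t = _LGAMMA_INT
        lb = lambda a, b: t[a] + t[b] - t[a + b]  # noqa: E731
        log_terms = (
            lb(a2i + j, b1i + b2i)
            - np.log(b1 + j)
            - lb(1 + j, b1i)
            - lb(a2i, b2i)
        )
    else:
        log_terms = (
            _log_beta(a2 + j, b1 + b2)
            - np.log(b1 + j)
            - _log_beta(1 + j, b1)
            - _log_beta(a2, b2)
        )
    m = log_terms.max()
    return float(math.exp(m) * np.exp(log_terms - m).sum())


def posterior_superiority(
    s_k: int,
    f_k: int,
    s_0: int,
    f_0: int,
    prior: Tuple[float, float] = (1.0, 1.0),
    method: str = "exact",
    n_draws: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Posterior probability that arm k beats the control.

    Computes Pr(p_k > p_0) for independent posteriors
    Beta(alpha0 + s_k, beta0 + f_k) and Beta(alpha0 + s_0, beta0 + f_0).
    ``method="exact"`` uses the closed-form finite sum (integer first shape);
    ``method="monte-carlo"`` uses seeded paired draws and exists to
    cross-validate the exact computation.
    """
    if min(s_k, f_k, s_0, f_0) < 0:
        raise ValueError("counts must be nonnegative")
    alpha0, beta0 = prior
    if alpha0 <= 0 or beta0 <= 0:
        raise ValueError("prior parameters must be positive")
    a1, b1 = alpha0 + s_k, beta0 + f_k
    a2, b2 = alpha0 + s_0, beta0 + f_0
    if method == "exact":
        if abs(a1 - round(a1)) > 1e-9:
            raise ValueError(
                "exact method requires an integer first shape parameter; "
                "use an integer prior alpha or method='monte-carlo'"
            )
        return _superiority_exact(a1, b1, a2, b2)
    if method == "monte-carlo":
        if rng is None:
            rng = np.random.default_rng(0)
        x = rng.beta(a1, b1, n_draws)
        y = rng.beta(a2, b2, n_draws)
        return float(np.mean(x > y))
    raise ValueError(f"unknown method {method!r}")


class BayesianAdaptiveRandomization(AllocationRule):
    """Multi-arm Bayesian adaptive randomization against a common control.

    Arm 0 is the control; arms 1..K are experimental.  With beta-binomial
    posteriors, experimental arm k receives unnormalized weight

        Pr(p_k > p_0 | data)^γ_i / Σ_j Pr(p_j > p_0 | data)^γ_i

    while the control receives (1/K)·exp{η_i·(max_k n_k − n_0)}, and the
    full (K+1)-vector is renormalized to sum to one.  γ_i = 10(i/n)^1.75
    sharpens the experimental split as the trial matures; η_i = 0.25(i/n)
    pulls the control allocation toward the size of the best experimental
    arm to protect power.

    The exact beta-superiority computation (default) keeps the rule a
    deterministic function of the history, which the permutation estimators
    require; the Monte Carlo posterior mode is for cross-checks only.
    """

    def __init__(
        self,
        n_experimental: int = 3,
        n: int = 140,
        prior: Tuple[float, float] = (1.0, 1.0),
        gamma_coeff: float = 10.0,
        gamma_exp: float = 1.75,
        eta_coeff: float = 0.25,
        posterior_method: str = "exact",
        posterior_draws: int = 100_000,
        posterior_seed: int = 0,
    ):
        if n_experimental < 1:
            raise ValueError("need at least one experimental arm")
        if min(gamma_coeff, gamma_exp, eta_coeff) < 0:
            raise ValueError("schedule parameters must be nonnegative")
        self.n_experimental = int(n_experimental)
        self.n_arms = self.n_experimental + 1
        self.n = int(n)
        self.prior = (float(prior[0]), float(prior[1]))
        self.gamma_coeff = float(gamma_coeff)
        self.gamma_exp = float(gamma_exp)
        self.eta_coeff = float(eta_coeff)
        self.posterior_method = posterior_method
        self.posterior_draws = int(posterior_draws)
        self.posterior_seed = int(posterior_seed)
        self._post_cache: dict = {}
        # schedules depend only on i; precompute for the fixed trial size
        self._gamma = [
            gamma_schedule(i, self.n, self.gamma_coeff, self.gamma_exp)
            for i in range(1, self.n + 1)
        ]
        self._eta = [
            eta_schedule(i, self.n, self.eta_coeff) for i in range(1, self.n + 1)
        ]

    # state = (s0, f0, s1, f1, ..., sK, fK)
    def initial_state(self) -> State:
        return (0,) * (2 * self.n_arms)

    def update_state(self, state: State, arm: int, outcome: int) -> State:
        return _count_state_update(state, arm, outcome)

    def _posterior(self, s_k: int, f_k: int, s_0: int, f_0: int) -> float:
        key = (s_k, f_k, s_0, f_0)
        value = self._post_cache.get(key)
        if value is None:
            if self.posterior_method == "exact":
                value = posterior_superiority(s_k, f_k, s_0, f_0, self.prior)
            else:
                rng = np.random.default_rng(
                    (self.posterior_seed, s_k, f_k, s_0, f_0)
                )
                value = posterior_superiority(
                    s_k, f_k, s_0, f_0, self.prior,
                    method="monte-carlo", n_draws=self.posterior_draws, rng=rng,
                )
            self._post_cache[key] = value
        return value

    def probs_for_state(self, state: State, i: int) -> Tuple[float, ...]:
        k_exp = self.n_experimental
        if i > self.n:
            raise ValueError(f"patient index {i} exceeds the trial size {self.n}")
        gamma_i = self._gamma[i - 1]
        eta_i = self._eta[i - 1]
        s0, f0 = state[0], state[1]
        cache = self._post_cache
        weights = [0.0] * self.n_arms
        max_n_exp = 0
        for k in range(1, self.n_arms):
            s_k, f_k = state[2 * k], state[2 * k + 1]
            n_k = s_k + f_k
            if n_k > max_n_exp:
                max_n_exp = n_k
            post = cache.get((s_k, f_k, s0, f0))
            if post is None:
                post = self._posterior(s_k, f_k, s0, f0)
            weights[k] = post**gamma_i
        exp_total = sum(weights)
        if exp_total > 0:
            for k in range(1, self.n_arms):
                weights[k] /= exp_total
        else:  # all posteriors numerically zero: fall back to an even split
            for k in range(1, self.n_arms):
                weights[k] = 1.0 / k_exp
        weights[0] = (1.0 / k_exp) * math.exp(eta_i * (max_n_exp - (s0 + f0)))
        total = sum(weights)
        return tuple(w / total for w in weights)


def rule_from_spec(spec: dict) -> AllocationRule:
    """Build a rule from a config mapping ``{"name": ..., <params>}``."""
    spec = dict(spec)
    name = spec.pop("name", None)
    if name in ("fr", "fixed"):
        return FixedRandomization(**spec)
    if name == "rpw":
        if "initial_balls" in spec:
            spec["initial_balls"] = tuple(spec["initial_balls"])
        return RandomizedPlayTheWinner(**spec)
    if name == "bayes_ar":
        if "prior" in spec:
            spec["prior"] = tuple(spec["prior"])
        return BayesianAdaptiveRandomization(**spec)
    raise ValueError(f"unknown rule name {name!r} (expected fr | rpw | bayes_ar)")
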