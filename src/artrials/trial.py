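"""Core containers for adaptive-trial histories.

A trial history is an ordered record, one row per patient, of the arm the
patient was randomized to, the binary outcome observed, and the full vector
of allocation probabilities that the design used at the moment of that
assignment.  The probabilities are stored with the data rather than
recomputed lazily because the inverse-probability estimators must weight by
the probabilities actually used; permutation-based estimators recompute
them under a named allocation rule instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialData",
    "SufficientStat",
    "EstimateSet",
    "sufficient_stat",
    "swap_columns",
    "read_trial",
    "write_trial",
]

#: tolerance on each stored allocation-probability vector summing to one
PROB_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TrialData:
    """Complete history of one trial.

    Parameters
    ----------
    arms
        0-based arm index per patient, in order of recruitment.
    outcomes
        Binary response per patient (0 = failure, 1 = response).
    n_arms
        Number of arms K.
    alloc_probs
        ``(n, K)`` matrix of allocation probabilities recorded at each
        assignment, or ``None`` when the history will be re-weighted by a
        named rule (permutation estimators) and the probabilities actually
        used are not needed.
    """

    arms: np.ndarray
    outcomes: np.ndarray
    n_arms: int
    alloc_probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        arms = np.asarray(self.arms, dtype=np.int64)
        outcomes = np.asarray(self.outcomes, dtype=np.int64)
        object.__setattr__(self, "arms", arms)
        object.__setattr__(self, "outcomes", outcomes)
        if arms.ndim != 1 or outcomes.shape != arms.shape:
            raise ValueError("arms and outcomes must be 1-D and equally long")
        if self.n_arms < 1:
            raise ValueError("n_arms must be >= 1")
        if arms.size and (arms.min() < 0 or arms.max() >= self.n_arms):
            raise ValueError("arm index out of range")
        if not np.isin(outcomes, (0, 1)).all():
            raise ValueError("outcomes must be 0 or 1")
        if self.alloc_probs is not None:
            probs = np.asarray(self.alloc_probs, dtype=float)
            object.__setattr__(self, "alloc_probs", probs)
            if probs.shape != (arms.size, self.n_arms):
                raise ValueError(
                    f"alloc_probs must have shape {(arms.size, self.n_arms)}, "
                    f"got {probs.shape}"
                )
            if probs.size:
                if np.any(probs < 0):
                    raise ValueError("allocation probabilities must be >= 0")
                bad = np.abs(probs.sum(axis=1) - 1.0) > PROB_SUM_TOL
                if bad.any():
                    row = int(np.nonzero(bad)[0][0])
                    raise ValueError(
                        f"allocation probabilities for patient {row + 1} sum to "
                        f"{probs[row].sum():.17g}, not 1"
                    )
                assigned = probs[np.arange(arms.size), arms]
                if np.any(assigned <= 0):
                    row = int(np.nonzero(assigned <= 0)[0][0])
                    raise ValueError(
                        f"patient {row + 1} was assigned an arm with recorded "
                        "probability 0"
                    )

    @property
    def n(self) -> int:
        return int(self.arms.size)

    def assigned_probs(self) -> np.ndarray:
        """Probability, per patient, of the arm actually assigned."""
        if self.alloc_probs is None:
            raise ValueError("trial history carries no allocation probabilities")
        return self.alloc_probs[np.arange(self.n), self.arms]


@dataclass(frozen=True)
class SufficientStat:
    """Per-arm patient counts and responder counts.

    This is the conditioning statistic for the Rao–Blackwellized estimators:
    two trial histories are equivalent for that purpose exactly when they
    share all ``n_k`` and ``s_k``.
    """

    n_per_arm: tuple
    s_per_arm: tuple

    def __post_init__(self) -> None:
        n_k = tuple(int(v) for v in self.n_per_arm)
        s_k = tuple(int(v) for v in self.s_per_arm)
        object.__setattr__(self, "n_per_arm", n_k)
        object.__setattr__(self, "s_per_arm", s_k)
        if len(n_k) != len(s_k):
            raise ValueError("count vectors must have equal length")
        for n, s in zip(n_k, s_k):
            if not 0 <= s <= n:
                raise ValueError("responder count outside [0, n_k]")

    @property
    def n_arms(self) -> int:
        return len(self.n_per_arm)

    @property
    def n(self) -> int:
        return sum(self.n_per_arm)


@dataclass
class EstimateSet:
    """Per-arm point estimates from one method.

    ``estimates`` uses NaN for arms on which the estimator is undefined
    (e.g. no patient was ever assigned there).
    """

    method: str
    estimates: np.ndarray
    mc_se: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.mc_se is not None:
            self.mc_se = np.asarray(self.mc_se, dtype=float)


def sufficient_stat(data: TrialData) -> SufficientStat:
    """Per-arm (n_k, s_k) counts of a history; order-invariant."""
    n_k = np.bincount(data.arms, minlength=data.n_arms)
    s_k = np.bincount(data.arms, weights=data.outcomes, minlength=data.n_arms)
    return SufficientStat(tuple(n_k.tolist()), tuple(s_k.astype(int).tolist()))


def swap_columns(data: TrialData, i1: int, i2: int) -> TrialData:
    """Exchange patients ``i1`` and ``i2`` (1-based) in the history.

    Arm and outcome travel together, so the sufficient statistic is
    unchanged.  The stored allocation probabilities are dropped: they are
    order-dependent and must be recomputed by the owning rule.
    """
    n = data.n
    for i in (i1, i2):
        if not 1 <= i <= n:
            raise IndexError(f"patient index {i} outside 1..{n}")
    arms = data.arms.copy()
    outcomes = data.outcomes.copy()
    a, b = i1 - 1, i2 - 1
    arms[[a, b]] = arms[[b, a]]
    outcomes[[a, b]] = outcomes[[b, a]]
    return TrialData(arms, outcomes, data.n_arms, alloc_probs=None)


def write_trial(data: TrialData, path) -> None:
    """Write a history as CSV (patient, arm, outcome, p_arm0..p_arm{K-1})."""
    frame = pd.DataFrame(
        {
            "patient": np.arange(1, data.n + 1),
            "arm": data.arms,
            "outcome": data.outcomes,
        }
    )
    if data.alloc_probs is not None:
        for k in range(data.n_arms):
            frame[f"p_arm{k}"] = data.alloc_probs[:, k]
    frame.to_csv(path, index=False, float_format="%.17g")


def read_trial(path, n_arms: Optional[int] = None) -> TrialData:
    """Read a history CSV written by :func:`write_trial`.

    Probability columns are optional only when the consumer recomputes them
    from a named rule; ``n_arms`` must then be given explicitly.
    """
    frame = pd.read_csv(path)
    for col in ("patient", "arm", "outcome"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    prob_cols = [c for c in frame.columns if c.startswith("p_arm")]
    if prob_cols:
        indices = sorted(int(c[len("p_arm"):]) for c in prob_cols)
        k = len(prob_cols)
        if indices != list(range(k)):
            raise ValueError(f"{path}: probability columns are not p_arm0..p_arm{k-1}")
        if n_arms is not None and n_arms != k:
            raise ValueError(f"{path}: file has {k} arms, expected {n_arms}")
        probs = frame[[f"p_arm{i}" for i in range(k)]].to_numpy(dtype=float)
    else:
        if n_arms is None:
            raise ValueError(
                f"{path}: no probability columns; n_arms must be supplied"
            )
        k, probs = n_arms, None
    expected = np.arange(1, len(frame) + 1)
    if not np.array_equal(frame["patient"].to_numpy(), expected):
        raise ValueError(f"{path}: patient column must run 1..n in order")
    try:
        return TrialData(
            frame["arm"].to_numpy(),
            frame["outcome"].to_numpy(),
            n_arms=k,
            alloc_probs=probs,
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
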