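"""Monte Carlo evaluation harness.

Ties designs, simulation and estimators together: replicate a scenario,
apply each requested estimator, and aggregate per-arm bias, MSE and Monte
Carlo standard errors, together with each arm's sample-size distribution
and its covariance with the MLE.  The covariance matters because of the
identity

    Bias(p̂_k) = −Cov(n(k), p̂_k) / E[n(k)]

which :func:`bias_covariance_check` verifies from the same replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .designs import rule_from_spec
from .estimators import MHSettings, ht, ipw, mle, rbht_mh
from .simulate import ScenarioConfig, replicate_rng, simulate_trial

__all__ = [
    "EvalResult",
    "evaluate",
    "bias_covariance_check",
    "RPW_SCENARIOS",
    "BAYES_AR_SCENARIOS",
]

_ESTIMATORS = ("mle", "ht", "ipw", "rbht_mh")

#: Default two-arm play-the-winner scenario grid.  These are documented
#: reconstructions spanning (0.2, 0.8) with a growing treatment difference,
#: not the (unpublished) parameter values behind the original six-scenario
#: comparison; only qualitative orderings should be read off them.
RPW_SCENARIOS = (
    (0.5, 0.5),
    (0.45, 0.55),
    (0.4, 0.6),
    (0.35, 0.65),
    (0.3, 0.7),
    (0.25, 0.75),
)

#: Default multi-arm Bayesian-AR constellations (arm 0 = control): a global
#: null plus a staircase of effects.  Reconstructions in the same sense as
#: above.
BAYES_AR_SCENARIOS = (
    (0.3, 0.3, 0.3, 0.3),
    (0.3, 0.3, 0.3, 0.5),
    (0.3, 0.3, 0.45, 0.6),
    (0.3, 0.45, 0.5, 0.6),
    (0.3, 0.2, 0.45, 0.6),
)


@dataclass
class EvalResult:
    """Aggregated operating characteristics of one scenario."""

    scenario_id: str
    table: pd.DataFrame          # arm, method, mean, bias, mse, mc_se, n_used
    arm_stats: pd.DataFrame      # arm, mean_n, cov_n_mle
    replications: int
    estimates: Optional[Dict[str, np.ndarray]] = None  # method -> (reps, K)
    n_matrix: Optional[np.ndarray] = None              # (reps, K) arm sizes


def _run_replicates(
    config: ScenarioConfig, methods: Sequence[str]
) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    rule = rule_from_spec(config.rule_spec)
    reps, k = config.replications, rule.n_arms
    store = {m: np.empty((reps, k)) for m in methods}
    n_matrix = np.empty((reps, k), dtype=np.int64)
    for r in range(reps):
        rng = replicate_rng(config.seed, r)
        trial = simulate_trial(rule, config.p, config.n, rng)
        n_matrix[r] = np.bincount(trial.arms, minlength=k)
        for m in methods:
            if m == "mle":
                store[m][r] = mle(trial).estimates
            elif m == "ht":
                store[m][r] = ht(trial).estimates
            elif m == "ipw":
                store[m][r] = ipw(trial).estimates
            elif m == "rbht_mh":
                settings = MHSettings(
                    iterations=config.mh_iterations,
                    burn_in=config.mh_burn_in,
                    thin=config.mh_thin,
                    seed=int(
                        np.random.default_rng((config.seed, r, 1)).integers(2**31)
                    ),
                )
                store[m][r] = rbht_mh(trial, rule, settings).estimates
            else:
                raise ValueError(f"unknown estimator {m!r} (expected {_ESTIMATORS})")
    return store, n_matrix


def evaluate(
    config: ScenarioConfig,
    methods: Optional[Sequence[str]] = None,
    keep_estimates: bool = False,
) -> EvalResult:
    """Replicate a scenario and aggregate estimator performance.

    Arms left empty in a replicate produce NaN estimates for the MLE and
    IPW methods; such replicates are excluded per-arm from that method's
    averages and the exclusion count is reported (``n_used`` column).
    """
    methods = tuple(methods) if methods is not None else tuple(config.methods)
    store, n_matrix = _run_replicates(config, methods)
    p = np.asarray(config.p, dtype=float)
    k = p.size
    rows = []
    for m in methods:
        est = store[m]
        for arm in range(k):
            col = est[:, arm]
            ok = ~np.isnan(col)
            used = int(ok.sum())
            if used == 0:
                rows.append((arm, m, np.nan, np.nan, np.nan, np.nan, 0))
                continue
            vals = col[ok]
            mean = vals.mean()
            rows.append(
                (
                    arm,
                    m,
                    mean,
                    mean - p[arm],
                    float(np.mean((vals - p[arm]) ** 2)),
                    vals.std(ddof=1) / math.sqrt(used) if used > 1 else np.nan,
                    used,
                )
            )
    table = pd.DataFrame(
        rows, columns=["arm", "method", "mean", "bias", "mse", "mc_se", "n_used"]
    )
    arm_rows = []
    mle_est = store.get("mle")
    for arm in range(k):
        cov = np.nan
        if mle_est is not None:
            col = mle_est[:, arm]
            ok = ~np.isnan(col)
            if ok.sum() > 1:
                cov = float(np.cov(n_matrix[ok, arm], col[ok], ddof=1)[0, 1])
        arm_rows.append((arm, float(n_matrix[:, arm].mean()), cov))
    arm_stats = pd.DataFrame(arm_rows, columns=["arm", "mean_n", "cov_n_mle"])
    return EvalResult(
        scenario_id=config.scenario_id,
        table=table,
        arm_stats=arm_stats,
        replications=config.replications,
        estimates=store if keep_estimates else None,
        n_matrix=n_matrix if keep_estimates else None,
    )


def bias_covariance_check(
    config: ScenarioConfig, n_batches: int = 20
) -> pd.DataFrame:
    """Check Bias(p̂_k) = −Cov(n(k), p̂_k)/E[n(k)] on simulated replicates.

    Both sides are estimated from the same replicates; the returned frame
    carries, per arm, the covariance side (``lhs``), the bias side
    (``rhs``), a batch-means standard error of their difference, and a pass
    flag at three standard errors.  The identity holds exactly only when
    the MLE is defined in every replicate (no empty arms), which the
    forced-split urn rule guarantees for two-arm trials.
    """
    store, n_matrix = _run_replicates(config, ("mle",))
    est = store["mle"]
    p = np.asarray(config.p, dtype=float)
    reps, k = est.shape
    b = reps // n_batches
    rows = []
    for arm in range(k):
        col = est[:, arm]
        ok = ~np.isnan(col)
        vals, sizes = col[ok], n_matrix[ok, arm]
        lhs = -float(np.cov(sizes, vals, ddof=1)[0, 1]) / sizes.mean()
        rhs = float(vals.mean() - p[arm])
        # batch-means SE of the (lhs - rhs) difference
        diffs = []
        cols = col[: b * n_batches].reshape(n_batches, b)
        ns = n_matrix[: b * n_batches, arm].reshape(n_batches, b)
        for i in range(n_batches):
            bc, bn = cols[i], ns[i]
            m = ~np.isnan(bc)
            if m.sum() < 2:
                continue
            l_i = -float(np.cov(bn[m], bc[m], ddof=1)[0, 1]) / bn[m].mean()
            diffs.append(l_i - (bc[m].mean() - p[arm]))
        diffs = np.asarray(diffs)
        se = float(diffs.std(ddof=1) / math.sqrt(diffs.size)) if diffs.size > 1 else np.nan
        gap = abs(lhs - rhs)
        rows.append((arm, lhs, rhs, se, bool(se == se and gap <= 3 * se)))
    return pd.DataFrame(rows, columns=["arm", "lhs", "rhs", "se", "ok"])
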