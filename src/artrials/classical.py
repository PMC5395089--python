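"""Comparator two-stage designs and the sign of their estimation bias.

Both designs here make the realized sample size a function of interim
data, which correlates it with the final maximum-likelihood estimate.  The
bias of the MLE then has sign opposite to Cov(sample size, estimate):

* a Simon-style single-arm futility design enrolls *more* patients exactly
  when the interim estimate is high (positive covariance, negative bias);
* an unblinded sample-size re-estimation design enrolls *more* patients
  when the interim effect estimate is small (negative covariance, positive
  bias).

The Simon design's operating characteristics are exact binomial
convolutions; the re-estimation design is evaluated by simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "SimonDesign",
    "SimonResult",
    "simon_exact",
    "SSRDesign",
    "SSRResult",
    "ssr_simulate",
]


@dataclass(frozen=True)
class SimonDesign:
    """Single-arm two-stage design with a futility stop.

    Stage 1 enrolls ``n1`` patients; the trial continues to ``n_total``
    only if at least ``continue_min`` respond.  The null response rate
    ``p0`` is rejected when total responders reach ``reject_min``.

    The default thresholds (13 patients, continue on >= 4; 34 patients,
    reject on >= 10) attain an exact type I error of 8.4% at p0 = 0.2,
    within the design's nominal 10% level.  ``reject_min`` follows the
    convention that the null is rejected only when responders *exceed* the
    stage-2 critical count of 9.
    """

    n1: int = 13
    continue_min: int = 4
    n_total: int = 34
    reject_min: int = 10
    p0: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.n1 < self.n_total:
            raise ValueError("need 0 < n1 < n_total")
        if not 0 <= self.continue_min <= self.n1 + 1:
            raise ValueError("continuation threshold outside stage-1 range")
        if not 0 <= self.reject_min <= self.n_total + 1:
            raise ValueError("rejection threshold outside total range")


@dataclass(frozen=True)
class SimonResult:
    reject_prob: float
    expected_mle: float
    bias: float
    expected_n: float
    cov_n_mle: float


def simon_exact(design: SimonDesign, p: float) -> SimonResult:
    """Exact operating characteristics at true response rate ``p``.

    Enumerates the stage-1 responder count x1 ~ Bin(n1, p) and, on
    continuation, the stage-2 count x2 ~ Bin(n_total − n1, p).  The MLE is
    x1/n1 on a stage-1 stop and (x1 + x2)/n_total otherwise, i.e. it always
    divides by the number of patients actually enrolled.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    d = design
    n2 = d.n_total - d.n1
    x1 = np.arange(d.n1 + 1)
    pmf1 = binom.pmf(x1, d.n1, p)
    stop = x1 < d.continue_min

    reject = 0.0
    e_mle = 0.0
    e_n = 0.0
    e_n_mle = 0.0
    # stage-1 stops
    mle_stop = x1[stop] / d.n1
    w = pmf1[stop]
    e_mle += float(w @ mle_stop)
    e_n += float(w.sum() * d.n1)
    e_n_mle += float(w @ mle_stop * d.n1)
    # continuations
    x2 = np.arange(n2 + 1)
    pmf2 = binom.pmf(x2, n2, p)
    for xi, wi in zip(x1[~stop], pmf1[~stop]):
        total = xi + x2
        mle_go = total / d.n_total
        reject += float(wi * pmf2[total >= d.reject_min].sum())
        e_mle += float(wi * (pmf2 @ mle_go))
        e_n += float(wi * d.n_total)
        e_n_mle += float(wi * (pmf2 @ mle_go) * d.n_total)
    cov = e_n_mle - e_n * e_mle
    return SimonResult(
        reject_prob=reject,
        expected_mle=e_mle,
        bias=e_mle - p,
        expected_n=e_n,
        cov_n_mle=cov,
    )


@dataclass(frozen=True)
class SSRDesign:
    """Two-arm design with unblinded sample-size re-estimation.

    Stage 1 enrolls ``n_stage1`` patients per arm under fixed 1:1
    randomization.  The interim statistic is the variance-stabilized
    z1 = θ̂·√(n_stage1/2) with θ̂ = 2[asin√p̂1 − asin√p̂2].  If z1 falls in
    ``(z_low, z_high)`` each arm is enlarged to

        ⌈((z_alpha + z_beta)² / z1² − 1)·n_stage1⌉

    patients (never below the ``n_stage1`` already enrolled); otherwise the
    trial stops at stage 1.  ``grouping`` selects how the printed resizing
    formula is bracketed: ``"subtract_inside"`` (default, shown above) or
    ``"multiply_only"`` for ⌈(z_alpha+z_beta)²/z1²·n_stage1⌉ − n_stage1
    added patients without the −1 inside.
    """

    n_stage1: int = 100
    z_low: float = 1.0
    z_high: float = 2.74
    z_alpha: float = 1.92
    z_beta: float = 0.84
    grouping: str = "subtract_inside"

    def __post_init__(self) -> None:
        if self.z_low >= self.z_high:
            raise ValueError("continuation window bounds out of order")
        if self.grouping not in ("subtract_inside", "multiply_only"):
            raise ValueError("unknown grouping option")


@dataclass(frozen=True)
class SSRResult:
    bias_diff: float
    bias_se: float
    cov_n_diff: float
    cov_se: float
    mean_total_n: float
    continue_frac: float


def ssr_simulate(
    design: SSRDesign,
    p1: float,
    p2: float,
    reps: int,
    rng: np.random.Generator,
    n_batches: int = 20,
) -> SSRResult:
    """Monte Carlo bias of the final p̂1 − p̂2 and its covariance with n.

    The final MLEs pool both stages of each arm.  Standard errors for the
    bias and the covariance come from batch means over the replicates.
    """
    d = design
    m1 = d.n_stage1
    x1 = rng.binomial(m1, p1, reps).astype(float)
    x2 = rng.binomial(m1, p2, reps).astype(float)
    theta = 2.0 * (np.arcsin(np.sqrt(x1 / m1)) - np.arcsin(np.sqrt(x2 / m1)))
    z1 = theta * math.sqrt(m1 / 2.0)
    go = (z1 > d.z_low) & (z1 < d.z_high)

    per_arm = np.full(reps, m1, dtype=float)
    z_go = z1[go]
    c = (d.z_alpha + d.z_beta) ** 2
    if d.grouping == "subtract_inside":
        resized = np.ceil((c / z_go**2 - 1.0) * m1)
    else:
        resized = np.ceil(c / z_go**2 * m1) - m1
    per_arm[go] = np.maximum(resized, m1)

    extra = (per_arm - m1).astype(np.int64)
    y1 = np.where(extra > 0, rng.binomial(np.maximum(extra, 1), p1), 0)
    y2 = np.where(extra > 0, rng.binomial(np.maximum(extra, 1), p2), 0)
    p1_hat = (x1 + y1) / per_arm
    p2_hat = (x2 + y2) / per_arm
    diff = p1_hat - p2_hat
    total_n = 2.0 * per_arm

    bias = float(diff.mean() - (p1 - p2))
    cov = float(np.cov(total_n, diff, ddof=1)[0, 1])

    b = reps // n_batches
    dd = diff[: b * n_batches].reshape(n_batches, b)
    nn = total_n[: b * n_batches].reshape(n_batches, b)
    batch_bias = dd.mean(axis=1) - (p1 - p2)
    batch_cov = np.array(
        [np.cov(nn[i], dd[i], ddof=1)[0, 1] for i in range(n_batches)]
    )
    return SSRResult(
        bias_diff=bias,
        bias_se=float(batch_bias.std(ddof=1) / math.sqrt(n_batches)),
        cov_n_diff=cov,
        cov_se=float(batch_cov.std(ddof=1) / math.sqrt(n_batches)),
        mean_total_n=float(total_n.mean()),
        continue_frac=float(go.mean()),
    )
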