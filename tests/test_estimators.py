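import itertools
import math

import numpy as np
import pytest

from artrials import (
    FixedRandomization,
    MHSettings,
    RandomizedPlayTheWinner,
    TrialData,
    ht,
    ipw,
    mle,
    pi_product_log,
    rbht_exhaustive,
    rbht_mh,
    rbht_rejection,
    replicate_rng,
    simulate_trial,
)
from artrials.estimators import _walk_segment


class TestMLE:
    def test_worked_history(self, worked_history):
        est = mle(worked_history).estimates
        assert est[0] == pytest.approx(5 / 8, abs=0)
        assert est[1] == pytest.approx(15 / 17, abs=0)

    def test_all_failures_and_empty_arm(self):
        data = TrialData([0, 0], [0, 0], 2, np.array([[0.5, 0.5], [0.5, 0.5]]))
        est = mle(data)
        assert est.estimates[0] == 0.0
        assert np.isnan(est.estimates[1])
        assert est.diagnostics["empty_arms"] == [1]

    def test_single_arm_is_sample_mean(self):
        data = TrialData([0, 0, 0], [1, 0, 1], 1, np.ones((3, 1)))
        assert mle(data).estimates[0] == pytest.approx(2 / 3)


class TestHTAndIPW:
    def test_unit_weights_reduce_to_sample_mean(self):
        data = TrialData([0, 0, 0], [1, 0, 1], 1, np.ones((3, 1)))
        assert ht(data).estimates[0] == pytest.approx(2 / 3)
        assert ipw(data).estimates[0] == pytest.approx(2 / 3)

    def test_ht_can_overshoot_one_while_ipw_stays_bounded(self):
        probs = np.array([[0.1, 0.9], [0.5, 0.5]])
        data = TrialData([0, 1], [1, 0], 2, probs)
        assert ht(data).estimates[0] == pytest.approx(5.0)
        assert ipw(data).estimates[0] == pytest.approx(1.0)

    def test_constant_probabilities_make_ipw_equal_mle(self):
        rule = FixedRandomization(2)
        for r in range(20):
            t = simulate_trial(rule, [0.4, 0.7], 15, replicate_rng(21, r))
            np.testing.assert_allclose(
                ipw(t).estimates, mle(t).estimates, equal_nan=True
            )

    def test_missing_probabilities_are_an_error(self):
        data = TrialData([0, 1], [1, 0], 2, alloc_probs=None)
        with pytest.raises(ValueError, match="probabilit"):
            ht(data)

    def test_ipw_solves_the_estimating_equation(self, rpw_rule):
        def bisect_root(weights, outcomes):
            # root of sum_i w_i (y_i - p) = 0 found by bisection on [0, 1]
            def g(p):
                return float(np.sum(weights * (outcomes - p)))
            lo, hi = 0.0, 1.0
            for _ in range(80):
                mid = (lo + hi) / 2
                if g(lo) * g(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            return (lo + hi) / 2

        for r in range(10):
            t = simulate_trial(rpw_rule, [0.3, 0.7], 20, replicate_rng(22, r))
            est = ipw(t).estimates
            pis = t.assigned_probs()
            for arm in range(2):
                mask = t.arms == arm
                if not mask.any():
                    continue
                root = bisect_root(1.0 / pis[mask], t.outcomes[mask])
                assert est[arm] == pytest.approx(root, abs=1e-9)

    def test_ipw_and_mle_range_property(self, rpw_rule):
        for r in range(50):
            t = simulate_trial(rpw_rule, [0.2, 0.8], 25, replicate_rng(23, r))
            for e in (ipw(t).estimates, mle(t).estimates):
                ok = ~np.isnan(e)
                assert np.all((e[ok] >= 0) & (e[ok] <= 1))
            assert np.all(ht(t).estimates >= 0)


class TestPiProductLog:
    def test_identity_ordering_matches_recorded_probabilities(
        self, rpw_rule, rpw_rule_unforced
    ):
        # without block randomization the recorded weights ARE the
        # mechanism probabilities, so the identity ordering reproduces them
        t = simulate_trial(rpw_rule_unforced, [0.3, 0.7], 15, replicate_rng(24, 0))
        assert pi_product_log(t.arms, t.outcomes, rpw_rule_unforced) == pytest.approx(
            float(np.log(t.assigned_probs()).sum())
        )
        # under the forced split the likelihood product uses the degenerate
        # step-2 mechanism probability (1), while the recorded HT weight is
        # the block marginal 1/2: the two differ by exactly log 2
        t = simulate_trial(rpw_rule, [0.3, 0.7], 15, replicate_rng(24, 0))
        assert pi_product_log(t.arms, t.outcomes, rpw_rule) == pytest.approx(
            float(np.log(t.assigned_probs()).sum()) + np.log(2.0)
        )

    def test_fixed_randomization_is_permutation_invariant(self):
        rule = FixedRandomization(2)
        arms, outs = [0, 1, 1, 0, 1], [1, 0, 1, 1, 0]
        expected = 5 * math.log(0.5)
        for perm in itertools.permutations(range(5)):
            assert pi_product_log(
                [arms[i] for i in perm], [outs[i] for i in perm], rule
            ) == pytest.approx(expected)

    def test_all_orderings_match_hand_urn_products(self, rpw_rule_unforced):
        arms = [0, 1, 1, 0]
        outs = [1, 1, 0, 0]
        for perm in itertools.permutations(range(4)):
            pa = [arms[i] for i in perm]
            po = [outs[i] for i in perm]
            balls, logprod = [1, 1], 0.0
            for a, y in zip(pa, po):
                logprod += math.log(balls[a] / sum(balls))
                balls[a if y else 1 - a] += 1
            assert pi_product_log(pa, po, rpw_rule_unforced) == pytest.approx(logprod)

    def test_impossible_ordering_under_forced_split(self, rpw_rule):
        # both early patients on the same arm cannot occur with the forced split
        assert pi_product_log([0, 0, 1], [1, 1, 1], rpw_rule) == -np.inf

    def test_segment_update_equals_full_recomputation(self, rpw_rule):
        rng = np.random.default_rng(25)
        for _ in range(1000):
            t = simulate_trial(rpw_rule, [0.4, 0.6], 10, rng)
            full, pis, states = _walk_segment(
                rpw_rule, rpw_rule.initial_state(), t.arms, t.outcomes, 0, 10
            )
            i1, i2 = sorted(rng.integers(0, 10, 2))
            arms = t.arms.copy()
            outs = t.outcomes.copy()
            arms[[i1, i2]] = arms[[i2, i1]]
            outs[[i1, i2]] = outs[[i2, i1]]
            prefix_state = states[i1 - 1] if i1 > 0 else rpw_rule.initial_state()
            seg_log, _, _ = _walk_segment(rpw_rule, prefix_state, arms, outs, i1, i2 + 1)
            incremental = (
                full - math.fsum(math.log(p) for p in pis[i1 : i2 + 1]) + seg_log
            )
            assert incremental == pytest.approx(
                pi_product_log(arms, outs, rpw_rule), abs=1e-9
            ) or (incremental == -np.inf and pi_product_log(arms, outs, rpw_rule) == -np.inf)


class TestRBHT:
    def test_single_patient_trial_equals_ht(self, rpw_rule):
        t = simulate_trial(rpw_rule, [0.5, 0.5], 1, replicate_rng(26, 0))
        base = ht(t).estimates
        np.testing.assert_allclose(rbht_exhaustive(t, rpw_rule).estimates, base)
        rj = rbht_rejection(t, rpw_rule, np.random.default_rng(0), n_accept=20)
        np.testing.assert_allclose(rj.estimates, base)

    def test_fixed_randomization_leaves_ht_unchanged(self):
        rule = FixedRandomization(2)
        t = simulate_trial(rule, [0.4, 0.6], 7, replicate_rng(27, 0))
        np.testing.assert_allclose(
            rbht_exhaustive(t, rule).estimates, ht(t).estimates, atol=1e-12
        )
        mh = rbht_mh(t, rule, MHSettings(iterations=500, burn_in=100, seed=1))
        np.testing.assert_allclose(mh.estimates, ht(t).estimates, atol=1e-12)
        # equal likelihoods: every proposal is accepted
        assert mh.diagnostics["acceptance_rate"] == pytest.approx(1.0)

    def test_exhaustive_refuses_large_trials(self, rpw_rule):
        t = simulate_trial(rpw_rule, [0.5, 0.5], 16, replicate_rng(28, 0))
        with pytest.raises(ValueError, match="rbht_mh"):
            rbht_exhaustive(t, rpw_rule)

    def test_exhaustive_matches_high_precision_rejection(self, rpw_rule):
        t = simulate_trial(rpw_rule, [0.3, 0.7], 8, replicate_rng(29, 1))
        exact = rbht_exhaustive(t, rpw_rule).estimates
        rj = rbht_rejection(
            t, rpw_rule, np.random.default_rng(2), n_accept=20_000, budget=10**6
        )
        for arm in range(2):
            assert abs(exact[arm] - rj.estimates[arm]) <= 3 * rj.mc_se[arm]

    def test_mh_estimate_matches_exhaustive(self, rpw_rule):
        for r in range(3):
            t = simulate_trial(rpw_rule, [0.3, 0.7], 8, replicate_rng(30, r))
            exact = rbht_exhaustive(t, rpw_rule).estimates
            mh = rbht_mh(t, rpw_rule, MHSettings(iterations=20_000, burn_in=2_000, seed=r))
            for arm in range(2):
                assert abs(exact[arm] - mh.estimates[arm]) <= 3 * mh.mc_se[arm]

    def test_rejection_error_shrinks_with_draw_count(self, rpw_rule):
        t = simulate_trial(rpw_rule, [0.3, 0.7], 10, replicate_rng(31, 0))
        exact = rbht_exhaustive(t, rpw_rule, max_n=10).estimates
        errors = []
        for m in (125, 2000):
            reps = []
            for r in range(8):
                rj = rbht_rejection(
                    t, rpw_rule, np.random.default_rng((3, r)), n_accept=m,
                    budget=10**6,
                )
                reps.append(rj.estimates[0])
            errors.append(np.std(np.array(reps) - exact[0]))
        assert errors[1] < errors[0]

    def test_mh_settings_validation(self):
        with pytest.raises(ValueError):
            MHSettings(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MHSettings(iterations=0)
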