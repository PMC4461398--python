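"""Threshold estimation, fate-boundary classification, SVM benchmark, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import c8fate as cf
from c8fate.datatypes import FATE_DIED, FATE_SURVIVED
from c8fate.threshold import BoundaryClassifier, misclassification_error


def _fates(died_mask):
    return np.where(died_mask, FATE_DIED, FATE_SURVIVED)


def brute_force_min_error(max_values, died):
    """Independent oracle: enumerate every piece of the piecewise-constant E.

    With the "dead iff Max >= theta" rule, E changes only at observed Max
    values, so evaluating at each observed value and one point above the
    maximum covers every piece exactly.
    """
    mv = np.asarray(max_values, float)
    grid = np.concatenate([np.unique(mv), [mv.max() + 1.0]])
    errors = [
        np.sum(died & (mv < th)) + np.sum(~died & (mv >= th)) for th in grid
    ]
    return int(np.min(errors))


class TestEstimateTheta:
    def test_separable_sets_midpoint_threshold(self):
        mv = np.array([3, 4, 5, 1, 2, 2.5]) * 1e-3
        died = np.array([True, True, True, False, False, False])
        res = cf.estimate_theta(mv, _fates(died))
        assert res.error_count == 0
        assert res.accuracy == 1.0
        assert res.theta_hat == pytest.approx(2.75e-3)

    def test_interleaved_case_exhaustive(self):
        # dead {2, 4}, alive {1, 3} (x 1e-3): best achievable error is 1,
        # attained first at the 1.5e-3 midpoint (smallest-theta tie rule)
        mv = np.array([2, 4, 1, 3]) * 1e-3
        died = np.array([True, True, False, False])
        res = cf.estimate_theta(mv, _fates(died))
        assert res.error_count == 1
        assert res.accuracy == pytest.approx(0.75)
        assert res.theta_hat == pytest.approx(1.5e-3)

    def test_single_fate_degenerate_path(self):
        res = cf.estimate_theta([1e-3, 2e-3], [FATE_DIED, FATE_DIED])
        assert res.degenerate
        assert res.accuracy == 1.0
        assert res.theta_hat <= 1e-3

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(30):
            n = rng.integers(5, 200)
            mv = 10.0 ** rng.normal(-2.6, 0.6, n)
            died = rng.random(n) < 0.5
            if died.all() or (~died).all():
                continue
            res = cf.estimate_theta(mv, _fates(died))
            assert res.error_count == brute_force_min_error(mv, died)
            assert misclassification_error(res.theta_hat, mv, _fates(died)) == res.error_count

    def test_error_function_piecewise_constant(self, rng):
        mv = np.sort(10.0 ** rng.normal(-2.6, 0.5, 40))
        died = rng.random(40) < 0.5
        fates = _fates(died)
        for i in range(5, 10):
            lo, hi = mv[i], mv[i + 1]
            vals = {
                misclassification_error(th, mv, fates)
                for th in np.linspace(lo + 1e-12, hi, 7)[:-1]
            }
            assert len(vals) == 1


class TestAccuracyAt:
    def test_separable_gap_is_perfect(self):
        mv = np.array([1.0, 2.0, 5.0, 6.0])
        fates = _fates(np.array([False, False, True, True]))
        assert cf.accuracy_at(3.0, mv, fates) == 1.0

    def test_extreme_threshold_boundary_behavior(self):
        mv = np.array([1.0, 2.0, 3.0])
        assert cf.accuracy_at(0.5, mv, _fates(np.ones(3, bool))) == 1.0
        assert cf.accuracy_at(0.5, mv, _fates(np.zeros(3, bool))) == 0.0


class TestBoundaryClassifier:
    CLF = BoundaryClassifier(theta=2.63e-3, t0_bar=20.0)

    def test_fast_cell_dies(self):
        # boundary tau* = theta/(2k) + 20 = 46.3 < 100
        assert cf.classify_by_boundary(5e-5, 100.0, self.CLF)[0]

    def test_floor_cell_survives(self):
        assert not cf.classify_by_boundary(1e-7, 600.0, self.CLF)[0]

    def test_cell_exactly_on_line_dies(self):
        k = 5e-5
        tau_star = 2.63e-3 / (2 * k) + 20.0
        assert cf.classify_by_boundary(k, tau_star, self.CLF)[0]

    def test_zero_rate_survives(self):
        assert not cf.classify_by_boundary(0.0, 500.0, self.CLF)[0]

    def test_equivalent_to_threshold_rule_when_lags_equal(self, rng):
        # with all t0 = t0_bar and exact fits, the boundary rule is the
        # threshold rule on Max(C8)
        k = 10.0 ** rng.normal(-5.3, 0.6, 200)
        tau = rng.uniform(60, 500, 200)
        mv = 2 * k * (tau - 20.0)
        died = mv >= np.median(mv)
        res = cf.estimate_theta(mv, _fates(died))
        clf = BoundaryClassifier(theta=res.theta_hat, t0_bar=20.0)
        np.testing.assert_array_equal(
            cf.classify_by_boundary(k, tau, clf), mv >= res.theta_hat
        )


class TestLinearMarginClassifier:
    def test_separable_clouds_perfect(self, rng):
        k = np.concatenate([10 ** rng.normal(-6, 0.1, 50), 10 ** rng.normal(-4, 0.1, 50)])
        tau = np.concatenate([rng.normal(150, 10, 50), rng.normal(350, 10, 50)])
        died = np.repeat([False, True], 50)
        out = cf.fit_linear_margin_classifier(k, tau, _fates(died))
        assert out["accuracy"] == 1.0

    def test_permuted_labels_near_chance(self, rng):
        n = 500
        k = 10 ** rng.normal(-5.3, 0.6, n)
        tau = rng.uniform(60, 500, n)
        died = rng.permutation(np.repeat([True, False], [200, 300]))
        out = cf.fit_linear_margin_classifier(k, tau, _fates(died))
        assert abs(out["accuracy"] - 0.6) < 0.05  # max class frequency 300/500

    def test_single_fate_rejected(self):
        with pytest.raises(ValueError):
            cf.fit_linear_margin_classifier([1e-5, 2e-5], [100, 200], [FATE_DIED, FATE_DIED])


class TestBootstrapSem:
    def test_constant_statistic_has_zero_sem(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=50)})
        assert cf.bootstrap_sem(lambda d: 1.0, df, n_boot=100, seed=0) == 0.0

    def test_mean_of_standard_normal_sample(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(100)})
        sem = cf.bootstrap_sem(lambda d: d["x"].mean(), df, n_boot=500, seed=1)
        assert sem == pytest.approx(0.1, rel=0.2)

    def test_separable_accuracy_has_zero_sem(self):
        df = pd.DataFrame(
            {"mv": [1.0, 2.0, 5.0, 6.0], "fate": _fates(np.array([0, 0, 1, 1], bool))}
        )
        sem = cf.bootstrap_sem(
            lambda d: cf.accuracy_at(3.0, d["mv"], d["fate"]), df, n_boot=200, seed=2
        )
        assert sem == 0.0

    def test_n_boot_validated(self):
        with pytest.raises(ValueError):
            cf.bootstrap_sem(lambda d: 0.0, pd.DataFrame({"x": [1.0]}), n_boot=1)
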