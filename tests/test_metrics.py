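"""Intended/unintended RMSE, aggregation, functional classification, best
combination, and nonparametric group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import myokf as mk


def double_loop_rmse(target, pred):
    """Naive double-loop oracle for the intended-RMSE definition."""
    h, m = target.shape
    acc = 0.0
    for k in range(h):
        for j in range(m):
            acc += (target[k, j] - pred[k, j]) ** 2
    return (acc / (h * m)) ** 0.5


def double_loop_xrmse(pred):
    h, m = pred.shape
    acc = 0.0
    for k in range(h):
        for j in range(m):
            acc += pred[k, j] ** 2
    return (acc / (h * m)) ** 0.5


class TestIntendedRmse:
    def test_perfect_prediction_is_zero(self, rng):
        t = rng.normal(size=(30, 2))
        assert mk.intended_rmse(target=t, pred=t) == 0.0

    def test_constant_offset(self, protocol):
        kin, labels, _ = mk.generate_target_kinematics(protocol, ["HC"])
        win = mk.attempt_windows(labels, "HC")[0]
        t = kin[win, 0]
        assert mk.intended_rmse(target=t, pred=t + 0.2) == pytest.approx(0.2)

    def test_zero_prediction_equals_target_rms(self, rng):
        t = rng.normal(size=(40, 3))
        rms = float(np.sqrt(np.mean(t**2)))
        assert mk.intended_rmse(target=t, pred=np.zeros_like(t)) == pytest.approx(rms)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="H = 0"):
            mk.intended_rmse(target=np.zeros((0, 1)), pred=np.zeros((0, 1)))

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            h, m = rng.integers(1, 40), rng.integers(1, 4)
            t, p = rng.normal(size=(h, m)), rng.normal(size=(h, m))
            assert abs(mk.intended_rmse(target=t, pred=p) - double_loop_rmse(t, p)) < 1e-12


class TestUnintendedRmse:
    def test_zero_stationary_predictions(self):
        assert mk.unintended_rmse(pred_stationary=np.zeros((20, 2))) == 0.0

    def test_two_stationary_dofs_mixed(self):
        p = np.column_stack([np.full(50, 0.1), np.zeros(50)])
        assert mk.unintended_rmse(pred_stationary=p) == pytest.approx(np.sqrt(0.005))

    @given(st.floats(min_value=-3, max_value=3, allow_nan=False))
    def test_homogeneous_in_scale(self, c):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(25, 2))
        base = mk.unintended_rmse(pred_stationary=p)
        assert mk.unintended_rmse(pred_stationary=c * p) == pytest.approx(abs(c) * base)

    def test_absent_when_no_stationary_dofs(self):
        assert mk.unintended_rmse(pred_stationary=None) is None
        assert mk.unintended_rmse(pred_stationary=np.zeros((10, 0))) is None

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            p = rng.normal(size=(rng.integers(1, 40), rng.integers(1, 4)))
            assert abs(mk.unintended_rmse(pred_stationary=p) - double_loop_xrmse(p)) < 1e-12


class TestAggregate:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["movement", "attempt", "intended", "unintended"])

    def test_single_attempt_passthrough(self):
        rep = mk.aggregate(self._df([("HC", 0, 0.3, 0.05)]))
        assert rep.intended == 0.3 and rep.unintended == 0.05

    def test_mean_over_attempts(self):
        rep = mk.aggregate(self._df([("HC", 0, 0.2, np.nan), ("HC", 1, 0.4, np.nan)]))
        assert rep.intended == pytest.approx(0.3)
        assert rep.unintended is None

    def test_permutation_invariant(self, rng):
        rows = [
            ("HC", a, float(rng.uniform()), float(rng.uniform())) for a in range(5)
        ] + [("WF", a, float(rng.uniform()), float(rng.uniform())) for a in range(5)]
        df = self._df(rows)
        rep1 = mk.aggregate(df)
        rep2 = mk.aggregate(df.sample(frac=1, random_state=0))
        assert rep1.intended == pytest.approx(rep2.intended)
        assert rep1.unintended == pytest.approx(rep2.unintended)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no attempts"):
            mk.aggregate(self._df([]))


class TestClassifyFunctional:
    @pytest.mark.parametrize(
        "intended,unintended,expected",
        [
            (0.36, 0.02, True),   # clearly inside both bounds
            (0.48, 0.11, False),  # outside both
            (0.37, 0.04, True),   # on the unintended boundary: inclusive
            (0.45, 0.0, True),    # on the intended boundary: inclusive
            (0.46, 0.0, False),
            (0.30, 0.05, False),
        ],
    )
    def test_inclusive_thresholds(self, intended, unintended, expected):
        assert mk.classify_functional(intended, unintended) is expected

    def test_single_dof_compares_intended_only(self):
        assert mk.classify_functional(0.40, None) is True
        assert mk.classify_functional(0.50, None) is False

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            mk.classify_functional(-0.1, 0.0)


class TestSelectBestCombination:
    def test_single_candidate(self):
        assert mk.select_best_combination({"HC/WS": (0.4, 0.02)}) == "HC/WS"

    def test_lowest_sum_wins(self):
        best = mk.select_best_combination({"A": (0.40, 0.00), "B": (0.36, 0.10)})
        assert best == "A"  # 0.40 < 0.46

    def test_tie_breaks_on_unintended_then_name(self):
        assert (
            mk.select_best_combination({"B": (0.30, 0.10), "A": (0.35, 0.05)}) == "A"
        )
        assert (
            mk.select_best_combination({"B": (0.30, 0.10), "A": (0.30, 0.10)}) == "A"
        )

    def test_absent_unintended_counts_as_zero(self):
        assert mk.select_best_combination({"HC": (0.4, None), "HO": (0.45, None)}) == "HC"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mk.select_best_combination({})


class TestGroupComparison:
    def test_identical_groups_pvalue_one(self):
        g = [1.0, 1.0, 1.0]
        res = mk.group_comparison([g, g, g], design="independent")
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.pvalue == pytest.approx(1.0)

    def test_paired_identical_vectors_degenerate(self):
        res = mk.group_comparison([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], design="paired")
        assert res.degenerate

    def test_separated_groups_significant(self, rng):
        a = rng.normal(loc=0.0, scale=0.1, size=7)
        b = rng.normal(loc=5.0, scale=0.1, size=7)
        res = mk.group_comparison([a, b], design="independent")
        assert res.pvalue < 0.05
        # cross-check against the exact two-sample rank enumeration
        from scipy.stats import mannwhitneyu

        exact = mannwhitneyu(a, b, method="exact").pvalue
        assert exact < 0.05

    def test_paired_shift_detected(self, rng):
        a = rng.normal(size=20)
        res = mk.group_comparison([a, a + 1.0], design="paired")
        assert res.pvalue < 0.01 and res.method == "wilcoxon"

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            mk.group_comparison([[1.0, 2.0]], design="independent")
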