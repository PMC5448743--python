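"""Fold-change/t filtering, stepwise discriminant selection and validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirisk.discovery import (
    differential_candidates,
    stepwise_discriminant,
    subgroup_comparison,
    validate_marker,
)
from mirisk.quantification import ExpressionMatrix


def _expr_from_qrel(q_rel: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(delta_ct=-np.log2(q_rel), q_rel=q_rel)


def _two_group(n0=10, n1=10):
    return np.r_[np.zeros(n0, int), np.ones(n1, int)]


class TestDifferentialCandidates:
    def _build(self, seed=0):
        rng = np.random.default_rng(seed)
        labels = _two_group(12, 12)
        rows = {
            # strong up-regulation in group 1, low noise → passes
            "up": np.r_[rng.normal(0.25, 0.05, 12), rng.normal(0.60, 0.08, 12)],
            # strong down-regulation → passes
            "down": np.r_[rng.normal(0.80, 0.10, 12), rng.normal(0.18, 0.04, 12)],
            # significant but fold 1.5 → inside [0.5, 2] → fails
            "mild": np.r_[rng.normal(1.00, 0.05, 12), rng.normal(1.50, 0.05, 12)],
            # no effect → fails
            "flat": rng.normal(1.0, 0.2, 24),
        }
        q = pd.DataFrame(rows).T
        q.columns = [f"s{i}" for i in range(24)]
        return _expr_from_qrel(q), labels

    def test_filter_logic(self):
        expr, labels = self._build()
        rep = differential_candidates(expr, labels)
        assert rep.table.loc["up", "passed_filter"]
        assert rep.table.loc["down", "passed_filter"]
        assert not rep.table.loc["mild", "passed_filter"]
        assert rep.table.loc["mild", "p"] < 0.05  # fails on fold alone
        assert not rep.table.loc["flat", "passed_filter"]

    def test_label_swap_maps_fold_to_reciprocal(self):
        expr, labels = self._build()
        rep1 = differential_candidates(expr, labels)
        rep2 = differential_candidates(expr, 1 - labels)
        np.testing.assert_allclose(
            rep1.table["fold"].to_numpy(), 1.0 / rep2.table["fold"].to_numpy()
        )
        pd.testing.assert_series_equal(
            rep1.table["passed_filter"], rep2.table["passed_filter"]
        )

    def test_zero_baseline_mean_excluded_with_warning(self):
        labels = _two_group(3, 3)
        q = pd.DataFrame(
            [[0.0, 0.0, 0.0, 1.0, 1.1, 0.9]], index=["z"],
            columns=[f"s{i}" for i in range(6)],
        )
        with pytest.warns(UserWarning, match="zero"):
            rep = differential_candidates(_expr_from_qrel(q + 1e-300 * 0), labels)
        assert not rep.table.loc["z", "passed_filter"]

    def test_requires_both_groups(self):
        expr, _ = self._build()
        with pytest.raises(ValueError):
            differential_candidates(expr, np.zeros(24, int))


class TestStepwiseDiscriminant:
    def test_single_candidate_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        labels = _two_group(15, 15)
        x = rng.normal(0, 1, 30) + 1.2 * labels
        q = pd.DataFrame([x], index=["m"], columns=[f"s{i}" for i in range(30)])
        selected, f_vals = stepwise_discriminant(q, labels, alpha_enter=0.5)
        t, _ = stats.ttest_ind(x[labels == 1], x[labels == 0], equal_var=True)
        assert selected == ["m"]
        assert f_vals["m"] == pytest.approx(t**2, rel=1e-10)

    def test_separating_variable_enters_first_with_max_f(self):
        rng = np.random.default_rng(2)
        labels = _two_group(20, 20)
        noise = rng.normal(0, 1, (5, 40))
        signal = labels * 3.0 + rng.normal(0, 0.3, 40)
        q = pd.DataFrame(
            np.vstack([noise[:3], signal, noise[3:]]),
            index=["n0", "n1", "n2", "sig", "n3", "n4"],
            columns=[f"s{i}" for i in range(40)],
        )
        selected, f_vals = stepwise_discriminant(q, labels)
        assert selected[0] == "sig"
        assert f_vals["sig"] == max(f_vals)

    def test_no_significant_variable_gives_empty_selection(self):
        rng = np.random.default_rng(3)
        labels = _two_group(10, 10)
        q = pd.DataFrame(
            rng.normal(0, 1, (4, 20)), index=list("abcd"),
            columns=[f"s{i}" for i in range(20)],
        )
        selected, f_vals = stepwise_discriminant(q, labels, alpha_enter=1e-6)
        assert selected == [] and len(f_vals) == 0

    def test_duplicate_of_entered_variable_never_enters(self):
        rng = np.random.default_rng(4)
        labels = _two_group(15, 15)
        sig = labels * 2.0 + rng.normal(0, 0.5, 30)
        q = pd.DataFrame(
            [sig, sig, rng.normal(0, 1, 30)], index=["sig", "dup", "noise"],
            columns=[f"s{i}" for i in range(30)],
        )
        with pytest.warns(UserWarning, match="singular"):
            selected, _ = stepwise_discriminant(q, labels)
        assert "dup" not in selected or "sig" not in selected  # only one copy enters
        assert len([v for v in selected if v in ("sig", "dup")]) == 1

    def test_scale_invariance(self):
        """Standardizing the variables does not change the selected set."""
        rng = np.random.default_rng(5)
        labels = _two_group(20, 20)
        q = pd.DataFrame(
            rng.normal(0, 1, (6, 40)) + labels * rng.uniform(0, 1.5, (6, 1)),
            index=[f"m{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(40)],
        )
        scaled = q.sub(q.mean(axis=1), axis=0).div(q.std(axis=1), axis=0)
        sel_raw, _ = stepwise_discriminant(q, labels)
        sel_std, _ = stepwise_discriminant(scaled, labels)
        assert sel_raw == sel_std

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            stepwise_discriminant(pd.DataFrame(), _two_group(2, 2))


class TestValidation:
    def test_validate_marker_reports_group_stats(self):
        rng = np.random.default_rng(6)
        labels = _two_group(33, 32)
        up = np.r_[rng.normal(0.027, 0.02, 33).clip(0.001), rng.normal(0.062, 0.05, 32).clip(0.001)]
        q = pd.DataFrame([up], index=["marker"], columns=[f"s{i}" for i in range(65)])
        res = validate_marker(_expr_from_qrel(q), labels, ["marker"])
        assert res.loc["marker", "mean_ath"] > res.loc["marker", "mean_nonath"]
        t, p = stats.ttest_ind(up[labels == 1], up[labels == 0], equal_var=True)
        assert res.loc["marker", "p"] == pytest.approx(p)

    def test_missing_marker_raises(self):
        q = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["m"], columns=list("abcd"))
        with pytest.raises(KeyError):
            validate_marker(_expr_from_qrel(q), [0, 0, 1, 1], ["absent"])


class TestSubgroupComparison:
    def test_two_categories_is_t_test_and_f_is_t_squared(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, 20)
        cats = np.repeat(["tia", "lacunar"], 10)
        t_stat, p_t = subgroup_comparison(vals, cats)
        # three-category ANOVA on a duplicated two-category design: F = t²
        f_stat, _ = stats.f_oneway(vals[:10], vals[10:])
        assert t_stat**2 == pytest.approx(f_stat, rel=1e-10)

    def test_three_categories_uses_anova(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, 30)
        cats = np.repeat(["no", "small", "branch"], 10)
        f_ours, p_ours = subgroup_comparison(vals, cats)
        f_ref, p_ref = stats.f_oneway(vals[:10], vals[10:20], vals[20:])
        assert f_ours == pytest.approx(f_ref)
        assert p_ours == pytest.approx(p_ref)

    def test_identical_categories_give_f_zero(self):
        vals = np.tile([1.0, 2.0, 3.0], 3)
        cats = np.repeat(list("abc"), 3)
        f, p = subgroup_comparison(vals, cats)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_null_calibration_three_groups(self):
        """Equal-mean groups rejected at ≈ the nominal 5% rate."""
        rng = np.random.default_rng(9)
        reps, rej = 1000, 0
        cats = np.repeat(list("abc"), 8)
        for _ in range(reps):
            _, p = subgroup_comparison(rng.normal(0, 1, 24), cats)
            rej += p < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_small_category_errors(self):
        with pytest.raises(ValueError):
            subgroup_comparison([1.0, 2.0, 3.0], ["a", "a", "b"])
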