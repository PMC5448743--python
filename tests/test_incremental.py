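"""Discrimination and reclassification metrics: AUC, DeLong, NRI, IDI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from mirisk.incremental import (
    classification_metrics,
    compare_auc,
    idi,
    nri,
    reclassification_counts,
    roc_auc,
)


def _brute_force_auc(scores, labels):
    """Exhaustive pairwise-comparison oracle: P(event > nonevent) + ½ ties."""
    scores = np.asarray(scores, float)
    ev = scores[np.asarray(labels) == 1]
    ne = scores[np.asarray(labels) == 0]
    total = 0.0
    for a in ev:
        for b in ne:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(ev) * len(ne))


class TestClassificationMetrics:
    def test_perfect_probabilities(self):
        labels = [1, 1, 0, 0]
        rep = classification_metrics([1.0, 0.9, 0.1, 0.0], labels)
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (100.0, 100.0, 100.0)

    def test_counts_at_study_size(self):
        """TP=24 FN=8 TN=27 FP=6 → 75.0 / 81.8 / 78.5 (n = 32 + 33)."""
        labels = np.r_[np.ones(32, int), np.zeros(33, int)]
        probs = np.r_[np.full(24, 0.9), np.full(8, 0.1), np.full(27, 0.1), np.full(6, 0.9)]
        rep = classification_metrics(probs, labels)
        assert round(rep.sensitivity, 1) == 75.0
        assert round(rep.specificity, 1) == 81.8
        assert round(rep.accuracy, 1) == 78.5

    def test_threshold_zero_boundary(self):
        labels = [1, 0, 1, 0]
        rep = classification_metrics([0.4, 0.3, 0.6, 0.7], labels, threshold=0.0)
        assert rep.sensitivity == 100.0 and rep.specificity == 0.0

    def test_accuracy_decomposition(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        probs = rng.random(40)
        rep = classification_metrics(probs, labels)
        n_e, n_ne = labels.sum(), len(labels) - labels.sum()
        recomposed = (rep.sensitivity * n_e + rep.specificity * n_ne) / len(labels)
        assert rep.accuracy == pytest.approx(recomposed)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            classification_metrics([0.4, 0.6], [1, 1])


class TestRocAuc:
    def test_hand_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(1)
        s = rng.random(20)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        assert roc_auc(s, y) == pytest.approx(1 - roc_auc(s, 1 - y))

    def test_constant_scores_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            assert roc_auc([0.5, 0.5, 0.5], [0, 1, 1]) == 0.5

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 1),
                st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.5, 0.75, 1.0]),
            ),
            min_size=2,
            max_size=12,
        ).filter(lambda rows: {r[0] for r in rows} == {0, 1})
    )
    def test_matches_exhaustive_pair_oracle(self, rows):
        labels = [r[0] for r in rows]
        scores = [r[1] for r in rows]
        assert roc_auc(scores, labels) == pytest.approx(
            _brute_force_auc(scores, labels), abs=1e-12
        )

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.random(50)
            y = rng.integers(0, 2, 50)
            y[:2] = [0, 1]
            assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestCompareAuc:
    def test_model_vs_itself_zero(self):
        rng = np.random.default_rng(3)
        p = rng.random(30)
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        d, pval = compare_auc(p, p, y)
        assert d == 0.0 and pval == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        d, _ = compare_auc(p, 1 / (1 + np.exp(-5 * p)), y)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_informative_added_covariate_detected(self):
        """Nested logistic scores: an informative addition shifts the AUC."""
        rng = np.random.default_rng(5)
        hits_alt, hits_null = 0, 0
        reps = 60
        for _ in range(reps):
            n = 200
            x1 = rng.normal(0, 1, n)
            x2 = rng.normal(0, 1, n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(x1 + 1.2 * x2)))).astype(int)
            if y.sum() in (0, n):
                continue
            old = x1
            _, p_alt = compare_auc(old, x1 + 1.2 * x2, y)
            _, p_null = compare_auc(old, x1 + 0.02 * rng.normal(0, 1, n), y)
            hits_alt += p_alt < 0.05
            hits_null += p_null < 0.05
        assert hits_alt / reps > 0.5
        assert hits_null / reps < 0.15


class TestNri:
    def test_hand_enumeration(self):
        """Events move (+,+,−), nonevents (+,−,−) → NRI = 2/3."""
        y = [1, 1, 1, 0, 0, 0]
        old = [0.5] * 6
        new = [0.6, 0.7, 0.4, 0.6, 0.4, 0.3]
        rep = nri(old, new, y)
        assert rep.nri == pytest.approx(2 / 3)
        assert (rep.up_events, rep.down_events) == (2, 1)
        assert (rep.up_nonevents, rep.down_nonevents) == (1, 2)

    def test_maximum_two(self):
        y = [1, 1, 0, 0]
        rep = nri([0.5, 0.5, 0.5, 0.5], [0.6, 0.7, 0.4, 0.3], y)
        assert rep.nri == 2.0

    def test_no_change_is_zero(self):
        y = [1, 0, 1, 0]
        p = [0.2, 0.4, 0.6, 0.8]
        rep = nri(p, list(p), y)
        assert rep.nri == 0.0 and rep.nri_p == 1.0

    def test_label_swap_negates(self):
        rng = np.random.default_rng(6)
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        old, new = rng.random(20), rng.random(20)
        assert nri(old, new, y).nri == pytest.approx(-nri(old, new, 1 - y).nri)

    def test_range_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            y = rng.integers(0, 2, 12)
            y[:2] = [0, 1]
            v = nri(rng.random(12), rng.random(12), y).nri
            assert -2.0 <= v <= 2.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            nri([0.1, 0.2], [0.2, 0.3], [1, 1])


class TestIdi:
    def test_forced_value(self):
        """+0.1 for every event, −0.1 for every nonevent → IDI = 0.2."""
        y = [1, 1, 0, 0]
        old = [0.6, 0.4, 0.5, 0.3]
        new = [0.7, 0.5, 0.4, 0.2]
        assert idi(old, new, y).idi == pytest.approx(0.2)

    def test_no_change_is_zero(self):
        y = [1, 0, 1, 0]
        p = [0.2, 0.4, 0.6, 0.8]
        assert idi(p, list(p), y).idi == 0.0

    def test_equals_discrimination_slope_difference(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        old, new = rng.random(40), rng.random(40)
        slope_old = old[y == 1].mean() - old[y == 0].mean()
        slope_new = new[y == 1].mean() - new[y == 0].mean()
        assert idi(old, new, y).idi == pytest.approx(slope_new - slope_old)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.zeros(8, int), np.ones(8, int)]
        old, new = rng.random(16), rng.random(16)
        assert idi(old, new, y).idi == pytest.approx(-idi(old, new, 1 - y).idi)


def test_reclassification_counts():
    y = [1, 1, 1, 0, 0]
    old = [0.6, 0.4, 0.4, 0.6, 0.4]   # events: 1 correct, 2 miss; nonevents: 1 miss
    new = [0.4, 0.6, 0.4, 0.4, 0.4]   # first event newly missed, second rescued
    out = reclassification_counts(old, new, y)
    assert out["events"]["misclassified_old"] == 2
    assert out["events"]["reclassified_correct"] == 1
    assert out["events"]["newly_misclassified"] == 1
    assert out["nonevents"]["misclassified_old"] == 1
    assert out["nonevents"]["reclassified_correct"] == 1
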