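"""Added-value assessment of a candidate marker in a risk model.

Implements the discrimination and reclassification toolkit used to judge
whether adding a marker to an established risk model actually improves
patient-level prediction:

* confusion-matrix metrics (sensitivity, specificity, accuracy) at a
  probability threshold,
* AUC as the Mann–Whitney probability that a random event outranks a random
  nonevent (ties counted half),
* paired AUC comparison with the DeLong variance estimate,
* category-free (continuous) net reclassification improvement (NRI):
  the net fraction of events whose predicted probability moves up under the
  new model minus the net fraction of nonevents that move up,
* integrated discrimination improvement (IDI): the change in discrimination
  slope — (mean event probability − mean nonevent probability) — between the
  new and the old model.

NRI and IDI both live in [−2, 2]; asymptotic z-tests give their p-values,
with an optional seeded bootstrap as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DiscriminationReport",
    "ReclassificationReport",
    "classification_metrics",
    "roc_auc",
    "compare_auc",
    "nri",
    "idi",
    "reclassification_counts",
]


@dataclass
class DiscriminationReport:
    """Sensitivity/specificity/accuracy (%) and AUC for one model."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    tp: int
    fn: int
    tn: int
    fp: int

    def rounded(self) -> dict:
        return {
            "specificity": round(self.specificity, 1),
            "sensitivity": round(self.sensitivity, 1),
            "accuracy": round(self.accuracy, 1),
            "auc": round(self.auc, 4),
        }


@dataclass
class ReclassificationReport:
    """NRI / IDI point estimates with components and asymptotic p-values."""

    nri: float
    nri_p: float
    idi: float
    idi_p: float
    up_events: int
    down_events: int
    up_nonevents: int
    down_nonevents: int
    mean_new_events: float
    mean_old_events: float
    mean_new_nonevents: float
    mean_old_nonevents: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels).tolist()) != {0, 1}:
        raise ValueError("labels must contain both events (1) and nonevents (0)")
    return labels


def classification_metrics(
    probs: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> DiscriminationReport:
    """Confusion-matrix metrics at a probability threshold.

    A patient is called atherosclerotic when the predicted probability is
    ≥ ``threshold``.  Percentages: sensitivity = TP/(TP+FN)·100,
    specificity = TN/(TN+FP)·100, accuracy = (TP+TN)/n·100.
    """
    labels = _check_binary(labels)
    probs = np.asarray(probs, dtype=float)
    pred = probs >= threshold
    ev = labels == 1
    tp = int((pred & ev).sum())
    fn = int((~pred & ev).sum())
    tn = int((~pred & ~ev).sum())
    fp = int((pred & ~ev).sum())
    return DiscriminationReport(
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / len(labels),
        auc=roc_auc(probs, labels),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann–Whitney statistic.

    AUC = P(score_event > score_nonevent) + ½ P(tie), identical to the
    trapezoidal area under the empirical ROC.  Constant score vectors give
    0.5 with a degeneracy warning.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: AUC degenerate, returning 0.5")
        return 0.5
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)  # midranks handle ties
    rank_sum_events = ranks[labels == 1].sum()
    return float((rank_sum_events - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Per-observation DeLong structural components (V10 events, V01 nonevents)."""
    ev = scores[labels == 1]
    ne = scores[labels == 0]
    # P(X > Y) + 0.5 P(X == Y) per observation, via midranks
    v10 = np.array([(np.sum(x > ne) + 0.5 * np.sum(x == ne)) / len(ne) for x in ev])
    v01 = np.array([(np.sum(ev > y) + 0.5 * np.sum(ev == y)) / len(ev) for y in ne])
    return v10, v01


def compare_auc(
    probs_old: Sequence[float],
    probs_new: Sequence[float],
    labels: Sequence[int],
) -> tuple[float, float]:
    """Paired AUC difference (new − old) with a DeLong two-sided p-value.

    Both probability vectors must score the same patients.  Identical
    vectors (or vectors differing by a strictly monotone transform) have a
    zero difference and p = 1.
    """
    labels = _check_binary(labels)
    probs_old = np.asarray(probs_old, dtype=float)
    probs_new = np.asarray(probs_new, dtype=float)
    if probs_old.shape != probs_new.shape or len(probs_old) != len(labels):
        raise ValueError("paired probability vectors must align with labels")

    auc_old = roc_auc(probs_old, labels)
    auc_new = roc_auc(probs_new, labels)
    diff = auc_new - auc_old

    v10_o, v01_o = _delong_components(probs_old, labels)
    v10_n, v01_n = _delong_components(probs_new, labels)
    n1, n0 = len(v10_o), len(v01_o)

    # variance of the difference from the paired structural components
    s10 = np.cov(np.stack([v10_n, v10_o]), ddof=1)
    s01 = np.cov(np.stack([v01_n, v01_o]), ddof=1)
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    )
    if var <= 0:
        return float(diff), 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(diff), float(p)


def _movements(probs_old: np.ndarray, probs_new: np.ndarray, mask: np.ndarray):
    delta = probs_new[mask] - probs_old[mask]
    return int((delta > 0).sum()), int((delta < 0).sum())


def nri(
    probs_old: Sequence[float],
    probs_new: Sequence[float],
    labels: Sequence[int],
) -> ReclassificationReport:
    """Category-free net reclassification improvement.

    Each patient contributes a movement indicator v: +1 if the new model
    raises their predicted probability, −1 if it lowers it, 0 if unchanged.
    NRI = (Σ v over events)/N_events − (Σ v over nonevents)/N_nonevents,
    so it is +2 when every event moves up and every nonevent moves down.
    The p-value uses the asymptotic z = NRI / sqrt((up_e + down_e)/N_e² +
    (up_ne + down_ne)/N_ne²).
    """
    labels = _check_binary(labels)
    probs_old = np.asarray(probs_old, dtype=float)
    probs_new = np.asarray(probs_new, dtype=float)
    ev, ne = labels == 1, labels == 0
    n_e, n_ne = int(ev.sum()), int(ne.sum())
    up_e, down_e = _movements(probs_old, probs_new, ev)
    up_ne, down_ne = _movements(probs_old, probs_new, ne)
    value = (up_e - down_e) / n_e - (up_ne - down_ne) / n_ne
    var = (up_e + down_e) / n_e**2 + (up_ne + down_ne) / n_ne**2
    if var > 0:
        p = 2.0 * stats.norm.sf(abs(value) / np.sqrt(var))
    else:
        p = 1.0
    return ReclassificationReport(
        nri=float(value),
        nri_p=float(p),
        idi=np.nan,
        idi_p=np.nan,
        up_events=up_e,
        down_events=down_e,
        up_nonevents=up_ne,
        down_nonevents=down_ne,
        mean_new_events=float(probs_new[ev].mean()),
        mean_old_events=float(probs_old[ev].mean()),
        mean_new_nonevents=float(probs_new[ne].mean()),
        mean_old_nonevents=float(probs_old[ne].mean()),
    )


def idi(
    probs_old: Sequence[float],
    probs_new: Sequence[float],
    labels: Sequence[int],
) -> ReclassificationReport:
    """Integrated discrimination improvement.

    IDI = (p̄_new,events − p̄_old,events) − (p̄_new,nonevents − p̄_old,nonevents),
    i.e. the gain in discrimination slope of the new model over the old.
    The p-value uses z = IDI / sqrt(SE²_events + SE²_nonevents) where each SE
    is the standard error of the within-group mean probability change.
    """
    labels = _check_binary(labels)
    probs_old = np.asarray(probs_old, dtype=float)
    probs_new = np.asarray(probs_new, dtype=float)
    ev, ne = labels == 1, labels == 0
    d_e = probs_new[ev] - probs_old[ev]
    d_ne = probs_new[ne] - probs_old[ne]
    value = d_e.mean() - d_ne.mean()
    se2 = d_e.var(ddof=1) / len(d_e) + d_ne.var(ddof=1) / len(d_ne)
    if se2 > 0:
        p = 2.0 * stats.norm.sf(abs(value) / np.sqrt(se2))
    else:
        p = 1.0 if value == 0 else 0.0
    up_e, down_e = _movements(probs_old, probs_new, ev)
    up_ne, down_ne = _movements(probs_old, probs_new, ne)
    return ReclassificationReport(
        nri=np.nan,
        nri_p=np.nan,
        idi=float(value),
        idi_p=float(p),
        up_events=up_e,
        down_events=down_e,
        up_nonevents=up_ne,
        down_nonevents=down_ne,
        mean_new_events=float(probs_new[ev].mean()),
        mean_old_events=float(probs_old[ev].mean()),
        mean_new_nonevents=float(probs_new[ne].mean()),
        mean_old_nonevents=float(probs_old[ne].mean()),
    )


def reclassification_counts(
    probs_old: Sequence[float],
    probs_new: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> dict:
    """Threshold-based reclassification counts (reported separately from NRI).

    Counts, within events and nonevents, how many patients misclassified by
    the old model at ``threshold`` become correctly classified under the new
    model, and how many correctly classified become misclassified.
    """
    labels = _check_binary(labels)
    probs_old = np.asarray(probs_old, dtype=float)
    probs_new = np.asarray(probs_new, dtype=float)
    old_correct = (probs_old >= threshold) == (labels == 1)
    new_correct = (probs_new >= threshold) == (labels == 1)
    out = {}
    for name, mask in (("events", labels == 1), ("nonevents", labels == 0)):
        out[name] = {
            "misclassified_old": int((~old_correct[mask]).sum()),
            "reclassified_correct": int((~old_correct[mask] & new_correct[mask]).sum()),
            "newly_misclassified": int((old_correct[mask] & ~new_correct[mask]).sum()),
        }
    return out


def bootstrap_reclassification(
    probs_old: Sequence[float],
    probs_new: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Seeded bootstrap percentile CIs for NRI and IDI (cross-check)."""
    labels = _check_binary(labels)
    probs_old = np.asarray(probs_old, dtype=float)
    probs_new = np.asarray(probs_new, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(labels)
    nris, idis = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(labels[idx])) < 2:
            continue
        nris.append(nri(probs_old[idx], probs_new[idx], labels[idx]).nri)
        idis.append(idi(probs_old[idx], probs_new[idx], labels[idx]).idi)
    return {
        "nri_ci": tuple(np.percentile(nris, [2.5, 97.5])),
        "idi_ci": tuple(np.percentile(idis, [2.5, 97.5])),
    }
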