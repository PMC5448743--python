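"""Candidate-marker discovery and validation.

Differential miRNAs are screened by a fold-change filter on the relative
quantity Q_rel (outside [0.5, 2.0]) combined with a two-sided equal-variance
t-test (p < 0.05).  The surviving candidates are reduced to a compact marker
set by forward stepwise linear discriminant analysis driven by partial
Wilks' Λ F-to-enter statistics, and the chosen markers are re-tested in an
independent validation cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantification import ExpressionMatrix

__all__ = [
    "MarkerReport",
    "differential_candidates",
    "stepwise_discriminant",
    "validate_marker",
    "subgroup_comparison",
]


@dataclass
class MarkerReport:
    """Per-miRNA differential statistics and selection flags.

    ``table`` has one row per miRNA with columns ``mean_nonath``, ``sd_nonath``,
    ``mean_ath``, ``sd_ath``, ``fold`` (atherosclerotic over non-atherosclerotic
    mean), ``p``, ``passed_filter``, ``discriminant_selected`` and
    ``F_to_enter`` (NaN unless selected).
    """

    table: pd.DataFrame
    selected: list[str] = field(default_factory=list)

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index[self.table["passed_filter"]])


def differential_candidates(
    expr: ExpressionMatrix,
    labels: Sequence[int],
    fold_bounds: tuple[float, float] = (0.5, 2.0),
    alpha: float = 0.05,
) -> MarkerReport:
    """Filter miRNAs with <0.5× or >2.0× group fold change and p < alpha.

    The test is a two-sided Student's t-test (equal variances) on Q_rel.
    Fold change is the atherosclerotic group mean over the non-atherosclerotic
    group mean; miRNAs with a zero non-atherosclerotic mean have an undefined
    fold and are excluded with a warning.
    """
    labels = np.asarray(labels).astype(int)
    groups = set(labels.tolist())
    if groups != {0, 1}:
        raise ValueError("labels must contain both groups coded 0/1")
    mask1 = labels == 1
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    q = expr.q_rel
    q1 = q.loc[:, mask1]
    q0 = q.loc[:, ~mask1]
    mean1, mean0 = q1.mean(axis=1), q0.mean(axis=1)
    sd1, sd0 = q1.std(axis=1, ddof=1), q0.std(axis=1, ddof=1)

    zero_base = mean0 == 0
    if zero_base.any():
        warnings.warn(
            f"{int(zero_base.sum())} miRNA(s) with zero non-atherosclerotic "
            "mean excluded (fold change undefined)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean1 / mean0
    fold[zero_base] = np.nan

    _, pvals = stats.ttest_ind(q1, q0, axis=1, equal_var=True)
    pvals = pd.Series(pvals, index=q.index)

    lo, hi = fold_bounds
    passed = ((fold < lo) | (fold > hi)) & (pvals < alpha) & ~zero_base

    table = pd.DataFrame(
        {
            "mean_nonath": mean0,
            "sd_nonath": sd0,
            "mean_ath": mean1,
            "sd_ath": sd1,
            "fold": fold,
            "p": pvals,
            "passed_filter": passed.fillna(False).astype(bool),
            "discriminant_selected": False,
            "F_to_enter": np.nan,
        }
    )
    return MarkerReport(table=table)


def _wilks_lambda(X: np.ndarray, mask1: np.ndarray, cols: list[int]) -> float:
    """Wilks' Λ = det(W)/det(T) for the given column subset (two groups)."""
    if not cols:
        return 1.0
    sub = X[:, cols]
    grand = sub.mean(axis=0, keepdims=True)
    t_mat = (sub - grand).T @ (sub - grand)
    w_mat = np.zeros_like(t_mat)
    for m in (mask1, ~mask1):
        g = sub[m]
        gc = g - g.mean(axis=0, keepdims=True)
        w_mat += gc.T @ gc
    sign_t, logdet_t = np.linalg.slogdet(t_mat)
    sign_w, logdet_w = np.linalg.slogdet(w_mat)
    if sign_t <= 0 or sign_w <= 0:
        return np.nan  # singular: caller skips the variable
    return float(np.exp(logdet_w - logdet_t))


def stepwise_discriminant(
    candidates: pd.DataFrame,
    labels: Sequence[int],
    alpha_enter: float = 0.05,
) -> tuple[list[str], pd.Series]:
    """Forward stepwise linear discriminant variable selection.

    Parameters
    ----------
    candidates
        Q_rel submatrix, miRNA × sample (rows are the variables).
    labels
        Binary group per sample.
    alpha_enter
        Entry significance level for the partial Wilks' Λ F-to-enter test.

    At each step the excluded variable with the largest F-to-enter
    F = (n − g − p) · (Λ_p / Λ_{p+1} − 1) / (g − 1), with p variables already
    entered and g = 2 groups, is entered if its p-value (F distribution with
    (g − 1, n − g − p) df) is below ``alpha_enter``.  Variables that make the
    covariance singular (e.g. duplicates of an entered variable) are skipped.

    Returns the entered variable names in entry order and a Series of their
    F-to-enter values at the step of entry.
    """
    if candidates.shape[0] == 0:
        raise ValueError("candidate set is empty")
    labels = np.asarray(labels).astype(int)
    mask1 = labels == 1
    X = candidates.to_numpy(dtype=float).T  # samples × variables
    names = list(candidates.index)
    n, n_vars = X.shape
    g = 2

    entered: list[int] = []
    f_at_entry: dict[str, float] = {}
    lambda_cur = 1.0

    while True:
        p = len(entered)
        df2 = n - g - p
        if df2 <= 0:
            break
        best: tuple[float, int, float] | None = None  # (F, col, lambda_new)
        for j in range(n_vars):
            if j in entered:
                continue
            lam = _wilks_lambda(X, mask1, entered + [j])
            if not np.isfinite(lam) or lam <= 0:
                warnings.warn(f"variable '{names[j]}' skipped (singular covariance)")
                continue
            if lam >= lambda_cur:
                f_stat = 0.0
            else:
                f_stat = df2 / (g - 1) * (lambda_cur / lam - 1.0)
            if best is None or f_stat > best[0]:
                best = (f_stat, j, lam)
        if best is None:
            break
        f_stat, j, lam = best
        p_val = stats.f.sf(f_stat, g - 1, df2)
        if p_val >= alpha_enter:
            break
        entered.append(j)
        f_at_entry[names[j]] = f_stat
        lambda_cur = lam

    order = [names[j] for j in entered]
    return order, pd.Series(f_at_entry, dtype=float)


def validate_marker(
    expr_validation: ExpressionMatrix,
    labels: Sequence[int],
    marker_ids: Sequence[str],
) -> pd.DataFrame:
    """Group comparison of Q_rel for chosen markers in a validation cohort.

    Two-sided equal-variance t-test per marker; returns group means ± SD and p.
    """
    labels = np.asarray(labels).astype(int)
    mask1 = labels == 1
    missing = [m for m in marker_ids if m not in expr_validation.q_rel.index]
    if missing:
        raise KeyError(f"markers absent from validation matrix: {missing}")
    q = expr_validation.q_rel.loc[list(marker_ids)]
    q1, q0 = q.loc[:, mask1], q.loc[:, ~mask1]
    _, pvals = stats.ttest_ind(q1, q0, axis=1, equal_var=True)
    return pd.DataFrame(
        {
            "mean_nonath": q0.mean(axis=1),
            "sd_nonath": q0.std(axis=1, ddof=1),
            "mean_ath": q1.mean(axis=1),
            "sd_ath": q1.std(axis=1, ddof=1),
            "p": pvals,
        },
        index=list(marker_ids),
    )


def subgroup_comparison(
    values: Sequence[float], categories: Sequence
) -> tuple[float, float]:
    """Compare marker expression across clinical subgroups.

    Two categories → two-sided Student's t-test; three or more → one-way
    ANOVA.  Returns ``(statistic, p)`` where the statistic is t for two
    groups and F otherwise.
    """
    values = np.asarray(values, dtype=float)
    categories = np.asarray(categories)
    levels = pd.unique(categories)
    groups = [values[categories == lv] for lv in levels]
    if len(groups) < 2:
        raise ValueError("need at least 2 categories")
    if any(len(grp) < 2 for grp in groups):
        raise ValueError("every category needs at least 2 samples")
    if len(groups) == 2:
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
    else:
        stat, p = stats.f_oneway(*groups)
    return float(stat), float(p)
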