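"""Reference-miRNA selection: candidate criteria and model-based stability.

A usable endogenous control must be (1) detected in every serum sample,
(2) essentially unchanged between groups (mean fold change within 0.9–1.1),
and (3) show no significant group difference (two-sided t-test, p > 0.05).
Candidates passing these screens are ranked by a two-group model-based
stability value in the NormFinder tradition: for each gene the score combines
its estimated group bias (gene × group interaction) with its intra-group
standard error, so that a low value means both "flat across groups" and
"quiet within groups".  Singles and all unordered pairs are scored; the
lowest-stability set is the recommended normalizer.

Stability is computed on log-scale expression.  Ct is already a log2
quantity, so negative Ct is the natural input (higher = more abundant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantification import CtPanel

__all__ = [
    "StabilityReport",
    "candidate_reference_filter",
    "normfinder_stability",
    "best_reference",
]


@dataclass
class StabilityReport:
    """Stability values for candidate reference sets.

    ``stability`` maps a tuple of miRNA ids (singleton or pair, sorted) to a
    non-negative stability value; ``best_set`` is the argmin, ties broken by
    lexicographic id order.
    """

    candidates: list[str]
    stability: dict[tuple[str, ...], float] = field(default_factory=dict)
    best_set: tuple[str, ...] = ()

    def sorted_sets(self) -> list[tuple[tuple[str, ...], float]]:
        return sorted(self.stability.items(), key=lambda kv: (kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"set": "/".join(k), "size": len(k), "stability": v}
            for k, v in self.sorted_sets()
        ]
        return pd.DataFrame(rows)


def candidate_reference_filter(
    panel: CtPanel,
    labels: Sequence[int],
    fold_change: pd.Series | None = None,
    fold_bounds: tuple[float, float] = (0.9, 1.1),
    alpha: float = 0.05,
) -> list[str]:
    """Screen miRNAs by the three reference-candidate criteria.

    Parameters
    ----------
    panel
        Imputed Ct panel.
    labels
        Binary group per sample (1 = atherosclerotic), aligned with columns.
    fold_change
        Optional per-miRNA mean fold change (group 1 over group 0) on the
        linear expression scale.  If omitted it is computed from the Ct group
        means as ``2 ** (mean_Ct_0 − mean_Ct_1)`` (lower Ct = higher
        expression).
    fold_bounds
        Inclusive bounds for "essentially unchanged" expression.
    alpha
        Significance level; candidates need p > alpha (no group difference).
        The test is a two-sided equal-variance t-test on the Ct (log) scale.

    Fold changes and tests are computed on sample-centered Ct (each sample's
    mean Ct over fully detected miRNAs subtracted), since per-sample loading
    offsets would otherwise move every miRNA's apparent fold change at once.
    """
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both groups must be present")
    mask1 = labels == 1

    detected_all = panel.detected.all(axis=1)
    # global-mean normalization: per-sample loading/extraction offsets are
    # common-mode across miRNAs and would shift every raw-Ct fold change
    # together; center each sample by its mean Ct over fully detected miRNAs
    center = panel.ct.loc[detected_all].mean(axis=0)
    ct = panel.ct.sub(center, axis=1)

    if fold_change is None:
        fold_change = np.power(
            2.0, ct.loc[:, ~mask1].mean(axis=1) - ct.loc[:, mask1].mean(axis=1)
        )
    fold_change = pd.Series(fold_change, index=ct.index).astype(float)
    lo, hi = fold_bounds
    fold_ok = (fold_change >= lo) & (fold_change <= hi)

    with np.errstate(invalid="ignore"):
        _, pvals = stats.ttest_ind(
            ct.loc[:, mask1], ct.loc[:, ~mask1], axis=1, equal_var=True
        )
    # zero-variance genes with equal group means yield NaN: trivially stable
    pvals = pd.Series(pvals, index=ct.index).fillna(1.0)
    not_different = pvals > alpha

    keep = detected_all & fold_ok & not_different
    return list(ct.index[keep])


def _interaction_and_variance(
    centered: np.ndarray, mask1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Raw gene×group interaction d-hat and within-group sample variances.

    ``centered`` is genes × samples, already sample-centered.  d-hat is the
    group mean minus the gene's unweighted two-group average, so it sums to 0
    over groups per gene and (by column centering) to 0 over genes per group.
    """
    g0 = centered[:, ~mask1]
    g1 = centered[:, mask1]
    m0 = g0.mean(axis=1)
    m1 = g1.mean(axis=1)
    gene_avg = (m0 + m1) / 2.0
    dhat = np.stack([m0 - gene_avg, m1 - gene_avg], axis=1)  # genes × 2
    s2 = np.stack([g0.var(axis=1, ddof=1), g1.var(axis=1, ddof=1)], axis=1)
    return dhat, s2


def normfinder_stability(
    values: pd.DataFrame,
    labels: Sequence[int],
    pairs: bool = True,
) -> StabilityReport:
    """Two-group model-based stability of candidate reference genes.

    Parameters
    ----------
    values
        Log-scale expression, genes × samples (for Ct data pass ``-ct``).
    labels
        Binary group per sample, aligned with the columns.
    pairs
        Also score all unordered pairs of candidates (pseudo-gene formed by
        averaging the two members' centered values).

    Notes
    -----
    The estimator follows the model-based two-group scheme:

    1. center each sample across the k candidate genes;
    2. estimate each gene's group bias d̂_ig (gene × group interaction) and
       within-group variance s²_ig from the centered values;
    3. bias-correct s²_ig for the centering step, solving
       E[s²_ig] = σ²_ig (1 − 2/k) + (1/k²) Σ_i' σ²_i'g, clamping negative
       solutions to zero;
    4. shrink d̂ empirically, d̃ = d̂ γ² / (γ² + σ̂²/n_g) with
       γ² = max(0, Var_i(d̂) − mean_i(σ̂²/n_g));
    5. stability = mean over groups of |d̃_ig| + sqrt(σ̂²_ig / n_g).

    Requires at least 3 candidates (the sample-centering is degenerate below
    that) and at least 2 samples per group.
    """
    k = values.shape[0]
    if k < 3:
        raise ValueError("need at least 3 candidate genes for sample centering")
    labels = np.asarray(labels).astype(int)
    mask1 = labels == 1
    n_g = np.array([(~mask1).sum(), mask1.sum()], dtype=float)
    if (n_g < 2).any():
        raise ValueError("need at least 2 samples per group")

    x = values.to_numpy(dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)

    dhat, s2 = _interaction_and_variance(centered, mask1)

    # bias correction: E[s²] = σ²(1 − 2/k) + Σσ²/k²  ⇒  Σσ² = Σs² · k/(k−1)
    sum_sigma2 = s2.sum(axis=0) * k / (k - 1.0)
    sigma2 = (s2 - sum_sigma2 / k**2) / (1.0 - 2.0 / k)
    sigma2 = np.clip(sigma2, 0.0, None)

    se2 = sigma2 / n_g  # genes × 2
    # gene-wise mean of d̂ is exactly 0 per group, so Var reduces to mean square
    gamma2 = np.maximum(0.0, (dhat**2).mean(axis=0) - se2.mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(gamma2 + se2 > 0, gamma2 / (gamma2 + se2), 0.0)
    dtilde = dhat * shrink

    rho = (np.abs(dtilde) + np.sqrt(se2)).mean(axis=1)

    ids = list(values.index)
    stability: dict[tuple[str, ...], float] = {
        (ids[i],): float(rho[i]) for i in range(k)
    }

    if pairs:
        for i, j in combinations(range(k), 2):
            w = (centered[i] + centered[j]) / 2.0
            d_pair = (dhat[i] + dhat[j]) / 2.0
            s2_pair = np.array(
                [w[~mask1].var(ddof=1), w[mask1].var(ddof=1)]
            )
            se2_pair = s2_pair / n_g
            with np.errstate(invalid="ignore", divide="ignore"):
                shr = np.where(
                    gamma2 + se2_pair > 0, gamma2 / (gamma2 + se2_pair), 0.0
                )
            d_t = d_pair * shr
            val = float((np.abs(d_t) + np.sqrt(se2_pair)).mean())
            stability[tuple(sorted((ids[i], ids[j])))] = val

    best = min(stability.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return StabilityReport(candidates=ids, stability=stability, best_set=best)


def best_reference(report: StabilityReport) -> tuple[str, ...]:
    """Reference set with the lowest stability value (ties: lexicographic)."""
    if not report.stability:
        raise ValueError("no scored candidate sets")
    return min(report.stability.items(), key=lambda kv: (kv[1], kv[0]))[0]
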