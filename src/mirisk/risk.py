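"""Cohort statistics and forward logistic risk modeling.

Covers the clinical-epidemiology layer: univariate group comparisons
(chi-squared for categorical risk-factor histories, Student's t for
continuous laboratory markers), forward-selection logistic regression of
atherosclerosis presence on clinical markers and miRNA quantities, and
leave-one-out cross-validated classification accuracy of a fixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "RiskModelFit",
    "univariate_tables",
    "forward_logistic",
    "loocv_accuracy",
    "fit_logistic",
]

# fitted probabilities this extreme on every observation indicate that the
# likelihood is diverging (complete separation); coefficient magnitude is not
# used, since a covariate on a tiny scale has a legitimately huge odds ratio
_SEPARATION_PROB = 1e-4


@dataclass
class RiskModelFit:
    """Fitted logistic risk model.

    ``params`` holds one row per term (including the intercept) with columns
    ``B`` (log-odds coefficient), ``se``, ``exp_b`` (odds ratio), ``ci_low``,
    ``ci_high`` (Wald 95% bounds) and ``p``.  ``selected`` lists covariates
    in entry order; ``fitted`` are per-patient predicted probabilities.
    """

    selected: list[str]
    params: pd.DataFrame
    fitted: pd.Series
    converged: bool = True
    separation: bool = False
    entry_log: list[dict] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        design = sm.add_constant(X[self.selected], has_constant="add")
        beta = self.params["B"].reindex(design.columns).to_numpy()
        eta = design.to_numpy() @ beta
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=X.index)


def univariate_tables(
    cohort: CohortTable,
    categorical: Sequence[str],
    continuous: Sequence[str],
) -> pd.DataFrame:
    """Per-covariate univariate comparison between the two groups.

    Categorical covariates are compared with a chi-squared test on the
    r × 2 contingency table (no continuity correction, matching the usual
    SPSS crosstab output); continuous covariates with a two-sided
    equal-variance t-test.  For categorical rows the summary columns hold
    per-group counts; for continuous rows, mean ± SD.

    Tables with an empty row or column margin make the chi-squared test
    unreliable; those rows are flagged in the ``unreliable`` column.
    """
    y = cohort.labels
    rows = []
    for cov in categorical:
        vals = cohort.data[cov]
        table = pd.crosstab(vals, y)
        unreliable = False
        if table.shape[0] < 2 or table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            p = np.nan
            stat = np.nan
            unreliable = True
        else:
            stat, p, _, expected = stats.chi2_contingency(table, correction=False)
            unreliable = bool((expected < 1).any())
        rows.append(
            {
                "covariate": cov,
                "kind": "categorical",
                "summary_nonath": _count_summary(table, 0),
                "summary_ath": _count_summary(table, 1),
                "statistic": stat,
                "p": p,
                "unreliable": unreliable,
            }
        )
    for cov in continuous:
        vals = pd.to_numeric(cohort.data[cov], errors="coerce")
        g1, g0 = vals[y == 1], vals[y == 0]
        stat, p = stats.ttest_ind(g1.dropna(), g0.dropna(), equal_var=True)
        rows.append(
            {
                "covariate": cov,
                "kind": "continuous",
                "summary_nonath": f"{g0.mean():.1f} ± {g0.std(ddof=1):.1f}",
                "summary_ath": f"{g1.mean():.1f} ± {g1.std(ddof=1):.1f}",
                "statistic": float(stat),
                "p": float(p),
                "unreliable": False,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def _count_summary(table: pd.DataFrame, col: int) -> str:
    if col not in table.columns:
        return "0"
    return ":".join(str(int(v)) for v in table[col])


def _robust_fit(model: sm.Logit):
    """Newton ML fit with BFGS/L-BFGS fallbacks for (quasi-)separated data."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("newton", "bfgs", "lbfgs"):
            try:
                return model.fit(disp=0, maxiter=200, method=method)
            except Exception:
                continue
    raise np.linalg.LinAlgError("logistic fit failed with all optimizers")


def fit_logistic(
    X: pd.DataFrame, y: np.ndarray, covariates: Sequence[str]
) -> tuple[sm.Logit, object, bool]:
    """Maximum-likelihood logistic fit; returns (model, results, separation_flag)."""
    design = sm.add_constant(X[list(covariates)].astype(float), has_constant="add")
    model = sm.Logit(y, design)
    res = _robust_fit(model)
    fitted = np.asarray(res.predict())
    y_arr = np.asarray(y)
    complete_sep = bool(
        fitted[y_arr == 1].min(initial=1.0) > 1 - _SEPARATION_PROB
        and fitted[y_arr == 0].max(initial=0.0) < _SEPARATION_PROB
    )
    sep = (not res.mle_retvals.get("converged", True)) or complete_sep
    return model, res, sep


def _fit_results_frame(res, separation: bool) -> pd.DataFrame:
    beta = res.params
    se = res.bse
    with np.errstate(over="ignore"):
        ci = np.exp(
            np.stack(
                [beta - 1.959963984540054 * se, beta + 1.959963984540054 * se], axis=1
            )
        )
    return pd.DataFrame(
        {
            "B": beta,
            "se": se,
            "exp_b": np.exp(beta),
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": res.pvalues,
        }
    )


def forward_logistic(
    cohort: CohortTable,
    candidate_covariates: Sequence[str],
    alpha_enter: float = 0.05,
) -> RiskModelFit:
    """Forward-selection logistic regression (likelihood-ratio entry test).

    At each step every excluded covariate is added in turn to the current
    model; the likelihood-ratio statistic 2·(ℓ_new − ℓ_cur) against a χ²(1)
    gives its entry p-value.  The most significant covariate enters if its
    p-value is below ``alpha_enter`` (default 0.05); selection stops when no
    covariate qualifies.  The final model is refit by maximum likelihood and
    reported with Wald 95% confidence intervals exp(B ± 1.96·SE).

    Covariates whose addition fails to fit (collinearity) are skipped with a
    warning; complete separation is flagged on the returned fit.
    """
    if len(candidate_covariates) == 0:
        raise ValueError("need at least one candidate covariate")
    X = cohort.data
    y = cohort.labels
    if set(np.unique(y).tolist()) != {0, 1}:
        raise ValueError("outcome must contain both classes")

    selected: list[str] = []
    entry_log: list[dict] = []
    separation = False

    _, res_cur, _ = fit_logistic(X, y, selected) if selected else _null_fit(y)
    ll_cur = res_cur.llf

    remaining = list(candidate_covariates)
    while remaining:
        best = None  # (p, lr, cov, res, sep)
        for cov in remaining:
            try:
                _, res_new, sep = fit_logistic(X, y, selected + [cov])
            except Exception:
                warnings.warn(f"covariate '{cov}' skipped (fit failed)")
                continue
            lr = 2.0 * (res_new.llf - ll_cur)
            lr = max(lr, 0.0)
            p = stats.chi2.sf(lr, df=1)
            if best is None or p < best[0] or (p == best[0] and lr > best[1]):
                best = (p, lr, cov, res_new, sep)
        if best is None or best[0] >= alpha_enter:
            break
        p, lr, cov, res_cur, sep = best
        selected.append(cov)
        remaining.remove(cov)
        separation = separation or sep
        ll_cur = res_cur.llf
        entry_log.append({"covariate": cov, "lr": lr, "p": p})

    if selected:
        _, res_final, sep = fit_logistic(X, y, selected)
        separation = separation or sep
    else:
        _, res_final, _ = _null_fit(y)
    params = _fit_results_frame(res_final, separation)
    fitted = pd.Series(np.asarray(res_final.predict()), index=X.index)
    return RiskModelFit(
        selected=selected,
        params=params,
        fitted=fitted,
        converged=bool(res_final.mle_retvals.get("converged", True)),
        separation=separation,
        entry_log=entry_log,
    )


def _null_fit(y: np.ndarray):
    design = pd.DataFrame({"const": np.ones(len(y))})
    model = sm.Logit(y, design)
    res = model.fit(disp=0)
    return model, res, False


def loocv_accuracy(
    cohort: CohortTable,
    covariates: Sequence[str],
    threshold: float = 0.5,
) -> float:
    """Leave-one-out cross-validated accuracy (%) for a fixed covariate set.

    For each patient the model coefficients are re-estimated on the other
    n − 1 patients and the held-out probability is classified at
    ``threshold``.  Variable selection is *not* re-run per fold — the
    covariate list is taken as fixed.  Folds that fail to converge keep the
    last-iterate prediction and emit a warning.
    """
    covariates = list(covariates)
    X = cohort.data[covariates].astype(float)
    y = cohort.labels
    n = len(y)
    correct = 0
    design_full = sm.add_constant(X, has_constant="add")
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = sm.Logit(y[mask], design_full.iloc[mask])
        res = _robust_fit(model)
        if not res.mle_retvals.get("converged", True):
            warnings.warn(f"LOOCV fold {i} did not converge; using last iterate")
        prob = float(res.predict(design_full.iloc[[i]]).iloc[0])
        correct += int((prob >= threshold) == bool(y[i]))
    return 100.0 * correct / n
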