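"""Reproducibility studies: seeded simulation checks of the whole toolkit.

Each function runs a self-contained study — generating its own inputs,
running the corresponding pipeline operation, and measuring the outcome —
and returns plain numbers.  They power both the test suite and the
repository's acceptance script.

Problem sizes are chosen so each study completes in seconds to a couple of
minutes on one CPU while leaving the Monte-Carlo error well below the margin
being checked; the methods note lists them.
"""

from __future__ import annotations

import json
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .incremental import idi, nri, roc_auc
from .pipeline import PipelineConfig, run_pipeline
from .reference import normfinder_stability
from .risk import forward_logistic

__all__ = [
    "auc_pair_oracle_agreement",
    "reclassification_exact_values",
    "normfinder_truth_recovery",
    "forward_selection_recovery",
    "null_calibration",
    "end_to_end_recovery",
]


def _brute_force_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive pairwise oracle: P(event > nonevent) + ½ P(tie)."""
    ev = scores[labels == 1]
    ne = scores[labels == 0]
    total = 0.0
    for a in ev:
        for b in ne:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(ev) * len(ne))


def auc_pair_oracle_agreement(seed: int = 0, n_vectors: int = 2000) -> float:
    """Fraction of random score/label vectors (n ≤ 12, with ties) on which
    the rank-based AUC equals the exhaustive pair-enumeration oracle."""
    rng = np.random.default_rng(seed)
    grid = np.array([0.0, 0.1, 0.25, 0.5, 0.75, 1.0])
    hits = 0
    for _ in range(n_vectors):
        n = int(rng.integers(2, 13))
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = rng.choice(grid, size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ours = roc_auc(scores, labels)
        if abs(ours - _brute_force_auc(scores, labels)) < 1e-12:
            hits += 1
    return hits / n_vectors


def reclassification_exact_values() -> dict:
    """NRI/IDI on hand-enumerable movement patterns (closed-form answers)."""
    # events move (+, +, −); nonevents move (+, −, −)  →  NRI = 2/3
    y = np.array([1, 1, 1, 0, 0, 0])
    old = np.full(6, 0.5)
    new = np.array([0.6, 0.7, 0.4, 0.6, 0.4, 0.3])
    nri_hand = nri(old, new, y).nri
    # every event up, every nonevent down  →  NRI = 2
    y2 = np.array([1, 1, 0, 0])
    nri_max = nri([0.5] * 4, [0.6, 0.7, 0.4, 0.3], y2).nri
    # +0.1 per event, −0.1 per nonevent  →  IDI = 0.2
    idi_forced = idi([0.6, 0.4, 0.5, 0.3], [0.7, 0.5, 0.4, 0.2], y2).idi
    return {"nri_hand": nri_hand, "nri_max": nri_max, "idi_forced": idi_forced}


def normfinder_truth_recovery(
    seed: int = 0, reps: int = 200, k: int = 20, n_g: int = 50
) -> float:
    """Rate at which the stability estimator ranks the truly best gene first.

    Each replicate plants one gene with zero group bias and low variance
    among genes with substantial bias (|d| ≥ 0.4, mean-centered so the
    panel-average bias is zero — the stability model measures bias relative
    to that average) and noisier variance.  The truth score per gene is
    |d_i − d̄|/2 + σ_i/√n_g; success means the estimator's most stable
    single gene coincides with the truth argmin.
    """
    rng = np.random.default_rng(seed)
    labels = np.r_[np.zeros(n_g, int), np.ones(n_g, int)]
    hits = 0
    for _ in range(reps):
        mags = rng.uniform(0.4, 1.0, k - 1)
        d_others = mags * np.resize([1.0, -1.0], k - 1)
        d_others -= d_others.mean()
        delta = np.r_[0.0, d_others]
        sigma = np.r_[0.3, rng.uniform(0.4, 1.0, k - 1)]
        mu = rng.normal(28.0, 2.0, k)
        truth = np.abs(delta - delta.mean()) / 2 + sigma / np.sqrt(n_g)
        noise = rng.normal(0.0, 1.0, (k, 2 * n_g)) * sigma[:, None]
        x = mu[:, None] + delta[:, None] * labels[None, :] + noise
        values = pd.DataFrame(x, index=[f"g{i}" for i in range(k)])
        rep = normfinder_stability(values, labels, pairs=False)
        est = np.array([rep.stability[(g,)] for g in values.index])
        hits += int(np.argmin(est) == np.argmin(truth))
    return hits / reps


def forward_selection_recovery(
    seed: int = 0,
    n_seeds: int = 100,
    n: int = 200,
    n_covariates: int = 15,
    log_or: float = 1.0,
) -> dict:
    """Parameter recovery of forward logistic selection.

    Two of ``n_covariates`` standard-normal covariates carry a true log
    odds ratio of ``log_or``.  Returns the fraction of seeds in which both
    planted covariates are selected, and the Wald 95% CI coverage of the
    true odds ratio among selected planted covariates.
    """
    rng = np.random.default_rng(seed)
    names = [f"x{i}" for i in range(n_covariates)]
    both_selected = 0
    covered, total = 0, 0
    for _ in range(n_seeds):
        X = rng.normal(0.0, 1.0, (n, n_covariates))
        eta = log_or * (X[:, 0] + X[:, 1])
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        if y.sum() in (0, n):
            continue
        df = pd.DataFrame(X, columns=names)
        df["group"] = y
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = forward_logistic(CohortTable(df), names)
        got = set(fit.selected)
        both_selected += int({"x0", "x1"} <= got)
        for v in ("x0", "x1"):
            if v in got:
                total += 1
                row = fit.params.loc[v]
                covered += int(row["ci_low"] <= np.exp(log_or) <= row["ci_high"])
    return {
        "planted_selected_rate": both_selected / n_seeds,
        "ci_coverage": covered / total if total else np.nan,
    }


def null_calibration(
    seed: int = 0,
    n_null_mirnas: int = 1000,
    n_per_group: int = 15,
    forward_reps: int = 1000,
    n: int = 200,
    n_covariates: int = 15,
    alpha: float = 0.05,
) -> dict:
    """Type-I error calibration of the t-test filter and forward selection.

    Without planted effects, the per-miRNA two-sided t-test should reject at
    ≈ ``alpha``, and forward logistic selection over m null covariates
    should select at least one in ≈ 1 − (1 − alpha)^m of runs.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    x = rng.normal(30.0, 1.0, (n_null_mirnas, 2 * n_per_group))
    _, p = stats.ttest_ind(x[:, :n_per_group], x[:, n_per_group:], axis=1)
    t_rate = float((p < alpha).mean())

    names = [f"x{i}" for i in range(n_covariates)]
    any_selected = 0
    for _ in range(forward_reps):
        X = rng.normal(0.0, 1.0, (n, n_covariates))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            continue
        df = pd.DataFrame(X, columns=names)
        df["group"] = y
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = forward_logistic(CohortTable(df), names, alpha_enter=alpha)
        any_selected += int(len(fit.selected) > 0)
    return {
        "t_filter_rejection_rate": t_rate,
        "forward_any_selection_rate": any_selected / forward_reps,
        "forward_expected_rate": 1.0 - (1.0 - alpha) ** n_covariates,
    }


def end_to_end_recovery(seed: int = 0, n_per_group: int = 32) -> dict:
    """Full pipeline on the default synthetic cohort.

    Runs the pipeline twice with the same seed; reports the fraction of
    planted differential miRNAs recovered by the fold/t filter, how many of
    the discriminant-selected markers are planted, whether the two runs are
    byte-identical, and the headline model metrics.
    """
    with tempfile.TemporaryDirectory() as tmp:
        reports = []
        for sub in ("a", "b"):
            cfg = PipelineConfig(
                simulate=True,
                n_per_group=n_per_group,
                seed=seed,
                out_dir=str(Path(tmp) / sub),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reports.append(run_pipeline(cfg))
        text_a = (Path(tmp) / "a" / "report.json").read_text()
        text_b = (Path(tmp) / "b" / "report.json").read_text()
    report = reports[0]
    rec = report["planted_recovery"]
    selected = report["discriminant_selected"]
    n_planted_sel = len(rec["discriminant_selected_planted"])
    return {
        "recovered_fraction": rec["recovered_fraction"],
        "n_discriminant_selected": len(selected),
        "planted_fraction_of_selected": (
            n_planted_sel / len(selected) if selected else np.nan
        ),
        "deterministic": float(text_a == text_b),
        "accuracy_old": report["model_old"]["accuracy"],
        "accuracy_new": report["model_new"]["accuracy"],
        "auc_old": report["model_old"]["auc"],
        "auc_new": report["model_new"]["auc"],
        "loocv_old": report["model_old"]["loocv_accuracy"],
        "loocv_new": report["model_new"]["loocv_accuracy"],
        "nri": report["nri"],
        "idi": report["idi"],
    }
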