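"""End-to-end orchestration: QC → reference → Q_rel → markers → risk model.

`run_pipeline` ties the stages into one reproducible run that writes
machine-readable JSON/CSV artifacts plus a run log (config hash, seed,
package versions).  Identical config and inputs give byte-identical reports:
every report is JSON with sorted keys, and all randomness flows from the
single seed in the config.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable
from .discovery import differential_candidates, stepwise_discriminant, validate_marker
from .incremental import (
    classification_metrics,
    compare_auc,
    idi,
    nri,
    reclassification_counts,
)
from .quantification import CtPanel, delta_ct, hemolysis_filter, impute_undetermined
from .reference import best_reference, candidate_reference_filter, normfinder_stability
from .risk import forward_logistic, loocv_accuracy
from .synthetic import SimulationParams, simulate_cohort, write_outputs

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

#: Clinical candidate covariates offered to the forward logistic model.
DEFAULT_CLINICAL_CANDIDATES = [
    "age",
    "bmi",
    "hypertension",
    "hba1c",
    "fasting_glucose",
    "triglyceride",
    "total_cholesterol",
    "hdl_c",
    "ldl_c",
    "apolipoprotein_a",
    "apolipoprotein_b",
    "lipoprotein_a",
    "hs_crp",
    "homocysteine",
]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    ct_paths: list[str] = field(default_factory=list)
    cohort_path: str | None = None
    out_dir: str = "mirisk_run"
    hemolysis_threshold: float = 0.2
    max_cycles: float = 40.0
    ref_fold_bounds: tuple[float, float] = (0.9, 1.1)
    marker_fold_bounds: tuple[float, float] = (0.5, 2.0)
    alpha_filter: float = 0.05
    alpha_discriminant: float = 0.05
    alpha_logistic: float = 0.05
    classification_threshold: float = 0.5
    max_reference_candidates: int = 25
    clinical_candidates: list[str] = field(
        default_factory=lambda: list(DEFAULT_CLINICAL_CANDIDATES)
    )
    simulate: bool = False
    n_per_group: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha_filter, self.alpha_discriminant, self.alpha_logistic):
            if not 0 < a < 1:
                raise ValueError("alpha levels must be in (0, 1)")
        for lo, hi in (self.ref_fold_bounds, self.marker_fold_bounds):
            if not 0 < lo < 1 < hi:
                raise ValueError("fold bounds must satisfy 0 < lower < 1 < upper")

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a plain ``key = value`` config file (lists comma-separated)."""
    kwargs: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in ("ct_paths", "clinical_candidates"):
            kwargs[key] = [v.strip() for v in value.split(",") if v.strip()]
        elif key in ("ref_fold_bounds", "marker_fold_bounds"):
            lo, hi = value.split(",")
            kwargs[key] = (float(lo), float(hi))
        elif key == "simulate":
            kwargs[key] = value.lower() in ("1", "true", "yes")
        elif key in ("cohort_path", "out_dir"):
            kwargs[key] = value
        elif key in ("n_per_group", "seed", "max_reference_candidates"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return PipelineConfig(**kwargs)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (pd.Series,)):
        return x.to_dict()
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write per-stage artifacts.

    Returns the run report (also written to ``<out_dir>/report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ load
    if config.simulate:
        params = SimulationParams(n_per_group=config.n_per_group, seed=config.seed)
        panel, cohort, truth = simulate_cohort(params)
        write_outputs(panel, cohort, truth, out / "inputs")
    else:
        if not config.ct_paths or config.cohort_path is None:
            raise ValueError("provide ct_paths and cohort_path, or set simulate")
        panels = [CtPanel.from_wide_csv(p) for p in config.ct_paths]
        panel = panels[0] if len(panels) == 1 else CtPanel.concat(panels)
        cohort = CohortTable.from_csv(config.cohort_path)
        truth = None
        missing = [s for s in cohort.sample_ids if s not in panel.sample_ids]
        if missing:
            raise ValueError(f"cohort samples missing from Ct panel: {missing}")

    # ------------------------------------------------------------------- qc
    cohort_qc, excluded = hemolysis_filter(cohort, config.hemolysis_threshold)
    panel = CtPanel(
        ct=panel.ct[cohort_qc.sample_ids],
        detected=panel.detected[cohort_qc.sample_ids],
        panel_of=panel.panel_of,
    )
    labels = cohort_qc.labels
    excluded.to_csv(out / "qc_excluded.csv", index=False)

    panel = impute_undetermined(panel, config.max_cycles)

    # -------------------------------------------------------- reference set
    candidates = candidate_reference_filter(
        panel, labels, fold_bounds=config.ref_fold_bounds, alpha=config.alpha_filter
    )
    if len(candidates) < 3:
        raise RuntimeError("fewer than 3 reference candidates pass the criteria")
    log_expr = -panel.ct.loc[candidates]
    singles = normfinder_stability(log_expr, labels, pairs=False)
    top = [s[0][0] for s in singles.sorted_sets()[: config.max_reference_candidates]]
    report = normfinder_stability(-panel.ct.loc[top], labels, pairs=True)
    reference_ids = list(best_reference(report))
    report.to_frame().to_csv(out / "reference_stability.csv", index=False)

    # ------------------------------------------------------- quantification
    expr = delta_ct(panel, reference_ids)
    expr.q_rel.to_csv(out / "q_rel.csv")

    # ------------------------------------------------------------ discovery
    marker_report = differential_candidates(
        expr, labels, fold_bounds=config.marker_fold_bounds, alpha=config.alpha_filter
    )
    passed = marker_report.candidates
    selected_markers: list[str] = []
    f_values = pd.Series(dtype=float)
    if passed:
        selected_markers, f_values = stepwise_discriminant(
            expr.q_rel.loc[passed], labels, alpha_enter=config.alpha_discriminant
        )
        marker_report.table.loc[selected_markers, "discriminant_selected"] = True
        marker_report.table.loc[selected_markers, "F_to_enter"] = f_values
    marker_report.table.to_csv(out / "marker_report.csv")

    validation = (
        validate_marker(expr, labels, selected_markers) if selected_markers else None
    )

    # ------------------------------------------------------------ modelling
    model_df = cohort_qc.data.copy()
    marker_cols = []
    for m in selected_markers:
        col = f"qrel_{m}"
        model_df[col] = expr.q_rel.loc[m, cohort_qc.sample_ids].to_numpy()
        marker_cols.append(col)
    model_cohort = CohortTable(model_df, label_col=cohort_qc.label_col)
    clinical = [c for c in config.clinical_candidates if c in model_df.columns]

    fit_old = forward_logistic(model_cohort, clinical, config.alpha_logistic)
    fit_new = forward_logistic(
        model_cohort, clinical + marker_cols, config.alpha_logistic
    )
    # guarantee nesting for the incremental comparison: the "new" model is the
    # old covariates plus any selected markers
    new_covs = fit_old.selected + [
        c for c in fit_new.selected if c not in fit_old.selected
    ]

    from .risk import fit_logistic  # local import avoids cycle at module load

    _, res_old, _ = fit_logistic(model_df, labels, fit_old.selected)
    _, res_new, _ = fit_logistic(model_df, labels, new_covs)
    probs_old = np.asarray(res_old.predict())
    probs_new = np.asarray(res_new.predict())

    loocv_old = loocv_accuracy(model_cohort, fit_old.selected, config.classification_threshold)
    loocv_new = loocv_accuracy(model_cohort, new_covs, config.classification_threshold)

    # ------------------------------------------------------------ evaluation
    metrics_old = classification_metrics(probs_old, labels, config.classification_threshold)
    metrics_new = classification_metrics(probs_new, labels, config.classification_threshold)
    auc_diff, auc_p = compare_auc(probs_old, probs_new, labels)
    nri_rep = nri(probs_old, probs_new, labels)
    idi_rep = idi(probs_old, probs_new, labels)
    counts = reclassification_counts(
        probs_old, probs_new, labels, config.classification_threshold
    )

    report_obj = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": {
            "mirisk": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_samples": int(len(labels)),
        "n_excluded_hemolysis": int(len(excluded)),
        "reference_ids": reference_ids,
        "reference_stability": report.stability[tuple(sorted(reference_ids))],
        "n_filter_passed": len(passed),
        "filter_passed": sorted(passed),
        "discriminant_selected": selected_markers,
        "F_to_enter": {k: float(v) for k, v in f_values.items()},
        "validation_p": (
            {m: float(validation.loc[m, "p"]) for m in selected_markers}
            if validation is not None
            else {}
        ),
        "model_old": {
            "covariates": fit_old.selected,
            "loocv_accuracy": loocv_old,
            **metrics_old.rounded(),
        },
        "model_new": {
            "covariates": new_covs,
            "loocv_accuracy": loocv_new,
            **metrics_new.rounded(),
        },
        "auc_difference": round(auc_diff, 4),
        "auc_difference_p": auc_p,
        "nri": round(nri_rep.nri, 4),
        "nri_p": nri_rep.nri_p,
        "idi": round(idi_rep.idi, 4),
        "idi_p": idi_rep.idi_p,
        "reclassification_counts": counts,
    }
    if truth is not None:
        planted = set(truth.differential_ids)
        recovered = planted & set(passed)
        report_obj["planted_recovery"] = {
            "n_planted": len(planted),
            "n_recovered_by_filter": len(recovered),
            "recovered_fraction": len(recovered) / len(planted),
            "discriminant_selected_planted": sorted(
                planted & set(selected_markers)
            ),
        }
    _write_json(out / "report.json", report_obj)
    return report_obj
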