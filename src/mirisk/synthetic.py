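"""Synthetic cohorts with known ground truth.

Generates the two inputs the pipeline consumes — a two-panel Ct matrix and a
clinical cohort table — with planted structure so every downstream stage can
be tested against a known answer:

* *reference* miRNAs: no group effect and low intra-group variance, so they
  satisfy the reference-candidate criteria and should win the stability
  ranking;
* *differential* miRNAs: an additive Ct shift of −log2FC in the
  atherosclerotic group, which makes the Q_rel fold change exactly
  2^log2FC up to noise (Ct is −log2 expression);
* *noise* miRNAs: group-free baselines spread over the detectable range,
  some of which drift past the detection limit and are emitted as
  undetermined, exercising the imputation rule;
* per-sample additive Ct offsets mimicking global extraction/loading
  efficiency differences, which ΔCt normalization must cancel;
* clinical covariates drawn per-group from configurable means/SDs and
  prevalences (defaults follow the atherosclerotic vs non-atherosclerotic
  contrasts of an ischemic-stroke cohort, e.g. HbA1c 5.7 ± 0.7 vs
  6.4 ± 1.1 %), plus a 415-nm hemolysis absorbance with a configurable
  fraction of hemolysed samples.

All draws come from a single seeded generator: identical parameters and seed
give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .quantification import CtPanel

__all__ = ["SimulationParams", "PlantedTruth", "simulate_cohort", "TABLE1_CLINICAL"]


#: Default per-covariate group parameters (non-atherosclerotic, atherosclerotic).
#: Continuous entries: (mean, sd) per group; binary entries: prevalence per
#: group; categorical entries: per-group probability vectors.
TABLE1_CLINICAL: dict = {
    "age": {"kind": "continuous", "mean": (69.3, 71.4), "sd": (4.9, 5.8)},
    "height": {"kind": "continuous", "mean": (161.2, 160.2), "sd": (9.3, 9.1)},
    "weight": {"kind": "continuous", "mean": (62.8, 62.1), "sd": (9.7, 10.2)},
    "bmi": {"kind": "continuous", "mean": (24.1, 24.1), "sd": (2.2, 3.4)},
    "nihss_er": {"kind": "continuous", "mean": (1.3, 1.1), "sd": (1.7, 1.7), "min": 0.0},
    "nihss_discharge": {"kind": "continuous", "mean": (0.7, 0.8), "sd": (1.3, 1.3), "min": 0.0},
    "hba1c": {"kind": "continuous", "mean": (5.7, 6.4), "sd": (0.7, 1.1), "min": 3.5},
    "fasting_glucose": {"kind": "continuous", "mean": (107.5, 133.8), "sd": (27.5, 54.6), "min": 40.0},
    "triglyceride": {"kind": "continuous", "mean": (120.3, 124.9), "sd": (55.2, 65.7), "min": 10.0},
    "total_cholesterol": {"kind": "continuous", "mean": (165.5, 162.5), "sd": (34.2, 46.8), "min": 50.0},
    "hdl_c": {"kind": "continuous", "mean": (45.1, 40.3), "sd": (9.0, 12.3), "min": 10.0},
    "ldl_c": {"kind": "continuous", "mean": (102.9, 101.2), "sd": (32.0, 40.1), "min": 20.0},
    "apolipoprotein_a": {"kind": "continuous", "mean": (108.8, 101.9), "sd": (20.0, 26.1), "min": 20.0},
    "apolipoprotein_b": {"kind": "continuous", "mean": (83.8, 89.2), "sd": (23.1, 29.5), "min": 20.0},
    "lipoprotein_a": {"kind": "continuous", "mean": (14.5, 21.9), "sd": (10.4, 15.7), "min": 0.1},
    "hs_crp": {"kind": "continuous", "mean": (1.0, 2.1), "sd": (1.0, 2.8), "min": 0.01},
    "homocysteine": {"kind": "continuous", "mean": (9.9, 13.2), "sd": (4.1, 8.9), "min": 1.0},
    "sex_male": {"kind": "binary", "p": (19 / 33, 19 / 32)},
    "hypertension": {"kind": "binary", "p": (15 / 33, 24 / 32)},
    "diabetes": {"kind": "binary", "p": (5 / 33, 18 / 32)},
    "smoking": {"kind": "binary", "p": (8 / 33, 6 / 32)},
    "alcohol": {"kind": "binary", "p": (3 / 33, 3 / 32)},
    "diagnosis_tia": {"kind": "binary", "p": (13 / 33, 11 / 32)},
    "previous_infarction": {
        "kind": "categorical",
        "levels": ["none", "small", "branch"],
        "p": ((20 / 33, 11 / 33, 2 / 33), (9 / 32, 16 / 32, 7 / 32)),
    },
}


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort; defaults mirror the study conditions."""

    n_per_group: int = 32
    n_mirnas: int = 754
    n_reference: int = 5
    n_differential: int = 14
    effect_log2fc: float | Sequence[float] = 2.0
    ct_base_mean: float = 30.0
    ct_base_sd: float = 3.5
    ct_sd: float = 1.0
    reference_sd: float = 0.15
    sample_offset_sd: float = 0.5
    dropout_ct: float = 40.0
    clinical_spec: dict = field(default_factory=lambda: TABLE1_CLINICAL)
    hemolysis_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference + self.n_differential > self.n_mirnas:
            raise ValueError("planted miRNAs exceed n_mirnas")
        if min(self.n_per_group, self.n_mirnas) <= 0:
            raise ValueError("counts must be positive")
        if self.ct_sd <= 0 or self.reference_sd <= 0 or self.ct_base_sd <= 0:
            raise ValueError("all SDs must be > 0")
        if self.dropout_ct > 40:
            raise ValueError("dropout_ct must be ≤ 40 cycles")

    @property
    def effects(self) -> np.ndarray:
        eff = np.asarray(self.effect_log2fc, dtype=float)
        if eff.ndim == 0:
            # alternate up/down regulation across the planted miRNAs
            eff = eff * np.where(np.arange(self.n_differential) % 2 == 0, 1.0, -1.0)
        if eff.shape != (self.n_differential,):
            raise ValueError("effect_log2fc must be scalar or length n_differential")
        return eff


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort."""

    reference_ids: list[str]
    differential_ids: list[str]
    log2fc: dict[str, float]
    clinical_effects: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "reference_ids": self.reference_ids,
                    "differential_ids": self.differential_ids,
                    "log2fc": self.log2fc,
                    "clinical_effects": self.clinical_effects,
                },
                indent=2,
                sort_keys=True,
            )
        )


def simulate_cohort(
    params: SimulationParams,
) -> tuple[CtPanel, CohortTable, PlantedTruth]:
    """Draw a Ct panel, cohort table and planted truth from one seeded RNG."""
    rng = np.random.default_rng(params.seed)
    n = 2 * params.n_per_group
    labels = np.repeat([0, 1], params.n_per_group)
    sample_ids = [f"S{i:03d}" for i in range(n)]

    mirna_ids = [f"miR-sim-{i:04d}" for i in range(params.n_mirnas)]
    ref_ids = mirna_ids[: params.n_reference]
    diff_ids = mirna_ids[params.n_reference : params.n_reference + params.n_differential]
    effects = params.effects

    # per-miRNA baselines: planted ones comfortably inside the detectable
    # range, noise miRNAs spread so some cross the detection limit
    base = rng.normal(params.ct_base_mean, params.ct_base_sd, size=params.n_mirnas)
    base[: params.n_reference] = rng.normal(26.0, 0.5, size=params.n_reference)
    base[params.n_reference : params.n_reference + params.n_differential] = rng.normal(
        28.0, 1.0, size=params.n_differential
    )

    sd = np.full(params.n_mirnas, params.ct_sd)
    sd[: params.n_reference] = params.reference_sd

    offsets = rng.normal(0.0, params.sample_offset_sd, size=n)

    shift = np.zeros((params.n_mirnas, n))
    for idx, eff in zip(range(params.n_reference, params.n_reference + params.n_differential), effects):
        shift[idx, labels == 1] = -eff  # lower Ct = higher expression

    ct = (
        base[:, None]
        + shift
        + offsets[None, :]
        + rng.normal(0.0, 1.0, size=(params.n_mirnas, n)) * sd[:, None]
    )
    ct = np.clip(ct, 1.0, None)
    undetermined = ct > params.dropout_ct
    ct_out = np.where(undetermined, np.nan, ct)

    ct_df = pd.DataFrame(ct_out, index=mirna_ids, columns=sample_ids)
    half = params.n_mirnas // 2
    panel_of = pd.Series(
        ["A"] * half + ["B"] * (params.n_mirnas - half), index=mirna_ids
    )
    panel = CtPanel(ct=ct_df, panel_of=panel_of)

    cohort_df = _draw_clinical(rng, labels, params)
    cohort_df.index = pd.Index(sample_ids, name="sample")

    clinical_effects = {}
    for name, spec in params.clinical_spec.items():
        if spec["kind"] == "continuous":
            clinical_effects[name] = spec["mean"][1] - spec["mean"][0]
        elif spec["kind"] == "binary":
            clinical_effects[name] = spec["p"][1] - spec["p"][0]
    truth = PlantedTruth(
        reference_ids=list(ref_ids),
        differential_ids=list(diff_ids),
        log2fc={m: float(e) for m, e in zip(diff_ids, effects)},
        clinical_effects=clinical_effects,
    )
    return panel, CohortTable(cohort_df), truth


def _draw_clinical(
    rng: np.random.Generator, labels: np.ndarray, params: SimulationParams
) -> pd.DataFrame:
    n = len(labels)
    cols: dict[str, np.ndarray] = {"group": labels}
    for name, spec in params.clinical_spec.items():
        vals = np.empty(n, dtype=object)
        for g in (0, 1):
            m = labels == g
            if spec["kind"] == "continuous":
                draw = rng.normal(spec["mean"][g], spec["sd"][g], size=m.sum())
                draw = np.clip(draw, spec.get("min", -np.inf), None)
                vals[m] = np.round(draw, 3)
            elif spec["kind"] == "binary":
                vals[m] = rng.binomial(1, spec["p"][g], size=m.sum())
            elif spec["kind"] == "categorical":
                vals[m] = rng.choice(spec["levels"], p=spec["p"][g], size=m.sum())
            else:
                raise ValueError(f"unknown covariate kind {spec['kind']!r}")
        cols[name] = vals
    # hemolysis absorbance: clean sera sit well under the 0.2 cutoff
    hemolysed = rng.random(n) < params.hemolysis_fraction
    absorb = np.where(
        hemolysed,
        rng.uniform(0.2, 0.6, size=n),
        rng.uniform(0.04, 0.18, size=n),
    )
    cols["absorbance_415"] = np.round(absorb, 4)
    df = pd.DataFrame(cols)
    for c in df.columns:
        if c != "previous_infarction":
            df[c] = pd.to_numeric(df[c])
    return df


def write_outputs(
    panel: CtPanel, cohort: CohortTable, truth: PlantedTruth, out_dir: str | Path
) -> None:
    """Write the standard artifact trio: Ct wide CSV, cohort CSV, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel.to_csv(out / "ct_panel.csv")
    cohort.to_csv(out / "cohort.csv")
    truth.to_json(out / "truth.json")
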