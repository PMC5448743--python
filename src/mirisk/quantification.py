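"""Ct-matrix handling, serum QC and relative quantification.

Cycle-threshold (Ct) values from TaqMan miRNA array cards behave as negative
log2 abundances: one cycle less means roughly twice as much template.  The
module provides

* :class:`CtPanel` — a miRNA × sample Ct matrix with detection flags and
  panel membership (cards A/B),
* hemolysis QC on the cohort table (free-oxyhemoglobin absorbance at 415 nm),
* replacement of "Undetermined" wells with the maximal cycle number,
* ΔCt / Q_rel computation against a chosen reference-miRNA set, yielding an
  :class:`ExpressionMatrix`.

ΔCt = Ct(target) − Ct(reference) within a sample, and Q_rel = 2^−ΔCt.
Subtracting the per-sample reference Ct cancels sample-level loading and
extraction offsets, which is what makes Q_rel comparable across sera.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "CtPanel",
    "ExpressionMatrix",
    "hemolysis_filter",
    "impute_undetermined",
    "delta_ct",
]

#: Maximal number of PCR cycles run on the array cards; Ct beyond this is
#: reported by the instrument as "Undetermined".
MAX_CYCLES = 40.0

#: Tokens (case-insensitive) that encode an undetermined well in CSV input.
UNDETERMINED_TOKENS = {"", "undetermined", "nan", "na"}


@dataclass
class CtPanel:
    """miRNA × sample cycle-threshold matrix.

    Parameters
    ----------
    ct
        DataFrame indexed by miRNA id with one column per sample.  Entries are
        cycles in ``(0, max_cycles]``; ``NaN`` marks an undetermined well that
        has not been imputed yet.
    detected
        Boolean DataFrame of the same shape; ``False`` where the instrument
        reported "Undetermined".
    panel_of
        Optional mapping miRNA id → panel label (``"A"`` / ``"B"``).
    """

    ct: pd.DataFrame
    detected: pd.DataFrame | None = None
    panel_of: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.detected is None:
            self.detected = self.ct.notna() & (self.ct < MAX_CYCLES)
        if not self.ct.index.equals(self.detected.index) or not self.ct.columns.equals(
            self.detected.columns
        ):
            raise ValueError("ct and detected must share index and columns")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_wide_csv(cls, path: str | Path, panel: str | None = None) -> "CtPanel":
        """Read a wide CSV (rows = miRNA id, columns = sample id).

        Undetermined wells may be empty cells or the token ``Undetermined``.
        """
        raw = pd.read_csv(path, index_col=0, dtype=str)
        ct = raw.apply(lambda col: col.map(_parse_ct))
        panel_of = (
            pd.Series(panel, index=ct.index, dtype=object) if panel is not None else None
        )
        return cls(ct=ct.astype(float), panel_of=panel_of)

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "CtPanel":
        """Read a long CSV with columns ``mirna, sample, ct, panel``."""
        raw = pd.read_csv(path, dtype={"mirna": str, "sample": str, "panel": str})
        raw["ct"] = raw["ct"].map(_parse_ct)
        ct = raw.pivot(index="mirna", columns="sample", values="ct").astype(float)
        panel_of = None
        if "panel" in raw.columns:
            panel_of = raw.drop_duplicates("mirna").set_index("mirna")["panel"]
            panel_of = panel_of.reindex(ct.index)
        return cls(ct=ct, panel_of=panel_of)

    def to_csv(self, path: str | Path) -> None:
        out = self.ct.copy()
        out = out.mask(~self.detected & out.isna(), other=np.nan)
        out.to_csv(path)

    @staticmethod
    def concat(panels: Iterable["CtPanel"]) -> "CtPanel":
        """Stack panels (e.g. cards A and B) that share the same samples."""
        panels = list(panels)
        ct = pd.concat([p.ct for p in panels], axis=0)
        detected = pd.concat([p.detected for p in panels], axis=0)
        if ct.index.has_duplicates:
            raise ValueError("duplicate miRNA ids across concatenated panels")
        panel_of = None
        if all(p.panel_of is not None for p in panels):
            panel_of = pd.concat([p.panel_of for p in panels], axis=0)
        return CtPanel(ct=ct, detected=detected, panel_of=panel_of)


def _parse_ct(token: object) -> float:
    if isinstance(token, float):
        return token
    text = str(token).strip().lower()
    if text in UNDETERMINED_TOKENS:
        return np.nan
    return float(token)


@dataclass
class ExpressionMatrix:
    """Per-miRNA, per-sample ΔCt and relative quantity Q_rel = 2^−ΔCt."""

    delta_ct: pd.DataFrame
    q_rel: pd.DataFrame
    reference_ids: list[str] = field(default_factory=list)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.delta_ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.delta_ct.columns)

    def to_csv(self, path: str | Path, what: str = "q_rel") -> None:
        getattr(self, what).to_csv(path)


# ---------------------------------------------------------------------------
# operations


def hemolysis_filter(
    cohort: CohortTable,
    threshold: float = 0.2,
    absorbance_col: str = "absorbance_415",
) -> tuple[CohortTable, pd.DataFrame]:
    """Drop sera whose 415-nm absorbance indicates hemolysis.

    Red cells are rich in miRNAs, so hemolysed serum contaminates the
    circulating-miRNA signal.  A sample is kept only if its free-oxyhemoglobin
    absorbance is *strictly below* ``threshold`` (default 0.2).  Samples with
    a missing absorbance cannot be QC'd and are excluded with a reason.

    Returns the filtered cohort and a log DataFrame of exclusions
    (columns: ``sample``, ``absorbance``, ``reason``).
    """
    if absorbance_col not in cohort.data.columns:
        raise KeyError(f"cohort table has no '{absorbance_col}' column")
    absorb = pd.to_numeric(cohort.data[absorbance_col], errors="coerce")
    missing = absorb.isna()
    hemolysed = absorb >= threshold
    excluded = pd.DataFrame(
        {
            "sample": cohort.data.index[missing | hemolysed],
            "absorbance": absorb[missing | hemolysed].values,
            "reason": np.where(
                missing[missing | hemolysed],
                "missing absorbance",
                f"absorbance >= {threshold}",
            ),
        }
    ).reset_index(drop=True)
    kept = cohort.data.loc[~(missing | hemolysed)]
    return CohortTable(kept, label_col=cohort.label_col), excluded


def impute_undetermined(panel: CtPanel, max_cycles: float = MAX_CYCLES) -> CtPanel:
    """Replace undetermined Ct wells with the maximal cycle number.

    Detection flags are preserved: an imputed well stays ``detected=False``,
    so downstream criteria (e.g. reference candidates must be detected in all
    samples) still see the original detection status.
    """
    if max_cycles <= 0:
        raise ValueError("max_cycles must be positive")
    ct = panel.ct.where(panel.ct.notna(), other=max_cycles)
    ct = ct.clip(upper=max_cycles)
    return CtPanel(ct=ct, detected=panel.detected.copy(), panel_of=panel.panel_of)


def delta_ct(panel: CtPanel, reference_ids: Sequence[str]) -> ExpressionMatrix:
    """Compute ΔCt and Q_rel against a reference miRNA set.

    The combined reference Ct of a multi-member set is the unweighted
    arithmetic mean of the members' Ct per sample — averaging on the Ct
    (log2) scale, i.e. geometric-mean normalization on the linear scale.

    Raises if any reference miRNA is undetected in any sample, since a
    reference must by definition be detected everywhere.
    """
    reference_ids = list(reference_ids)
    missing = [m for m in reference_ids if m not in panel.ct.index]
    if missing:
        raise KeyError(f"reference miRNAs not in panel: {missing}")
    if not reference_ids:
        raise ValueError("reference set is empty")
    undet = ~panel.detected.loc[reference_ids]
    if undet.to_numpy().any():
        bad = undet.index[undet.any(axis=1)].tolist()
        raise ValueError(
            f"reference miRNA(s) undetected in at least one sample: {bad}"
        )
    ref_ct = panel.ct.loc[reference_ids].mean(axis=0)
    dct = panel.ct.sub(ref_ct, axis=1)
    q_rel = np.power(2.0, -dct)
    return ExpressionMatrix(delta_ct=dct, q_rel=q_rel, reference_ids=reference_ids)
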