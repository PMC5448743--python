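"""Per-patient cohort table: clinical covariates, QC fields and group label."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortTable"]


@dataclass
class CohortTable:
    """Clinical/laboratory covariates with a binary atherosclerosis label.

    ``data`` is indexed by patient/sample id.  ``label_col`` names the binary
    outcome column; the event (atherosclerotic) group is coded 1 / True and
    the nonevent group 0 / False.
    """

    data: pd.DataFrame
    label_col: str = "group"

    def __post_init__(self) -> None:
        if self.label_col in self.data.columns:
            vals = set(pd.unique(self.data[self.label_col].dropna()))
            if not vals <= {0, 1, True, False}:
                raise ValueError(
                    f"label column '{self.label_col}' must be binary 0/1, got {vals}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def labels(self) -> np.ndarray:
        """Binary outcome vector (1 = atherosclerotic / event)."""
        return self.data[self.label_col].to_numpy().astype(int)

    @property
    def n_events(self) -> int:
        return int(self.labels.sum())

    @property
    def n_nonevents(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def dropna_covariates(self, covariates: list[str]) -> "CohortTable":
        """Exclude patients with missing values among the modeled covariates."""
        kept = self.data.dropna(subset=covariates)
        return CohortTable(kept, label_col=self.label_col)

    @classmethod
    def from_csv(cls, path: str | Path, label_col: str = "group") -> "CohortTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df, label_col=label_col)

    @classmethod
    def from_xlsx(cls, path: str | Path, label_col: str = "group", **kwargs) -> "CohortTable":
        df = pd.read_excel(path, index_col=0, **kwargs)
        return cls(df, label_col=label_col)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)
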