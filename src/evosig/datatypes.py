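"""Core in-memory containers shared across the pipeline.

Expression matrices are plain :class:`pandas.DataFrame` objects (genes as
rows, samples as columns, log2 scale for bulk data); the thin dataclasses
here bundle them with the sample-level metadata each stage needs and
validate the invariants the downstream algebra relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultiRegionMatrix",
    "SurvivalCohort",
    "SignatureModel",
]


@dataclass
class MultiRegionMatrix:
    """Log2 expression from spatially distinct regions of several tumors.

    Parameters
    ----------
    values:
        genes x samples matrix of log2 expression; all entries finite.
    samples:
        one row per sample (index = sample id) with columns
        ``patient_id`` and ``region_id``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        for col in ("patient_id", "region_id"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        # keep metadata aligned with the matrix column order
        self.samples = self.samples.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def patient_of(self) -> pd.Series:
        """sample id -> patient id."""
        return self.samples["patient_id"]

    @property
    def region_of(self) -> pd.Series:
        """sample id -> region id."""
        return self.samples["region_id"]

    def n_patients(self) -> int:
        return self.samples["patient_id"].nunique()


@dataclass
class SurvivalCohort:
    """Expression matrix paired with right-censored follow-up.

    ``clinical`` is indexed by sample id and must carry ``time`` (positive,
    finite) and ``event`` (0 = censored, 1 = event); any further columns are
    treated as clinical covariates (age, stage, ...).
    """

    expr: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if "time" not in self.clinical or "event" not in self.clinical:
            raise ValueError("clinical table needs 'time' and 'event' columns")
        t = self.clinical["time"].to_numpy(dtype=float)
        if not (np.isfinite(t).all() and (t > 0).all()):
            raise ValueError("survival times must be positive and finite")
        ev = self.clinical["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        missing = self.expr.columns.difference(self.clinical.index)
        if len(missing):
            raise ValueError(f"samples without follow-up: {list(missing)[:5]}")
        self.clinical = self.clinical.loc[self.expr.columns]

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def time(self) -> np.ndarray:
        return self.clinical["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.clinical["event"].to_numpy(dtype=int)

    def n_events(self) -> int:
        return int(self.clinical["event"].sum())

    def covariates(self) -> pd.DataFrame:
        return self.clinical.drop(columns=["time", "event"])

    def subset(self, samples: Sequence[str]) -> "SurvivalCohort":
        samples = list(samples)
        return SurvivalCohort(self.expr[samples], self.clinical.loc[samples])


@dataclass
class SignatureModel:
    """A fitted risk-score model: ordered genes, per-SD Cox coefficients
    and the training-cohort standardization needed to apply them.

    The risk score of sample *i* is ``sum_g beta_g * z_{g,i}`` where *z* is
    the standardized expression of gene *g*.  ``train_median_score`` is the
    median score of the training cohort, kept so external cohorts can be
    dichotomized against the training distribution if desired.
    """

    genes: list[str]
    beta: pd.Series
    mean: pd.Series
    sd: pd.Series
    train_median_score: float
    selection_frequencies: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        for name in ("beta", "mean", "sd"):
            s = getattr(self, name)
            if list(s.index) != self.genes:
                raise ValueError(f"{name} index does not match gene order")
        if (self.sd.to_numpy(dtype=float) <= 0).any():
            bad = self.sd.index[self.sd <= 0].tolist()
            raise ValueError(f"non-positive training SD for genes {bad}")

    def __len__(self) -> int:
        return len(self.genes)
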