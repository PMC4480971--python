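"""Core in-memory containers shared across the pipeline.

Expression data live in a :class:`ExpressionMatrix` (features x samples,
log2 intensities, tagged with the originating array platform); per-cell-line
drug response lives in a :class:`ResponsePanel` (IC50 on linear and log2
scale plus sensitive/resistant class labels once a cutoff has been set);
patient data live in a :class:`ClinicalCohort`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("drugresp")

SENSITIVE = "sensitive"
RESISTANT = "resistant"


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot proceed with its inputs."""


@dataclass
class ExpressionMatrix:
    """Log2 expression intensities, features x samples.

    Parameters
    ----------
    values
        DataFrame indexed by feature identifier with one column per sample.
    platform
        Free-text label of the array platform the data were measured on;
        used to guard cross-platform probe mapping.
    """

    values: pd.DataFrame
    platform: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis("feature_id")
        if self.values.index.has_duplicates:
            raise PipelineError("duplicated feature identifiers")
        if self.values.columns.has_duplicates:
            raise PipelineError("duplicated sample identifiers")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise PipelineError("expression matrix contains non-finite values")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)], self.platform)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.platform)

    def to_tsv(self, path) -> None:
        self.values.rename_axis("feature_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, platform: str = "unspecified") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, platform)


@dataclass
class ResponsePanel:
    """Per-cell-line IC50 response, linear and log2 scale.

    Class labels (sensitive/resistant) are defined only after a response
    cutoff has been assigned via :meth:`assign_labels`.
    """

    table: pd.DataFrame  # index sample_id; columns ic50_linear, ic50_log2
    cutoff: float | None = None

    def __post_init__(self) -> None:
        required = {"ic50_linear", "ic50_log2"}
        if not required.issubset(self.table.columns):
            raise PipelineError(f"response table must contain columns {sorted(required)}")
        if self.table.index.has_duplicates:
            raise PipelineError("duplicated sample identifiers in response panel")
        expected = np.log2(self.table["ic50_linear"].to_numpy(dtype=float))
        if not np.allclose(expected, self.table["ic50_log2"].to_numpy(dtype=float), atol=1e-9):
            raise PipelineError("ic50_log2 inconsistent with log2(ic50_linear)")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def ic50_log2(self) -> pd.Series:
        return self.table["ic50_log2"]

    @property
    def labels(self) -> pd.Series:
        if "label" not in self.table.columns:
            raise PipelineError("labels undefined: assign a response cutoff first")
        return self.table["label"]

    def assign_labels(self, cutoff: float) -> "ResponsePanel":
        """Label each line sensitive (log2 IC50 strictly below cutoff) or resistant."""
        table = self.table.copy()
        table["label"] = np.where(table["ic50_log2"] < cutoff, SENSITIVE, RESISTANT)
        return ResponsePanel(table, cutoff=float(cutoff))

    def subset(self, samples) -> "ResponsePanel":
        return ResponsePanel(self.table.loc[list(samples)], cutoff=self.cutoff)

    def to_tsv(self, path) -> None:
        self.table.rename_axis("sample_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ResponsePanel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "ic50_log2" not in df.columns:
            df["ic50_log2"] = np.log2(df["ic50_linear"])
        return cls(df)

    @classmethod
    def from_linear(cls, ic50_linear: pd.Series) -> "ResponsePanel":
        df = pd.DataFrame(
            {"ic50_linear": ic50_linear, "ic50_log2": np.log2(ic50_linear)}
        )
        return cls(df)


@dataclass
class ClinicalCohort:
    """Patient cohort: normalized expression plus survival follow-up.

    ``clinical`` is indexed by patient id with columns ``pfs_months``
    (progression-free survival, months), ``event`` (1 = progressed,
    0 = censored) and optional ``arm`` / ``indication`` labels.
    """

    expression: ExpressionMatrix
    clinical: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = self.clinical.index.difference(self.expression.sample_ids)
        if len(missing):
            raise PipelineError(f"{len(missing)} patients lack expression data")
        if (self.clinical["pfs_months"] <= 0).any():
            raise PipelineError("pfs_months must be positive")
        if not self.clinical["event"].isin([0, 1]).all():
            raise PipelineError("event indicator must be 0/1")

    @property
    def patient_ids(self) -> pd.Index:
        return self.clinical.index
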