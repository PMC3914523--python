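"""Expression containers and their plain-text serialization.

All tables are tab-separated text so that every intermediate of the
pipeline can be inspected and diffed.  A count or abundance matrix is a
gene-by-sample :class:`pandas.DataFrame` wrapped together with a
sample-to-condition map and a *flavor* flag distinguishing raw integer
counts from library-size-normalized abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
NORMALIZED = "normalized"


class MatrixError(ValueError):
    """Raised when an expression matrix violates its schema."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    condition_of
        Mapping from sample id to condition label.  Every sample in
        ``values`` must be labeled.
    flavor
        ``"raw_counts"`` (integer values) or ``"normalized"``.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]
    flavor: str = RAW_COUNTS

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise MatrixError("duplicate gene ids in matrix")
        if v.columns.duplicated().any():
            raise MatrixError("duplicate sample ids in matrix")
        arr = v.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise MatrixError("expression values must be non-negative")
        missing = [s for s in v.columns if s not in self.condition_of]
        if missing:
            raise MatrixError(f"samples without a condition label: {missing}")
        if self.flavor not in (RAW_COUNTS, NORMALIZED):
            raise MatrixError(f"unknown flavor {self.flavor!r}")
        if self.flavor == RAW_COUNTS and arr.size:
            if not np.allclose(arr, np.round(arr)):
                raise MatrixError("raw_counts flavor requires integer values")

    # -- basic views --------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order over samples."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, conditions_path: str | Path) -> None:
        """Write the matrix and its condition sidecar as tab-separated text."""
        df = self.values.copy()
        df.index.name = "gene_id"
        df.to_csv(matrix_path, sep="\t", float_format="%.6g")
        cond = pd.DataFrame(
            {"sample_id": self.sample_ids,
             "condition": [self.condition_of[s] for s in self.sample_ids]}
        )
        cond.to_csv(conditions_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, conditions_path: str | Path,
                 flavor: str = RAW_COUNTS) -> "ExpressionMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        cond = pd.read_csv(conditions_path, sep="\t", dtype=str, comment="#")
        condition_of = dict(zip(cond["sample_id"], cond["condition"]))
        return cls(df, condition_of, flavor=flavor)


@dataclass
class ConditionProfile:
    """Per-gene, per-condition expression summary with presence calls.

    ``mean_abundance`` holds the linear-scale mean normalized abundance
    per condition; ``log2_summary`` is ``log2(mean + pseudocount)``;
    ``presence`` is ``mean >= presence_threshold``.
    """

    mean_abundance: pd.DataFrame
    log2_summary: pd.DataFrame
    presence: pd.DataFrame
    pseudocount: float = 1.0
    presence_threshold: float = 1.0

    def __post_init__(self) -> None:
        for df in (self.log2_summary, self.presence):
            if not df.index.equals(self.mean_abundance.index):
                raise MatrixError("profile tables must share a gene index")
            if list(df.columns) != list(self.mean_abundance.columns):
                raise MatrixError("profile tables must share condition columns")

    @property
    def conditions(self) -> list[str]:
        return list(self.mean_abundance.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mean_abundance.index)

    def expressed_set(self, condition: str) -> set[str]:
        mask = self.presence[condition]
        return set(self.presence.index[mask])

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.mean_abundance.index)
        out.index.name = "gene_id"
        for c in self.conditions:
            out[f"log2_{c}"] = self.log2_summary[c]
        for c in self.conditions:
            out[f"present_{c}"] = self.presence[c].astype(int)
        out.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, pseudocount: float = 1.0,
                 presence_threshold: float = 1.0) -> "ConditionProfile":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        conds = [c[len("log2_"):] for c in df.columns if c.startswith("log2_")]
        log2 = df[[f"log2_{c}" for c in conds]].set_axis(conds, axis=1)
        pres = df[[f"present_{c}" for c in conds]].set_axis(conds, axis=1).astype(bool)
        mean = (2.0 ** log2) - pseudocount
        mean = mean.clip(lower=0.0)
        return cls(mean, log2, pres, pseudocount, presence_threshold)
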