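"""CPM / RPKM normalization and expression-sum filtering.

The per-sample denominator for both units is the column sum of the delivered
count matrix (assigned reads); original mapping totals are not available
downstream, so "per million mapped reads" is interpreted as per million
assigned reads.  This choice is recorded in the written file metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, FormatError
from .io_formats import CountMatrix, GeneAnnotation, GeneSet

__all__ = [
    "ExpressionMatrix",
    "cpm",
    "rpkm",
    "filter_by_expression_sum",
    "write_expression_matrix",
    "read_expression_matrix",
]

VALID_UNITS = ("CPM", "RPKM")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression values with a unit tag."""

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        arr = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("expression values must be finite and non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.unit)

    def gene_sums(self) -> pd.Series:
        return self.data.sum(axis=1)


def _column_sums(matrix: CountMatrix) -> pd.Series:
    sums = matrix.data.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise DegenerateSampleError(
            f"sample(s) with zero total counts cannot be normalized: {zero}"
        )
    return sums.astype(float)


def cpm(matrix: CountMatrix) -> ExpressionMatrix:
    """Counts per million: count / column-sum * 1e6."""
    sums = _column_sums(matrix)
    values = matrix.data.astype(float).div(sums, axis=1) * 1e6
    return ExpressionMatrix(values, "CPM")


def rpkm(matrix: CountMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Reads per kb of gene model per million assigned reads."""
    sums = _column_sums(matrix)
    lengths_kb = annotation.lengths(matrix.gene_ids) / 1000.0
    values = (
        matrix.data.astype(float)
        .div(sums / 1e6, axis=1)
        .div(lengths_kb.to_numpy(), axis=0)
    )
    return ExpressionMatrix(values, "RPKM")


def filter_by_expression_sum(expr: ExpressionMatrix, threshold: float) -> GeneSet:
    """Genes whose expression summed over all samples is >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sums = expr.gene_sums()
    members = frozenset(sums.index[sums >= threshold])
    return GeneSet(f"{expr.unit.lower()}_sum_ge_{threshold:g}", members)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# unit={expr.unit} denominator=assigned_reads\n")
        out = expr.data.copy()
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t", float_format="%.10g")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    unit = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line.lstrip("#").split():
                if tok.startswith("unit="):
                    unit = tok.split("=", 1)[1]
    if unit is None:
        raise FormatError(f"no '# unit=' metadata line in {path}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float), unit)
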