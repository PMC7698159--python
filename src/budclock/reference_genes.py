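"""qRT-PCR reference-gene candidate ranking.

Candidates are genes with a substantial expression level (CPM summed over
all samples at or above a threshold, default 500), ranked by a stability
score: standard deviation across all samples divided by the median.  Lower
is more stable; the top-N list (default 20) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyRankingError, UndefinedScoreError
from .io_formats import GeneAnnotation
from .normalization import ExpressionMatrix, filter_by_expression_sum

__all__ = ["StabilityRanking", "stability_score", "rank_reference_candidates"]

DEFAULT_MIN_TOTAL_CPM = 500.0
DEFAULT_TOP_N = 20


@dataclass(frozen=True)
class StabilityRanking:
    """Ordered candidates: rank, gene_id, total_cpm, stability (SD/median)."""

    records: pd.DataFrame
    min_total_cpm: float

    def __post_init__(self) -> None:
        df = self.records
        expected = ["rank", "gene_id", "total_cpm", "stability"]
        if list(df.columns[: len(expected)]) != expected:
            raise ValueError(f"ranking columns must start with {expected}")
        if list(df["rank"]) != list(range(1, len(df) + 1)):
            raise ValueError("ranks must be consecutive starting at 1")
        if not df["stability"].is_monotonic_increasing:
            raise ValueError("stability must be non-decreasing down the ranking")
        if (df["total_cpm"] < self.min_total_cpm).any():
            raise ValueError("record below the configured total-CPM threshold")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records["gene_id"])

    def __len__(self) -> int:
        return len(self.records)


def stability_score(values) -> float:
    """Standard deviation (n-1 denominator) divided by the median.

    Dimensionless and invariant under positive rescaling; 0 for a constant
    gene.  Raises when the median is zero — such genes must be filtered out
    by the expression-sum cutoff beforehand.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    med = float(np.median(arr))
    if med <= 0:
        raise UndefinedScoreError("stability score undefined for median <= 0")
    return float(np.std(arr, ddof=1)) / med


def rank_reference_candidates(
    expr: ExpressionMatrix,
    min_total_cpm: float = DEFAULT_MIN_TOTAL_CPM,
    top_n: int = DEFAULT_TOP_N,
    annotation: GeneAnnotation | None = None,
) -> StabilityRanking:
    """Filter by total CPM, score survivors, return the top-N most stable.

    Ties in stability are broken lexicographically by gene id so the ranking
    is fully deterministic.
    """
    if expr.unit != "CPM":
        raise ValueError("reference-gene ranking operates on a CPM matrix")
    if min_total_cpm < 0:
        raise ValueError("min_total_cpm must be >= 0")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    passing = filter_by_expression_sum(expr, min_total_cpm)
    if len(passing) == 0:
        raise EmptyRankingError(
            f"no gene has a CPM sum >= {min_total_cpm}"
        )
    genes = passing.sorted_members()
    sums = expr.gene_sums()
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g,
                "total_cpm": float(sums[g]),
                "stability": stability_score(expr.data.loc[g].to_numpy()),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["stability", "gene_id"], kind="mergesort"
    )
    table = table.head(top_n).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    if annotation is not None:
        desc = annotation.descriptions()
        table["description"] = [
            desc.get(g, "") for g in table["gene_id"]
        ]
    return StabilityRanking(table, min_total_cpm)
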