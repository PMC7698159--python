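"""Readers, writers and domain types for the pipeline's tabular formats.

All external inputs are plain UTF-8 text: tab- or comma-delimited tables with
a header row.  Dates are ISO-8601 day-resolution strings; time zones are
ignored throughout.  Lines starting with ``#`` are treated as comments in
count tables (featureCounts emits such a header line).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CovariateCoverageError,
    EmptyDesignError,
    FormatError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "GeneAnnotation",
    "EnvSeries",
    "GeneSet",
    "read_count_table",
    "read_count_tables",
    "write_count_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_env_series",
    "write_env_series",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
    "gene_lengths_from_gff3",
    "filter_complete_timepoints",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples table of non-negative integer read counts.

    ``data`` is indexed by gene id with one column per sample id; both axes
    must be unique and non-empty, and every entry must be a non-negative
    integer.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise FormatError("count matrix needs at least 1 gene and 1 sample")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise FormatError("counts must be integral")
            object.__setattr__(self, "data", df.astype(np.int64))
            values = self.data.to_numpy()
        if np.any(values < 0):
            raise FormatError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise FormatError(f"unknown sample ids: {missing}")
        return CountMatrix(self.data.loc[:, list(sample_ids)].copy())


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: time point label, calendar date, replicate index."""

    records: pd.DataFrame  # columns: sample_id, timepoint, date, replicate

    REQUIRED = ("sample_id", "timepoint", "date", "replicate")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids in sheet: {dups}")
        pair = df[["timepoint", "replicate"]].apply(tuple, axis=1)
        if pair.duplicated().any():
            dups = pair[pair.duplicated()].tolist()
            raise FormatError(f"duplicate (timepoint, replicate) pairs: {dups}")
        if (df["replicate"].astype(int) < 1).any():
            raise FormatError("replicate indices must be >= 1")
        for tp, grp in df.groupby("timepoint"):
            if grp["date"].nunique() != 1:
                raise FormatError(
                    f"timepoint {tp!r} maps to multiple dates: "
                    f"{sorted(grp['date'].unique())}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records["sample_id"])

    @property
    def timepoints(self) -> list[str]:
        return list(pd.unique(self.records["timepoint"]))

    def dates(self) -> Mapping[str, _dt.date]:
        """Map sample_id -> calendar date."""
        return dict(zip(self.records["sample_id"], self.records["date"]))

    def timepoint_dates(self) -> Mapping[str, _dt.date]:
        """Map timepoint label -> its (unique) calendar date."""
        return {
            tp: grp["date"].iloc[0] for tp, grp in self.records.groupby("timepoint")
        }

    def check_matches(self, matrix: CountMatrix) -> None:
        extra = set(self.sample_ids) - set(matrix.sample_ids)
        if extra:
            raise FormatError(
                f"sample sheet lists samples absent from count matrix: {sorted(extra)}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene length (bp), free-text description and optional homolog id."""

    table: pd.DataFrame  # index gene_id; columns length_bp, description, homolog_id

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids in annotation: {dups}")
        for col, default in (
            ("length_bp", np.nan),
            ("description", ""),
            ("homolog_id", None),
        ):
            if col not in df.columns:
                df = df.assign(**{col: default})
        lengths = df["length_bp"].dropna()
        if (lengths < 1).any():
            bad = df.index[df["length_bp"] < 1].tolist()
            raise FormatError(f"non-positive gene lengths for: {bad}")
        object.__setattr__(self, "table", df)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def lengths(self, gene_ids: Sequence[str]) -> pd.Series:
        from .errors import MissingGeneError

        missing = [g for g in gene_ids if g not in self.table.index]
        if missing:
            raise MissingGeneError(f"genes missing from annotation: {missing}")
        lengths = self.table.loc[list(gene_ids), "length_bp"]
        if lengths.isna().any():
            bad = lengths.index[lengths.isna()].tolist()
            raise MissingGeneError(f"genes without a length: {bad}")
        return lengths.astype(float)

    def descriptions(self) -> pd.Series:
        return self.table["description"].fillna("").astype(str)


@dataclass(frozen=True)
class EnvSeries:
    """Calendar-dated daily environmental values (mean air temperature, °C)."""

    series: pd.Series  # index: datetime.date, strictly increasing; values: float

    def __post_init__(self) -> None:
        s = self.series
        if s.index.has_duplicates:
            dups = [d.isoformat() for d in s.index[s.index.duplicated()].unique()]
            raise FormatError(f"duplicate dates in environmental series: {dups}")
        if not s.index.is_monotonic_increasing:
            s = s.sort_index()
            object.__setattr__(self, "series", s)
        if not np.all(np.isfinite(s.to_numpy(dtype=float))):
            raise FormatError("environmental values must be finite numbers")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def dates(self) -> list[_dt.date]:
        return list(self.series.index)

    def value_on(self, date: _dt.date) -> float:
        if date not in self.series.index:
            raise CovariateCoverageError(f"no environmental value for date {date}")
        return float(self.series.loc[date])

    def check_covers(self, sheet: SampleSheet) -> None:
        missing = sorted(
            {d for d in sheet.records["date"] if d not in self.series.index}
        )
        if missing:
            raise CovariateCoverageError(
                "sampling dates missing from environmental series: "
                f"{[d.isoformat() for d in missing]}"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise FormatError(f"empty file: {path}")


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", **kwargs)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc
    if df.empty:
        raise FormatError(f"no data rows in: {path}")
    return df


def _parse_date(raw: object, context: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(raw))
    except ValueError as exc:
        raise FormatError(f"unparseable ISO date {raw!r} in {context}") from exc


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def read_count_table(
    path: str | Path, dialect: str = "auto"
) -> tuple[CountMatrix, GeneAnnotation | None]:
    """Read one count table.

    Two dialects are supported:

    ``merged``
        first column gene ids, remaining columns one per sample.
    ``per_sample``
        columns ``gene_id`` [``length``] ``count``; the sample id is the
        file's stem.  If a length column is present it is returned as a
        GeneAnnotation side table, otherwise the second element is None.

    ``auto`` picks ``per_sample`` when the header matches that layout.
    """
    path = Path(path)
    df = _read_table(path, dtype=str)
    header = [str(c).strip().lower() for c in df.columns]
    if dialect == "auto":
        per_sample = header[0] in {"gene_id", "geneid", "gene"} and header[-1] in {
            "count",
            "counts",
        }
        dialect = "per_sample" if per_sample else "merged"

    if dialect == "per_sample":
        return _read_per_sample(df, path)
    if dialect == "merged":
        return _read_merged(df, path), None
    raise ValueError(f"unknown count-table dialect: {dialect!r}")


def _to_int_counts(raw: pd.DataFrame, path: Path) -> pd.DataFrame:
    try:
        numeric = raw.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from exc
    arr = numeric.to_numpy()
    if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
        raise FormatError(f"non-integer count value in {path}")
    if np.any(arr < 0):
        raise FormatError(f"negative count value in {path}")
    return numeric.astype(np.int64)


def _check_unique_genes(gene_ids: pd.Series, path: Path) -> None:
    if gene_ids.duplicated().any():
        dups = gene_ids[gene_ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene id(s) {dups} in {path}")


def _read_merged(df: pd.DataFrame, path: Path) -> CountMatrix:
    gene_ids = df.iloc[:, 0].astype(str)
    _check_unique_genes(gene_ids, path)
    counts = _to_int_counts(df.iloc[:, 1:], path)
    counts.index = pd.Index(gene_ids, name="gene_id")
    counts.columns = [str(c) for c in df.columns[1:]]
    return CountMatrix(counts)


def _read_per_sample(
    df: pd.DataFrame, path: Path
) -> tuple[CountMatrix, GeneAnnotation | None]:
    header = [str(c).strip().lower() for c in df.columns]
    gene_ids = df.iloc[:, 0].astype(str)
    _check_unique_genes(gene_ids, path)
    sample_id = path.stem
    counts = _to_int_counts(df.iloc[:, [-1]], path)
    counts.index = pd.Index(gene_ids, name="gene_id")
    counts.columns = [sample_id]
    annotation = None
    if "length" in header:
        lengths = pd.to_numeric(df.iloc[:, header.index("length")], errors="coerce")
        if lengths.isna().any():
            raise FormatError(f"non-numeric length value in {path}")
        annotation = GeneAnnotation(
            pd.DataFrame(
                {"length_bp": lengths.astype(np.int64).to_numpy()},
                index=pd.Index(gene_ids, name="gene_id"),
            )
        )
    return CountMatrix(counts), annotation


def read_count_tables(
    paths: Sequence[str | Path],
) -> tuple[CountMatrix, GeneAnnotation | None]:
    """Merge per-sample count files into one matrix.

    All files must share an identical gene universe; differing universes are
    an error rather than silently intersected, because dropping genes would
    corrupt downstream per-sample normalization sums.
    """
    if not paths:
        raise FormatError("no count files given")
    matrices: list[CountMatrix] = []
    annotation: GeneAnnotation | None = None
    for p in paths:
        matrix, ann = read_count_table(p, dialect="per_sample")
        matrices.append(matrix)
        if ann is not None and annotation is None:
            annotation = ann
    reference = matrices[0].data.index
    for p, m in zip(paths[1:], matrices[1:]):
        if set(m.data.index) != set(reference):
            raise FormatError(
                f"gene universe of {p} differs from {paths[0]}; "
                "all per-sample files must cover identical genes"
            )
    merged = pd.concat([m.data.reindex(reference) for m in matrices], axis=1)
    return CountMatrix(merged), annotation


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_table(path, dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"sample_id", "timepoint", "date", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet {path} missing columns: {sorted(missing)}")
    records = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "timepoint": df["timepoint"].astype(str),
            "date": [_parse_date(d, f"sample sheet {path}") for d in df["date"]],
            "replicate": pd.to_numeric(df["replicate"], errors="raise").astype(int),
        }
    )
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.records.copy()
    out["date"] = [d.isoformat() for d in out["date"]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# environmental series
# ---------------------------------------------------------------------------


def read_env_series(path: str | Path) -> EnvSeries:
    df = _read_table(path, dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "date" not in df.columns or "value" not in df.columns:
        raise FormatError(f"environmental series {path} needs columns date, value")
    dates = [_parse_date(d, f"environmental series {path}") for d in df["date"]]
    try:
        values = df["value"].astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in {path}: {exc}") from exc
    series = pd.Series(values.to_numpy(), index=pd.Index(dates, name="date"))
    return EnvSeries(series)


def write_env_series(env: EnvSeries, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "date": [d.isoformat() for d in env.series.index],
            "value": env.series.to_numpy(),
        }
    )
    out.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# annotations and gene lists
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = _read_table(path, dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "gene_id" not in df.columns:
        raise FormatError(f"annotation {path} needs a gene_id column")
    table = pd.DataFrame(index=pd.Index(df["gene_id"].astype(str), name="gene_id"))
    if "length_bp" in df.columns:
        table["length_bp"] = pd.to_numeric(
            df["length_bp"].to_numpy(), errors="coerce"
        )
    elif "length" in df.columns:
        table["length_bp"] = pd.to_numeric(df["length"].to_numpy(), errors="coerce")
    if "description" in df.columns:
        table["description"] = df["description"].fillna("").to_numpy()
    if "homolog_id" in df.columns:
        table["homolog_id"] = df["homolog_id"].to_numpy()
    return GeneAnnotation(table)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    out = annotation.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one- or two-column gene-family list (gene_id [display_name])."""
    path = Path(path)
    df = _read_table(path, dtype=str, header=None)
    genes = frozenset(df.iloc[:, 0].astype(str))
    return GeneSet(name or path.stem, genes)


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column gene_id -> display-name alias table."""
    df = _read_table(path, dtype=str, header=None)
    if df.shape[1] < 2:
        raise FormatError(f"alias table {path} needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def gene_lengths_from_gff3(path: str | Path) -> GeneAnnotation:
    """Extract per-gene exon-union lengths from a GFF3 file.

    GFF3 coordinates are 1-based end-inclusive; the union is computed on
    half-open intervals per gene (exons preferred, gene span as fallback).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    lengths: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        intervals = [
            (exon.start - 1, exon.end)  # to half-open
            for exon in db.children(gene, featuretype="exon")
        ]
        if not intervals:
            intervals = [(gene.start - 1, gene.end)]
        intervals.sort()
        total = 0
        cur_start, cur_end = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_end:
                total += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        total += cur_end - cur_start
        lengths[gene.id] = total
    if not lengths:
        raise FormatError(f"no gene features found in {path}")
    table = pd.DataFrame(
        {"length_bp": pd.Series(lengths, dtype=np.int64)},
    )
    table.index.name = "gene_id"
    return GeneAnnotation(table)


# ---------------------------------------------------------------------------
# design filtering
# ---------------------------------------------------------------------------


def filter_complete_timepoints(
    matrix: CountMatrix, sheet: SampleSheet, required_replicates: int = 3
) -> tuple[CountMatrix, SampleSheet]:
    """Drop every sample of any time point with too few replicates.

    Time points represented by fewer than ``required_replicates`` samples are
    removed entirely; the returned matrix/sheet pair is consistent.
    """
    if required_replicates < 1:
        raise ValueError("required_replicates must be >= 1")
    sheet.check_matches(matrix)
    counts = sheet.records.groupby("timepoint")["sample_id"].count()
    keep_tps = set(counts.index[counts >= required_replicates])
    dropped = sorted(set(counts.index) - keep_tps)
    if dropped:
        logger.info(
            "dropping %d incomplete timepoint(s): %s", len(dropped), dropped
        )
    keep = sheet.records["timepoint"].isin(keep_tps)
    if not keep.any():
        raise EmptyDesignError(
            f"no timepoint has >= {required_replicates} replicates"
        )
    new_records = sheet.records.loc[keep].reset_index(drop=True)
    new_sheet = SampleSheet(new_records)
    new_matrix = matrix.select_samples(new_sheet.sample_ids)
    return new_matrix, new_sheet
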