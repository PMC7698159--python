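"""Gene-set aggregation vs. environmental covariate, with a random-set null.

The focal gene set is defined by case-insensitive substring keywords over the
functional annotation text.  Its per-sample aggregate (median or mean) is
rank-correlated with the daily mean temperature of each sample's date, and
the observed coefficient is calibrated against random gene sets of the same
size drawn from genes passing the same expression-sum cutoff.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    MissingGeneError,
    SamplingError,
    UndefinedCorrelationError,
)
from .io_formats import EnvSeries, GeneAnnotation, GeneSet, SampleSheet
from .normalization import ExpressionMatrix

__all__ = [
    "GeneSetCorrelation",
    "NullDistribution",
    "select_genes_by_keywords",
    "aggregate_gene_set",
    "spearman",
    "environment_correlation",
    "random_set_null",
]

AGGREGATIONS = ("median", "mean")
PAIRINGS = ("per_sample", "per_timepoint")


@dataclass(frozen=True)
class GeneSetCorrelation:
    """Result of correlating a gene-set aggregate with a covariate."""

    set_name: str
    aggregation: str
    pairing: str
    n_obs: int
    rho: float
    p_analytic: float
    observations: pd.DataFrame  # columns: unit, date, aggregate, covariate

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| > 1: {self.rho}")
        if self.n_obs < 3:
            raise ValueError("n_obs must be >= 3")
        if len(self.observations) != self.n_obs:
            raise ValueError("observation table length != n_obs")


@dataclass(frozen=True)
class NullDistribution:
    """Random-set null distribution of the correlation statistic."""

    set_size: int
    n_draws: int
    seed: int
    rho_obs: float
    draws: np.ndarray
    empirical_p: float
    z: float

    def __post_init__(self) -> None:
        if len(self.draws) != self.n_draws:
            raise ValueError("draws length != n_draws")
        if np.any(np.abs(self.draws) > 1 + 1e-12):
            raise ValueError("null draw outside [-1, 1]")
        if not (0 < self.empirical_p <= 1):
            raise ValueError("empirical_p outside (0, 1]")


def select_genes_by_keywords(
    annotation: GeneAnnotation, keywords: list[str], name: str | None = None
) -> GeneSet:
    """Genes whose description contains every keyword, case-insensitively.

    Plain substring matching, not word-boundary: a description containing
    "heatmap" matches keyword "heat".  An empty result is returned (with a
    warning) rather than raised.
    """
    if not keywords:
        raise ValueError("at least one keyword is required")
    lowered = [k.lower() for k in keywords]
    descriptions = annotation.descriptions().str.lower()
    mask = pd.Series(True, index=descriptions.index)
    for kw in lowered:
        mask &= descriptions.str.contains(kw, regex=False)
    members = frozenset(descriptions.index[mask])
    set_name = name or "+".join(keywords)
    if not members:
        warnings.warn(
            f"no gene description contains all of {keywords}", stacklevel=2
        )
    return GeneSet(set_name, members)


def aggregate_gene_set(
    expr: ExpressionMatrix, genes: GeneSet, method: str = "median"
) -> pd.Series:
    """Per-sample median or mean of the set's expression values."""
    if method not in AGGREGATIONS:
        raise ValueError(f"method must be one of {AGGREGATIONS}, got {method!r}")
    if len(genes) == 0:
        raise ValueError("cannot aggregate an empty gene set")
    missing = [g for g in genes.sorted_members() if g not in expr.data.index]
    if missing:
        raise MissingGeneError(f"genes absent from expression matrix: {missing}")
    sub = expr.data.loc[genes.sorted_members()]
    return sub.median(axis=0) if method == "median" else sub.mean(axis=0)


def _midranks(values: np.ndarray) -> np.ndarray:
    # average ranks for ties (midrank convention), 1-based
    return stats.rankdata(values, method="average")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an analytic two-sided p-value.

    rho is the Pearson correlation of midrank-transformed values; the p-value
    uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    rx = _midranks(x)
    ry = _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    rho = float((rx * ry).sum() / denom)
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0) if p > 0 else max(p, np.nextafter(0, 1))


def _paired_observations(
    expr: ExpressionMatrix,
    genes: GeneSet,
    env: EnvSeries,
    sheet: SampleSheet,
    method: str,
    pairing: str,
) -> pd.DataFrame:
    if pairing not in PAIRINGS:
        raise ValueError(f"pairing must be one of {PAIRINGS}, got {pairing!r}")
    extra = set(sheet.sample_ids) - set(expr.sample_ids)
    if extra:
        raise MissingGeneError(
            f"sheet samples absent from expression matrix: {sorted(extra)}"
        )
    env.check_covers(sheet)
    aggregate = aggregate_gene_set(expr, genes, method)
    sample_dates = sheet.dates()
    if pairing == "per_sample":
        rows = [
            {
                "unit": s,
                "date": sample_dates[s],
                "aggregate": float(aggregate[s]),
                "covariate": env.value_on(sample_dates[s]),
            }
            for s in sheet.sample_ids
        ]
    else:
        rows = []
        for tp, grp in sheet.records.groupby("timepoint", sort=False):
            date = grp["date"].iloc[0]
            rows.append(
                {
                    "unit": tp,
                    "date": date,
                    "aggregate": float(aggregate[grp["sample_id"]].mean()),
                    "covariate": env.value_on(date),
                }
            )
        rows.sort(key=lambda r: r["date"])
    return pd.DataFrame(rows)


def environment_correlation(
    expr: ExpressionMatrix,
    genes: GeneSet,
    env: EnvSeries,
    sheet: SampleSheet,
    method: str = "median",
    pairing: str = "per_sample",
) -> GeneSetCorrelation:
    """Correlate a gene-set aggregate with the environmental series.

    ``per_sample`` pairs each replicate's aggregate with the temperature of
    its sampling date; ``per_timepoint`` first averages the aggregate over
    replicates of each time point.
    """
    obs = _paired_observations(expr, genes, env, sheet, method, pairing)
    rho, p = spearman(obs["aggregate"].to_numpy(), obs["covariate"].to_numpy())
    return GeneSetCorrelation(
        set_name=genes.name,
        aggregation=method,
        pairing=pairing,
        n_obs=len(obs),
        rho=rho,
        p_analytic=p,
        observations=obs,
    )


def random_set_null(
    expr: ExpressionMatrix,
    eligible: GeneSet,
    set_size: int,
    env: EnvSeries,
    sheet: SampleSheet,
    rho_obs: float,
    method: str = "median",
    pairing: str = "per_sample",
    n_draws: int = 200,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution from random same-size sets of eligible genes.

    ``eligible`` should be the genes passing the same expression-sum cutoff
    as the focal set.  Each draw samples ``set_size`` genes uniformly without
    replacement and records the resulting correlation.  The empirical
    two-sided p uses the add-one estimator
    ``(1 + #{|draw| >= |rho_obs|}) / (1 + n_draws)``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if set_size < 2:
        raise ValueError("set_size must be >= 2")
    pool = eligible.sorted_members()
    if set_size > len(pool):
        raise SamplingError(
            f"cannot draw {set_size} genes from {len(pool)} eligible"
        )
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws, dtype=float)
    pool_arr = np.asarray(pool, dtype=object)
    for i in range(n_draws):
        picked = rng.choice(pool_arr, size=set_size, replace=False)
        gs = GeneSet(f"null_{i}", frozenset(picked))
        draws[i] = environment_correlation(
            expr, gs, env, sheet, method=method, pairing=pairing
        ).rho
    exceed = int(np.sum(np.abs(draws) >= abs(rho_obs)))
    empirical_p = (1 + exceed) / (1 + n_draws)
    sd = float(np.std(draws, ddof=1)) if n_draws > 1 else float("nan")
    z = (rho_obs - float(np.mean(draws))) / sd if sd and sd > 0 else float("nan")
    return NullDistribution(
        set_size=set_size,
        n_draws=n_draws,
        seed=seed,
        rho_obs=rho_obs,
        draws=draws,
        empirical_p=empirical_p,
        z=z,
    )
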