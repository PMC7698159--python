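"""Synthetic dated, replicated count matrices with planted gene classes.

The generator emulates a one-season bud-sampling design: a configurable
number of time points between two calendar dates, each sampled in
replicates, with a matching daily temperature series.  Planted gene classes:

``coupled``
    log-mean tracks the daily temperature (slope ``coupling_beta`` per deg C);
    descriptions contain the literal phrase "heat shock protein" so keyword
    selection doubles as a truth-recovery test.
``housekeeping``
    high, nearly constant expression with very low dispersion.
``switch``
    sigmoidal up- or down-regulation centred on ``switch_date``.
``peak``
    transient Gaussian bump at a per-gene date.
``background`` / ``low``
    constant baselines spanning a wide / very low expression range.

Counts are negative-binomial with per-class dispersion, scaled by log-normal
per-sample library sizes.  All randomness flows from one seed through fixed
per-component sub-streams, so e.g. adding genes never perturbs the
temperature series.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import (
    CountMatrix,
    EnvSeries,
    GeneAnnotation,
    SampleSheet,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_temperature",
    "simulate_counts",
    "seasonal_mean",
]

GENE_CLASSES = ("coupled", "housekeeping", "switch", "peak", "background", "low")

# fixed sub-stream keys: adding components must not renumber existing ones
_STREAM_TEMPERATURE = 0
_STREAM_GENES = 1
_STREAM_LIBSIZES = 2
_STREAM_COUNTS = 3


@dataclass(frozen=True)
class SimulationConfig:
    n_timepoints: int = 18
    replicates: int = 3
    date_start: _dt.date = _dt.date(2016, 6, 1)
    date_end: _dt.date = _dt.date(2016, 11, 3)
    # gene class sizes
    n_coupled: int = 60
    n_housekeeping: int = 20
    n_switch: int = 40
    n_peak: int = 20
    n_background: int = 800
    n_low: int = 60
    # class log-mean (natural log of CPM-scale expectation) and spread
    baseline_log_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "coupled": math.log(500.0),
            "housekeeping": math.log(3000.0),
            "switch": math.log(400.0),
            "peak": math.log(200.0),
            "background": math.log(500.0),
            "low": math.log(0.1),
        }
    )
    baseline_log_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "coupled": 0.5,
            "housekeeping": 0.3,
            "switch": 0.4,
            "peak": 0.4,
            "background": 1.2,
            "low": 0.7,
        }
    )
    dispersion: Mapping[str, float] = field(
        default_factory=lambda: {
            "coupled": 0.05,
            "housekeeping": 0.005,
            "switch": 0.1,
            "peak": 0.1,
            "background": 0.2,
            "low": 0.3,
        }
    )
    # class-specific shape parameters
    coupling_beta: float = 0.08  # log-scale change per deg C
    switch_date: _dt.date = _dt.date(2016, 7, 15)
    switch_width_days: float = 5.0
    switch_amplitude: float = 1.8
    peak_amplitude: float = 2.3
    peak_sigma_days: float = 8.0
    # temperature model
    temp_mean: float = 15.0
    temp_amplitude: float = 8.0
    temp_peak_doy: int = 196  # mid-July
    temp_noise_sd: float = 1.5
    temp_ar1: float = 0.7
    # library sizes
    library_size_mean: float = 1e6
    library_size_log_sd: float = 0.2
    seed: int = 1

    def validate(self) -> None:
        if self.date_end <= self.date_start:
            raise ConfigError("date_end must be after date_start")
        if self.n_timepoints < 1 or self.replicates < 1:
            raise ConfigError("need >= 1 timepoint and >= 1 replicate")
        n_days = (self.date_end - self.date_start).days + 1
        if self.n_timepoints > n_days:
            raise ConfigError("more timepoints than days in the date range")
        sizes = self.class_sizes()
        if any(n < 0 for n in sizes.values()):
            raise ConfigError("gene class sizes must be >= 0")
        if sum(sizes.values()) < 2:
            raise ConfigError("need at least 2 genes in total")
        if not (0 <= self.temp_ar1 < 1):
            raise ConfigError("temp_ar1 must be in [0, 1)")
        for cls in GENE_CLASSES:
            for mapping, what in (
                (self.baseline_log_mean, "baseline_log_mean"),
                (self.baseline_log_sd, "baseline_log_sd"),
                (self.dispersion, "dispersion"),
            ):
                if cls not in mapping:
                    raise ConfigError(f"{what} missing class {cls!r}")

    def class_sizes(self) -> dict[str, int]:
        return {
            "coupled": self.n_coupled,
            "housekeeping": self.n_housekeeping,
            "switch": self.n_switch,
            "peak": self.n_peak,
            "background": self.n_background,
            "low": self.n_low,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("date_start", "date_end", "switch_date"):
            d[key] = d[key].isoformat()
        for key in ("baseline_log_mean", "baseline_log_sd", "dispersion"):
            d[key] = dict(d[key])
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        kwargs = dict(raw)
        for key in ("date_start", "date_end", "switch_date"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = _dt.date.fromisoformat(kwargs[key])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-gene parameters plus realized covariates."""

    genes: pd.DataFrame  # gene_id, gene_class, baseline_log_cpm, coupling,
    #                      switch_direction, peak_date, dispersion
    library_sizes: pd.Series  # per sample
    scale_log: pd.Series  # per-sample log factor normalizing composition to 1e6
    env: EnvSeries
    config: SimulationConfig

    def genes_of_class(self, gene_class: str) -> list[str]:
        mask = self.genes["gene_class"] == gene_class
        return list(self.genes.loc[mask, "gene_id"])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _date_range(config: SimulationConfig) -> list[_dt.date]:
    n_days = (config.date_end - config.date_start).days + 1
    return [config.date_start + _dt.timedelta(days=i) for i in range(n_days)]


def seasonal_mean(config: SimulationConfig, dates: list[_dt.date]) -> np.ndarray:
    """Deterministic seasonal temperature component (no noise)."""
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    return config.temp_mean + config.temp_amplitude * np.cos(
        2.0 * np.pi * (doy - config.temp_peak_doy) / 365.25
    )


def simulate_temperature(config: SimulationConfig) -> EnvSeries:
    """Daily series: seasonal sinusoid plus stationary AR(1) noise."""
    config.validate()
    dates = _date_range(config)
    base = seasonal_mean(config, dates)
    rng = _rng(config, _STREAM_TEMPERATURE)
    phi, sd = config.temp_ar1, config.temp_noise_sd
    noise = np.zeros(len(dates))
    if sd > 0:
        innov_sd = sd * math.sqrt(1.0 - phi * phi)
        noise[0] = rng.normal(0.0, sd)
        eps = rng.normal(0.0, innov_sd, size=len(dates) - 1)
        for i in range(1, len(dates)):
            noise[i] = phi * noise[i - 1] + eps[i - 1]
    series = pd.Series(base + noise, index=pd.Index(dates, name="date"))
    return EnvSeries(series)


_HK_DESCRIPTIONS = (
    "polyubiquitin",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "elongation factor Tu",
    "actin",
)


def _gene_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    dates = _date_range(config)
    idx = 0
    for cls in GENE_CLASSES:
        n = config.class_sizes()[cls]
        mu0 = config.baseline_log_mean[cls]
        sd0 = config.baseline_log_sd[cls]
        baselines = rng.normal(mu0, sd0, size=n)
        peak_offsets = rng.integers(0, len(dates), size=n)
        for j in range(n):
            idx += 1
            gene_id = f"G{idx:05d}"
            if cls == "coupled":
                desc = f"heat shock protein {j + 1} family member"
            elif cls == "housekeeping":
                desc = f"{_HK_DESCRIPTIONS[j % len(_HK_DESCRIPTIONS)]} {j + 1}"
            elif cls == "switch":
                desc = f"WRKY transcription factor {j + 1}"
            elif cls == "peak":
                desc = f"MADS-box transcription factor {j + 1}"
            elif cls == "background":
                desc = f"hypothetical protein {j + 1}"
            else:
                desc = f"uncharacterized protein {j + 1}"
            rows.append(
                {
                    "gene_id": gene_id,
                    "gene_class": cls,
                    "baseline_log_cpm": float(baselines[j]),
                    "coupling": config.coupling_beta if cls == "coupled" else 0.0,
                    "switch_direction": (1 if j % 2 == 0 else -1)
                    if cls == "switch"
                    else 0,
                    "peak_date": dates[int(peak_offsets[j])] if cls == "peak" else None,
                    "dispersion": config.dispersion[cls],
                    "description": desc,
                }
            )
    return pd.DataFrame(rows)


def _sampling_design(config: SimulationConfig) -> SampleSheet:
    dates = _date_range(config)
    offsets = np.unique(
        np.round(np.linspace(0, len(dates) - 1, config.n_timepoints)).astype(int)
    )
    records = []
    for t, off in enumerate(offsets, start=1):
        for r in range(1, config.replicates + 1):
            records.append(
                {
                    "sample_id": f"T{t:02d}R{r}",
                    "timepoint": f"T{t:02d}",
                    "date": dates[off],
                    "replicate": r,
                }
            )
    return SampleSheet(pd.DataFrame(records))


def _log_means(
    config: SimulationConfig,
    genes: pd.DataFrame,
    sheet: SampleSheet,
    env: EnvSeries,
) -> np.ndarray:
    """(n_genes, n_samples) natural-log CPM-scale means."""
    sample_dates = [d for d in sheet.records["date"]]
    temp = np.array([env.value_on(d) for d in sample_dates])
    temp_centred = temp - float(env.series.mean())
    days = np.array(
        [(d - config.switch_date).days for d in sample_dates], dtype=float
    )
    mu = np.tile(
        genes["baseline_log_cpm"].to_numpy()[:, None], (1, len(sample_dates))
    )
    cls = genes["gene_class"].to_numpy()
    coupled = cls == "coupled"
    mu[coupled] += np.outer(genes.loc[coupled, "coupling"], temp_centred)
    switch = cls == "switch"
    if switch.any():
        sig = 1.0 / (1.0 + np.exp(-days / config.switch_width_days))
        mu[switch] += (
            config.switch_amplitude
            * genes.loc[switch, "switch_direction"].to_numpy()[:, None]
            * sig[None, :]
        )
    peak = cls == "peak"
    if peak.any():
        peak_days = np.array(
            [
                (pd_ - config.date_start).days
                for pd_ in genes.loc[peak, "peak_date"]
            ],
            dtype=float,
        )
        sample_offsets = np.array(
            [(d - config.date_start).days for d in sample_dates], dtype=float
        )
        delta = sample_offsets[None, :] - peak_days[:, None]
        mu[peak] += config.peak_amplitude * np.exp(
            -0.5 * (delta / config.peak_sigma_days) ** 2
        )
    return mu


def _draw_counts(
    rng: np.random.Generator, means: np.ndarray, dispersions: np.ndarray
) -> np.ndarray:
    counts = np.zeros(means.shape, dtype=np.int64)
    for i in range(means.shape[0]):
        m = means[i]
        alpha = dispersions[i]
        if alpha <= 0:
            counts[i] = rng.poisson(m)
        else:
            size = 1.0 / alpha
            p = size / (size + m)
            counts[i] = rng.negative_binomial(size, p)
    return counts


def simulate_counts(
    config: SimulationConfig | None = None,
) -> tuple[CountMatrix, SampleSheet, GeneAnnotation, EnvSeries, SyntheticTruth]:
    """Generate the full synthetic dataset for one configuration."""
    if config is None:
        config = SimulationConfig()
    config.validate()
    env = simulate_temperature(config)
    gene_rng = _rng(config, _STREAM_GENES)
    genes = _gene_table(config, gene_rng)
    sheet = _sampling_design(config)
    n_samples = len(sheet.sample_ids)

    lib_rng = _rng(config, _STREAM_LIBSIZES)
    sigma = config.library_size_log_sd
    lib_sizes = pd.Series(
        np.exp(
            lib_rng.normal(
                math.log(config.library_size_mean) - 0.5 * sigma * sigma,
                sigma,
                size=n_samples,
            )
        ),
        index=pd.Index(sheet.sample_ids, name="sample_id"),
    )

    mu = _log_means(config, genes, sheet, env)
    # normalize the expected composition to exactly 1e6 per sample so that
    # baseline_log_cpm really is on the CPM scale (up to the stored shift)
    scale_log = np.log(1e6 / np.exp(mu).sum(axis=0))
    mu = mu + scale_log[None, :]
    means = np.exp(mu) * (lib_sizes.to_numpy()[None, :] / 1e6)
    count_rng = _rng(config, _STREAM_COUNTS)
    counts = _draw_counts(count_rng, means, genes["dispersion"].to_numpy())

    matrix = CountMatrix(
        pd.DataFrame(
            counts,
            index=pd.Index(genes["gene_id"], name="gene_id"),
            columns=sheet.sample_ids,
        )
    )
    lengths = gene_rng.integers(500, 5001, size=len(genes))
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "length_bp": lengths,
                "description": genes["description"].to_numpy(),
            },
            index=pd.Index(genes["gene_id"], name="gene_id"),
        )
    )
    truth = SyntheticTruth(
        genes=genes.drop(columns=["description"]),
        library_sizes=lib_sizes,
        scale_log=pd.Series(
            scale_log, index=pd.Index(sheet.sample_ids, name="sample_id")
        ),
        env=env,
        config=config,
    )
    return matrix, sheet, annotation, env, truth


def write_truth(truth: SyntheticTruth, path: str) -> None:
    out = truth.genes.copy()
    out["peak_date"] = [
        d.isoformat() if d is not None else "" for d in out["peak_date"]
    ]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
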