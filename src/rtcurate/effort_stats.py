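"""Cohort aggregation of per-case curation effort logs.

Curation effort is recorded per cohort as (n, mean, median, sd) summaries.
Combining cohorts uses sample-size-weighted pooling with the population
(1/n) variance convention::

    pooled_mean = sum(n_i * mean_i) / N
    pooled_sd   = sqrt( sum(n_i * (sd_i^2 + mean_i^2)) / N - pooled_mean^2 )

Total per-case effort across independent workflow stages is estimated by
summing stage medians, with the combined uncertainty taken as the stage
standard deviations added in quadrature.
"""

from __future__ import annotations

import importlib.resources
import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class CohortStat:
    """Summary of one cohort's time-per-case distribution."""

    n: int
    mean: float
    median: float = float("nan")
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort sample count must be >= 1")
        if self.sd < 0:
            raise ValidationError("cohort sd must be >= 0")


def pooled_mean(stats: Sequence[CohortStat]) -> float:
    """Sample-size-weighted mean over cohorts."""
    if not stats:
        raise ValidationError("cannot pool an empty list of cohorts")
    total_n = sum(s.n for s in stats)
    return sum(s.n * s.mean for s in stats) / total_n


def pooled_sd(stats: Sequence[CohortStat]) -> float:
    """Pooled standard deviation over cohorts (population convention).

    Equals the direct standard deviation of the concatenated raw samples
    when each cohort sd also used the 1/n convention.
    """
    if not stats:
        raise ValidationError("cannot pool an empty list of cohorts")
    total_n = sum(s.n for s in stats)
    mu = pooled_mean(stats)
    second_moment = sum(s.n * (s.sd**2 + s.mean**2) for s in stats) / total_n
    return math.sqrt(max(0.0, second_moment - mu**2))


def quadrature(sds: Iterable[float]) -> float:
    """Combined uncertainty of independent stages: sqrt(sum sd_i^2)."""
    sds = list(sds)
    if any(s < 0 for s in sds):
        raise ValidationError("standard deviations must be >= 0")
    return math.sqrt(sum(s**2 for s in sds))


def combine_medians(medians: Iterable[float]) -> float:
    """Per-case total-effort estimator: the sum of stage medians."""
    return float(sum(medians))


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Display rounding with ties away from zero (7.25 -> 7.3)."""
    factor = 10**ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def load_effort_table(path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Load a cohort effort table (CSV).

    Without a path, returns the packaged head-and-neck reference table:
    per-cohort time summaries for carotid segmentation (minutes), all other
    OAR segmentation (hours) and physician review (hours).
    """
    if path is not None:
        return pd.read_csv(path)
    ref = importlib.resources.files("rtcurate.data") / "hn_effort_table.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def _stats_for_role(table: pd.DataFrame, role: str) -> list[CohortStat]:
    rows = table[table["role"] == role]
    return [
        CohortStat(
            n=int(r.n_samples), mean=float(r.mean), median=float(r.median),
            sd=float(r.sd),
        )
        for r in rows.itertuples()
    ]


def summarize_effort(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Combined (pooled) row per effort role, rounded for display."""
    if table is None:
        table = load_effort_table()
    out = []
    for role in table["role"].unique():
        stats = _stats_for_role(table, role)
        out.append(
            {
                "role": role,
                "n": sum(s.n for s in stats),
                "mean": round_half_up(pooled_mean(stats), 1),
                "sd": round_half_up(pooled_sd(stats), 1),
                "unit": table.loc[table["role"] == role, "unit"].iloc[0],
            }
        )
    return pd.DataFrame(out)


def per_case_estimate(
    stage_medians: Sequence[float], stage_sds: Sequence[float]
) -> tuple[float, float]:
    """Total per-case effort: summed medians +/- quadrature uncertainty."""
    return combine_medians(stage_medians), quadrature(stage_sds)
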