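"""Normalization, measurement-error, and goodness statistics.

For a pool of n species sequenced to depth D, unbiased sampling gives each
species an expected abundance of D/n reads, i.e. 1e6/n counts per million
(CPM). The per-species measurement error is

    delta_m = log10(CPM_m + pc) - log10(expected CPM)

with a half-count pseudo-count pc so zero-count species stay finite.
Errors and correction work in log10; distribution summaries (ECDF, RMSE)
are reported in log2, matching small-RNA benchmarking convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import CountTable

#: half-count pseudo-count, in CPM (or counts on the median-normalized scale)
PSEUDOCOUNT = 0.5

CPM_SCALE = "cpm"
MEDIAN_SCALE = "median_normalized"


class AbundanceTable(CountTable):
    """A CountTable carrying normalized abundances plus their scale."""

    def __init__(self, values: pd.DataFrame, scale: str):
        super().__init__(values)
        if scale not in (CPM_SCALE, MEDIAN_SCALE, "cpm_corrected"):
            raise ValueError(f"unknown abundance scale {scale!r}")
        if scale == CPM_SCALE:
            sums = self.values.sum(axis=0)
            live = sums > 0
            if not np.allclose(sums[live], 1e6, rtol=1e-9):
                raise ValueError("cpm columns must sum to 1e6")
        self.scale = scale


@dataclass
class ErrorVector:
    """Per-species Δlog10CPM (observed − expected log10 abundance)."""

    values: pd.Series
    expected_cpm: float | None = None

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("measurement errors must be finite")
        if self.expected_cpm is not None and not self.expected_cpm > 0:
            raise ValueError("expected_cpm must be positive")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


def cpm(table: CountTable) -> AbundanceTable:
    """Counts-per-million: count / column total × 1e6, per sample."""
    sums = table.values.sum(axis=0)
    dead = sums[sums == 0]
    if len(dead):
        raise ValueError(f"all-zero sample column(s): {list(dead.index)}")
    return AbundanceTable(table.values / sums * 1e6, scale=CPM_SCALE)


def median_normalize(table: CountTable) -> AbundanceTable:
    """Median-of-ratios normalization to a geometric-mean pseudo-reference.

    Species with a zero count in any sample are excluded from the size-factor
    computation (their geometric mean would vanish); values are counts
    divided by the per-sample size factor.
    """
    counts = table.values
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no species with nonzero counts in every sample; "
                         "cannot compute size factors")
    sub = counts.loc[usable]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.log(sub).sub(log_ref, axis=0).median(axis=0))
    return AbundanceTable(counts / factors, scale=MEDIAN_SCALE)


def measurement_errors(
    ab: AbundanceTable,
    expected_cpm: float,
    pseudocount: float = PSEUDOCOUNT,
) -> ErrorVector:
    """Δlog10CPM per species; replicate columns averaged on the log scale."""
    if ab.scale != CPM_SCALE:
        raise ValueError("measurement_errors requires a CPM-scale table")
    if not expected_cpm > 0:
        raise ValueError("expected_cpm must be positive")
    logcpm = np.log10(ab.values + pseudocount).mean(axis=1)
    return ErrorVector(values=logcpm - np.log10(expected_cpm),
                       expected_cpm=expected_cpm)


def rmse_log2(
    ab: AbundanceTable,
    expected: float,
    subset=None,
    pseudocount: float = PSEUDOCOUNT,
) -> float:
    """Root-mean-square log2 error against a flat expected abundance.

    The pseudo-count enters both sides of the difference, so a table equal
    to ``expected`` everywhere scores exactly zero. Computed over all
    (species, sample) entries of the subset.
    """
    if ab.scale == CPM_SCALE:
        warnings.warn("rmse_log2 is conventionally reported on "
                      "median-normalized counts; got a CPM table",
                      stacklevel=2)
    values = ab.values
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("empty species subset")
        values = values.loc[subset]
    resid = np.log2(values + pseudocount) - np.log2(expected + pseudocount)
    return float(np.sqrt(np.mean(np.square(resid.to_numpy()))))


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF as sorted unique values x and F(x) = P(X <= x)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("ecdf of empty input")
    x, counts = np.unique(arr, return_counts=True)
    return x, np.cumsum(counts) / arr.size
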