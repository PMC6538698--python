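"""Method-comparison statistics: saturation, summaries, and factor tests.

Saturation curves track how many pool species reach a detection threshold
as reads accumulate; abundance summaries rank methods by how far the
median CPM sits from the expected value; sequence-factor analysis asks
whether length, GC, secondary structure (self-fold), adapter/cDNA pairing
(co-fold), or free terminal bases distinguish outlier species from the
rest (rank-sum tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .fold import FoldProvider, MaxPairingProvider
from .normcore import PSEUDOCOUNT, AbundanceTable
from .endprofile import RepresentationLabels
from .seqio import CountTable, ReferencePool

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

FACTOR_COLUMNS = ["length", "gc", "self_fold", "co_fold",
                  "free_5p", "free_3p"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SaturationCurve:
    """Detected species vs cumulative reads, in fixed-size read bins."""

    reads: np.ndarray      # cumulative read totals (multiples of bin_size)
    detected: np.ndarray   # species with >= threshold reads so far
    bin_size: int
    threshold: int
    seed: int

    def plateau(self) -> int:
        return int(self.detected[-1]) if len(self.detected) else 0


def saturation_curve(
    table: CountTable,
    bin_size: int = 200,
    threshold: int = 10,
    seed: int = 0,
    max_reads: int = 3_000_000,
) -> SaturationCurve:
    """Shuffle the observed read multiset and consume it in bins.

    Multiple sample columns are pooled first. After each bin the count of
    species with cumulative reads >= threshold is recorded; the curve is
    truncated at ``max_reads``.
    """
    if threshold < 1:
        raise ValueError("detection threshold must be at least 1")
    counts = table.values.sum(axis=1).to_numpy()
    counts = np.rint(counts).astype(np.int64)
    total = int(counts.sum())
    if total < bin_size:
        raise ValueError(f"need at least bin_size={bin_size} reads, "
                         f"got {total}")
    reads = np.repeat(np.arange(len(counts)), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(reads)
    reads = reads[:max_reads]
    # occurrence index of each read within its species, in shuffled order
    occurrence = pd.Series(reads).groupby(reads).cumcount().to_numpy()
    detect_pos = np.sort(np.nonzero(occurrence == threshold - 1)[0])
    n_bins = len(reads) // bin_size
    boundaries = (np.arange(1, n_bins + 1)) * bin_size
    detected = np.searchsorted(detect_pos, boundaries, side="left")
    return SaturationCurve(reads=boundaries, detected=detected,
                           bin_size=bin_size, threshold=threshold, seed=seed)


def abundance_summary(ab: AbundanceTable, expected: float) -> pd.DataFrame:
    """Per-sample quartiles, 95% interval, and median deviation from the
    expected abundance (the method-ranking statistic)."""
    if ab.scale not in ("cpm", "cpm_corrected"):
        raise ValueError("abundance_summary expects a CPM-scale table")
    rows = {}
    for col in ab.samples:
        v = ab.values[col].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        lo, hi = np.percentile(v, [2.5, 97.5])
        rows[col] = {"q1": q1, "median": med, "q3": q3,
                     "ci95_low": lo, "ci95_high": hi,
                     "median_deviation": med - expected}
    return pd.DataFrame(rows).T


def replicate_correlation(
    table: CountTable, method: str = "spearman"
) -> pd.DataFrame:
    """Pairwise rank-based (or pearson) correlation between samples."""
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    corr = table.values.corr(method=method)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    off = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
    if np.isnan(off).any():
        warnings.warn("constant sample column: correlation undefined, "
                      "reported as NaN", stacklevel=2)
    return corr


def sequence_factors(
    pool: ReferencePool,
    adapter_seq: str | None = None,
    provider: FoldProvider | None = None,
) -> pd.DataFrame:
    """Per-species candidate bias factors.

    Columns: length, GC fraction, self-fold score, co-fold score of the
    ligating adapter against the species' cDNA (reverse complement), and
    free 5'/3' terminal base counts from one maximal-pairing traceback.
    Fold scores come from the base-pair-maximization proxy unless an
    external provider is supplied; co-fold is NaN without an adapter.
    """
    provider = provider or MaxPairingProvider()
    rows = {}
    for ident, seq in pool:
        fold = provider.self_fold(seq)
        row = {
            "length": len(seq),
            "gc": (seq.count("G") + seq.count("C")) / len(seq),
            "self_fold": float(fold.pairs),
            "co_fold": np.nan,
            "free_5p": fold.free_5p,
            "free_3p": fold.free_3p,
        }
        if adapter_seq is not None:
            row["co_fold"] = provider.duplex_score(
                adapter_seq.upper().replace("U", "T"),
                reverse_complement(seq))
        rows[ident] = row
    return pd.DataFrame.from_dict(rows, orient="index")[FACTOR_COLUMNS]


def _rank_sum(group: np.ndarray, rest: np.ndarray) -> float:
    """Two-sided Mann-Whitney p-value; exact for small tie-free groups,
    midrank normal approximation otherwise."""
    small = len(group) <= 20 and len(rest) <= 20
    no_ties = len(np.unique(np.concatenate([group, rest]))) == (
        len(group) + len(rest))
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(group, rest, alternative="two-sided",
                                    method=method).pvalue)


def outlier_factor_test(
    factors: pd.DataFrame,
    labels: RepresentationLabels,
) -> pd.DataFrame:
    """Rank-sum p-values per factor for over-vs-rest and under-vs-rest."""
    results = {}
    for contrast in ("over", "under"):
        ids = getattr(labels, contrast)
        if not ids:
            raise ValueError(f"no {contrast}-represented species to test")
        in_group = factors.index.isin(ids)
        pvals = {}
        for col in factors.columns:
            v = factors[col].to_numpy(dtype=float)
            ok = ~np.isnan(v)
            pvals[col] = _rank_sum(v[in_group & ok], v[~in_group & ok])
        results[f"{contrast}_vs_rest"] = pvals
    return pd.DataFrame(results)


class LengthFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def length_abundance_fit(
    ab: AbundanceTable,
    pool: ReferencePool,
    pseudocount: float = PSEUDOCOUNT,
) -> LengthFit:
    """OLS of log10(CPM + pc) on species length (log10 CPM per nt)."""
    lengths = pool.lengths().reindex(ab.species)
    if lengths.isna().any():
        raise ValueError("abundance table has species not in the pool")
    if lengths.nunique() < 3:
        raise ValueError("need at least 3 distinct lengths to fit")
    y = np.log10(ab.values + pseudocount).mean(axis=1).to_numpy()
    fit = stats.linregress(lengths.to_numpy(dtype=float), y)
    return LengthFit(slope=float(fit.slope), intercept=float(fit.intercept),
                     r_squared=float(fit.rvalue ** 2))
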