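"""Positional nucleotide-bias profiling and representation classification.

The central readout is the abundance-adjusted base frequency at each end
position: the frequency of base b at position p among reads, weighting each
species by its measured abundance, divided by the unweighted frequency in
the reference pool. With no bias the ratio is 1 at every position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .biascorrect import BASES, EndFeatureMatrix, base_at
from .normcore import AbundanceTable, ErrorVector
from .seqio import ReferencePool

#: the ±6 end positions profiled by default
DEFAULT_POSITIONS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, -6, -5, -4, -3, -2, -1)


@dataclass
class BiasProfile:
    """Observed vs reference base frequencies per end position."""

    positions: tuple[int, ...]
    observed: pd.DataFrame   # positions × bases, rows sum to 1
    reference: pd.DataFrame  # same shape, uniform-weight frequencies
    ratio: pd.DataFrame      # observed / reference (NaN where reference = 0)
    weighting: str           # "uniform" or "abundance"


@dataclass
class RepresentationLabels:
    """Over/under/normal labels from a k-standard-deviation rule."""

    labels: pd.Series
    threshold_sd: float
    center: float
    spread: float

    @property
    def over(self) -> list[str]:
        return list(self.labels.index[self.labels == "over"])

    @property
    def under(self) -> list[str]:
        return list(self.labels.index[self.labels == "under"])

    @property
    def flagged(self) -> list[str]:
        return list(self.labels.index[self.labels != "normal"])


def _base_table(pool: ReferencePool, positions) -> pd.DataFrame:
    min_len = pool.min_length()
    for p in positions:
        if abs(p) > min_len:
            short = next(i for i, s in pool if len(s) < abs(p))
            raise ValueError(
                f"position {p:+d} lies beyond sequence {short!r}")
    return pd.DataFrame(
        {p: {i: base_at(s, p) for i, s in pool} for p in positions}
    )


def _frequencies(bases: pd.DataFrame, weights: pd.Series) -> pd.DataFrame:
    total = float(weights.sum())
    out = {}
    for p in bases.columns:
        w = weights.groupby(bases[p]).sum() / total
        out[p] = w.reindex(list(BASES), fill_value=0.0)
    return pd.DataFrame(out).T


def end_nucleotide_frequencies(
    pool: ReferencePool,
    weights=None,
    positions: tuple[int, ...] = DEFAULT_POSITIONS,
) -> BiasProfile:
    """Weighted base frequencies at end positions, relative to the pool.

    ``weights`` (per-species, non-negative, e.g. CPM values) yields the
    abundance-adjusted profile; omitted weights give the uniform reference
    profile (all ratios 1).
    """
    bases = _base_table(pool, positions)
    uniform = pd.Series(1.0, index=bases.index)
    if weights is None:
        w = uniform
        weighting = "uniform"
    else:
        w = pd.Series(weights, dtype=float).reindex(bases.index)
        if w.isna().any():
            raise ValueError("weights missing for some pool species")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if w.sum() == 0:
            raise ValueError("weights must not all be zero")
        weighting = "abundance"
    observed = _frequencies(bases, w)
    reference = _frequencies(bases, uniform)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed / reference
    ratio[reference == 0] = np.nan
    return BiasProfile(positions=tuple(positions), observed=observed,
                       reference=reference, ratio=ratio, weighting=weighting)


def three_prime_composition(
    ab: AbundanceTable, pool: ReferencePool
) -> dict[str, float]:
    """Fraction of total abundance carried by species ending in each base."""
    last = pd.Series({i: s[-1] for i, s in pool})
    totals = ab.values.sum(axis=1).reindex(last.index)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise ValueError(f"abundance table missing pool species {missing}")
    grand = float(totals.sum())
    if grand == 0:
        raise ValueError("zero total abundance")
    frac = totals.groupby(last).sum() / grand
    return {b: float(frac.get(b, 0.0)) for b in BASES}


def classify_representation(
    errors: ErrorVector, threshold_sd: float = 1.0
) -> RepresentationLabels:
    """Flag species whose error is >= k SD above/below the mean.

    k = 1 delineates the over/under-represented sets used for end-bias
    analysis; k = 2 the outliers used for sequence-factor comparisons.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    v = errors.values
    if len(v) < 2:
        raise ValueError("need at least 2 species to classify")
    center = float(v.mean())
    spread = float(v.std(ddof=1))
    labels = pd.Series("normal", index=v.index)
    if spread == 0:
        warnings.warn("zero spread in errors; all species labeled normal",
                      stacklevel=2)
    else:
        labels[v >= center + threshold_sd * spread] = "over"
        labels[v <= center - threshold_sd * spread] = "under"
    return RepresentationLabels(labels=labels, threshold_sd=threshold_sd,
                                center=center, spread=spread)


@dataclass
class EndFeaturePCA:
    """PCA of centered one-hot end features of the flagged species."""

    scores: pd.DataFrame            # species × components
    loadings: pd.DataFrame          # features × components, orthonormal
    variance_explained: np.ndarray  # fraction per component


def pca_end_features(
    features: EndFeatureMatrix,
    labels: RepresentationLabels,
    n_components: int = 2,
) -> EndFeaturePCA:
    """PCA of the over/under-represented species' end features.

    Columns are centered but not rescaled: the indicators share units, and
    rescaling would inflate rare-base positions. PC1 loadings per
    (position, base) feature rank the drivers of the over/under split.
    """
    flagged = labels.flagged
    if len(flagged) < 2:
        raise ValueError("need at least 2 flagged (over/under) species")
    X = features.values.loc[flagged]
    if n_components > min(X.shape):
        raise ValueError(
            f"{n_components} components requested from a {X.shape} matrix")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.to_numpy(dtype=float))
    comp = [f"PC{i + 1}" for i in range(n_components)]
    return EndFeaturePCA(
        scores=pd.DataFrame(scores, index=X.index, columns=comp),
        loadings=pd.DataFrame(pca.components_.T, index=X.columns,
                              columns=comp),
        variance_explained=pca.explained_variance_ratio_,
    )
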