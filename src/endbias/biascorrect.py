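"""Terminal-sequence bias modeling and abundance correction.

The measurement error of each species in an equimolar pool is modeled as a
function of its terminal bases only:

    delta_m = f(x_{m,+1}, x_{m,+2}, x_{m,+3}, x_{m,-3}, x_{m,-2}, x_{m,-1})

where x_{m,i} is the base of species m at position i (+1..+3 from the 5'
end, -3..-1 from the 3' end), one-hot encoded into 24 indicators, and f is
a random-forest regressor. Corrected abundances subtract the predicted
error on the log10 scale:

    corrected_m = 10 ** (log10(CPM_m + pc) - delta_hat_m)

The module also provides k-fold cross-validation, position-level importance
summaries, and an alternative corrector that reweights abundances by the
ratio of reference to observed terminal-trinucleotide frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from .normcore import PSEUDOCOUNT, AbundanceTable, ErrorVector
from .seqio import ReferencePool

log = logging.getLogger(__name__)

BASES = "ACGT"

#: terminal positions modeled by default: first and last three bases
TERMINAL_POSITIONS: tuple[int, ...] = (1, 2, 3, -3, -2, -1)

#: internal-position control used to confirm the biases are terminal
INTERNAL_POSITIONS: tuple[int, ...] = (4, 5, 6, -6, -5, -4)


def feature_name(position: int, base: str) -> str:
    return f"{position:+d}{base}"


def base_at(sequence: str, position: int) -> str:
    """Base at a signed position: +1 is the first, -1 the last base."""
    if position == 0:
        raise ValueError("positions are 1-based and signed; 0 is invalid")
    return sequence[position - 1] if position > 0 else sequence[position]


@dataclass
class EndFeatureMatrix:
    """One-hot indicators of the bases at a fixed set of end positions.

    Rows are species; columns are (position, base) pairs in fixed order
    (positions as given, bases A, C, G, T within each position). Every row
    sums to the number of positions and every position block sums to 1.
    """

    values: pd.DataFrame
    positions: tuple[int, ...] = TERMINAL_POSITIONS

    def __post_init__(self) -> None:
        expected = [feature_name(p, b) for p in self.positions for b in BASES]
        if list(self.values.columns) != expected:
            raise ValueError("feature columns do not match the position list")
        arr = self.values.to_numpy()
        if not (arr.sum(axis=1) == len(self.positions)).all():
            raise ValueError("each row must sum to the number of positions")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


def encode_end_features(
    pool: ReferencePool,
    positions: tuple[int, ...] = TERMINAL_POSITIONS,
) -> EndFeatureMatrix:
    """One-hot encode the bases at ``positions`` for every pool species."""
    span = max(p for p in positions if p > 0) + max(-p for p in positions if p < 0)
    rows = {}
    for ident, seq in pool:
        if len(seq) < span:
            raise ValueError(
                f"sequence {ident!r} shorter than {span} nt; cannot encode "
                f"positions {positions}"
            )
        row = []
        for p in positions:
            b = base_at(seq, p)
            row.extend(1 if b == x else 0 for x in BASES)
        rows[ident] = row
    columns = [feature_name(p, b) for p in positions for b in BASES]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    return EndFeatureMatrix(values=df.loc[[i for i, _ in pool]],
                            positions=tuple(positions))


@dataclass(frozen=True)
class BiasModelConfig:
    """Random-forest hyperparameters.

    500 trees with one-third of the features considered per split and
    unlimited depth are the canonical regression-forest defaults; the seed
    fixes the tree ensemble so refits are bit-identical.
    """

    n_estimators: int = 500
    max_features: float = 1 / 3
    seed: int = 20190528


@dataclass
class BiasModel:
    """A fitted end-feature regressor with per-feature importances."""

    regressor: RandomForestRegressor
    feature_names: list[str]
    positions: tuple[int, ...]
    importances: pd.Series
    train_r2: float
    config: BiasModelConfig


def _align(features: EndFeatureMatrix, errors: ErrorVector):
    if set(features.species) != set(errors.species):
        raise ValueError("feature matrix and error vector index different "
                         "species sets")
    X = features.values
    y = errors.values.loc[X.index]
    return X, y


def fit_bias_model(
    features: EndFeatureMatrix,
    errors: ErrorVector,
    config: BiasModelConfig | None = None,
) -> BiasModel:
    """Fit the error regressor; deterministic under ``config.seed``."""
    config = config or BiasModelConfig()
    X, y = _align(features, errors)
    if len(X) < 50:
        raise ValueError(f"need at least 50 species to fit, got {len(X)}")
    if float(np.std(y)) == 0.0:
        warnings.warn("constant error vector: the fit is degenerate and "
                      "feature importances are meaningless", stacklevel=2)
    reg = RandomForestRegressor(
        n_estimators=config.n_estimators,
        max_features=config.max_features,
        random_state=config.seed,
        n_jobs=1,
    )
    reg.fit(X.to_numpy(), y.to_numpy())
    train_r2 = float(reg.score(X.to_numpy(), y.to_numpy()))
    importances = pd.Series(reg.feature_importances_,
                            index=features.feature_names)
    return BiasModel(regressor=reg, feature_names=features.feature_names,
                     positions=features.positions, importances=importances,
                     train_r2=train_r2, config=config)


def predict_errors(model: BiasModel, features: EndFeatureMatrix) -> ErrorVector:
    """Predicted Δlog10CPM per species."""
    if features.feature_names != model.feature_names:
        raise ValueError("feature columns do not match the fitted model")
    pred = model.regressor.predict(features.values.to_numpy())
    return ErrorVector(values=pd.Series(pred, index=features.species))


def correct_counts(
    ab: AbundanceTable,
    model: BiasModel | None,
    pool: ReferencePool,
    predictions: ErrorVector | None = None,
    pseudocount: float = PSEUDOCOUNT,
    renormalize: bool = False,
) -> AbundanceTable:
    """Subtract predicted errors from log10 abundances.

    ``predictions`` overrides the model (e.g. out-of-fold predictions from
    :func:`cross_validate` to avoid self-fitting). With ``renormalize`` the
    corrected pseudo-counts are rescaled back to CPM.
    """
    if ab.scale != "cpm":
        raise ValueError("correct_counts requires a CPM-scale table")
    if predictions is None:
        if model is None:
            raise ValueError("either a model or explicit predictions required")
        predictions = predict_errors(model, encode_end_features(
            pool, positions=model.positions))
    delta = predictions.values.reindex(ab.species)
    if delta.isna().any():
        missing = list(delta.index[delta.isna()])
        raise ValueError(f"no predicted error for species {missing}")
    corrected = 10 ** (np.log10(ab.values + pseudocount)
                       .sub(delta, axis=0))
    if renormalize:
        corrected = corrected / corrected.sum(axis=0) * 1e6
        return AbundanceTable(corrected, scale="cpm")
    return AbundanceTable(corrected, scale="cpm_corrected")


@dataclass
class CVResult:
    """Out-of-fold evaluation of the bias model."""

    fold_r2: list[float]
    assignments: pd.Series  # species -> fold index
    predictions: ErrorVector  # out-of-fold predictions, all species

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))


def cross_validate(
    features: EndFeatureMatrix,
    errors: ErrorVector,
    k: int = 8,
    seed: int = 0,
    config: BiasModelConfig | None = None,
) -> CVResult:
    """Shuffled k-fold CV: every species is held out exactly once."""
    config = config or BiasModelConfig()
    X, y = _align(features, errors)
    n = len(X)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of species ({n})")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_r2 = []
    assignments = pd.Series(index=X.index, dtype=int)
    oof = pd.Series(index=X.index, dtype=float)
    for fold, (train_idx, test_idx) in enumerate(kf.split(X)):
        reg = RandomForestRegressor(
            n_estimators=config.n_estimators,
            max_features=config.max_features,
            random_state=config.seed,
            n_jobs=1,
        )
        reg.fit(X.iloc[train_idx].to_numpy(), y.iloc[train_idx].to_numpy())
        pred = reg.predict(X.iloc[test_idx].to_numpy())
        fold_r2.append(float(r2_score(y.iloc[test_idx], pred)))
        assignments.iloc[test_idx] = fold
        oof.iloc[test_idx] = pred
    return CVResult(fold_r2=fold_r2, assignments=assignments,
                    predictions=ErrorVector(values=oof))


@dataclass
class PositionalImportance:
    """Position-level share of the model's impurity importance."""

    per_position: pd.Series  # index: positions, normalized to sum 1
    five_prime_share: float
    three_prime_share: float


def positional_importance(model: BiasModel) -> PositionalImportance:
    """Sum base-level importances per position; report the 5'/3' split."""
    total = float(model.importances.sum())
    if total == 0:
        raise ValueError("model has all-zero feature importances")
    per_pos = pd.Series(
        {p: float(model.importances[[feature_name(p, b) for b in BASES]].sum())
         for p in model.positions}
    ) / total
    five = float(per_pos[[p for p in model.positions if p > 0]].sum())
    return PositionalImportance(per_position=per_pos,
                                five_prime_share=five,
                                three_prime_share=1.0 - five)


def trinucleotide_reweight(
    ab: AbundanceTable,
    pool: ReferencePool,
    clip: tuple[float, float] = (0.1, 10.0),
) -> AbundanceTable:
    """Reweight abundances by terminal-trinucleotide frequency ratios.

    Each species is weighted by
    ``[f_ref(t5)/f_obs(t5)] * [f_ref(t3)/f_obs(t3)]`` where t5/t3 are its
    first/last trinucleotides, f_ref the uniform pool frequency and f_obs
    the abundance-weighted frequency in that sample. Weights are clipped to
    ``clip`` and each column rescaled to preserve its total abundance. This
    is a reconstruction of the read-start trinucleotide reweighting scheme
    and is advisory relative to the regression corrector.
    """
    t5 = pd.Series({i: s[:3] for i, s in pool})
    t3 = pd.Series({i: s[-3:] for i, s in pool})
    n = len(pool)
    f_ref5 = t5.value_counts() / n
    f_ref3 = t3.value_counts() / n
    out = {}
    lo, hi = clip
    for col in ab.samples:
        a = ab.values[col].reindex(t5.index)
        total = float(a.sum())
        if total == 0:
            raise ValueError(f"zero total abundance in sample {col!r}")
        f_obs5 = a.groupby(t5).sum() / total
        f_obs3 = a.groupby(t3).sum() / total

        def _ratio(f_ref, f_obs, tri):
            r = pd.Series(index=tri.index, dtype=float)
            for ident, t in tri.items():
                obs = float(f_obs.get(t, 0.0))
                if obs == 0.0:
                    warnings.warn(
                        f"trinucleotide {t} has zero observed frequency in "
                        f"{col!r}; weight clipped", stacklevel=3)
                    r[ident] = hi
                else:
                    r[ident] = float(f_ref[t]) / obs
            return r

        w = (_ratio(f_ref5, f_obs5, t5) * _ratio(f_ref3, f_obs3, t3)).clip(lo, hi)
        new = a * w
        out[col] = new / new.sum() * total
    return AbundanceTable(pd.DataFrame(out).loc[ab.species], scale=ab.scale)
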