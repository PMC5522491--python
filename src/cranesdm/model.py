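"""Class-weighted random-forest suitability model.

The classifier is a 1,000-tree random forest with balanced class weights
(weight of class c is N / (2 * N_c)), which counteracts the deliberately
extreme 1:100 presence:pseudo-absence prevalence of the training design.
Its presence-class probability is the relative index of occurrence (RIO)
in [0, 1].  Internal validation uses out-of-bag (OOB) probabilities: for
every training row, the mean presence probability over the trees that did
not see the row in their bootstrap sample.

Variable importance is the forest's impurity-based importance rescaled so
the top variable scores 100.0.  Response curves are partial dependence:
the mean predicted RIO over the training rows with one covariate clamped
to each value of an evaluation grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .grid import PointTable
from .sampling import TrainingDesign

__all__ = [
    "SuitabilityModel",
    "ImportanceRanking",
    "ResponseCurve",
    "fit",
    "score",
    "variable_importance",
    "response_curve",
    "half_maximum_crossing",
]


def _one_hot(features: pd.DataFrame, categorical: tuple[str, ...],
             categories: dict[str, list] | None = None
             ) -> tuple[pd.DataFrame, dict[str, list]]:
    """Encode categorical columns as 0/1 indicator columns.

    When ``categories`` is given (scoring time), the training-time category
    sets are reused so the encoded matrix always matches the fitted model.
    """
    out = features.copy()
    cats: dict[str, list] = {}
    for col in categorical:
        if col not in out.columns:
            continue
        if categories is not None:
            levels = categories[col]
        else:
            levels = sorted(pd.unique(out[col].dropna()))
        cats[col] = list(levels)
        for lv in levels:
            out[f"{col}={int(lv)}"] = (out[col] == lv).astype(float)
        out = out.drop(columns=[col])
    return out, cats


@dataclass
class SuitabilityModel:
    """Fitted forest plus everything needed to score new points."""

    forest: BaggingClassifier
    feature_names: list[str]          # raw covariate names, pre-encoding
    encoded_names: list[str]
    categorical: tuple[str, ...]
    categories: dict[str, list]
    n_trees: int
    seed: int
    oob_scores: np.ndarray            # per-training-row OOB presence probability
    class_weights: dict[int, float]
    design: TrainingDesign | None = field(default=None, repr=False)

    def encode(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"missing covariate column(s): {missing}")
        enc, _ = _one_hot(features[self.feature_names], self.categorical,
                          categories=self.categories)
        return enc[self.encoded_names]

    def predict_rio(self, features: pd.DataFrame) -> np.ndarray:
        enc = self.encode(features)
        proba = self.forest.predict_proba(enc.to_numpy())
        presence_col = int(np.flatnonzero(self.forest.classes_ == 1)[0])
        return proba[:, presence_col]


def fit(design: TrainingDesign, n_trees: int = 1000, seed: int = 0,
        n_jobs: int = 1, keep_design: bool = True) -> SuitabilityModel:
    """Fit the balanced-class-weight forest and record OOB probabilities.

    Requires both classes in the design.  With the default tree count every
    row receives an OOB estimate; rows that would not (possible only for
    very small forests) raise rather than silently producing NaN.
    """
    classes = np.unique(design.labels)
    if len(classes) < 2:
        raise ValueError("training design contains a single class; need both")
    X_df, cats = _one_hot(design.features, design.categorical)
    X = X_df.to_numpy(dtype=float)
    y = design.labels
    const = X_df.columns[(X.std(axis=0) == 0)].tolist()
    if const:
        warnings.warn(f"zero-variance feature(s) in design: {const}")

    n = len(y)
    weights = {int(c): n / (2.0 * (y == c).sum()) for c in classes}
    # bagged class-weighted trees with per-split feature subsampling: a
    # random forest whose bootstrap stays *uniform* so every row is
    # out-of-bag for ~37% of trees (a class-weighted bootstrap would pull
    # the rare presence class into every bag and leave it with no OOB
    # estimate at all)
    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(class_weight=weights,
                                         max_features="sqrt"),
        n_estimators=n_trees,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=n_jobs,
    )
    with warnings.catch_warnings():
        # sklearn warns when a row lacks OOB trees; we check explicitly below
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        forest.fit(X, y)
    presence_col = int(np.flatnonzero(forest.classes_ == 1)[0])
    oob_all = forest.oob_decision_function_
    oob = oob_all[:, presence_col]
    no_oob = np.isnan(oob) | (oob_all.sum(axis=1) == 0)
    if no_oob.any():
        raise RuntimeError(
            f"{int(no_oob.sum())} training rows have no out-of-bag trees; "
            f"increase n_trees (got {n_trees})"
        )
    return SuitabilityModel(
        forest=forest,
        feature_names=list(design.features.columns),
        encoded_names=list(X_df.columns),
        categorical=design.categorical,
        categories=cats,
        n_trees=n_trees,
        seed=seed,
        oob_scores=oob,
        class_weights=weights,
        design=design if keep_design else None,
    )


def score(model: SuitabilityModel, points: PointTable) -> PointTable:
    """Score points: RIO = forest presence-class probability in [0, 1].

    Flagged points (nodata covariates) receive NaN RIO.
    """
    feats = points.covariates
    rio = np.full(len(points), np.nan)
    ok = ~points.flagged
    if ok.any():
        rio[ok] = model.predict_rio(feats.loc[ok])
    return points.with_columns(rio=rio)


@dataclass
class ImportanceRanking:
    """Impurity importances rescaled so the top variable scores 100.0."""

    variables: list[str]
    scores: np.ndarray  # non-increasing, scores[0] == 100.0

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.variables, name="importance")

    def rank_of(self, variable: str) -> int:
        """1-based rank of a variable (categoricals ranked by their summed
        indicator importances under the raw name)."""
        return self.variables.index(variable) + 1


def variable_importance(model: SuitabilityModel) -> ImportanceRanking:
    """Rank covariates by forest impurity importance, top = 100.0.

    One-hot indicator columns are summed back into their parent categorical
    variable so the ranking is per original covariate.
    """
    imp = np.mean([t.feature_importances_ for t in model.forest.estimators_],
                  axis=0)
    raw = pd.Series(imp, index=model.encoded_names)
    agg: dict[str, float] = {}
    for name, val in raw.items():
        parent = name.split("=")[0] if "=" in name else name
        agg[parent] = agg.get(parent, 0.0) + float(val)
    ser = pd.Series(agg).sort_values(ascending=False)
    top = ser.iloc[0]
    scores = (ser / top * 100.0) if top > 0 else ser * 0.0
    return ImportanceRanking(variables=list(scores.index),
                             scores=scores.to_numpy())


@dataclass
class ResponseCurve:
    """Partial-dependence curve of predicted RIO against one covariate."""

    variable: str
    grid: np.ndarray
    rio: np.ndarray

    def half_maximum_crossing(self, direction: str | None = None) -> float:
        return half_maximum_crossing(self.grid, self.rio, direction=direction)


def response_curve(model: SuitabilityModel, design: TrainingDesign,
                   variable: str, grid_size: int = 50,
                   max_rows: int = 2000,
                   percentiles: tuple[float, float] = (1.0, 99.0)
                   ) -> ResponseCurve:
    """Partial dependence of RIO on one continuous covariate.

    For each of ``grid_size`` values spanning the variable's training
    range between the given data percentiles, the variable is clamped to
    that value in every training row and the mean predicted RIO is
    recorded.  The percentile clip keeps the curve inside the data-
    supported range — tree ensembles extrapolate erratically beyond it;
    pass ``(0, 100)`` for the absolute range.  Designs larger than
    ``max_rows`` are subsampled deterministically (the partial-dependence
    average is over rows, so a few thousand suffice).
    """
    if variable not in design.features.columns:
        raise KeyError(f"{variable!r} is not a model covariate")
    if variable in design.categorical:
        raise ValueError(f"{variable!r} is categorical; response curves are "
                         "defined for continuous covariates")
    col = design.features[variable].to_numpy(dtype=float)
    lo, hi = np.nanpercentile(col, list(percentiles))
    if lo == hi:
        warnings.warn(f"{variable!r} is constant in the design; flat curve")
        grid = np.full(grid_size, lo)
    else:
        grid = np.linspace(lo, hi, grid_size)
    work = design.features
    if len(work) > max_rows:
        keep = np.random.default_rng(model.seed).choice(
            len(work), size=max_rows, replace=False
        )
        work = work.iloc[np.sort(keep)]
    work = work.copy()
    means = np.empty(grid_size)
    for i, v in enumerate(grid):
        work[variable] = v
        means[i] = model.predict_rio(work).mean()
    return ResponseCurve(variable=variable, grid=grid, rio=means)


def half_maximum_crossing(grid: np.ndarray, values: np.ndarray,
                          direction: str | None = None) -> float:
    """Covariate value where a curve crosses halfway between its minimum
    and maximum (linear interpolation between grid points).

    For monotone threshold-shaped responses this recovers the inflection.
    ``direction`` restricts the search to ``"increase"`` (curve rising
    through the half level) or ``"decrease"`` crossings — useful when a
    fitted curve carries small artifacts in data-sparse regions; with
    several candidates the steepest one wins.  Default: first crossing.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("flat curve has no half-maximum crossing")
    half = (lo + hi) / 2.0
    above = values >= half
    idx = np.flatnonzero(above[1:] != above[:-1])
    if len(idx) == 0:
        raise ValueError("curve never crosses its half-maximum")
    slopes = values[idx + 1] - values[idx]
    if direction == "increase":
        idx = idx[slopes > 0]
    elif direction == "decrease":
        idx = idx[slopes < 0]
    elif direction is not None:
        raise ValueError(f"direction must be 'increase', 'decrease' or None, got {direction!r}")
    if len(idx) == 0:
        raise ValueError(f"curve has no {direction} crossing of its half-maximum")
    if direction is None:
        i = int(idx[0])
    else:
        i = int(idx[np.argmax(np.abs(values[idx + 1] - values[idx]))])
    v0, v1 = values[i], values[i + 1]
    g0, g1 = grid[i], grid[i + 1]
    t = (half - v0) / (v1 - v0)
    return float(g0 + t * (g1 - g0))
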