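"""Native kNN read-across classifier and the autoML grid-search engine.

The k-nearest-neighbour model is the package's own, because read-across
reporting needs the neighbour identities and Euclidean distances, not just
a label.  Random forest, XGBoost and the fully connected neural network
are consumed through a thin estimator-adapter contract around established
implementations (scikit-learn, xgboost) — their internals are not part of
this package.

Grid search expands [min, max; step] ranges per hyperparameter, scores
every candidate by mean validation accuracy over stratified k-fold
cross-validation, and picks the maximum (ties go to the first candidate in
enumeration order).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .dataset_io import DescriptorMatrix, ToxClass, ValidationError

FAMILIES = ("knn", "random_forest", "xgboost", "neural_network")


def _as_array(X) -> np.ndarray:
    if isinstance(X, DescriptorMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _encode(y: Sequence) -> np.ndarray:
    return np.array([v.code if isinstance(v, ToxClass) else int(v) for v in y])


@dataclass
class KNNModel:
    """Lazy k-nearest-neighbour classifier over z-scored descriptors.

    Binary voting with odd k can never tie, so even k is rejected rather
    than given a tie rule.
    """

    k: int
    train_matrix: np.ndarray
    train_labels: np.ndarray  # 0 = low, 1 = high
    train_ids: list[str]
    feature_names: list[str]

    @property
    def n_train(self) -> int:
        return self.train_matrix.shape[0]

    def vote_fraction(self, X) -> np.ndarray:
        """Fraction of the k nearest neighbours voting high, per query row.

        This continuous output (in {0, 1/k, ..., 1}) is the quantity the
        Shapley explainer attributes.
        """
        X = np.atleast_2d(_as_array(X))
        if X.shape[1] != self.train_matrix.shape[1]:
            raise ValidationError(
                f"query has {X.shape[1]} features, model expects "
                f"{self.train_matrix.shape[1]}"
            )
        d = np.sqrt(((X[:, None, :] - self.train_matrix[None, :, :]) ** 2).sum(-1))
        idx = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        return self.train_labels[idx].mean(axis=1)

    def predict(self, X) -> list[ToxClass]:
        vf = self.vote_fraction(X)
        return [ToxClass.HIGH if v > 0.5 else ToxClass.LOW for v in vf]


@dataclass
class PredictionRecord:
    """A single kNN prediction with its read-across evidence."""

    query_id: str
    predicted_class: ToxClass
    vote_fraction_high: float
    neighbours: list[tuple[str, float]]  # (train id, distance), non-decreasing
    ad_reliable: bool | None = None


def knn_fit(X, y, k: int = 3) -> KNNModel:
    """Store the (z-scored) training data verbatim; kNN is a lazy learner."""
    arr = _as_array(X)
    if arr.ndim != 2:
        raise ValidationError("training matrix must be 2-D")
    n = arr.shape[0]
    if k < 1 or k > n:
        raise ValidationError(f"k={k} out of range 1..{n}")
    if k % 2 == 0:
        raise ValidationError(f"k must be odd for binary voting (got {k})")
    labels = _encode(y)
    if len(labels) != n:
        raise ValidationError("label count does not match row count")
    ids = X.row_ids if isinstance(X, DescriptorMatrix) else [str(i) for i in range(n)]
    names = X.column_names if isinstance(X, DescriptorMatrix) else [
        f"f{j}" for j in range(arr.shape[1])
    ]
    return KNNModel(k=k, train_matrix=arr, train_labels=labels,
                    train_ids=ids, feature_names=names)


def knn_predict(model: KNNModel, x, query_id: str = "query") -> PredictionRecord:
    """Predict one query vector: majority vote of the k nearest neighbours.

    Neighbours are the k smallest Euclidean distances; exact distance ties
    are broken by training-row order so read-across groups are reproducible.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.train_matrix.shape[1]:
        raise ValidationError(
            f"query has {x.shape[0]} features, model expects "
            f"{model.train_matrix.shape[1]}"
        )
    d = np.sqrt(((model.train_matrix - x) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[: model.k]
    neighbours = [(model.train_ids[i], float(d[i])) for i in order]
    vf = float(model.train_labels[order].mean())
    return PredictionRecord(
        query_id=query_id,
        predicted_class=ToxClass.HIGH if vf > 0.5 else ToxClass.LOW,
        vote_fraction_high=vf,
        neighbours=neighbours,
    )


@dataclass
class EstimatorSpec:
    """A model family plus its hyperparameter search grid.

    ``grid`` entries are (name, min, max, step) ranges expanded inclusively;
    ``fixed`` carries non-numeric settings (e.g. activation function).
    """

    family: str
    grid: list[tuple[str, float, float, float]] = field(default_factory=list)
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown model family {self.family!r}; expected one of {FAMILIES}"
            )

    def expand(self) -> list[dict]:
        """Enumerate candidates, ascending in every hyperparameter.

        For the knn family, even neighbour counts are not valid candidates
        (binary voting admits no tie rule), so a [3, 9; 1] range enumerates
        k = 3, 5, 7, 9.
        """
        axes: list[list[tuple[str, float]]] = []
        for name, lo, hi, step in self.grid:
            if step <= 0:
                vals = [lo]
            else:
                vals, v = [], lo
                while v <= hi + 1e-9:
                    vals.append(round(v, 10))
                    v += step
            if self.family == "knn" and name == "k":
                vals = [v for v in vals if int(round(v)) % 2 == 1]
            axes.append([(name, v) for v in vals])
        out = []
        for combo in itertools.product(*axes):
            cand = dict(self.fixed)
            cand.update(dict(combo))
            out.append(cand)
        return out


def default_grids() -> dict[str, EstimatorSpec]:
    """The reproduction search ranges for the four model families."""
    return {
        "knn": EstimatorSpec("knn", grid=[("k", 3, 9, 1)]),
        "xgboost": EstimatorSpec(
            "xgboost",
            grid=[
                ("n_trees", 5, 20, 5),
                ("learning_rate", 0.1, 0.3, 0.1),
                ("lambda", 0.8, 1.0, 0.1),
                ("alpha", 0.8, 1.0, 0.1),
            ],
            fixed={"gamma": 0, "max_depth": 6, "min_child_weight": 1,
                   "colsample_bytree": 1, "subsample": 1},
        ),
        "random_forest": EstimatorSpec(
            "random_forest",
            grid=[
                ("feature_fraction", 0.5, 0.9, 0.2),
                ("n_ensembles", 100, 200, 50),
            ],
            fixed={"min_impurity_decrease": 0},
        ),
        "neural_network": EstimatorSpec(
            "neural_network",
            grid=[
                ("n_neurons", 50, 100, 50),
                ("n_epochs", 50, 150, 50),
                ("learning_rate", 0.001, 0.01, 0.009),
                ("momentum", 0.8, 0.9, 0.1),
            ],
            fixed={"n_hidden_layers": 2, "activation": "relu", "batch_size": 128},
        ),
    }


class FittedEstimator:
    """Uniform predict() wrapper over a fitted model of any family."""

    def __init__(self, family: str, params: dict, inner):
        self.family = family
        self.params = params
        self.inner = inner

    def predict(self, X) -> np.ndarray:
        """Predicted labels, 0 = low / 1 = high."""
        arr = _as_array(X)
        if self.family == "knn":
            return (self.inner.vote_fraction(arr) > 0.5).astype(int)
        return np.asarray(self.inner.predict(arr)).astype(int)


def train_estimator(spec: EstimatorSpec | str, params: dict, X, y,
                    seed: int = 0) -> FittedEstimator:
    """Fit one hyperparameter candidate of the given family."""
    family = spec.family if isinstance(spec, EstimatorSpec) else spec
    arr = _as_array(X)
    y_enc = _encode(y)
    if family == "knn":
        inner = knn_fit(X, y, k=int(round(params.get("k", 3))))
    elif family == "random_forest":
        inner = RandomForestClassifier(
            n_estimators=int(round(params.get("n_ensembles", 100))),
            max_features=float(params.get("feature_fraction", 0.9)),
            min_impurity_decrease=float(params.get("min_impurity_decrease", 0.0)),
            random_state=seed,
        ).fit(arr, y_enc)
    elif family == "xgboost":
        from xgboost import XGBClassifier

        inner = XGBClassifier(
            n_estimators=int(round(params.get("n_trees", 20))),
            learning_rate=float(params.get("learning_rate", 0.2)),
            gamma=float(params.get("gamma", 0)),
            max_depth=int(round(params.get("max_depth", 6))),
            min_child_weight=float(params.get("min_child_weight", 1)),
            colsample_bytree=float(params.get("colsample_bytree", 1)),
            subsample=float(params.get("subsample", 1)),
            reg_lambda=float(params.get("lambda", 1.0)),
            reg_alpha=float(params.get("alpha", 0.8)),
            random_state=seed,
            n_jobs=1,
        ).fit(arr, y_enc)
    elif family == "neural_network":
        layers = int(round(params.get("n_hidden_layers", 2)))
        neurons = int(round(params.get("n_neurons", 100)))
        inner = MLPClassifier(
            hidden_layer_sizes=(neurons,) * layers,
            activation=str(params.get("activation", "relu")),
            solver="sgd",
            batch_size=min(int(round(params.get("batch_size", 128))), len(y_enc)),
            max_iter=int(round(params.get("n_epochs", 100))),
            learning_rate_init=float(params.get("learning_rate", 0.01)),
            momentum=float(params.get("momentum", 0.9)),
            random_state=seed,
        ).fit(arr, y_enc)
    else:
        raise ValidationError(f"unknown model family {family!r}")
    return FittedEstimator(family, dict(params), inner)


def predict_estimator(adapter: FittedEstimator, X) -> np.ndarray:
    """Predicted class codes (0 = low, 1 = high) for each row of X."""
    return adapter.predict(X)


@dataclass
class GridSearchResult:
    family: str
    candidates: list[dict]
    fold_scores: np.ndarray  # (n_candidates, n_folds) validation accuracies
    mean_scores: np.ndarray
    best_index: int
    fold_of_row: np.ndarray  # validation-fold index per training row

    @property
    def best_candidate(self) -> dict:
        return self.candidates[self.best_index]

    @property
    def best_mean_accuracy(self) -> float:
        return float(self.mean_scores[self.best_index])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cand in enumerate(self.candidates):
            row = {"candidate": repr(cand)}
            for j in range(self.fold_scores.shape[1]):
                row[f"fold_{j + 1}"] = self.fold_scores[i, j]
            row["mean_accuracy"] = self.mean_scores[i]
            rows.append(row)
        return pd.DataFrame(rows)


def stratified_folds(y: Sequence, n_folds: int, seed: int) -> np.ndarray:
    """Validation-fold index per row; per-class counts differ by <= 1."""
    y_enc = _encode(y)
    counts = np.bincount(y_enc)
    if (counts[counts > 0] < n_folds).any():
        raise ValidationError(f"every class needs >= {n_folds} members")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold = np.empty(len(y_enc), dtype=int)
    for f, (_, val_idx) in enumerate(skf.split(np.zeros(len(y_enc)), y_enc)):
        fold[val_idx] = f
    return fold


def grid_search_cv(
    X, y, spec: EstimatorSpec, n_folds: int = 5, seed: int = 0
) -> GridSearchResult:
    """Score every grid candidate by stratified k-fold validation accuracy.

    All candidates share the same fold assignment; the winner is the
    maximum mean accuracy, first-in-grid on exact ties.
    """
    candidates = spec.expand()
    if not candidates:
        raise ValidationError("empty hyperparameter grid")
    arr = _as_array(X)
    y_enc = _encode(y)
    fold = stratified_folds(y_enc, n_folds, seed)

    scores = np.zeros((len(candidates), n_folds))
    for ci, cand in enumerate(candidates):
        for f in range(n_folds):
            tr, va = fold != f, fold == f
            try:
                est = train_estimator(spec.family, cand, arr[tr], y_enc[tr], seed=seed)
                pred = est.predict(arr[va])
            except Exception as exc:  # attach candidate identity
                raise ValidationError(
                    f"estimator {spec.family} failed for candidate {cand}: {exc}"
                ) from exc
            scores[ci, f] = float((pred == y_enc[va]).mean())
    means = scores.mean(axis=1)
    best = int(np.argmax(means))  # argmax takes the first maximum
    return GridSearchResult(
        family=spec.family,
        candidates=candidates,
        fold_scores=scores,
        mean_scores=means,
        best_index=best,
        fold_of_row=fold,
    )
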