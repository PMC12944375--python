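"""Boruta all-relevant feature selection, implemented from scratch.

Each iteration appends a "shadow" copy of every still-undecided feature
with its rows independently permuted, asks a pluggable importance function
(by default a small random forest) to score real and shadow features
together, and records a *hit* for every real feature whose importance
strictly exceeds the maximum shadow importance.  A two-sided binomial test
(p = 0.5, Bonferroni-corrected across the undecided features) then either
confirms (upper tail) or rejects (lower tail) features; decided features
drop out of later iterations.  Whatever is still undecided when the
iteration budget runs out is reported tentative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .dataset_io import DescriptorMatrix, ToxClass, ValidationError

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"

# importance adapter: (X, y, seed) -> one non-negative importance per column
ImportanceFn = Callable[[np.ndarray, np.ndarray, int], np.ndarray]


def rf_importance(
    n_estimators: int = 10,
    feature_fraction: float = 0.9,
    min_impurity_decrease: float = 0.0,
) -> ImportanceFn:
    """Default adapter: impurity importance from a small random forest."""

    def fn(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features=feature_fraction,
            min_impurity_decrease=min_impurity_decrease,
            random_state=seed,
        )
        rf.fit(X, y)
        return rf.feature_importances_

    return fn


@dataclass
class BorutaConfig:
    max_iterations: int = 100
    alpha: float = 0.05
    importance_source: ImportanceFn = field(default_factory=rf_importance)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0,1)")


@dataclass
class BorutaResult:
    status: dict[str, str]  # feature -> confirmed | rejected | tentative
    hit_counts: dict[str, int]
    n_iterations_run: int
    importance_history: list[pd.Series]  # per-iteration real-feature importances

    @property
    def confirmed(self) -> list[str]:
        return [f for f, s in self.status.items() if s == CONFIRMED]

    @property
    def rejected(self) -> list[str]:
        return [f for f, s in self.status.items() if s == REJECTED]

    @property
    def tentative(self) -> list[str]:
        return [f for f, s in self.status.items() if s == TENTATIVE]

    def to_csv(self, path) -> None:
        mean_imp = {}
        for f in self.status:
            vals = [h[f] for h in self.importance_history if f in h.index]
            mean_imp[f] = float(np.mean(vals)) if vals else float("nan")
        pd.DataFrame(
            {
                "feature": list(self.status),
                "status": [self.status[f] for f in self.status],
                "hit_count": [self.hit_counts[f] for f in self.status],
                "mean_importance": [mean_imp[f] for f in self.status],
            }
        ).to_csv(path, index=False)


def _encode_labels(y: Sequence) -> np.ndarray:
    enc = []
    for v in y:
        enc.append(v.code if isinstance(v, ToxClass) else v)
    arr = np.asarray(enc)
    if len(np.unique(arr)) < 2:
        raise ValidationError("both classes must be present for Boruta")
    return arr


def boruta_select(
    X: DescriptorMatrix,
    y: Sequence | Mapping[str, ToxClass],
    config: BorutaConfig | None = None,
) -> BorutaResult:
    """Run Boruta on a (z-scored) feature matrix.

    ``y`` may be a per-row sequence or an id-keyed mapping.  Returns the
    per-feature status partition plus hit counts and the real-feature
    importance history.
    """
    config = config or BorutaConfig()
    if isinstance(y, Mapping):
        y = [y[i] for i in X.row_ids]
    y_arr = _encode_labels(y)
    df = X.df
    if df.shape[1] < 2:
        raise ValidationError("Boruta needs at least 2 features")
    if len(y_arr) != df.shape[0]:
        raise ValidationError("label length does not match row count")

    features = list(df.columns)
    status = {f: TENTATIVE for f in features}
    hits = {f: 0 for f in features}
    trials = {f: 0 for f in features}
    history: list[pd.Series] = []
    rng = np.random.default_rng(config.seed)

    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):
        undecided = [f for f in features if status[f] == TENTATIVE]
        if not undecided:
            n_iter -= 1
            break
        real = df[undecided].to_numpy(dtype=float)
        shadow = real.copy()
        for j in range(shadow.shape[1]):  # independent permutation per column
            shadow[:, j] = shadow[rng.permutation(shadow.shape[0]), j]
        X_iter = np.hstack([real, shadow])
        imp = np.asarray(
            config.importance_source(X_iter, y_arr, int(rng.integers(2**31 - 1)))
        )
        if imp.shape[0] != X_iter.shape[1] or not np.all(np.isfinite(imp)):
            raise ValidationError("importance adapter returned invalid importances")
        real_imp = imp[: len(undecided)]
        shadow_max = imp[len(undecided):].max()
        history.append(pd.Series(real_imp, index=undecided))
        for f, v in zip(undecided, real_imp):
            trials[f] += 1
            if v > shadow_max:
                hits[f] += 1

        # two-sided binomial decision, Bonferroni across undecided features
        threshold = config.alpha / len(undecided)
        for f in undecided:
            upper = stats.binom.sf(hits[f] - 1, trials[f], 0.5)  # P[X >= hits]
            lower = stats.binom.cdf(hits[f], trials[f], 0.5)  # P[X <= hits]
            if upper < threshold:
                status[f] = CONFIRMED
            elif lower < threshold:
                status[f] = REJECTED

    return BorutaResult(
        status=status,
        hit_counts=hits,
        n_iterations_run=n_iter,
        importance_history=history,
    )
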