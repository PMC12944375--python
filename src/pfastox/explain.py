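"""Exact Shapley-value attributions and read-across similarity reports.

The Shapley value of feature j for a query x distributes the deviation of
the model output f(x) from its background mean across the features:

    phi_j = sum over S subset of F\\{j} of
            |S|! (m - |S| - 1)! / m!  *  (v(S u {j}) - v(S))

with the interventional value function v(S) = mean over background rows b
of f(x with features outside S taken from b).  At the small feature counts
this package targets (m <= 15 after selection) the 2^m coalitions are
enumerated exactly, so the usual kernel-regression approximation is
unnecessary: the result is the quantity that approximation converges to.

For the kNN classifier the explained output is the continuous vote
fraction for the high-toxicity class (encoded low = 0, high = 1); hard
labels would give degenerate, non-additive attributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .appdomain import ADModel, ad_check
from .dataset_io import CompoundRecord, ToxClass, ValidationError
from .models import KNNModel, knn_predict


@dataclass
class ShapleyExplanation:
    query_id: str
    feature_names: list[str]
    base_value: float  # mean model output over the background
    phi: np.ndarray  # per-feature attribution
    model_output: float  # f(x); equals base_value + sum(phi)

    def as_series(self) -> pd.Series:
        return pd.Series(self.phi, index=self.feature_names, name=self.query_id)


def shapley_exact(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    x,
    background,
    feature_names: Sequence[str] | None = None,
    max_exact_features: int = 15,
    query_id: str = "query",
) -> ShapleyExplanation:
    """Exact Shapley attribution of ``predict_fn`` at ``x`` by enumeration.

    ``predict_fn`` maps an (n, m) matrix to n continuous outputs;
    ``background`` supplies the rows that stand in for absent features.
    Feature counts above ``max_exact_features`` are refused (2^m coalition
    evaluations) — reduce the feature set or use a sampling explainer.
    """
    x = np.asarray(x, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    m = x.shape[0]
    if bg.shape[1] != m:
        raise ValidationError("background width does not match query width")
    if m > max_exact_features:
        raise ValidationError(
            f"{m} features exceed the exact-enumeration cap "
            f"({max_exact_features}); use a sampling explainer"
        )
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(m)
    ]
    if len(names) != m:
        raise ValidationError("feature_names length does not match query width")

    # v(S) for every coalition bitmask
    v = np.empty(1 << m)
    for mask in range(1 << m):
        rows = bg.copy()
        for j in range(m):
            if mask >> j & 1:
                rows[:, j] = x[j]
        out = np.asarray(predict_fn(rows), dtype=float)
        if not np.all(np.isfinite(out)):
            raise ValidationError("model returned non-finite outputs")
        v[mask] = out.mean()

    fact = [math.factorial(i) for i in range(m + 1)]
    weight = [fact[s] * fact[m - s - 1] / fact[m] for s in range(m)]
    phi = np.zeros(m)
    for mask in range(1 << m):
        s = bin(mask).count("1")
        for j in range(m):
            if not mask >> j & 1:
                phi[j] += weight[s] * (v[mask | (1 << j)] - v[mask])

    return ShapleyExplanation(
        query_id=query_id,
        feature_names=names,
        base_value=float(v[0]),
        phi=phi,
        model_output=float(v[(1 << m) - 1]),
    )


def global_importance(
    explanations: Sequence[ShapleyExplanation],
) -> pd.Series:
    """Features ranked by mean |phi| across explanations (descending)."""
    if not explanations:
        raise ValidationError("no explanations given")
    names = explanations[0].feature_names
    for e in explanations:
        if e.feature_names != names:
            raise ValidationError("explanations disagree on feature names")
    mat = np.abs(np.vstack([e.phi for e in explanations]))
    s = pd.Series(mat.mean(axis=0), index=names, name="mean_abs_phi")
    return s.sort_values(ascending=False, kind="stable")


def export_beeswarm_data(
    explanations: Sequence[ShapleyExplanation],
    feature_values: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format table (feature, phi, feature value, query id) for plotting.

    Features appear in global-importance order, queries in input order;
    one row per (query, feature) pair.  ``feature_values`` is indexed by
    query id with the explained features as columns.
    """
    ranking = global_importance(explanations)
    rows = []
    for feat in ranking.index:
        j = explanations[0].feature_names.index(feat)
        for e in explanations:
            if e.query_id not in feature_values.index:
                raise ValidationError(f"no feature values for query {e.query_id!r}")
            rows.append({
                "feature": feat,
                "phi": float(e.phi[j]),
                "feature_value": float(feature_values.loc[e.query_id, feat]),
                "query_id": e.query_id,
            })
    return pd.DataFrame(rows)


@dataclass
class ReadAcrossReport:
    """A query and its k-nearest similarity group with metadata."""

    query_id: str
    query_smiles: str
    predicted_class: ToxClass
    ad_reliable: bool
    ad_distance: float
    group: list[dict] = field(default_factory=list)
    # each entry: train_id, smiles, tox_class, distance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.group)

    def to_text(self) -> str:
        flag = "reliable" if self.ad_reliable else "UNRELIABLE"
        lines = [
            f"query {self.query_id} ({self.query_smiles}): "
            f"predicted {self.predicted_class} [{flag}, centroid distance "
            f"{self.ad_distance:.3f}]",
            "similarity group (nearest first):",
        ]
        for g in self.group:
            lines.append(
                f"  {g['train_id']}  d={g['distance']:.3f}  "
                f"class={g['tox_class']}  {g['smiles']}"
            )
        return "\n".join(lines)


def read_across_report(
    model: KNNModel,
    query,
    ad: ADModel,
    compound_lookup: Mapping[str, CompoundRecord],
    query_id: str = "query",
    query_smiles: str = "",
) -> ReadAcrossReport:
    """Join a kNN prediction's neighbour group with compound metadata.

    The neighbour Euclidean distances double as a qualitative similarity
    measure; the group justifies the read-across inference compound by
    compound.
    """
    pred = knn_predict(model, query, query_id=query_id)
    reliable, dist = ad_check(ad, query)
    group = []
    for nid, d in pred.neighbours:
        if nid not in compound_lookup:
            raise ValidationError(f"neighbour {nid!r} missing from compound lookup")
        rec = compound_lookup[nid]
        group.append({
            "train_id": nid,
            "smiles": rec.smiles,
            "tox_class": str(rec.tox_class) if rec.tox_class else "",
            "distance": float(d),
        })
    return ReadAcrossReport(
        query_id=query_id,
        query_smiles=query_smiles,
        predicted_class=pred.predicted_class,
        ad_reliable=reliable,
        ad_distance=dist,
        group=group,
    )
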