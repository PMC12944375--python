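"""Training-set-blind preprocessing.

Order of operations in the reference workflow: stratified 70/30 split,
repeated-value column filter (> 20% identical values), z-score
normalisation with train-derived parameters, duplicate-row removal, and a
Pearson inter-correlation report on the selected descriptors.  Every
parameter (filter decision, mean, sd) is a function of the training
partition only, so the held-out set never leaks into model construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset_io import DescriptorMatrix, ValidationError


@dataclass
class SplitResult:
    """Outcome of a stratified train/test partition."""

    train_ids: list[str]
    test_ids: list[str]
    test_fraction: float
    seed: int

    def to_csv(self, path: str | Path) -> None:
        rows = [{"id": i, "partition": "train"} for i in self.train_ids]
        rows += [{"id": i, "partition": "test"} for i in self.test_ids]
        pd.DataFrame(rows).to_csv(path, index=False)


def stratified_split(
    labels: Mapping[str, Hashable],
    test_fraction: float = 0.3,
    seed: int = 0,
) -> SplitResult:
    """Stratified random train/test partition with largest-remainder quotas.

    The total test size is round(N * test_fraction).  Each class receives a
    base quota floor(n_c * test_fraction); remaining test slots go to the
    classes with the largest fractional remainder (ties favour the larger
    class).  Membership within each class is uniformly random under
    ``seed``, so the seed controls *which* compounds move, never how many.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError(f"test_fraction must be in (0,1), got {test_fraction}")
    by_class: dict[Hashable, list[str]] = {}
    for cid, lab in labels.items():
        by_class.setdefault(lab, []).append(cid)
    for lab, members in by_class.items():
        if len(members) < 2:
            raise ValidationError(f"class {lab!r} has fewer than 2 members")

    n_total = len(labels)
    n_test = math.floor(n_total * test_fraction + 0.5)

    quotas: dict[Hashable, int] = {}
    remainders: list[tuple[float, int, Hashable]] = []
    for lab, members in by_class.items():
        exact = len(members) * test_fraction
        quotas[lab] = math.floor(exact)
        remainders.append((exact - quotas[lab], len(members), lab))
    leftover = n_test - sum(quotas.values())
    # largest fractional remainder first; ties -> larger class first
    remainders.sort(key=lambda t: (-t[0], -t[1], str(t[2])))
    for _, _, lab in remainders[:leftover]:
        quotas[lab] += 1

    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for lab in sorted(by_class, key=str):
        members = by_class[lab]
        perm = rng.permutation(len(members))
        chosen = {members[i] for i in perm[: quotas[lab]]}
        test_ids += [m for m in members if m in chosen]
        train_ids += [m for m in members if m not in chosen]
    # preserve the original table order across classes
    order = {cid: i for i, cid in enumerate(labels)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return SplitResult(train_ids, test_ids, test_fraction, seed)


@dataclass
class ColumnFilterResult:
    """Columns kept/dropped by the repeated-value filter."""

    kept: list[str]
    dropped: list[str]
    modal_fraction: dict[str, float]


def filter_repeated_columns(
    matrix: DescriptorMatrix, max_repeat_fraction: float = 0.2
) -> ColumnFilterResult:
    """Drop columns whose most frequent value exceeds the repeat budget.

    A column is dropped iff modal_count / n_rows > ``max_repeat_fraction``
    (strict).  A constant column has modal fraction 1 and always drops; an
    all-distinct column has modal fraction 1/n and survives any threshold
    of at least that.
    """
    df = matrix.df
    if df.shape[0] == 0:
        raise ValidationError("empty descriptor matrix")
    n = df.shape[0]
    kept, dropped, frac = [], [], {}
    for col in df.columns:
        modal = df[col].value_counts(dropna=False).iloc[0]
        f = modal / n
        frac[col] = float(f)
        (dropped if f > max_repeat_fraction else kept).append(col)
    return ColumnFilterResult(kept, dropped, frac)


@dataclass
class Normalizer:
    """Per-feature z-score parameters fitted on the training partition."""

    mean: pd.Series
    sd: pd.Series
    fitted_on: list[str]
    ddof: int = 1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: float(v) for k, v in self.sd.items()},
            "ddof": self.ddof,
            "fitted_on": self.fitted_on,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Normalizer":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean=pd.Series(payload["mean"], dtype=float),
            sd=pd.Series(payload["sd"], dtype=float),
            fitted_on=list(payload["fitted_on"]),
            ddof=int(payload["ddof"]),
        )


def zscore_fit(train: DescriptorMatrix, ddof: int = 1) -> Normalizer:
    """Fit z-score parameters (mean, sample sd by default) on training rows.

    Zero-variance columns are an error: they must be removed first (see
    :func:`filter_repeated_columns`).
    """
    df = train.df
    sd = df.std(ddof=ddof)
    zero = sd[~(sd > 0)].index.tolist()
    if zero:
        raise ValidationError(
            f"zero-variance columns {zero[:5]}; run filter_repeated_columns first"
        )
    return Normalizer(mean=df.mean(), sd=sd, fitted_on=list(df.index), ddof=ddof)


def zscore_apply(norm: Normalizer, matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Apply train-fitted z-score parameters to any matrix (train or test)."""
    df = matrix.df
    missing = [c for c in norm.mean.index if c not in df.columns]
    if missing:
        raise ValidationError(f"matrix lacks normalised columns {missing[:5]}")
    cols = list(norm.mean.index)
    out = (df[cols] - norm.mean[cols]) / norm.sd[cols]
    return DescriptorMatrix(out)


@dataclass
class DuplicateReport:
    removed_ids: list[str]
    kept_for: dict[str, str]  # removed id -> retained id
    label_conflicts: list[str] = field(default_factory=list)


def drop_duplicate_rows(
    matrix: DescriptorMatrix,
    labels: Mapping[str, Hashable] | None = None,
) -> tuple[DescriptorMatrix, DuplicateReport]:
    """Collapse rows identical across all feature columns to the first seen.

    Exact equality on the retained descriptor columns; when duplicates carry
    conflicting labels the first is kept and the conflict is reported.
    """
    df = matrix.df
    first_of: dict[tuple, str] = {}
    removed, kept_for, conflicts = [], {}, []
    keep_mask = []
    for rid, row in zip(df.index, df.itertuples(index=False, name=None)):
        if row in first_of:
            keeper = first_of[row]
            removed.append(rid)
            kept_for[rid] = keeper
            keep_mask.append(False)
            if labels is not None and labels.get(rid) != labels.get(keeper):
                conflicts.append(
                    f"duplicate rows {keeper!r}/{rid!r} have conflicting labels; kept first"
                )
        else:
            first_of[row] = rid
            keep_mask.append(True)
    return (
        DescriptorMatrix(df.loc[keep_mask]),
        DuplicateReport(removed, kept_for, conflicts),
    )


def pearson_correlation_matrix(matrix: DescriptorMatrix) -> pd.DataFrame:
    """Pearson inter-correlation of descriptor columns (symmetric, unit diag)."""
    df = matrix.df
    if df.shape[0] < 3:
        raise ValidationError("need at least 3 rows for a correlation matrix")
    sd = df.std(ddof=1)
    constant = sd[~(sd > 0)].index.tolist()
    if constant:
        raise ValidationError(f"constant columns {constant[:5]} have undefined r")
    corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)
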