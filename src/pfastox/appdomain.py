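"""Euclidean-distance applicability domain (AD).

The AD marks the region of descriptor space where predictions interpolate
the training data and are therefore considered reliable.  Fitting: compute
each normalised training row's Euclidean distance to the training centroid;
take the subset of rows closer than the mean distance; the threshold is

    thr = d_bar + Z * sigma

where d_bar and sigma are the mean and sample standard deviation of the
inner subset's distances and Z is an empirical cutoff (default 0.5).  A
query is reliable iff its centroid distance is <= thr (boundary inclusive).

An alternative convention from the read-across literature is available as
``mode="knn"``: the per-point distance is the mean distance to the k
nearest *other* training rows, the threshold is derived from those
pairwise distances by the same inner-subset rule, and a query is judged by
the mean distance to its k nearest training rows.  The centroid rule is
the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset_io import DescriptorMatrix, ValidationError


@dataclass
class ADModel:
    centroid: np.ndarray
    d_bar: float
    sigma: float
    Z: float
    thr: float
    mode: str = "centroid"  # or "knn"
    k: int = 3
    train: np.ndarray | None = None  # kept only for knn mode

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "centroid": self.centroid.tolist(),
            "d_bar": self.d_bar,
            "sigma": self.sigma,
            "Z": self.Z,
            "thr": self.thr,
            "mode": self.mode,
            "k": self.k,
            "train": self.train.tolist() if self.train is not None else None,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ADModel":
        p = json.loads(Path(path).read_text())
        return cls(
            np.asarray(p["centroid"], dtype=float),
            p["d_bar"], p["sigma"], p["Z"], p["thr"],
            mode=p.get("mode", "centroid"), k=p.get("k", 3),
            train=(np.asarray(p["train"], dtype=float)
                   if p.get("train") is not None else None),
        )


def _as_array(X) -> np.ndarray:
    if isinstance(X, DescriptorMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _threshold(d: np.ndarray, Z: float) -> tuple[float, float, float]:
    """Inner-subset mean/sd and the resulting threshold for distances d."""
    A = d.mean()
    inner = d[d < A]
    if inner.size == 0:
        inner = d
    d_bar = float(inner.mean())
    sigma = float(inner.std(ddof=1)) if inner.size > 1 else 0.0
    return d_bar, sigma, d_bar + Z * sigma


def _knn_mean_distance(train: np.ndarray, X: np.ndarray, k: int) -> np.ndarray:
    d = np.sqrt(((X[:, None, :] - train[None, :, :]) ** 2).sum(-1))
    d.sort(axis=1)
    return d[:, :k].mean(axis=1)


def ad_fit(X_train_norm, Z: float = 0.5, mode: str = "centroid",
           k: int = 3) -> ADModel:
    """Fit the distance threshold on normalised training rows.

    The inner subset is {d_i : d_i < mean(d)} (strict); if every distance
    equals the mean (degenerate, e.g. identical rows) the full set is used.
    Sample (n-1) standard deviation; a singleton inner set has sigma 0.
    """
    X = np.atleast_2d(_as_array(X_train_norm))
    if X.shape[0] < 2:
        raise ValidationError("AD fitting needs at least 2 training rows")
    centroid = X.mean(axis=0)
    if mode == "centroid":
        d = np.sqrt(((X - centroid) ** 2).sum(axis=1))
        d_bar, sigma, thr = _threshold(d, Z)
        return ADModel(centroid=centroid, d_bar=d_bar, sigma=sigma, Z=Z,
                       thr=thr)
    if mode == "knn":
        kk = min(k, X.shape[0] - 1)
        pair = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        pair.sort(axis=1)
        d = pair[:, 1:kk + 1].mean(axis=1)  # skip self-distance 0
        d_bar, sigma, thr = _threshold(d, Z)
        return ADModel(centroid=centroid, d_bar=d_bar, sigma=sigma, Z=Z,
                       thr=thr, mode="knn", k=kk, train=X.copy())
    raise ValidationError(f"unknown AD mode {mode!r}")


def ad_check(model: ADModel, x) -> tuple[bool, float]:
    """Reliability flag and distance for one query vector."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.centroid.shape[0]:
        raise ValidationError(
            f"query has {x.shape[0]} features, AD model expects "
            f"{model.centroid.shape[0]}"
        )
    if model.mode == "knn":
        dist = float(_knn_mean_distance(model.train, x[None, :], model.k)[0])
    else:
        dist = float(np.sqrt(((x - model.centroid) ** 2).sum()))
    return dist <= model.thr, dist
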