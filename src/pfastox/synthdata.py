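"""Synthetic descriptor tables with known ground truth.

The generator emulates the statistical shape of the acute-oral-toxicity
modelling data: a two-class compound set with roughly 64/36 imbalance
(defaults 195 high / 112 low), a numeric descriptor table containing a few
class-informative features among many pure-noise ones, and LD50 values
straddling the 500 mg/kg class boundary so that threshold classification
recovers the generating labels exactly.

Informative features are class-conditionally Gaussian with a configurable
mean separation (in units of the within-class standard deviation) and
equicorrelation rho; noise features are independent standard Gaussians.
LD50 values are drawn log-uniformly — (500, 5000] mg/kg for the low class,
(5, 500] for the high class — since toxicity endpoints are log-distributed.
Placeholder structures are single-fragment perfluorocarboxylic-acid SMILES
of varying chain length; they carry no descriptor information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import (
    CompoundRecord,
    DescriptorMatrix,
    LabeledDataset,
    ToxClass,
)

import pandas as pd


@dataclass
class SyntheticSpec:
    n_high: int = 195
    n_low: int = 112
    n_informative: int = 6
    n_noise: int = 44
    class_mean_shift: float = 2.0  # units of within-class feature sd
    rho: float = 0.3  # within-class equicorrelation of informative features
    n_constant: int = 0  # decoy columns for the repeated-value filter
    n_near_constant: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if self.class_mean_shift < 0:
            raise ValueError("class_mean_shift must be >= 0")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")


def _smiles(i: int) -> str:
    # perfluorocarboxylic acid with 1..8 CF2 units; always one fragment
    return "OC(=O)" + "C(F)(F)" * (1 + i % 8) + "F"


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, list[str]]:
    """Generate a labelled dataset plus the informative-feature names.

    Deterministic under ``spec.seed``: the same spec yields byte-identical
    tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_high + spec.n_low
    labels = np.array([1] * spec.n_high + [0] * spec.n_low)

    m = spec.n_informative
    cov = (1 - spec.rho) * np.eye(m) + spec.rho * np.ones((m, m))
    chol = np.linalg.cholesky(cov)
    informative = rng.standard_normal((n, m)) @ chol.T
    informative += np.where(labels[:, None] == 1,
                            spec.class_mean_shift / 2,
                            -spec.class_mean_shift / 2)

    blocks = {f"inf_{j + 1}": informative[:, j] for j in range(m)}
    noise = rng.standard_normal((n, spec.n_noise))
    for j in range(spec.n_noise):
        blocks[f"noise_{j + 1}"] = noise[:, j]
    for j in range(spec.n_constant):
        blocks[f"const_{j + 1}"] = np.full(n, float(j))
    for j in range(spec.n_near_constant):
        col = np.full(n, 1.0)
        k = max(1, n // 10)  # 10% of rows deviate -> modal fraction ~0.9
        col[rng.choice(n, size=k, replace=False)] = rng.standard_normal(k)
        blocks[f"nearconst_{j + 1}"] = col

    ids = [f"syn_{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(blocks, index=ids)

    # log-uniform LD50 consistent with the generating class (strict >500 = low)
    ld50 = np.where(
        labels == 1,
        np.exp(rng.uniform(np.log(5.0), np.log(500.0), n)),
        np.exp(rng.uniform(np.log(500.0 + 1e-6), np.log(5000.0), n)),
    )

    records = [
        CompoundRecord(
            id=ids[i],
            smiles=_smiles(i),
            ld50=float(ld50[i]),
            tox_class=ToxClass.HIGH if labels[i] == 1 else ToxClass.LOW,
        )
        for i in range(n)
    ]
    dataset = LabeledDataset(records=records, descriptors=DescriptorMatrix(df))
    return dataset, [f"inf_{j + 1}" for j in range(m)]
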