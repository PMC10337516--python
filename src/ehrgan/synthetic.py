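"""Synthetic EHR-like fixture generators with planted, analytically known
structure.

Three generators cover the pipeline's needs: a mixed categorical/numerical
record table with class-conditional feature distributions (the shape of a
preprocessed observational cohort: a binary outcome, class imbalance,
cluster structure, a dozen-to-sixty columns after encoding), an isotropic
Gaussian mixture with a separation dial (the standard semisupervised test
bed), and an independent-Bernoulli binary table whose marginals are exact
inputs (ground truth for dimension-wise probability checks).  Everything is
seeded and bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import FeatureSchema

__all__ = [
    "SyntheticSpec",
    "default_ehr_spec",
    "generate_mixed_ehr",
    "generate_gaussian_mixture",
    "generate_bernoulli_table",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Class-first sampling plan for a mixed-type record table.

    categorical: list of (name, categories, per-class probability rows).
    numerical: list of (name, per-class means, per-class sds).
    separation scales the between-class offsets of the numerical means
    around their grand mean (1 = as given, 0 = no class signal).
    """

    n: int = 1000
    class_priors: tuple = (0.7, 0.3)
    categorical: list = field(default_factory=list)
    numerical: list = field(default_factory=list)
    separation: float = 1.0
    duplicate_fraction: float = 0.0
    correlated: bool = False  # Gaussian-copula coupling of numericals
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        for name, means, sds in self.numerical:
            if np.min(sds) <= 0:
                raise ValueError(f"numerical feature {name!r} needs positive sds")


def default_ehr_spec(n: int = 1000, seed: int = 0) -> SyntheticSpec:
    """A two-class cohort in the dimensional range of preprocessed registry
    data: 5 categoricals (2-4 levels) + 3 numericals -> d = 17 encoded
    columns, 70/30 class imbalance, moderate class signal.
    """
    cat = [
        ("sex", ["M", "F"], [[0.55, 0.45], [0.45, 0.55]]),
        ("stage", ["I", "II", "III", "IV"],
         [[0.40, 0.30, 0.20, 0.10], [0.10, 0.20, 0.30, 0.40]]),
        ("grade", ["low", "mid", "high"],
         [[0.50, 0.30, 0.20], [0.20, 0.30, 0.50]]),
        ("site", ["colon", "rectum", "other"],
         [[0.45, 0.35, 0.20], [0.40, 0.35, 0.25]]),
        ("surgery", ["yes", "no"], [[0.70, 0.30], [0.45, 0.55]]),
    ]
    num = [
        ("age", [58.0, 66.0], [9.0, 9.0]),
        ("nodes_examined", [14.0, 10.0], [4.0, 4.0]),
        ("tumor_size", [28.0, 41.0], [10.0, 10.0]),
    ]
    return SyntheticSpec(n=n, class_priors=(0.7, 0.3), categorical=cat,
                         numerical=num, seed=seed)


def generate_mixed_ehr(spec: SyntheticSpec) -> tuple[pd.DataFrame, FeatureSchema, np.ndarray]:
    """Sample a record table: draw each record's class from the priors, then
    its features independently given the class.  Returns (table, schema,
    ground-truth labels); the table's ``outcome`` column equals the truth.
    Exact duplicates of earlier rows are appended at ``duplicate_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    priors = np.asarray(spec.class_priors, dtype=np.float64)
    if np.any(priors == 0):
        warnings.warn("a class prior is 0; that class will be absent")
    n_dup = int(round(spec.duplicate_fraction * spec.n))
    n_base = spec.n - n_dup
    y = rng.choice(len(priors), size=n_base, p=priors)

    cols: dict[str, np.ndarray] = {}
    for name, cats, probs in spec.categorical:
        probs = np.asarray(probs, dtype=np.float64)
        draws = np.empty(n_base, dtype=object)
        for c in range(len(priors)):
            m = y == c
            draws[m] = rng.choice(cats, size=int(m.sum()), p=probs[c] / probs[c].sum())
        cols[name] = draws

    if spec.numerical:
        k = len(spec.numerical)
        if spec.correlated:
            rho = 0.5
            cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
            zmat = rng.multivariate_normal(np.zeros(k), cov, size=n_base)
        else:
            zmat = rng.standard_normal((n_base, k))
        for j, (name, means, sds) in enumerate(spec.numerical):
            means = np.asarray(means, dtype=np.float64)
            grand = means.mean()
            means = grand + spec.separation * (means - grand)
            sds = np.asarray(sds, dtype=np.float64)
            cols[name] = means[y] + sds[y] * zmat[:, j]

    table = pd.DataFrame(cols)
    table["outcome"] = y.astype(str)
    if n_dup > 0:
        dup_idx = rng.choice(n_base, size=n_dup, replace=True)
        table = pd.concat([table, table.iloc[dup_idx]], ignore_index=True)
        y = np.concatenate([y, y[dup_idx]])

    schema = FeatureSchema(
        columns=[(name, "categorical", list(cats)) for name, cats, _ in spec.categorical]
        + [(name, "numerical", None) for name, _, _ in spec.numerical],
        label_column="outcome",
    )
    return table, schema, y


def generate_gaussian_mixture(n: int, width: int, n_classes: int = 2,
                              separation: float = 3.0, seed: int = 0,
                              priors: Optional[tuple] = None) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian mixture: class c has its mean at ``separation`` along
    unit direction e_c, unit spherical noise.  Returns (X, y)."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    p = np.asarray(priors, dtype=np.float64) if priors is not None else np.full(n_classes, 1 / n_classes)
    y = rng.choice(n_classes, size=n, p=p / p.sum())
    means = np.zeros((n_classes, width))
    for c in range(n_classes):
        means[c, c % width] = separation
    X = means[y] + rng.standard_normal((n, width))
    return X, y


def generate_bernoulli_table(n: int, p_vector, seed: int = 0) -> np.ndarray:
    """Independent Bernoulli columns at the stated success probabilities."""
    p = np.asarray(p_vector, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p entries must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random((n, len(p))) < p[None, :]).astype(np.float64)
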