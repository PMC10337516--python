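"""Dataset schema, readers, preprocessing and label masking.

Tabular patient records (mixed categorical/numerical columns plus a class
outcome) are turned into the unit-scaled numeric matrix the rest of the
pipeline consumes: categoricals one-hot encoded, numericals min-max scaled to
[0, 1].  Label deficiency is modelled explicitly through a per-record boolean
mask; masking is stratified per class so every class keeps at least one
visible label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureSchema",
    "ProcessedDataset",
    "SplitSpec",
    "SchemaError",
    "RowError",
    "read_tabular_dataset",
    "preprocess",
    "mask_labels",
    "split_train_test",
    "write_processed",
    "read_processed",
]


class SchemaError(ValueError):
    """Schema/config-level problem (missing column, bad label rate...)."""


class RowError(ValueError):
    """Row-level data problem; carries the offending row indices."""

    def __init__(self, message: str, rows=()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class FeatureSchema:
    """Declared structure of a raw table.

    columns: ordered list of (name, kind, domain) where kind is
    'categorical' (domain = list of category strings) or 'numerical'
    (domain = optional (lo, hi) range or None).
    """

    columns: list[tuple]
    label_column: str
    id_column: Optional[str] = None

    def __post_init__(self):
        names = [c[0] for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature column names")
        if self.label_column in names:
            raise SchemaError("label column must not be among feature columns")
        for name, kind, domain in self.columns:
            if kind == "categorical":
                if domain is None or len(domain) < 2:
                    raise SchemaError(f"categorical column {name!r} needs >=2 categories")
            elif kind != "numerical":
                raise SchemaError(f"unknown column kind {kind!r} for {name!r}")

    @property
    def feature_names(self) -> list[str]:
        return [c[0] for c in self.columns]

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        raw = yaml.safe_load(Path(path).read_text())
        cols = []
        for c in raw["columns"]:
            kind = c["kind"]
            domain = c.get("categories") if kind == "categorical" else c.get("range")
            cols.append((c["name"], kind, domain))
        return cls(columns=cols, label_column=raw["label_column"], id_column=raw.get("id_column"))

    def to_yaml(self, path) -> None:
        cols = []
        for name, kind, domain in self.columns:
            entry = {"name": name, "kind": kind}
            if kind == "categorical":
                entry["categories"] = list(domain)
            elif domain is not None:
                entry["range"] = list(domain)
            cols.append(entry)
        doc = {"columns": cols, "label_column": self.label_column}
        if self.id_column:
            doc["id_column"] = self.id_column
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class ProcessedDataset:
    """Unit-scaled feature matrix with class labels and a visibility mask.

    X: (n, d) matrix with all entries in [0, 1].
    y: length-n integer class codes in {0..M-1}.
    mask: length-n booleans, True where the label is visible to a learner.
    colmap: original feature name -> (start, stop) column block in X.
    binary_cols: indices of one-hot (0/1) columns.
    """

    X: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    M: int
    colmap: dict = field(default_factory=dict)
    binary_cols: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite entries in feature matrix")
        if self.X.min(initial=0.0) < -1e-12 or self.X.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("feature matrix entries must lie in [0, 1]")
        if not (len(self.X) == len(self.y) == len(self.mask)):
            raise ValueError("X, y, mask length mismatch")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "ProcessedDataset":
        idx = np.asarray(idx)
        return replace(self, X=self.X[idx], y=self.y[idx], mask=self.mask[idx])


@dataclass(frozen=True)
class SplitSpec:
    """Experimental split configuration."""

    test_fraction: float = 0.2
    label_rate: float = 0.1
    folds: int = 10
    repeats: int = 30
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise SchemaError("test_fraction must be in (0, 1)")
        if not 0 < self.label_rate <= 1:
            raise SchemaError("label_rate must be in (0, 1]")


# ---------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------

def read_tabular_dataset(path, schema: FeatureSchema) -> pd.DataFrame:
    """Read a delimited text table and validate it against the schema.

    Returns a typed DataFrame whose feature columns are in schema order,
    followed by the label column.  Rows with values outside a declared
    categorical domain, or unparseable numerics, raise :class:`RowError`
    naming the offending rows and columns.
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    needed = schema.feature_names + [schema.label_column]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {missing}")
    if len(df) == 0:
        return df.loc[:, needed]

    out = {}
    bad_cells: list[str] = []
    bad_rows: list[int] = []
    for name, kind, domain in schema.columns:
        col = df[name].astype(str).str.strip()
        if kind == "categorical":
            allowed = set(map(str, domain))
            bad = ~col.isin(allowed)
            if bad.any():
                rows = list(np.flatnonzero(bad.to_numpy()))
                bad_rows += rows
                bad_cells.append(f"column {name!r} rows {rows}: values outside {sorted(allowed)}")
            out[name] = pd.Categorical(col, categories=[str(c) for c in domain])
        else:
            vals = pd.to_numeric(col, errors="coerce").astype(np.float64)
            bad = vals.isna()
            if bad.any():
                rows = list(np.flatnonzero(bad.to_numpy()))
                bad_rows += rows
                bad_cells.append(f"column {name!r} rows {rows}: unparseable numeric")
            out[name] = vals
    if bad_cells:
        raise RowError("invalid cells: " + "; ".join(bad_cells), rows=sorted(set(bad_rows)))
    out[schema.label_column] = df[schema.label_column].astype(str).str.strip()
    return pd.DataFrame(out)


# ---------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------

def preprocess(
    raw: pd.DataFrame,
    schema: FeatureSchema,
    dedupe: bool = False,
    label_order: Optional[list[str]] = None,
) -> ProcessedDataset:
    """One-hot encode categoricals, min-max scale numericals, drop duplicates.

    The processed width d equals the sum of the category counts plus the
    number of numerical columns.  A constant numerical column scales to 0
    (with a warning).  Deduplication compares post-encoding feature vectors
    exactly, ignoring labels.
    """
    import warnings

    if len(raw) == 0:
        raise ValueError("empty table")
    blocks = []
    colmap: dict[str, tuple[int, int]] = {}
    binary_cols: list[int] = []
    pos = 0
    for name, kind, domain in schema.columns:
        if kind == "categorical":
            cats = [str(c) for c in domain]
            codes = pd.Categorical(raw[name].astype(str), categories=cats).codes
            block = np.zeros((len(raw), len(cats)))
            block[np.arange(len(raw)), codes] = 1.0
            binary_cols.extend(range(pos, pos + len(cats)))
            colmap[name] = (pos, pos + len(cats))
            pos += len(cats)
        else:
            vals = raw[name].to_numpy(dtype=np.float64)
            lo, hi = vals.min(), vals.max()
            if hi == lo:
                warnings.warn(f"numerical column {name!r} is constant; scaled to 0")
                block = np.zeros((len(raw), 1))
            else:
                block = ((vals - lo) / (hi - lo))[:, None]
            colmap[name] = (pos, pos + 1)
            pos += 1
        blocks.append(block)
    X = np.hstack(blocks)

    labels = raw[schema.label_column].astype(str)
    classes = label_order if label_order is not None else sorted(labels.unique())
    lut = {c: i for i, c in enumerate(classes)}
    unknown = set(labels.unique()) - set(classes)
    if unknown:
        raise RowError(f"labels outside declared order: {sorted(unknown)}")
    y = labels.map(lut).to_numpy(dtype=np.int64)

    if dedupe:
        _, keep = np.unique(X.round(12), axis=0, return_index=True)
        keep = np.sort(keep)
        if len(keep) < 2:
            raise ValueError("fewer than 2 unique records after deduplication")
        X, y = X[keep], y[keep]

    return ProcessedDataset(
        X=X, y=y, mask=np.ones(len(y), dtype=bool), M=len(classes),
        colmap=colmap, binary_cols=binary_cols,
    )


def mask_labels(ds: ProcessedDataset, label_rate: float, seed: int) -> ProcessedDataset:
    """Hide labels, keeping round(label_rate * n_c) visible per class (min 1)."""
    if not 0 < label_rate <= 1:
        raise SchemaError("label_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mask = np.zeros(ds.n, dtype=bool)
    for c in range(ds.M):
        members = np.flatnonzero(ds.y == c)
        if len(members) == 0:
            continue
        n_vis = max(1, int(round(label_rate * len(members))))
        chosen = rng.choice(members, size=min(n_vis, len(members)), replace=False)
        mask[chosen] = True
    return replace(ds, mask=mask)


def split_train_test(ds: ProcessedDataset, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split; test labels are always visible.

    Returns (train_idx, test_idx) into ``ds``; use :meth:`ProcessedDataset.subset`
    to materialize either side.  Test-set sizing is per class:
    round(test_fraction * n_c), at least 1.
    """
    if ds.n < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(spec.seed)
    test_parts = []
    for c in range(ds.M):
        members = np.flatnonzero(ds.y == c)
        n_test = max(1, int(round(spec.test_fraction * len(members))))
        if n_test >= len(members):
            raise ValueError(f"class {c} would be absent from the training set")
        test_parts.append(rng.choice(members, size=n_test, replace=False))
    test_idx = np.sort(np.concatenate(test_parts))
    train_idx = np.setdiff1d(np.arange(ds.n), test_idx)
    return train_idx, test_idx


# ---------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------

def write_processed(ds: ProcessedDataset, prefix) -> None:
    """Write matrix+labels+mask as TSV and the column map as a JSON sidecar."""
    prefix = Path(prefix)
    cols = {f"x{j}": ds.X[:, j] for j in range(ds.d)}
    frame = pd.DataFrame(cols)
    frame["y"] = ds.y
    frame["mask"] = ds.mask.astype(int)
    frame.to_csv(prefix.with_suffix(".tsv"), sep="\t", index_label="index", float_format="%.17g")
    sidecar = {
        "M": ds.M,
        "colmap": {k: list(v) for k, v in ds.colmap.items()},
        "binary_cols": list(map(int, ds.binary_cols)),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_processed(prefix) -> ProcessedDataset:
    prefix = Path(prefix)
    frame = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="index")
    side = json.loads(prefix.with_suffix(".json").read_text())
    d = len([c for c in frame.columns if c.startswith("x")])
    return ProcessedDataset(
        X=frame[[f"x{j}" for j in range(d)]].to_numpy(),
        y=frame["y"].to_numpy(),
        mask=frame["mask"].to_numpy().astype(bool),
        M=int(side["M"]),
        colmap={k: tuple(v) for k, v in side["colmap"].items()},
        binary_cols=[int(j) for j in side["binary_cols"]],
    )
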