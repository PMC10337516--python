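"""Evaluation protocols: classification under label deficiency, generator
fidelity (dimension-wise probability / prediction), and the k-NN
attribute-disclosure attack, plus a harmonic label-propagation baseline and
frontier-node extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import ProcessedDataset, SplitSpec, mask_labels
from .graph import PatientGraph

__all__ = [
    "ClassificationMetrics",
    "FidelityReport",
    "DisclosureReport",
    "classification_metrics",
    "repeated_cv",
    "baseline_label_propagation",
    "dimensionwise_probability",
    "dimensionwise_prediction",
    "knn_disclosure_attack",
    "extract_frontier_nodes",
]


@dataclass
class ClassificationMetrics:
    auc: float
    accuracy: float
    recall: float
    auc_sd: float = 0.0
    accuracy_sd: float = 0.0
    recall_sd: float = 0.0
    label_rate: float = 1.0
    n_repeats: int = 1
    n_folds: int = 1
    flags: list = field(default_factory=list)


@dataclass
class FidelityReport:
    """Per-dimension real-vs-synthetic comparison.

    probabilities: list of (p_real_k, p_syn_k) Bernoulli success pairs.
    predictions: list of (f1_real_k, f1_syn_k) pairs (None until computed).
    """

    probabilities: list = field(default_factory=list)
    predictions: list = field(default_factory=list)
    mean_abs_dev: float = float("nan")
    correlation: float = float("nan")
    skipped_dims: list = field(default_factory=list)


@dataclass
class DisclosureReport:
    per_r: dict  # r -> {"precision": float, "sensitivity": float}
    compromised_fraction: float
    k_attack: int
    n_repeats: int
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------

def classification_metrics(y_true, scores, positive_class: int = 1) -> ClassificationMetrics:
    """AUC (rank statistic, midrank ties), accuracy at argmax, and recall of
    the positive class.  ``scores`` is (n, M) class probabilities or a 1-D
    positive-class score vector for binary problems.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    flags = []
    if scores.ndim == 1:
        pos_score = scores
        pred = (scores >= 0.5).astype(int)
    else:
        pos_score = scores[:, positive_class]
        pred = scores.argmax(axis=1)
    if len(np.unique(y_true)) < 2:
        flags.append("single-class truth: AUC undefined")
        auc = float("nan")
    elif scores.ndim == 2 and scores.shape[1] > 2:
        auc = roc_auc_score(y_true, scores, multi_class="ovr")
    else:
        auc = roc_auc_score((y_true == positive_class).astype(int), pos_score)
    accuracy = float(np.mean(pred == y_true))
    tp = np.sum((pred == positive_class) & (y_true == positive_class))
    fn = np.sum((pred != positive_class) & (y_true == positive_class))
    recall = float(tp / (tp + fn)) if (tp + fn) > 0 else float("nan")
    return ClassificationMetrics(auc=float(auc), accuracy=accuracy, recall=recall, flags=flags)


def repeated_cv(method, ds: ProcessedDataset, spec: SplitSpec,
                positive_class: int = 1) -> ClassificationMetrics:
    """Repeated stratified k-fold cross-validation under label masking.

    ``method`` follows a fit/score contract: ``fit(train_ds)`` trains on a
    ProcessedDataset whose mask reflects the configured label rate, and
    ``score(X)`` returns class-probability rows for a feature matrix.
    Metrics are averaged over repeats; per-repeat values are fold-pooled.
    """
    aucs, accs, recs = [], [], []
    skipped = 0
    for rep in range(spec.repeats):
        skf = StratifiedKFold(n_splits=spec.folds, shuffle=True,
                              random_state=spec.seed + rep)
        y_all, s_all = [], []
        for fold, (tr, te) in enumerate(skf.split(ds.X, ds.y)):
            if len(np.unique(ds.y[tr])) < ds.M or len(np.unique(ds.y[te])) < 2:
                skipped += 1
                warnings.warn(f"repeat {rep} fold {fold} lacks a class; skipped")
                continue
            train = mask_labels(ds.subset(tr), spec.label_rate,
                                seed=spec.seed + 1000 * rep + fold)
            method.fit(train)
            s_all.append(np.asarray(method.score(ds.X[te])))
            y_all.append(ds.y[te])
        m = classification_metrics(np.concatenate(y_all), np.vstack(s_all), positive_class)
        aucs.append(m.auc)
        accs.append(m.accuracy)
        recs.append(m.recall)
    out = ClassificationMetrics(
        auc=float(np.mean(aucs)), accuracy=float(np.mean(accs)),
        recall=float(np.nanmean(recs)),
        auc_sd=float(np.std(aucs)), accuracy_sd=float(np.std(accs)),
        recall_sd=float(np.nanstd(recs)),
        label_rate=spec.label_rate, n_repeats=spec.repeats, n_folds=spec.folds,
    )
    if skipped:
        out.flags.append(f"{skipped} folds skipped (missing class)")
    return out


# ---------------------------------------------------------------------
# label propagation baseline
# ---------------------------------------------------------------------

def baseline_label_propagation(g: PatientGraph, y, mask, tol: float = 1e-6,
                               max_iter: int = 1000) -> np.ndarray:
    """Harmonic-function propagation on the Jaccard-weighted graph.

    Labeled nodes are clamped to their one-hot label; each unlabeled node's
    score vector is iterated to the weighted mean of its neighbours'.
    Returns (n_nodes, M) probability rows aligned with sorted node ids.
    Isolated unlabeled nodes keep uniform scores (flagged with a warning).
    """
    y = np.asarray(y, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    nodes = g.nodes
    n = len(nodes)
    if len(y) != n or len(mask) != n:
        raise ValueError("labels/mask must align with sorted graph nodes")
    M = int(y.max()) + 1
    pos = {int(v): i for i, v in enumerate(nodes)}

    import scipy.sparse as sp

    rows, cols, vals = [], [], []
    for i, j, w in g.edges():
        rows += [pos[i], pos[j]]
        cols += [pos[j], pos[i]]
        vals += [w, w]
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    deg = np.asarray(W.sum(axis=1)).ravel()
    isolated = deg == 0
    if np.any(isolated & ~mask):
        warnings.warn("isolated unlabeled node(s): uniform scores assigned")

    F = np.full((n, M), 1.0 / M)
    F[mask] = 0.0
    F[mask, y[mask]] = 1.0
    clamp = F[mask].copy()
    inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-300), 0.0)
    for _ in range(max_iter):
        F_new = (W @ F) * inv_deg[:, None]
        F_new[isolated] = F[isolated]
        F_new[mask] = clamp
        delta = np.abs(F_new - F).max()
        F = F_new
        if delta < tol:
            break
    rs = F.sum(axis=1, keepdims=True)
    return F / np.where(rs > 0, rs, 1.0)


# ---------------------------------------------------------------------
# fidelity
# ---------------------------------------------------------------------

def _binarize(cols: np.ndarray) -> np.ndarray:
    return (np.asarray(cols, dtype=np.float64) > 0.5).astype(np.float64)


def dimensionwise_probability(real_features, syn_features, binary_cols) -> FidelityReport:
    """Bernoulli success probability of each binary dimension, real vs synthetic.

    The synthetic set is subsampled (or cycled) to the real sample size and
    binarized at 0.5.  Summaries: mean |p_syn - p_real| and the Pearson
    correlation of the (p_real, p_syn) pairs across dimensions.
    """
    binary_cols = list(binary_cols)
    if not binary_cols:
        raise ValueError("no binary columns to compare")
    R = np.asarray(real_features, dtype=np.float64)[:, binary_cols]
    S = np.asarray(syn_features, dtype=np.float64)[:, binary_cols]
    n = len(R)
    idx = np.arange(n) % len(S)
    S = _binarize(S[idx])
    R = _binarize(R)
    p_real = R.mean(axis=0)
    p_syn = S.mean(axis=0)
    pairs = list(zip(p_real.tolist(), p_syn.tolist()))
    dev = float(np.mean(np.abs(p_syn - p_real)))
    if np.std(p_real) > 0 and np.std(p_syn) > 0:
        corr = float(np.corrcoef(p_real, p_syn)[0, 1])
    else:
        corr = float("nan")
    return FidelityReport(probabilities=pairs, mean_abs_dev=dev, correlation=corr)


def dimensionwise_prediction(real_features, syn_features, held_out_real,
                             binary_cols, C: float = 1.0) -> FidelityReport:
    """Per-dimension F1 of classifiers trained on real vs synthetic data.

    For each binary dimension k, a logistic (L2, fixed strength) classifier
    predicting column k from the remaining columns is trained once on the
    real set and once on the (binarized) synthetic set, and both are scored
    by F1 on the held-out real records.  Dimensions constant in either
    training set are skipped and reported.
    """
    binary_cols = list(binary_cols)
    if not binary_cols:
        raise ValueError("no binary columns to compare")
    R = _binarize(np.asarray(real_features, dtype=np.float64)[:, binary_cols])
    S = _binarize(np.asarray(syn_features, dtype=np.float64)[:, binary_cols])
    H = _binarize(np.asarray(held_out_real, dtype=np.float64)[:, binary_cols])
    pairs, skipped = [], []
    for k in range(len(binary_cols)):
        rest = [j for j in range(len(binary_cols)) if j != k]
        if len(np.unique(R[:, k])) < 2 or len(np.unique(S[:, k])) < 2:
            skipped.append(binary_cols[k])
            continue
        f1 = []
        for T in (R, S):
            clf = LogisticRegression(C=C, max_iter=1000)
            clf.fit(T[:, rest], T[:, k])
            f1.append(float(f1_score(H[:, k], clf.predict(H[:, rest]), zero_division=0)))
        pairs.append((f1[0], f1[1]))
    return FidelityReport(predictions=pairs, skipped_dims=skipped)


# ---------------------------------------------------------------------
# disclosure attack
# ---------------------------------------------------------------------

def knn_disclosure_attack(real_features, syn_features, compromised_fraction: float = 0.01,
                          r_known: int = 5, k_attack: int = 1, repeats: int = 100,
                          seed: int = 0, binary_cols=None) -> DisclosureReport:
    """k-NN attribute-disclosure attack against synthetic data.

    Per repeat: a random ``compromised_fraction`` of real records and a
    random set of ``r_known`` feature indices are assumed known to the
    attacker.  Each compromised record's ``k_attack`` nearest synthetic rows
    under Hamming distance on the known features (distance ties broken by
    synthetic row index) vote on every unknown feature (vote ties -> 1).
    Precision = TP/(TP+FP) and sensitivity = TP/(TP+FN) are pooled over
    records and unknown features, then averaged over repeats.
    """
    R = np.asarray(real_features, dtype=np.float64)
    S = np.asarray(syn_features, dtype=np.float64)
    if binary_cols is not None:
        R, S = R[:, list(binary_cols)], S[:, list(binary_cols)]
    R, S = _binarize(R), _binarize(S)
    n, d = R.shape
    if not 1 <= r_known < d:
        raise ValueError(f"r_known must be in [1, {d - 1}]")
    rng = np.random.default_rng(seed)
    n_comp = max(1, int(np.ceil(compromised_fraction * n)))
    precisions, sensitivities, flags = [], [], []
    for _ in range(repeats):
        rec = rng.choice(n, size=n_comp, replace=False)
        known = np.sort(rng.choice(d, size=r_known, replace=False))
        unknown = np.setdiff1d(np.arange(d), known)
        # Hamming distances on known features, ties by synthetic row index
        dist = np.abs(R[np.ix_(rec, known)][:, None, :] - S[:, known][None, :, :]).sum(axis=2)
        order = np.argsort(dist, axis=1, kind="stable")[:, :k_attack]
        votes = S[:, unknown][order]              # (n_comp, k, |unknown|)
        est = (votes.mean(axis=1) >= 0.5).astype(np.float64)  # majority, tie -> 1
        truth = R[np.ix_(rec, unknown)]
        tp = float(np.sum((est == 1) & (truth == 1)))
        fp = float(np.sum((est == 1) & (truth == 0)))
        fn = float(np.sum((est == 0) & (truth == 1)))
        if tp + fp == 0:
            precisions.append(0.0)
            flags.append("no positive estimates: precision undefined, reported 0")
        else:
            precisions.append(tp / (tp + fp))
        sensitivities.append(tp / (tp + fn) if (tp + fn) > 0 else 0.0)
    return DisclosureReport(
        per_r={r_known: {"precision": float(np.mean(precisions)),
                         "sensitivity": float(np.mean(sensitivities))}},
        compromised_fraction=compromised_fraction, k_attack=k_attack,
        n_repeats=repeats, flags=sorted(set(flags)),
    )


def disclosure_curve(real_features, syn_features, r_values, **kwargs) -> DisclosureReport:
    """Run the attack for each r in ``r_values`` and merge the reports."""
    merged: dict = {}
    flags: list = []
    base = None
    for r in r_values:
        rep = knn_disclosure_attack(real_features, syn_features, r_known=r, **kwargs)
        merged.update(rep.per_r)
        flags += rep.flags
        base = rep
    return DisclosureReport(per_r=merged, compromised_fraction=base.compromised_fraction,
                           k_attack=base.k_attack, n_repeats=base.n_repeats,
                           flags=sorted(set(flags)))


# ---------------------------------------------------------------------
# frontier nodes
# ---------------------------------------------------------------------

def extract_frontier_nodes(g: PatientGraph, predicted_classes: dict) -> set:
    """Nodes adjacent to at least one node of a different predicted class.

    ``predicted_classes`` maps node id -> class; every graph node must be
    covered.  (Cluster-border definition; an adjacency-based reconstruction.)
    """
    missing = [v for v in g.graph.nodes() if v not in predicted_classes]
    if missing:
        raise ValueError(f"nodes without predicted class: {sorted(missing)[:5]}...")
    frontier = set()
    for u, v in g.graph.edges():
        if predicted_classes[u] != predicted_classes[v]:
            frontier.update((u, v))
    return frontier
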