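"""Weighted-graph embedding in the LINE family.

Nodes of the Jaccard patient graph are embedded into real vectors by
stochastic optimization of first- and/or second-order proximity with
negative sampling: edges are drawn with probability proportional to their
weight (alias method, O(1) per draw), and for each drawn edge the source
embedding is pulled toward the target (its context vector for second order)
and pushed away from noise nodes sampled proportionally to degree^0.75.

The default output dimension is half the processed feature dimension; the
embedded vectors are the "real sample" coordinates handed to the GAN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .graph import PatientGraph

__all__ = [
    "LineConfig",
    "EmbeddingMatrix",
    "AliasSampler",
    "alias_edge_sampler",
    "train_line",
    "GanInputs",
    "assemble_gan_inputs",
    "write_embedding",
    "read_embedding",
]


@dataclass(frozen=True)
class LineConfig:
    dim: int = 8
    order: str = "second"  # 'first' | 'second' | 'both'
    negatives: int = 5
    sample_count: Optional[int] = None  # default: chosen from edge count
    lr: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.dim < 2:
            raise ValueError("embedding dim must be >= 2")
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.order not in ("first", "second", "both"):
            raise ValueError("order must be 'first', 'second' or 'both'")


@dataclass
class EmbeddingMatrix:
    """Per-node embedding rows aligned with sorted graph node ids."""

    node_ids: np.ndarray
    vectors: np.ndarray
    objective_history: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.node_ids) != len(self.vectors):
            raise ValueError("node id / vector count mismatch")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


class AliasSampler:
    """Vose alias method: O(n) setup, O(1) draws from a discrete distribution."""

    def __init__(self, weights: np.ndarray, rng: np.random.Generator):
        w = np.asarray(weights, dtype=np.float64)
        if w.sum() <= 0:
            raise ValueError("weights must have positive sum")
        self.rng = rng
        n = len(w)
        p = w * n / w.sum()
        self.prob = np.zeros(n)
        self.alias = np.zeros(n, dtype=np.int64)
        small = [i for i in range(n) if p[i] < 1.0]
        large = [i for i in range(n) if p[i] >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            self.prob[s] = p[s]
            self.alias[s] = l
            p[l] -= 1.0 - p[s]
            (small if p[l] < 1.0 else large).append(l)
        for i in large + small:
            self.prob[i] = 1.0
        self.n = n

    def draw(self, size: int) -> np.ndarray:
        cols = self.rng.integers(0, self.n, size=size)
        toss = self.rng.random(size)
        return np.where(toss < self.prob[cols], cols, self.alias[cols])


def alias_edge_sampler(g: PatientGraph, seed: int = 0):
    """Sampler over the graph's edges with P(edge) ∝ its Jaccard weight.

    Returns (sampler, edges) where ``sampler.draw(T)`` yields indices into
    ``edges`` (the sorted (i, j, w) list).
    """
    edges = g.edges()
    weights = np.array([w for _, _, w in edges])
    return AliasSampler(weights, np.random.default_rng(seed)), edges


def _train_single_order(
    g: PatientGraph, dim: int, order: str, cfg: LineConfig, seed: int
) -> tuple[np.ndarray, list]:
    rng = np.random.default_rng(seed)
    node_ids = g.nodes
    n = len(node_ids)
    pos = {int(v): i for i, v in enumerate(node_ids)}

    edges = g.edges()
    total = cfg.sample_count
    if total is None:
        total = int(min(2_000_000, max(100_000, 300 * len(edges))))
    edge_sampler = AliasSampler(np.array([w for _, _, w in edges]), rng)
    deg = np.array([g.weighted_degree(int(v)) for v in node_ids])
    noise_sampler = AliasSampler(deg**0.75, rng)

    src = np.array([pos[i] for i, _, _ in edges], dtype=np.int64)
    dst = np.array([pos[j] for _, j, _ in edges], dtype=np.int64)

    emb = (rng.random((n, dim)) - 0.5) / dim
    ctx = np.zeros((n, dim)) if order == "second" else emb  # first order is symmetric

    batch = 256
    lr0, lr_min = cfg.lr, cfg.lr / 100.0
    done = 0
    history: list[float] = []
    run_loss, run_cnt = 0.0, 0
    while done < total:
        b = min(batch, total - done)
        e = edge_sampler.draw(b)
        # random orientation: undirected edges act in both directions
        flip = rng.random(b) < 0.5
        s = np.where(flip, dst[e], src[e])
        t = np.where(flip, src[e], dst[e])
        neg = noise_sampler.draw(b * cfg.negatives).reshape(b, cfg.negatives)

        lr = lr0 + (lr_min - lr0) * (done / total)
        u = emb[s]  # (b, dim)
        v = ctx[t]
        w = ctx[neg]  # (b, neg, dim)

        # dot products clipped to keep the sigmoid/SGD numerically tame
        pos_dot = np.clip(np.sum(u * v, axis=1), -30.0, 30.0)
        neg_dot = np.clip(np.einsum("bd,bnd->bn", u, w), -30.0, 30.0)
        pos_score = 1.0 / (1.0 + np.exp(-pos_dot))  # σ(u·v)
        neg_score = 1.0 / (1.0 + np.exp(-neg_dot))

        run_loss += float(-np.sum(np.log(np.clip(pos_score, 1e-12, None)))
                          - np.sum(np.log(np.clip(1 - neg_score, 1e-12, None))))
        run_cnt += b

        g_pos = (1.0 - pos_score)[:, None]  # d/dv of log σ(u·v) factor
        grad_u = g_pos * v - np.einsum("bn,bnd->bd", neg_score, w)
        grad_v = g_pos * u
        grad_w = -neg_score[..., None] * u[:, None, :]

        np.add.at(emb, s, lr * grad_u)
        np.add.at(ctx, t, lr * grad_v)
        np.add.at(ctx, neg, lr * grad_w)

        done += b
        if run_cnt >= 20_000 or done >= total:
            history.append(run_loss / max(run_cnt, 1))
            run_loss, run_cnt = 0.0, 0
    return emb, history


def train_line(g: PatientGraph, cfg: LineConfig) -> EmbeddingMatrix:
    """Embed the graph; deterministic given ``cfg.seed``.

    With ``order='both'`` the dimension is split between a first-order and a
    second-order model and the two embeddings are concatenated.
    """
    import warnings

    if g.n_nodes < 2 or g.n_edges < 1:
        raise ValueError("graph must have >= 2 nodes and >= 1 edge")
    if cfg.dim > 2 * g.n_nodes:
        warnings.warn("embedding dimension exceeds 2x node count (over-parameterized)")
    if cfg.order == "both":
        d1 = cfg.dim // 2
        e1, h1 = _train_single_order(g, d1, "first", cfg, cfg.seed)
        e2, h2 = _train_single_order(g, cfg.dim - d1, "second", cfg, cfg.seed + 1)
        vectors, history = np.hstack([e1, e2]), h1 + h2
    else:
        vectors, history = _train_single_order(g, cfg.dim, cfg.order, cfg, cfg.seed)
    return EmbeddingMatrix(node_ids=g.nodes, vectors=vectors, objective_history=history)


@dataclass
class GanInputs:
    """Real-sample matrix for the adversarial learner, aligned with labels.

    ``feature_dim`` > 0 means the first ``feature_dim`` columns are the
    original (unit-scaled) features — the view used for fidelity and
    disclosure evaluation of generated samples.
    """

    samples: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    index_map: np.ndarray  # row -> original record index
    feature_dim: int
    M: int


def assemble_gan_inputs(ds, emb: EmbeddingMatrix, mode: str = "concat_features") -> GanInputs:
    """Combine dataset features and node embeddings into GAN real samples.

    mode 'embedding_only': rows are embedding vectors.
    mode 'concat_features': rows are [X_i || emb_i].
    Records pruned from the graph as noise are dropped, with the surviving
    record indices recorded in ``index_map``.
    """
    if mode not in ("embedding_only", "concat_features"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = emb.node_ids
    if ids.max(initial=-1) >= ds.n:
        raise ValueError("embedding node ids exceed dataset size")
    if mode == "embedding_only":
        samples = emb.vectors.copy()
        feature_dim = 0
    else:
        samples = np.hstack([ds.X[ids], emb.vectors])
        feature_dim = ds.d
    return GanInputs(
        samples=samples, y=ds.y[ids], mask=ds.mask[ids],
        index_map=ids.copy(), feature_dim=feature_dim, M=ds.M,
    )


def write_embedding(emb: EmbeddingMatrix, path) -> None:
    with open(path, "w") as fh:
        for nid, row in zip(emb.node_ids, emb.vectors):
            fh.write(str(int(nid)) + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_embedding(path) -> EmbeddingMatrix:
    ids, rows = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split("\t")
        ids.append(int(parts[0]))
        rows.append([float(v) for v in parts[1:]])
    return EmbeddingMatrix(node_ids=np.array(ids), vectors=np.array(rows))
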