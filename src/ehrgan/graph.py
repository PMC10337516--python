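"""Conversion of a feature matrix into a Jaccard-weighted k-NN patient graph.

Records become nodes; each record is linked to the union of its k nearest
neighbours (Euclidean distance on the unit-scaled features), and every edge
weight is the Jaccard coefficient of the two endpoints' neighbour sets:

    w_ij = |N_k(i) ∩ N_k(j)| / |N_k(i) ∪ N_k(j)|

which keeps weights in [0, 1] and makes a node's weighted degree track the
local sample density.  Edges at or below a lower bound are removed and any
node left isolated is reported as noise and dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "NeighborSets",
    "PatientGraph",
    "knn_neighborhoods",
    "jaccard_weights",
    "prune_graph",
    "build_patient_graph",
    "write_edge_list",
    "read_edge_list",
]


@dataclass(frozen=True)
class NeighborSets:
    """Per-record ordered k nearest neighbour indices (self excluded)."""

    indices: np.ndarray  # (n, k) int array, row i = neighbours of record i
    k: int

    def __post_init__(self):
        if self.indices.shape[1] != self.k:
            raise ValueError("neighbour array width != k")

    @property
    def n(self) -> int:
        return len(self.indices)

    def as_sets(self) -> list[set]:
        return [set(row) for row in self.indices]


@dataclass
class PatientGraph:
    """Undirected Jaccard-weighted graph over record indices."""

    graph: nx.Graph
    noise_nodes: list = field(default_factory=list)
    n_components: int = 1

    @property
    def nodes(self) -> np.ndarray:
        return np.array(sorted(self.graph.nodes()), dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[int, int, float]]:
        """Edges as (i, j, w) with i < j, sorted."""
        out = []
        for u, v, w in self.graph.edges(data="weight"):
            i, j = (u, v) if u < v else (v, u)
            out.append((int(i), int(j), float(w)))
        return sorted(out)

    def weighted_degree(self, node: int) -> float:
        return float(self.graph.degree(node, weight="weight"))

    def weight(self, i: int, j: int) -> float:
        return float(self.graph[i][j]["weight"])


def knn_neighborhoods(X: np.ndarray, k: int, chunk: int = 2048) -> NeighborSets:
    """Exact Euclidean k nearest neighbours of every row of X.

    Deterministic: distance ties are broken by ascending record index.
    Accepts either a feature matrix or a ProcessedDataset-like object with
    an ``X`` attribute.
    """
    X = np.asarray(getattr(X, "X", X), dtype=np.float64)
    n = len(X)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    out = np.empty((n, k), dtype=np.int64)
    idx = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(X[start:stop], X)
        d[np.arange(stop - start), idx[start:stop]] = np.inf  # exclude self
        # lexsort: primary key distance, secondary ascending index
        order = np.lexsort((np.broadcast_to(idx, d.shape), d), axis=1)
        out[start:stop] = order[:, :k]
    return NeighborSets(indices=out, k=k)


def jaccard_weights(nb: NeighborSets) -> dict[tuple[int, int], float]:
    """Jaccard coefficient for every pair linked by a directed k-NN relation.

    The candidate edge set is the union of directed relations (j in N_k(i)
    or i in N_k(j)); weights may be 0 and are pruned separately.
    """
    sets = nb.as_sets()
    weights: dict[tuple[int, int], float] = {}
    for i in range(nb.n):
        for j in nb.indices[i]:
            j = int(j)
            key = (i, j) if i < j else (j, i)
            if key in weights:
                continue
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            weights[key] = inter / union if union else 0.0
    return weights


def prune_graph(
    edges: dict[tuple[int, int], float],
    lower_bound: float = 0.0,
    n_records: int | None = None,
) -> PatientGraph:
    """Drop edges with w <= lower_bound; isolated nodes become noise.

    ``n_records`` (total record count) determines which record indices are
    reported as noise; by default it is inferred from the candidate edges.
    """
    if not 0 <= lower_bound < 1:
        raise ValueError("lower_bound must be in [0, 1)")
    all_nodes: set[int] = set()
    for i, j in edges:
        all_nodes.update((i, j))
    if n_records is not None:
        all_nodes = set(range(n_records))
    g = nx.Graph()
    for (i, j), w in edges.items():
        if w > lower_bound:
            g.add_edge(int(i), int(j), weight=float(w))
    if g.number_of_nodes() == 0:
        raise ValueError("graph empty after pruning; lower k or lower_bound")
    noise = sorted(all_nodes - set(g.nodes()))
    return PatientGraph(
        graph=g, noise_nodes=noise, n_components=nx.number_connected_components(g)
    )


def build_patient_graph(X, k: int = 10, lower_bound: float = 0.0) -> PatientGraph:
    """knn_neighborhoods → jaccard_weights → prune_graph in one call."""
    nb = knn_neighborhoods(X, k=k)
    return prune_graph(jaccard_weights(nb), lower_bound=lower_bound, n_records=nb.n)


def write_edge_list(g: PatientGraph, path) -> None:
    """Tab-separated ``i  j  w`` lines with i < j, weights to 10 decimals."""
    lines = [f"{i}\t{j}\t{w:.10f}" for i, j, w in g.edges()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_edge_list(path) -> PatientGraph:
    g = nx.Graph()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed edge at line {lineno}: {line!r}")
        try:
            i, j, w = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed edge at line {lineno}: {line!r}") from exc
        g.add_edge(i, j, weight=w)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no edges")
    return PatientGraph(graph=g, noise_nodes=[], n_components=nx.number_connected_components(g))
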