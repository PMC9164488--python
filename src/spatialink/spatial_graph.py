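"""Proximity graph construction and edge splits for link prediction.

The observed cell-cell interaction graph is built from spatial coordinates:
for each cell the ``k`` nearest neighbours (default 3) within a distance
threshold are its direct contacts, and the union over cells of these
nominations forms the symmetric adjacency.  The threshold defaults to the
97.5th percentile of the per-cell 3-NN distance distribution ("auto"), which
trims the long tail of isolated cells while keeping nearly all contacts.

Edges are split 90/10 into train/test sets, with a negative test set sampled
uniformly from non-edges at a configurable ratio (default 100x the positive
test set).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import SamplingError, ValidationError

__all__ = [
    "CellGraph",
    "EdgeSplit",
    "pairwise_distance_summary",
    "build_adjacency",
    "split_edges",
    "write_edge_list",
    "read_edge_list",
]

Edge = tuple[int, int]


def _canon(i: int, j: int) -> Edge:
    if i == j:
        raise ValidationError(f"self-edge ({i},{i}) not allowed")
    return (i, j) if i < j else (j, i)


@dataclasses.dataclass
class CellGraph:
    """Symmetric binary interaction graph over ``n_cells`` cells.

    Edges are stored once as ``(i, j)`` with ``i < j``; the adjacency matrix
    is materialized on demand.
    """

    n_cells: int
    edges: set[Edge]

    def __post_init__(self) -> None:
        self.edges = {_canon(i, j) for i, j in self.edges}
        for i, j in self.edges:
            if not (0 <= i < self.n_cells and 0 <= j < self.n_cells):
                raise ValidationError(f"edge ({i},{j}) out of range")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_cells, self.n_cells))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        return A

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def non_edges_count(self) -> int:
        return self.n_cells * (self.n_cells - 1) // 2 - len(self.edges)


@dataclasses.dataclass
class EdgeSplit:
    """Train/test partition of a graph's edges plus sampled negative test edges."""

    train_pos: set[Edge]
    test_pos: set[Edge]
    test_neg: set[Edge]
    neg_ratio: float

    def __post_init__(self) -> None:
        if self.train_pos & self.test_pos:
            raise ValidationError("train/test positive sets overlap")
        if self.test_neg & (self.train_pos | self.test_pos):
            raise ValidationError("negative test edges overlap true edges")


def pairwise_distance_summary(coords: np.ndarray, k: int = 3) -> dict:
    """Distance distributions used to choose the direct-contact threshold.

    Returns the full pairwise Euclidean distance multiset (condensed, length
    n(n-1)/2) and, per cell, the distances to its ``k`` nearest neighbours.
    Duplicate coordinates yield zero distances without error.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 cells for pairwise distances")
    all_pairs = pdist(coords)
    if n < k + 1:
        raise ValidationError(f"need at least {k + 1} cells for {k}-NN distances")
    D = squareform(all_pairs)
    np.fill_diagonal(D, np.inf)
    knn = np.sort(D, axis=1)[:, :k]
    return {"all_pairs": all_pairs, "knn_distances": knn}


def auto_threshold(coords: np.ndarray, k: int = 3, percentile: float = 97.5) -> float:
    """Distance threshold from the per-cell k-NN distance distribution."""
    knn = pairwise_distance_summary(coords, k=k)["knn_distances"]
    return float(np.percentile(knn.ravel(), percentile))


def build_adjacency(
    coords: np.ndarray,
    k: int = 3,
    distance_threshold: float | str = "auto",
) -> CellGraph:
    """Build the direct-contact graph from coordinates.

    For each cell: take its ``k`` nearest neighbours (ties broken by
    ascending cell index), discard those beyond ``distance_threshold``, and
    nominate the rest as direct contacts.  The edge set is the union of the
    nominations over all cells, hence symmetric.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < k + 1:
        raise ValidationError(f"need at least {k + 1} cells for a {k}-NN graph")
    if distance_threshold == "auto":
        threshold = auto_threshold(coords, k=k)
    else:
        threshold = float(distance_threshold)
        if threshold <= 0:
            raise ValidationError("distance_threshold must be positive")
    D = squareform(pdist(coords))
    np.fill_diagonal(D, np.inf)
    edges: set[Edge] = set()
    for i in range(n):
        order = np.lexsort((np.arange(n), D[i]))[:k]
        for j in order:
            if D[i, j] <= threshold:
                edges.add(_canon(i, int(j)))
    return CellGraph(n_cells=n, edges=edges)


def _sample_non_edges(
    n_cells: int,
    forbidden: set[Edge],
    n_samples: int,
    rng: np.random.Generator,
) -> set[Edge]:
    """Uniform sample (without replacement) of unordered non-edge pairs."""
    total_pairs = n_cells * (n_cells - 1) // 2
    available = total_pairs - len(forbidden)
    if n_samples > available:
        raise SamplingError(
            f"requested {n_samples} negative edges but only {available} "
            f"non-edges exist (max feasible ratio "
            f"{available / max(1, n_samples) :.3g}x of request)"
        )
    out: set[Edge] = set()
    # Rejection sampling; dense fallback when the graph is nearly complete.
    if n_samples <= 0.5 * available:
        while len(out) < n_samples:
            batch = max(256, 2 * (n_samples - len(out)))
            ii = rng.integers(0, n_cells, size=batch)
            jj = rng.integers(0, n_cells, size=batch)
            for i, j in zip(ii, jj):
                if i == j:
                    continue
                e = _canon(int(i), int(j))
                if e in forbidden or e in out:
                    continue
                out.add(e)
                if len(out) == n_samples:
                    break
    else:
        pool = [
            (i, j)
            for i in range(n_cells)
            for j in range(i + 1, n_cells)
            if (i, j) not in forbidden
        ]
        idx = rng.choice(len(pool), size=n_samples, replace=False)
        out = {pool[i] for i in idx}
    return out


def split_edges(
    graph: CellGraph,
    test_fraction: float = 0.1,
    neg_ratio: float = 100.0,
    seed: int = 0,
) -> EdgeSplit:
    """Random train/test edge partition with negative test sampling.

    ``round(test_fraction * |edges|)`` edges (at least 1) become the positive
    test set; negatives are ``round(neg_ratio * |test_pos|)`` unordered
    non-edge pairs sampled uniformly without replacement.
    """
    if graph.n_edges < 10:
        raise ValidationError("need at least 10 edges to split")
    rng = np.random.default_rng(seed)
    edges = sorted(graph.edges)
    n_test = max(1, round(test_fraction * len(edges)))
    perm = rng.permutation(len(edges))
    test_pos = {edges[i] for i in perm[:n_test]}
    train_pos = {edges[i] for i in perm[n_test:]}
    n_neg = round(neg_ratio * len(test_pos))
    test_neg = _sample_non_edges(graph.n_cells, graph.edges, n_neg, rng)
    return EdgeSplit(
        train_pos=train_pos, test_pos=test_pos, test_neg=test_neg, neg_ratio=neg_ratio
    )


def write_edge_list(
    graph: CellGraph, path: str | Path, cell_ids: Optional[list[str]] = None
) -> None:
    """Write edges as TSV ``cell_i<TAB>cell_j`` (0-based indices).

    When ``cell_ids`` is given, an additional ``<path>.ids.tsv`` variant with
    identifier columns is emitted alongside.
    """
    path = Path(path)
    df = pd.DataFrame(sorted(graph.edges), columns=["cell_i", "cell_j"])
    df.to_csv(path, sep="\t", index=False)
    if cell_ids is not None:
        labelled = pd.DataFrame(
            [(cell_ids[i], cell_ids[j]) for i, j in sorted(graph.edges)],
            columns=["cell_i", "cell_j"],
        )
        labelled.to_csv(path.with_suffix(path.suffix + ".ids.tsv"), sep="\t", index=False)


def read_edge_list(path: str | Path, n_cells: int) -> CellGraph:
    """Read a TSV edge list (as written by :func:`write_edge_list`)."""
    df = pd.read_csv(path, sep="\t")
    edges = {_canon(int(i), int(j)) for i, j in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return CellGraph(n_cells=n_cells, edges=edges)
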