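"""Assembly of the final interaction network from decoder probabilities.

The decoder scores every cell pair; the network is assembled from the pairs
whose probability clears a threshold chosen to maximize accuracy on the
held-out test split.  Edges are then partitioned into proximal and distal by
an endpoint-distance cutoff (default: the 95th percentile of the ORIGINAL
proximity-edge length distribution — "distal" means beyond the
direct-contact regime the adjacency graph encodes).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ValidationError
from .spatial_graph import CellGraph, EdgeSplit

__all__ = [
    "ReconstructedNetwork",
    "select_threshold",
    "assemble_network",
    "classify_distal",
    "distance_probability_correlation",
    "export_network",
]


@dataclasses.dataclass
class ReconstructedNetwork:
    """Thresholded interaction network with per-edge probability and distance."""

    edges: dict[tuple[int, int], float]  # (i,j) i<j -> probability
    threshold: float
    distances: dict[tuple[int, int], float]
    distal_edges: set = dataclasses.field(default_factory=set)
    proximal_edges: set = dataclasses.field(default_factory=set)
    distal_distance_cutoff: Optional[float] = None
    degenerate_scores: bool = False  # all candidate scores identical

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _best_threshold(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Accuracy-maximizing threshold over the unique candidate scores;
    prediction rule is score >= t; ties broken toward the larger threshold."""
    if pos_scores.size == 0 or neg_scores.size == 0:
        raise ValidationError("test sets must be non-empty")
    candidates = np.unique(np.concatenate([pos_scores, neg_scores]))
    best_t, best_acc = None, -1.0
    total = pos_scores.size + neg_scores.size
    for t in candidates:  # ascending, so later ties overwrite -> larger t wins
        acc = ((pos_scores >= t).sum() + (neg_scores < t).sum()) / total
        if acc >= best_acc:
            best_acc, best_t = acc, float(t)
    return best_t


def select_threshold(
    probs: np.ndarray, split: EdgeSplit, balanced: bool = False
) -> float:
    """Probability threshold maximizing accuracy on the held-out test pairs.

    ``balanced=True`` maximizes balanced accuracy (mean of sensitivity and
    specificity) instead, which is not dominated by the 100:1 negative set.
    If every candidate score is identical, that score is returned and the
    degenerate case is left to the caller's warning flag.
    """
    pos = np.array([probs[i, j] for i, j in sorted(split.test_pos)])
    neg = np.array([probs[i, j] for i, j in sorted(split.test_neg)])
    if not balanced:
        return _best_threshold(pos, neg)
    candidates = np.unique(np.concatenate([pos, neg]))
    best_t, best_acc = None, -1.0
    for t in candidates:
        bacc = 0.5 * ((pos >= t).mean() + (neg < t).mean())
        if bacc >= best_acc:
            best_acc, best_t = bacc, float(t)
    return best_t


def assemble_network(
    probs: np.ndarray, threshold: float, coords: np.ndarray
) -> ReconstructedNetwork:
    """All unordered pairs with probability >= threshold (diagonal excluded),
    each annotated with the Euclidean distance between its endpoints."""
    n = probs.shape[0]
    coords = np.asarray(coords, dtype=float)
    iu, ju = np.triu_indices(n, 1)
    keep = probs[iu, ju] >= threshold
    edges, distances = {}, {}
    d = np.sqrt(((coords[iu[keep]] - coords[ju[keep]]) ** 2).sum(axis=1))
    for i, j, p, dist in zip(iu[keep], ju[keep], probs[iu, ju][keep], d):
        edges[(int(i), int(j))] = float(p)
        distances[(int(i), int(j))] = float(dist)
    scores = probs[iu, ju]
    return ReconstructedNetwork(
        edges=edges,
        threshold=float(threshold),
        distances=distances,
        degenerate_scores=bool(np.unique(scores).size == 1),
    )


def distal_cutoff_auto(
    original_graph: CellGraph, coords: np.ndarray, percentile: float = 95.0
) -> float:
    """Distal cutoff: percentile of the ORIGINAL proximity-edge lengths."""
    coords = np.asarray(coords, dtype=float)
    lengths = [
        float(np.linalg.norm(coords[i] - coords[j])) for i, j in original_graph.edges
    ]
    if not lengths:
        raise ValidationError("original graph has no edges")
    return float(np.percentile(lengths, percentile))


def classify_distal(
    network: ReconstructedNetwork,
    cutoff: float | str = "auto",
    original_graph: Optional[CellGraph] = None,
    coords: Optional[np.ndarray] = None,
) -> ReconstructedNetwork:
    """Partition the network's edges at the distance cutoff: edges longer
    than the cutoff are distal, the rest proximal.  ``cutoff='auto'``
    requires the original proximity graph and coordinates."""
    if not network.edges:
        raise ValidationError("cannot classify an empty network")
    if cutoff == "auto":
        if original_graph is None or coords is None:
            raise ValidationError("auto cutoff needs original_graph and coords")
        cutoff = distal_cutoff_auto(original_graph, coords)
    cutoff = float(cutoff)
    distal = {e for e, d in network.distances.items() if d > cutoff}
    network.distal_edges = distal
    network.proximal_edges = set(network.edges) - distal
    network.distal_distance_cutoff = cutoff
    return network


def distance_probability_correlation(
    probs: np.ndarray, coords: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """Spearman correlation between pairwise distance and predicted
    probability over all off-diagonal pairs, plus the per-pair table."""
    n = probs.shape[0]
    coords = np.asarray(coords, dtype=float)
    iu, ju = np.triu_indices(n, 1)
    d = np.sqrt(((coords[iu] - coords[ju]) ** 2).sum(axis=1))
    p = probs[iu, ju]
    rho = float(spearmanr(d, p).statistic)
    table = pd.DataFrame(
        {"cell_i": iu, "cell_j": ju, "distance": d, "probability": p}
    )
    return rho, table


def export_network(
    network: ReconstructedNetwork,
    path: str | Path,
    original_graph: Optional[CellGraph] = None,
) -> pd.DataFrame:
    """Write the edge table: cell_i, cell_j, probability, distance,
    is_distal, is_in_original_adjacency."""
    original = original_graph.edges if original_graph is not None else set()
    rows = [
        dict(
            cell_i=i, cell_j=j,
            probability=network.edges[(i, j)],
            distance=network.distances[(i, j)],
            is_distal=(i, j) in network.distal_edges,
            is_in_original_adjacency=(i, j) in original,
        )
        for i, j in sorted(network.edges)
    ]
    df = pd.DataFrame(
        rows, columns=["cell_i", "cell_j", "probability", "distance",
                       "is_distal", "is_in_original_adjacency"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
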