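"""Corruption models and evaluation metrics for benchmarking link recovery.

Corruptions mirror the imperfections of real spatial transcriptome data:
multiplicative log-normal fold noise on expression values, dropout of whole
genes or of individual non-zero values, random deletion of observed edges
(missing interactions), random insertion of fake edges (false interactions),
and cropping of the tissue field.  All operators are pure functions of their
inputs and a seed.

Metrics: AUROC by the Mann-Whitney pair-counting convention (ties get half
credit), which must agree with trapezoidal ROC integration; AUPRC by step
interpolation (average precision); and FPR at a score threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import SpatialExpressionDataset, crop_field
from .errors import SamplingError, ValidationError
from .spatial_graph import (CellGraph, EdgeSplit, _sample_non_edges,
                            build_adjacency, split_edges)
from . import vgae_core

__all__ = [
    "CorruptionSpec",
    "add_fold_noise",
    "apply_dropout",
    "remove_edges",
    "add_fake_edges",
    "compute_auroc",
    "compute_auroc_trapezoid",
    "compute_auprc",
    "compute_fpr_at_threshold",
    "run_benchmark",
]


@dataclasses.dataclass
class CorruptionSpec:
    """One corruption to apply before retraining: what kind, how much, seed.

    ``magnitude`` is sigma for ``gaussian_fold_noise``, a fraction for the
    dropout/removal kinds, a fold multiplier for ``edge_addition``, and the
    retained side fraction for ``crop``.
    """

    kind: str
    magnitude: float
    seed: int = 0

    _FRACTION_KINDS = ("gene_dropout", "value_dropout", "edge_removal", "crop")
    _KINDS = _FRACTION_KINDS + ("gaussian_fold_noise", "edge_addition")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValidationError(f"unknown corruption kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValidationError("corruption magnitude must be non-negative")
        if self.kind in self._FRACTION_KINDS and self.magnitude >= 1:
            raise ValidationError(f"{self.kind} magnitude must be < 1")
        if self.kind == "edge_addition" and self.magnitude > 10:
            raise ValidationError("edge_addition fold capped at 10 by default")


def add_fold_noise(X: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Multiply each entry by 2^r with r ~ N(0, sigma), independently.

    The log2 fold change of each regenerated value is therefore normally
    distributed around zero; zeros stay zero.
    """
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    X = np.asarray(X, dtype=float)
    if sigma == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X * 2.0 ** rng.normal(0.0, sigma, size=X.shape)


def apply_dropout(X: np.ndarray, kind: str, fraction: float, seed: int = 0) -> np.ndarray:
    """Zero out whole gene columns (``kind='gene'``) or a random subset of
    currently non-zero entries (``kind='value'``); exact counts
    round(fraction * pool size)."""
    if not (0 <= fraction < 1):
        raise ValidationError("fraction must be in [0, 1)")
    X = np.asarray(X, dtype=float).copy()
    rng = np.random.default_rng(seed)
    if kind == "gene":
        n_drop = round(fraction * X.shape[1])
        cols = rng.choice(X.shape[1], size=n_drop, replace=False)
        X[:, cols] = 0.0
    elif kind == "value":
        nz = np.flatnonzero(X)
        n_drop = round(fraction * nz.size)
        picked = rng.choice(nz.size, size=n_drop, replace=False)
        X.flat[nz[picked]] = 0.0
    else:
        raise ValidationError(f"unknown dropout kind {kind!r}")
    return X


def remove_edges(
    graph: CellGraph, fraction: float, seed: int = 0
) -> tuple[CellGraph, set]:
    """Discard round(fraction * |edges|) edges uniformly without replacement."""
    if not (0 <= fraction < 1):
        raise ValidationError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    edges = sorted(graph.edges)
    n_remove = round(fraction * len(edges))
    if len(edges) - n_remove < 1:
        raise ValidationError("removal would leave no training edges")
    idx = rng.choice(len(edges), size=n_remove, replace=False)
    removed = {edges[i] for i in idx}
    return CellGraph(graph.n_cells, graph.edges - removed), removed


def add_fake_edges(
    graph: CellGraph, fold: float, seed: int = 0
) -> tuple[CellGraph, set]:
    """Insert round(fold * |edges|) distinct non-edges, tracked separately."""
    if fold < 0:
        raise ValidationError("fold must be non-negative")
    rng = np.random.default_rng(seed)
    n_fake = round(fold * graph.n_edges)
    if n_fake > graph.non_edges_count():
        raise SamplingError(
            f"cannot add {n_fake} fake edges; only {graph.non_edges_count()} "
            f"non-edges available (max feasible fold "
            f"{graph.non_edges_count() / max(1, graph.n_edges):.2f})"
        )
    fakes = _sample_non_edges(graph.n_cells, graph.edges, n_fake, rng)
    return CellGraph(graph.n_cells, graph.edges | fakes), fakes


def _as_arrays(pos, neg) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(list(pos), dtype=float)
    neg = np.asarray(list(neg), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score lists must be non-empty")
    return pos, neg


def compute_auroc(scores_pos, scores_neg) -> float:
    """AUROC by pair counting: P(pos > neg) + 0.5 P(tie), via midranks."""
    pos, neg = _as_arrays(scores_pos, scores_neg)
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def compute_auroc_trapezoid(scores_pos, scores_neg) -> float:
    """AUROC by trapezoidal integration of the ROC curve (independent route)."""
    pos, neg = _as_arrays(scores_pos, scores_neg)
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(roc_auc_score(y, np.concatenate([pos, neg])))


def compute_auprc(scores_pos, scores_neg) -> float:
    """Area under the precision-recall curve by step interpolation over
    descending thresholds (average precision)."""
    pos, neg = _as_arrays(scores_pos, scores_neg)
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(average_precision_score(y, np.concatenate([pos, neg])))


def compute_fpr_at_threshold(scores_neg, threshold: float) -> float:
    """Fraction of negative scores at or above the threshold."""
    neg = np.asarray(list(scores_neg), dtype=float)
    if neg.size == 0:
        raise ValidationError("negative score list must be non-empty")
    return float(np.mean(neg >= threshold))


def _evaluate_run(
    ds: SpatialExpressionDataset,
    graph: CellGraph,
    config: vgae_core.ModelConfig,
    pos_pairs: Sequence,
    neg_pairs: Sequence,
    split=None,
    seed: int = 0,
) -> dict:
    """Train on ``graph`` (or the given split) and score pos/neg pair sets.

    The threshold is selected on the split's test sets when a split with a
    test partition is used, on the benchmark sets themselves otherwise.
    """
    if split is None:
        split = split_edges(graph, test_fraction=0.1, neg_ratio=100.0, seed=seed)
    cfg = dataclasses.replace(config, seed=seed)
    result = vgae_core.train(ds, split, cfg)
    H = result.embedding.H
    pos_scores = vgae_core.score_pairs(H, list(pos_pairs))
    neg_scores = vgae_core.score_pairs(H, list(neg_pairs))
    if split.test_pos and split.test_neg:
        thr_pos = vgae_core.score_pairs(H, sorted(split.test_pos))
        thr_neg = vgae_core.score_pairs(H, sorted(split.test_neg))
    else:
        thr_pos, thr_neg = pos_scores, neg_scores
    threshold = select_threshold_from_scores(thr_pos, thr_neg)
    return dict(
        auroc=compute_auroc(pos_scores, neg_scores),
        auprc=compute_auprc(pos_scores, neg_scores),
        fpr=compute_fpr_at_threshold(neg_scores, threshold),
        threshold=threshold,
    )


def select_threshold_from_scores(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    from .reconstruction import _best_threshold
    return _best_threshold(np.asarray(pos_scores), np.asarray(neg_scores))


def run_benchmark(
    ds: SpatialExpressionDataset,
    corruption: CorruptionSpec,
    repeats: int = 30,
    config: Optional[vgae_core.ModelConfig] = None,
    graph: Optional[CellGraph] = None,
    distance_threshold: float | str = "auto",
) -> pd.DataFrame:
    """Corrupt, retrain, and score; one row per repeat.

    The scored positive/negative sets depend on the corruption kind:
    removed-vs-nonexistent (size-matched) for ``edge_removal``, real-vs-fake
    for ``edge_addition``, and the held-out 90/10 split with 100:1 negatives
    otherwise.  Per-repeat seeds are ``corruption.seed + repeat`` for
    auditability.
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    if config is None:
        config = vgae_core.ModelConfig()
    if graph is None:
        graph = build_adjacency(ds.coordinates, distance_threshold=distance_threshold)
    rows = []
    for rep in range(repeats):
        seed = corruption.seed + rep
        rng = np.random.default_rng(seed)
        ds_run, graph_run = ds, graph
        pos_pairs = neg_pairs = None
        split = None
        if corruption.kind == "gaussian_fold_noise":
            X = add_fold_noise(ds.expression, corruption.magnitude, seed)
            ds_run = dataclasses.replace(ds, expression=X)
        elif corruption.kind in ("gene_dropout", "value_dropout"):
            kind = "gene" if corruption.kind == "gene_dropout" else "value"
            X = apply_dropout(ds.expression, kind, corruption.magnitude, seed)
            ds_run = dataclasses.replace(ds, expression=X)
        elif corruption.kind == "edge_removal":
            graph_run, removed = remove_edges(graph, corruption.magnitude, seed)
            pos_pairs = sorted(removed)
            # equal numbers of originally non-existing pairs as true negatives
            neg_pairs = sorted(
                _sample_non_edges(graph.n_cells, graph.edges, len(removed), rng)
            )
        elif corruption.kind == "edge_addition":
            graph_run, fakes = add_fake_edges(graph, corruption.magnitude, seed)
            pos_pairs = sorted(graph.edges)
            neg_pairs = sorted(fakes)
        elif corruption.kind == "crop":
            frac = corruption.magnitude if corruption.magnitude > 0 else 0.5
            x, y = ds.coordinates[:, 0], ds.coordinates[:, 1]
            wx = (x.max() - x.min()) * frac
            wy = (y.max() - y.min()) * frac
            x0 = rng.uniform(x.min(), x.max() - wx)
            y0 = rng.uniform(y.min(), y.max() - wy)
            ds_run = crop_field(ds, (x0, x0 + wx), (y0, y0 + wy))
            graph_run = build_adjacency(
                ds_run.coordinates, distance_threshold=distance_threshold
            )

        if pos_pairs is None:
            split = split_edges(graph_run, 0.1, 100.0, seed=seed)
            pos_pairs = sorted(split.test_pos)
            neg_pairs = sorted(split.test_neg)
        else:
            # Edge benchmarks train on the full corrupted graph: the scored
            # sets (removed or fake edges) are defined by the corruption
            # itself, so no test partition is carved from the training edges.
            split = EdgeSplit(
                train_pos=set(graph_run.edges), test_pos=set(), test_neg=set(),
                neg_ratio=0.0,
            )
        metrics = _evaluate_run(
            ds_run, graph_run, config, pos_pairs, neg_pairs, split=split, seed=seed
        )
        rows.append(
            dict(repeat=rep, kind=corruption.kind, magnitude=corruption.magnitude,
                 n_cells=ds_run.n_cells, **metrics)
        )
    return pd.DataFrame(rows)
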