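"""Per-gene sensitivity of the reconstructed network, and simple-classifier
benchmarks of gene panels.

The sensitivity of the model to a gene is measured by permutation
importance: shuffle that gene's expression across cells, re-score the
held-out edge sets with the frozen trained model, and record the drop in
AUPRC.  Averaged over repeats this is the gene's sensitivity score; a
full-retrain mode is available for small panels.

The classifier benchmark compares gene panels (e.g. top-ranked signature
genes vs annotated ligand/receptor genes) by how well simple models (SVC,
k-NN, gradient boosting) separate adjacent from non-adjacent cell pairs
using the concatenated expression vectors of each pair.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .data_io import SpatialExpressionDataset, preprocess_expression
from .errors import ValidationError
from .robustness import compute_auprc, compute_auroc
from .spatial_graph import CellGraph, EdgeSplit, _sample_non_edges
from . import vgae_core

__all__ = [
    "SensitivityTable",
    "shuffle_gene",
    "sensitivity_scores",
    "baseline_classifier_benchmark",
]


@dataclasses.dataclass
class SensitivityTable:
    """Mean/sd ΔAUPRC per gene, ranked by descending mean (rank 1 = most
    sensitive)."""

    table: pd.DataFrame
    n_repeats: int

    def ranked_list(self) -> pd.DataFrame:
        """Export-ready ranked list (gene_name, score, rank)."""
        return self.table.sort_values("rank")[
            ["gene_name", "mean_delta_auprc", "rank"]
        ].rename(columns={"mean_delta_auprc": "score"})


def shuffle_gene(X: np.ndarray, gene_index: int, seed: int = 0) -> np.ndarray:
    """Permute one gene's expression values uniformly across cells."""
    X = np.asarray(X, dtype=float)
    if not (0 <= gene_index < X.shape[1]):
        raise ValidationError(f"gene index {gene_index} out of range")
    rng = np.random.default_rng(seed)
    out = X.copy()
    out[:, gene_index] = out[rng.permutation(X.shape[0]), gene_index]
    return out


def _frozen_model_auprc(
    X: np.ndarray,
    A_norm: np.ndarray,
    params: vgae_core.ModelParameters,
    pos_pairs: list,
    neg_pairs: list,
    scaling: str,
) -> float:
    emb = vgae_core.encode(preprocess_expression(X, scaling), A_norm, params,
                           mode="eval")
    pos = vgae_core.score_pairs(emb.H, pos_pairs)
    neg = vgae_core.score_pairs(emb.H, neg_pairs)
    return compute_auprc(pos, neg)


def sensitivity_scores(
    ds: SpatialExpressionDataset,
    split: EdgeSplit,
    model: vgae_core.TrainResult,
    repeats: int = 30,
    seed: int = 0,
    mode: str = "rescore",
    gene_subset: Optional[Sequence[int]] = None,
) -> SensitivityTable:
    """Permutation-importance sensitivity score for each gene.

    For each gene and repeat, the gene's column is shuffled and ΔAUPRC =
    AUPRC(original) - AUPRC(shuffled) is computed on the held-out test edge
    sets.  ``mode='rescore'`` (default) re-runs only the frozen model's
    forward pass; ``mode='retrain'`` retrains per shuffle and is intended
    for small gene panels only.
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    if mode not in ("rescore", "retrain"):
        raise ValidationError(f"unknown mode {mode!r}")
    genes = list(gene_subset) if gene_subset is not None else list(range(ds.n_genes))
    n = ds.n_cells
    A_target = np.zeros((n, n))
    for i, j in split.train_pos:
        A_target[i, j] = A_target[j, i] = 1.0
    A_norm = vgae_core.normalize_adjacency(A_target)
    pos_pairs = sorted(split.test_pos)
    neg_pairs = sorted(split.test_neg)
    scaling = model.config.feature_scaling

    baseline = _frozen_model_auprc(
        ds.expression, A_norm, model.params, pos_pairs, neg_pairs, scaling
    )

    rows = []
    for rank_seed, g in enumerate(genes):
        deltas = np.empty(repeats)
        for rep in range(repeats):
            shuf_seed = seed + 10_000 * rank_seed + rep
            X_shuf = shuffle_gene(ds.expression, g, seed=shuf_seed)
            if mode == "rescore":
                auprc = _frozen_model_auprc(
                    X_shuf, A_norm, model.params, pos_pairs, neg_pairs, scaling
                )
            else:
                ds_shuf = dataclasses.replace(ds, expression=X_shuf)
                cfg = dataclasses.replace(model.config, seed=shuf_seed)
                res = vgae_core.train(ds_shuf, split, cfg)
                pos = vgae_core.score_pairs(res.embedding.H, pos_pairs)
                neg = vgae_core.score_pairs(res.embedding.H, neg_pairs)
                auprc = compute_auprc(pos, neg)
            deltas[rep] = baseline - auprc
        rows.append(
            dict(gene_index=g, gene_name=ds.gene_names[g],
                 mean_delta_auprc=deltas.mean(), sd_delta_auprc=deltas.std(ddof=0))
        )
    table = pd.DataFrame(rows)
    order = np.lexsort((table["gene_index"], -table["mean_delta_auprc"]))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    table["n_repeats"] = repeats
    return SensitivityTable(table=table, n_repeats=repeats)


def _pair_features(X: np.ndarray, pairs: Sequence, gene_set: Sequence[int]):
    """Concatenated expression of both cells, in both orders (undirected)."""
    sub = X[:, list(gene_set)]
    feats = []
    for i, j in pairs:
        feats.append(np.concatenate([sub[i], sub[j]]))
        feats.append(np.concatenate([sub[j], sub[i]]))
    return np.asarray(feats)


_MODELS = {
    "svc": lambda seed: SVC(random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(),
    "gbdt": lambda seed: GradientBoostingClassifier(random_state=seed),
}


def baseline_classifier_benchmark(
    ds: SpatialExpressionDataset,
    graph: CellGraph,
    gene_set_a: Sequence[int],
    gene_set_b: Sequence[int],
    models: Sequence[str] = ("svc", "knn", "gbdt"),
    repeats: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjacent vs non-adjacent pair classification from gene-panel features.

    Positives are the observed adjacency edges; negatives are equally many
    random non-adjacent pairs.  Per repeat: a fresh 4:1 train/test split,
    each classifier fit on the concatenated pair features (both orderings of
    each pair included, to respect undirectedness), test AUROC recorded.
    Returns the per-repeat AUROC table and a per-model t-test comparison of
    the two gene sets across repeats.
    """
    if not len(gene_set_a) or not len(gene_set_b):
        raise ValidationError("gene sets must be non-empty")
    unknown = set(models) - set(_MODELS)
    if unknown:
        raise ValidationError(f"unknown models {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    pos = sorted(graph.edges)
    X = ds.expression
    rows = []
    for rep in range(repeats):
        neg = sorted(_sample_non_edges(graph.n_cells, graph.edges, len(pos), rng))
        pairs = pos + neg
        y_pair = np.array([1] * len(pos) + [0] * len(neg))
        perm = rng.permutation(len(pairs))
        n_test = max(1, len(pairs) // 5)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        if len(np.unique(y_pair[train_idx])) < 2 or len(np.unique(y_pair[test_idx])) < 2:
            rows.append(dict(repeat=rep, skipped=True))
            continue
        for set_name, gene_set in (("set_a", gene_set_a), ("set_b", gene_set_b)):
            feats = _pair_features(X, pairs, gene_set)
            y = np.repeat(y_pair, 2)
            tr = np.concatenate([2 * train_idx, 2 * train_idx + 1])
            te = 2 * test_idx  # score each test pair once (first ordering)
            for model_name in models:
                clf = _MODELS[model_name](seed + rep)
                clf.fit(feats[tr], y[tr])
                if hasattr(clf, "decision_function"):
                    s = clf.decision_function(feats[te])
                else:
                    s = clf.predict_proba(feats[te])[:, 1]
                y_te = y_pair[test_idx]
                auroc = compute_auroc(s[y_te == 1], s[y_te == 0])
                rows.append(dict(repeat=rep, model=model_name, gene_set=set_name,
                                 auroc=auroc, skipped=False))
    table = pd.DataFrame(rows)
    usable = table[~table.get("skipped", False).astype(bool)]
    comparisons = []
    for model_name in models:
        a = usable.query("model == @model_name and gene_set == 'set_a'")["auroc"]
        b = usable.query("model == @model_name and gene_set == 'set_b'")["auroc"]
        t, p = ttest_ind(a, b)
        comparisons.append(dict(model=model_name, mean_a=a.mean(), mean_b=b.mean(),
                                t_statistic=float(t), p_value=float(p)))
    return table, pd.DataFrame(comparisons)
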