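"""Spatial domains from the latent embedding, and domain marker genes.

Cells are clustered by k-means on the latent vectors (a model trained with a
10-dimensional latent space is the intended input for this workflow); the
number of clusters is chosen by the Calinski-Harabasz score over a candidate
range.  Domain-specific marker genes are those significantly upregulated in
one domain against the pooled rest AND against every other domain
individually (one-sided Mann-Whitney U tests), within an optional cell-type
filter.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .data_io import SpatialExpressionDataset
from .errors import ValidationError

__all__ = [
    "DomainAssignment",
    "DomainDEResult",
    "cluster_latent",
    "domain_marker_genes",
    "spatial_coherence_test",
]


@dataclasses.dataclass
class DomainAssignment:
    """Cluster id per cell, the chosen k, and the model-selection trace."""

    cluster_id: np.ndarray
    k: int
    ch_scores: dict[int, float]
    latent_dim_used: int
    skipped_k: list[int] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class DomainDEResult:
    """Per (domain, gene) marker statistics."""

    table: pd.DataFrame
    alpha: float
    excluded_domains: list[int] = dataclasses.field(default_factory=list)


def cluster_latent(
    H: np.ndarray,
    k_range: tuple[int, int] = (2, 12),
    latent_dim: int = 10,
    seed: int = 0,
    n_restarts: int = 20,
    fixed_k: Optional[int] = None,
) -> DomainAssignment:
    """K-means over the first ``latent_dim`` latent dimensions, choosing k by
    the Calinski-Harabasz score over ``k_range`` (closed interval) unless
    ``fixed_k`` is given.  20 seeded restarts per k, best inertia kept."""
    H = np.asarray(H, dtype=float)
    if latent_dim > H.shape[1]:
        raise ValidationError(
            f"latent_dim {latent_dim} exceeds embedding width {H.shape[1]}"
        )
    Z = H[:, :latent_dim]
    n_distinct = np.unique(Z, axis=0).shape[0]
    if n_distinct < 2:
        raise ValidationError("all latent points identical; no valid clustering")
    lo, hi = k_range
    if lo < 2 or hi >= Z.shape[0]:
        raise ValidationError("k_range must lie within [2, n_cells - 1]")

    candidates = [fixed_k] if fixed_k is not None else list(range(lo, hi + 1))
    ch_scores: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    skipped = []
    for k in candidates:
        if k > n_distinct:
            skipped.append(k)
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(Z)
        if len(np.unique(labels)) < 2:
            skipped.append(k)
            continue
        ch_scores[k] = float(calinski_harabasz_score(Z, labels))
        labels_by_k[k] = labels
    if not ch_scores:
        raise ValidationError("no candidate k produced a valid clustering")
    best_k = fixed_k if fixed_k is not None else max(ch_scores, key=ch_scores.get)
    return DomainAssignment(
        cluster_id=labels_by_k[best_k], k=best_k, ch_scores=ch_scores,
        latent_dim_used=latent_dim, skipped_k=skipped,
    )


def _mwu_greater(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided (greater) Mann-Whitney U p-value; degenerate all-tied input
    returns 1 by convention."""
    if np.unique(np.concatenate([a, b])).size < 2:
        return 1.0
    return float(mannwhitneyu(a, b, alternative="greater", method="asymptotic").pvalue)


def domain_marker_genes(
    ds: SpatialExpressionDataset,
    assignment: DomainAssignment,
    cell_type_filter: Optional[str] = None,
    alpha: float = 0.01,
    min_cells: int = 3,
) -> DomainDEResult:
    """Domain-specific upregulated genes.

    For each (domain, gene): one-sided Mann-Whitney U of the domain's cells
    against the pooled rest, and against each other domain individually.  A
    gene is domain-specific iff p < alpha in the one-vs-rest test and in ALL
    one-vs-one tests.  Also reports the median per-gene z-score (z computed
    gene-wise across the filtered cells; constant genes get z = 0).
    """
    labels = np.asarray(assignment.cluster_id)
    mask = np.ones(ds.n_cells, dtype=bool)
    if cell_type_filter is not None:
        if ds.cell_types is None:
            raise ValidationError("dataset has no cell types to filter on")
        mask = np.array([t == cell_type_filter for t in ds.cell_types])
    X = ds.expression[mask]
    labels = labels[mask]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd_safe

    domains = sorted(np.unique(labels))
    sizes = {d: int((labels == d).sum()) for d in domains}
    excluded = [d for d in domains if sizes[d] < min_cells]
    tested = [d for d in domains if d not in excluded]
    if len(tested) < 2:
        raise ValidationError("fewer than 2 domains with enough cells")

    rows = []
    for d in tested:
        in_d = labels == d
        rest = np.isin(labels, [o for o in tested if o != d])
        for g in range(ds.n_genes):
            p_ovr = _mwu_greater(X[in_d, g], X[rest, g])
            p_ovo = [
                _mwu_greater(X[in_d, g], X[labels == o, g])
                for o in tested if o != d
            ]
            p_ovo_max = max(p_ovo)
            rows.append(
                dict(
                    domain=d, gene=ds.gene_names[g],
                    median_z=float(np.median(Z[in_d, g])),
                    p_one_vs_rest=p_ovr, p_one_vs_one_max=p_ovo_max,
                    is_domain_specific=bool(p_ovr < alpha and p_ovo_max < alpha),
                )
            )
    return DomainDEResult(table=pd.DataFrame(rows), alpha=alpha,
                          excluded_domains=excluded)


def spatial_coherence_test(
    assignment: DomainAssignment,
    coords: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
) -> dict:
    """Are clusters more spatially contiguous than a random partition?

    Statistic: mean within-cluster pairwise distance.  The null permutes
    cluster labels over cells; p is the add-one fraction of permutations
    with a statistic as small or smaller than observed.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(assignment.cluster_id)
    rng = np.random.default_rng(seed)

    def stat(lab: np.ndarray) -> float:
        vals = []
        for d in np.unique(lab):
            pts = coords[lab == d]
            if len(pts) < 2:
                continue
            diff = pts[:, None, :] - pts[None, :, :]
            dm = np.sqrt((diff**2).sum(-1))
            vals.append(dm[np.triu_indices(len(pts), 1)].mean())
        return float(np.mean(vals))

    observed = stat(labels)
    null = np.array(
        [stat(rng.permutation(labels)) for _ in range(n_permutations)]
    )
    p = (1 + int((null <= observed).sum())) / (n_permutations + 1)
    return dict(observed=observed, null_mean=float(null.mean()), p_value=p)
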