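"""Permutation tests for cell-type interaction enrichment.

Whether two cell types interact more (or less) often than chance is judged
against a null ensemble of randomly re-drawn networks with the same node
set, type labels, and edge count.  Per unordered type pair, the one-tailed
add-one p-value counts how often the null count is as or more extreme than
the observed count (smaller tail), and the two-tailed p doubles it.  A
variant restricts the null to distal cell pairs for testing the distal part
of a reconstructed network, and a per-cell diagnostic compares the cell's
edge distances with those of randomly re-chosen partners.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SamplingError, ValidationError

__all__ = [
    "EnrichmentTable",
    "count_type_interactions",
    "permutation_test",
    "distal_permutation_test",
    "edge_distance_null",
]

Edge = tuple[int, int]


@dataclasses.dataclass
class EnrichmentTable:
    """Per-type-pair enrichment statistics plus run metadata."""

    table: pd.DataFrame
    n_permutations: int
    warnings: list[str] = dataclasses.field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _type_pair_key(ta: str, tb: str) -> tuple[str, str]:
    return (ta, tb) if ta <= tb else (tb, ta)


def count_type_interactions(
    edges: Sequence[Edge], cell_types: Sequence[str]
) -> dict[tuple[str, str], int]:
    """Count edges per unordered cell-type pair; every edge lands in exactly
    one bucket, so the counts sum to |edges|."""
    counts: dict[tuple[str, str], int] = {}
    for ta, tb in itertools.combinations_with_replacement(sorted(set(cell_types)), 2):
        counts[_type_pair_key(ta, tb)] = 0
    for i, j in edges:
        key = _type_pair_key(cell_types[i], cell_types[j])
        counts[key] += 1
    return counts


def _connectivity(
    counts: dict, cell_types: Sequence[str]
) -> dict[tuple[str, str], float]:
    """Edges between two types divided by the number of possible pairs:
    n_a * n_b across types, C(n_a, 2) within a type."""
    sizes = pd.Series(list(cell_types)).value_counts().to_dict()
    out = {}
    for (ta, tb), c in counts.items():
        if ta == tb:
            possible = sizes[ta] * (sizes[ta] - 1) / 2
        else:
            possible = sizes[ta] * sizes[tb]
        out[(ta, tb)] = c / possible if possible > 0 else np.nan
    return out


def _null_counts_table(
    null_edge_sampler,
    cell_types: Sequence[str],
    n_permutations: int,
    keys: list[tuple[str, str]],
) -> np.ndarray:
    key_index = {k: idx for idx, k in enumerate(keys)}
    null = np.zeros((n_permutations, len(keys)), dtype=int)
    for p in range(n_permutations):
        counts = count_type_interactions(null_edge_sampler(), cell_types)
        for k, c in counts.items():
            null[p, key_index[k]] = c
    return null


def _assemble_table(
    observed: dict,
    null: np.ndarray,
    keys: list,
    cell_types: Sequence[str],
    n_permutations: int,
) -> pd.DataFrame:
    conn = _connectivity(observed, cell_types)
    rows = []
    for idx, key in enumerate(keys):
        obs = observed[key]
        nulls = null[:, idx]
        ge = int((nulls >= obs).sum())
        le = int((nulls <= obs).sum())
        p_one = (1 + min(ge, le)) / (n_permutations + 1)
        p_two = min(1.0, 2.0 * p_one)
        null_mean = float(nulls.mean())
        if obs > null_mean:
            direction = "enriched"
        elif obs < null_mean:
            direction = "depleted"
        else:
            direction = "neutral"
        sign = {"enriched": 1.0, "depleted": -1.0, "neutral": 0.0}[direction]
        rows.append(
            dict(
                type_a=key[0], type_b=key[1], observed_count=obs,
                connectivity=conn[key], null_mean=null_mean,
                null_sd=float(nulls.std(ddof=0)), p_two_tail=p_two,
                direction=direction,
                signed_log10_p=sign * -np.log10(p_two),
            )
        )
    return pd.DataFrame(rows)


def _sample_edges_uniform(
    n_cells: int, n_edges: int, rng: np.random.Generator
) -> list[Edge]:
    """Uniform draw of n_edges distinct unordered pairs among all cells."""
    total = n_cells * (n_cells - 1) // 2
    if n_edges > total:
        raise SamplingError("more edges requested than pairs exist")
    flat = rng.choice(total, size=n_edges, replace=False)
    # Decode linear index of the upper triangle.
    i = (n_cells - 2 - np.floor(
        np.sqrt(-8 * flat + 4 * n_cells * (n_cells - 1) - 7) / 2.0 - 0.5
    )).astype(int)
    j = (flat + i + 1 - i * (2 * n_cells - i - 1) // 2).astype(int)
    return list(zip(i.tolist(), j.tolist()))


def _degree_preserving_rewire(
    edges: list[Edge], n_swaps: int, rng: np.random.Generator
) -> list[Edge]:
    """Double-edge-swap rewiring preserving the degree sequence."""
    edges = list(edges)
    edge_set = set(edges)
    m = len(edges)
    attempts = 0
    swaps = 0
    while swaps < n_swaps and attempts < 50 * n_swaps:
        attempts += 1
        a, b = rng.integers(0, m, size=2)
        (u, v), (x, y) = edges[a], edges[b]
        if len({u, v, x, y}) < 4:
            continue
        e1 = (min(u, x), max(u, x))
        e2 = (min(v, y), max(v, y))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set -= {edges[a], edges[b]}
        edge_set |= {e1, e2}
        edges[a], edges[b] = e1, e2
        swaps += 1
    return edges


def permutation_test(
    edges: Sequence[Edge],
    cell_types: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
    null_model: str = "uniform",
) -> EnrichmentTable:
    """Two-tailed permutation test of type-pair interaction counts.

    The null re-draws the same number of edges uniformly among all cell
    pairs (default), or rewires the observed network preserving degrees
    (``null_model='degree_preserving'``).  Node set, type labels and edge
    count are preserved exactly in either case.
    """
    if len(set(cell_types)) < 2:
        raise ValidationError("need at least 2 cell types")
    warnings = []
    if n_permutations < 100:
        warnings.append(
            f"n_permutations={n_permutations} < 100; p-values are coarse"
        )
    rng = np.random.default_rng(seed)
    n_cells = len(cell_types)
    edges = [(min(i, j), max(i, j)) for i, j in edges]
    observed = count_type_interactions(edges, cell_types)
    keys = sorted(observed)

    if null_model == "uniform":
        sampler = lambda: _sample_edges_uniform(n_cells, len(edges), rng)
    elif null_model == "degree_preserving":
        sampler = lambda: _degree_preserving_rewire(edges, 10 * len(edges), rng)
    else:
        raise ValidationError(f"unknown null_model {null_model!r}")

    null = _null_counts_table(sampler, cell_types, n_permutations, keys)
    table = _assemble_table(observed, null, keys, cell_types, n_permutations)
    return EnrichmentTable(table=table, n_permutations=n_permutations,
                           warnings=warnings)


def distal_permutation_test(
    distal_edges: Sequence[Edge],
    coords: np.ndarray,
    distal_cutoff: float,
    cell_types: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentTable:
    """Enrichment of distal interactions per type pair.

    The null draws |distal_edges| pairs uniformly from the set of cell pairs
    whose endpoint distance exceeds ``distal_cutoff``.
    """
    distal_edges = [(min(i, j), max(i, j)) for i, j in distal_edges]
    if not distal_edges:
        raise ValidationError("no distal edges to test")
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, 1)
    d = np.sqrt(((coords[iu] - coords[ju]) ** 2).sum(axis=1))
    candidates = np.flatnonzero(d > distal_cutoff)
    if candidates.size < len(distal_edges):
        raise SamplingError(
            f"only {candidates.size} distal candidate pairs for "
            f"{len(distal_edges)} edges"
        )
    rng = np.random.default_rng(seed)

    def sampler() -> list[Edge]:
        picked = rng.choice(candidates, size=len(distal_edges), replace=False)
        return list(zip(iu[picked].tolist(), ju[picked].tolist()))

    observed = count_type_interactions(distal_edges, cell_types)
    keys = sorted(observed)
    null = _null_counts_table(sampler, cell_types, n_permutations, keys)
    table = _assemble_table(observed, null, keys, cell_types, n_permutations)
    return EnrichmentTable(table=table, n_permutations=n_permutations)


def edge_distance_null(
    cell: int,
    edges: Sequence[Edge],
    coords: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict:
    """Observed edge distances of one cell vs distances to randomly re-chosen
    partners (degree preserved per shuffle), with a one-sided rank p-value
    for the observed mean distance being SHORTER than the null."""
    coords = np.asarray(coords, dtype=float)
    partners = [j if i == cell else i for i, j in edges if cell in (i, j)]
    if not partners:
        raise ValidationError(f"cell {cell} has no edges")
    observed = np.sqrt(((coords[partners] - coords[cell]) ** 2).sum(axis=1))
    rng = np.random.default_rng(seed)
    others = np.array([c for c in range(coords.shape[0]) if c != cell])
    k = len(partners)
    null = np.empty((n_shuffles, k))
    for s in range(n_shuffles):
        pick = rng.choice(others, size=k, replace=False)
        null[s] = np.sqrt(((coords[pick] - coords[cell]) ** 2).sum(axis=1))
    obs_mean = observed.mean()
    null_means = null.mean(axis=1)
    p = (1 + int((null_means <= obs_mean).sum())) / (n_shuffles + 1)
    return dict(observed=observed, null=null.ravel(), p_shorter=p)
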