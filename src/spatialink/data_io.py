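"""Reading, writing and simulation of single-cell spatial transcriptome data.

The central container is :class:`SpatialExpressionDataset`: a cells x genes
expression matrix together with 2-D cell coordinates and optional per-cell
type annotations.  Loaders accept dense CSV/TSV (first row gene names, first
column cell identifiers) and MatrixMarket coordinate triplets with companion
row/column name files.  Coordinate and annotation tables are aligned to the
expression rows by shared cell identifiers when all files carry them, by
position otherwise.

:func:`simulate_tissue` generates synthetic tissue with known ground truth:
a planar point pattern of cells, a small number of cell types, and expression
profiles in which a subset of "informative" genes varies smoothly in space
and with cell type, so that cells joined by a proximity edge have correlated
profiles and expression statistically encodes the interaction graph.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import AlignmentError, EmptyResultError, ValidationError

__all__ = [
    "SpatialExpressionDataset",
    "SyntheticTruth",
    "load_dataset",
    "write_dataset",
    "crop_field",
    "simulate_tissue",
]


@dataclasses.dataclass
class SpatialExpressionDataset:
    """Expression matrix with spatial coordinates and optional cell types.

    Attributes
    ----------
    expression : (n_cells, n_genes) ndarray
        Non-negative, finite expression values.
    coordinates : (n_cells, 2) ndarray
        Finite 2-D positions, in the length units of the source dataset.
    gene_names : list of str
        Unique gene identifiers, one per column.
    cell_ids : list of str
        One identifier per cell (synthesized as ``cell_0..`` if absent).
    cell_types : list of str, optional
        Categorical label per cell.
    """

    expression: np.ndarray
    coordinates: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    cell_types: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def validate(self) -> None:
        if self.expression.ndim != 2:
            raise ValidationError("expression must be a 2-D matrix")
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValidationError("coordinates must be an (n_cells, 2) matrix")
        if not np.all(np.isfinite(self.expression)):
            i, j = np.argwhere(~np.isfinite(self.expression))[0]
            raise ValidationError(f"non-finite expression at cell {i}, gene {j}")
        if np.any(self.expression < 0):
            i, j = np.argwhere(self.expression < 0)[0]
            raise ValidationError(f"negative expression at cell {i}, gene {j}")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("non-finite coordinates")
        n = self.expression.shape[0]
        if self.coordinates.shape[0] != n:
            raise AlignmentError(
                f"coordinates have {self.coordinates.shape[0]} rows, expression has {n}"
            )
        if len(self.cell_ids) != n:
            raise AlignmentError("cell_ids length does not match expression rows")
        if len(self.gene_names) != self.expression.shape[1]:
            raise AlignmentError("gene_names length does not match expression columns")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValidationError("gene_names are not unique")
        if self.cell_types is not None and len(self.cell_types) != n:
            raise AlignmentError("cell_types length does not match expression rows")

    def subset_cells(self, indices: np.ndarray) -> "SpatialExpressionDataset":
        """Return a copy restricted to the given cell indices (order kept)."""
        indices = np.asarray(indices, dtype=int)
        return SpatialExpressionDataset(
            expression=self.expression[indices].copy(),
            coordinates=self.coordinates[indices].copy(),
            gene_names=list(self.gene_names),
            cell_ids=[self.cell_ids[i] for i in indices],
            cell_types=None
            if self.cell_types is None
            else [self.cell_types[i] for i in indices],
        )


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of a simulated tissue: planted edges, informative genes,
    and the full generator parameter record (including the seed)."""

    true_edges: set[tuple[int, int]]
    informative_gene_indices: list[int]
    generator_params: dict

    def __post_init__(self) -> None:
        for i, j in self.true_edges:
            if i == j:
                raise ValidationError(f"self-pair ({i},{i}) in true_edges")


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0)


def _read_expression(path: Path, fmt: str) -> pd.DataFrame:
    if fmt in ("dense_csv", "dense_tsv"):
        sep = "," if fmt == "dense_csv" else "\t"
        return _read_table(path, sep)
    if fmt == "mtx_triplet":
        mat = scipy.io.mmread(str(path))
        mat = scipy.sparse.coo_matrix(mat).toarray()
        rows_file = path.with_suffix(".rows.txt")
        cols_file = path.with_suffix(".cols.txt")
        if not rows_file.exists() or not cols_file.exists():
            raise AlignmentError(
                f"MTX companions {rows_file.name}/{cols_file.name} not found"
            )
        cell_ids = rows_file.read_text().split()
        gene_names = cols_file.read_text().split()
        if len(cell_ids) != mat.shape[0] or len(gene_names) != mat.shape[1]:
            raise AlignmentError(
                f"MTX companion name files disagree with matrix shape {mat.shape} "
                f"({path.name})"
            )
        return pd.DataFrame(mat, index=cell_ids, columns=gene_names)
    raise ValueError(f"unknown format {fmt!r}")


def load_dataset(
    expression_path: str | Path,
    coordinates_path: str | Path,
    annotation_path: Optional[str | Path] = None,
    format: str = "dense_csv",
) -> SpatialExpressionDataset:
    """Load an expression matrix, coordinates, and optional annotations.

    Row order of the coordinate/annotation tables is aligned to the
    expression rows by cell identifier when every file carries identifiers
    shared with the expression index, by position otherwise.

    Raises
    ------
    AlignmentError
        On dimension mismatch or unmatched cell identifiers, naming the
        offending file.
    ValidationError
        On negative or non-finite expression values.
    """
    expression_path = Path(expression_path)
    coordinates_path = Path(coordinates_path)
    expr = _read_expression(expression_path, format)
    sep = "\t" if str(coordinates_path).endswith((".tsv", ".txt")) else ","
    coords = _read_table(coordinates_path, sep)
    if coords.shape[1] != 2:
        raise AlignmentError(
            f"{coordinates_path.name}: expected columns cell_id,x,y"
        )

    def _align(table: pd.DataFrame, name: str) -> pd.DataFrame:
        if table.shape[0] != expr.shape[0]:
            raise AlignmentError(
                f"{name}: {table.shape[0]} rows do not match "
                f"{expr.shape[0]} expression rows"
            )
        expr_ids = expr.index.astype(str)
        tab_ids = table.index.astype(str)
        if set(expr_ids) == set(tab_ids) and len(set(expr_ids)) == len(expr_ids):
            return table.set_axis(tab_ids, axis=0).loc[expr_ids]
        return table  # positional alignment

    coords = _align(coords, coordinates_path.name)
    cell_types = None
    if annotation_path is not None:
        annotation_path = Path(annotation_path)
        asep = "\t" if str(annotation_path).endswith((".tsv", ".txt")) else ","
        ann = _read_table(annotation_path, asep)
        ann = _align(ann, annotation_path.name)
        cell_types = [str(v) for v in ann.iloc[:, 0]]

    return SpatialExpressionDataset(
        expression=expr.to_numpy(dtype=float),
        coordinates=coords.to_numpy(dtype=float),
        gene_names=[str(g) for g in expr.columns],
        cell_ids=[str(c) for c in expr.index],
        cell_types=cell_types,
    )


def write_dataset(
    ds: SpatialExpressionDataset,
    expression_path: str | Path,
    coordinates_path: str | Path,
    annotation_path: Optional[str | Path] = None,
    format: str = "dense_csv",
) -> None:
    """Write a dataset back to disk in the formats read by :func:`load_dataset`."""
    expression_path = Path(expression_path)
    expr = pd.DataFrame(ds.expression, index=ds.cell_ids, columns=ds.gene_names)
    if format in ("dense_csv", "dense_tsv"):
        sep = "," if format == "dense_csv" else "\t"
        expr.to_csv(expression_path, sep=sep)
    elif format == "mtx_triplet":
        scipy.io.mmwrite(str(expression_path), scipy.sparse.coo_matrix(ds.expression))
        expression_path.with_suffix(".rows.txt").write_text(
            "\n".join(ds.cell_ids) + "\n"
        )
        expression_path.with_suffix(".cols.txt").write_text(
            "\n".join(ds.gene_names) + "\n"
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    coords = pd.DataFrame(ds.coordinates, index=ds.cell_ids, columns=["x", "y"])
    coords.index.name = "cell_id"
    coords.to_csv(coordinates_path)
    if annotation_path is not None and ds.cell_types is not None:
        ann = pd.DataFrame({"cell_type": ds.cell_types}, index=ds.cell_ids)
        ann.index.name = "cell_id"
        ann.to_csv(annotation_path)


def crop_field(
    ds: SpatialExpressionDataset,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
) -> SpatialExpressionDataset:
    """Restrict a dataset to cells inside a rectangular field.

    Both intervals are closed: a cell sitting exactly on a boundary is kept.
    """
    x_lo, x_hi = x_range
    y_lo, y_hi = y_range
    if not (np.isfinite([x_lo, x_hi, y_lo, y_hi]).all()):
        raise ValidationError("crop ranges must be finite")
    if x_lo > x_hi or y_lo > y_hi:
        raise ValidationError("crop range min exceeds max")
    x = ds.coordinates[:, 0]
    y = ds.coordinates[:, 1]
    keep = (x >= x_lo) & (x <= x_hi) & (y >= y_lo) & (y <= y_hi)
    if not keep.any():
        raise EmptyResultError("crop field contains no cells")
    return ds.subset_cells(np.flatnonzero(keep))


def _knn_edges(coords: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Union-of-nominations k-NN edge set with index tie-breaking."""
    n = coords.shape[0]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        order = np.lexsort((np.arange(n), d2[i]))[:k]
        for j in order:
            edges.add((min(i, j), max(i, j)))
    return edges


def simulate_tissue(
    n_cells: int = 500,
    n_types: int = 5,
    n_genes: int = 60,
    n_informative: int = 20,
    edge_rule: str = "proximity",
    dropout_rate: float = 0.0,
    seed: int = 0,
    n_distal_edges: int = 0,
    field_scale: float = 100.0,
    signal_strength: float = 1.2,
    base_rate: float = 5.0,
) -> tuple[SpatialExpressionDataset, SyntheticTruth]:
    """Simulate a tissue section with a planted interaction network.

    Cells are placed on a jittered square grid inside a ``field_scale`` x
    ``field_scale`` square and assigned one of ``n_types`` cell types in
    spatially clustered patches (types occupy coherent regions, as in real
    tissue).  The planted interaction network is the 3-nearest-neighbour
    proximity graph; with ``edge_rule='proximity_plus_type_affinity'``,
    ``n_distal_edges`` extra distal edges are planted between randomly chosen
    same-type, non-adjacent cell pairs.

    Informative genes follow a log-linear model: a gene-specific low-frequency
    spatial wave plus a cell-type effect, both scaled by ``signal_strength``,
    exponentiated into a Poisson rate around ``base_rate``.  Because the wave
    varies slowly relative to the inter-cell spacing, cells that share an edge
    have correlated informative-gene profiles.  The remaining genes are pure
    Poisson noise at ``base_rate``.  Technical dropout finally zeroes each
    entry independently with probability ``dropout_rate``.

    Returns the dataset and a :class:`SyntheticTruth` with the planted edges
    and informative gene indices.  Bit-reproducible from ``seed``.
    """
    if n_cells < 4:
        raise ValidationError("need at least 4 cells to form a 3-NN graph")
    if n_informative > n_genes:
        raise ValidationError("n_informative exceeds n_genes")
    if not (0 <= dropout_rate < 1):
        raise ValidationError("dropout_rate must be in [0, 1)")
    if edge_rule not in ("proximity", "proximity_plus_type_affinity"):
        raise ValueError(f"unknown edge_rule {edge_rule!r}")

    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_cells)))
    spacing = field_scale / side
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    grid = np.c_[gx.ravel(), gy.ravel()][:n_cells] * spacing + spacing / 2
    coords = grid + rng.normal(0, 0.25 * spacing, size=grid.shape)

    # Spatially clustered cell types: nearest of n_types random patch centres.
    centres = rng.uniform(0, field_scale, size=(n_types, 2))
    type_idx = np.argmin(
        ((coords[:, None, :] - centres[None, :, :]) ** 2).sum(-1), axis=1
    )
    cell_types = [f"type_{t}" for t in type_idx]

    true_edges = _knn_edges(coords, k=3)
    if edge_rule == "proximity_plus_type_affinity" and n_distal_edges > 0:
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        median_d = np.median(d[np.triu_indices(n_cells, 1)])
        candidates = [
            (i, j)
            for i in range(n_cells)
            for j in range(i + 1, n_cells)
            if type_idx[i] == type_idx[j]
            and (i, j) not in true_edges
            and d[i, j] > median_d
        ]
        if len(candidates) < n_distal_edges:
            raise ValidationError("not enough distal same-type pairs to plant")
        chosen = rng.choice(len(candidates), size=n_distal_edges, replace=False)
        true_edges |= {candidates[c] for c in chosen}

    informative = list(rng.choice(n_genes, size=n_informative, replace=False))
    log_rate = np.full((n_cells, n_genes), np.log(base_rate))
    if n_informative:
        # Low-frequency plane waves, 0.5-2.5 periods across the field:
        # slow enough that 3-NN neighbours share a similar phase, but bounded
        # away from zero so every informative gene carries spatial signal.
        angle = rng.uniform(0, 2 * np.pi, size=n_informative)
        periods = rng.uniform(0.5, 2.5, size=n_informative)
        freq = (periods / field_scale) * np.array([np.cos(angle), np.sin(angle)])
        phase = rng.uniform(0, 2 * np.pi, size=n_informative)
        wave = np.sin(2 * np.pi * coords @ freq + phase)
        type_effect = rng.normal(0, 1.0, size=(n_types, n_informative))
        signal = signal_strength * (wave + type_effect[type_idx])
        log_rate[:, informative] += signal
    expression = rng.poisson(np.exp(log_rate)).astype(float)

    if dropout_rate > 0:
        mask = rng.random(expression.shape) < dropout_rate
        expression[mask] = 0.0

    ds = SpatialExpressionDataset(
        expression=expression,
        coordinates=coords,
        gene_names=[f"gene_{g}" for g in range(n_genes)],
        cell_ids=[f"cell_{c}" for c in range(n_cells)],
        cell_types=cell_types,
    )
    truth = SyntheticTruth(
        true_edges=true_edges,
        informative_gene_indices=[int(g) for g in informative],
        generator_params=dict(
            n_cells=n_cells,
            n_types=n_types,
            n_genes=n_genes,
            n_informative=n_informative,
            edge_rule=edge_rule,
            dropout_rate=dropout_rate,
            seed=seed,
            n_distal_edges=n_distal_edges,
            field_scale=field_scale,
            signal_strength=signal_strength,
            base_rate=base_rate,
        ),
    )
    return ds, truth


def preprocess_expression(X: np.ndarray, mode: str = "none") -> np.ndarray:
    """Optional feature scaling before the encoder.

    ``none`` feeds values as loaded (the default); ``log1p_zscore`` applies
    log1p then a per-gene z-score (constant genes map to zero).
    """
    if mode == "none":
        return np.asarray(X, dtype=float)
    if mode == "log1p_zscore":
        Xl = np.log1p(np.asarray(X, dtype=float))
        mu = Xl.mean(axis=0)
        sd = Xl.std(axis=0)
        sd[sd == 0] = 1.0
        return (Xl - mu) / sd
    raise ValueError(f"unknown preprocessing mode {mode!r}")
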