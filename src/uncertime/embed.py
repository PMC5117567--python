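"""Expression-matrix handling and 2-D reduced representations.

Single-cell pseudotime inference operates on a low-dimensional embedding of
the cells, not on the full expression matrix.  This module reads and
validates log2 expression tables (genes x cells), selects detected and
highly variable genes, and produces the two standard embeddings used for
trajectory fitting: principal components and Laplacian eigenmaps on a
symmetric k-nearest-neighbour graph.

Any external N x P embedding can be supplied instead via
:func:`read_embedding`; the downstream model only sees coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "ExpressionMatrix",
    "Embedding",
    "FormatError",
    "EmptySelectionError",
    "DegenerateInputError",
    "DisconnectedGraphError",
    "read_expression",
    "write_expression",
    "read_embedding",
    "write_embedding",
    "select_genes",
    "pca_embed",
    "laplacian_eigenmaps",
    "standardize",
]


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


class EmptySelectionError(ValueError):
    """Raised when gene filtering leaves no genes."""


class DegenerateInputError(ValueError):
    """Raised when an embedding cannot be computed (e.g. constant matrix)."""


class DisconnectedGraphError(ValueError):
    """Raised when the k-NN graph for Laplacian eigenmaps is disconnected."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """G x N matrix of log2 expression values with gene and cell identifiers."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"shape {values.shape} does not match {len(self.gene_ids)} genes "
                f"x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"missing/non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            seen: dict[str, int] = {}
            for i in ids:
                seen[i] = seen.get(i, 0) + 1
            dups = [i for i, c in seen.items() if c > 1]
            if dups:
                raise FormatError(f"duplicate {name} IDs: {dups}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.cell_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), tuple(df.index.astype(str)), tuple(df.columns.astype(str)))


@dataclass(frozen=True)
class Embedding:
    """N x P matrix of reduced-dimension cell coordinates."""

    coords: np.ndarray
    cell_ids: tuple[str, ...]
    method_tag: str = "external"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise FormatError("embedding coordinates must be a 2-D array")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if coords.shape[0] != len(self.cell_ids):
            raise FormatError(
                f"{coords.shape[0]} coordinate rows but {len(self.cell_ids)} cell IDs"
            )
        if coords.shape[1] < 1:
            raise FormatError("embedding must have at least one dimension")
        if not np.all(np.isfinite(coords)):
            raise FormatError("non-finite embedding coordinates")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{j + 1}" for j in range(self.n_dims)]
        return pd.DataFrame(self.coords, index=list(self.cell_ids), columns=cols)


def _sniff_delimiter(path: Path) -> str:
    import csv

    sample = path.open().read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,; ").delimiter
    except csv.Error:
        return "\t"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # sniff the delimiter ourselves: the C engine's round_trip parser keeps
    # write->read cycles bit-exact, but does not support sep=None
    try:
        df = pd.read_csv(
            path, sep=_sniff_delimiter(path), index_col=0, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged table ({exc})") from None
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no data columns found")
    nonnum = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(nonnum):
        # locate the first offending cell for the error message
        for col in nonnum:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()]
            if len(bad_rows):
                raise FormatError(
                    f"{path}: non-numeric value in column {col!r}, row {bad_rows[0]!r}"
                )
        raise FormatError(f"{path}: non-numeric columns {list(nonnum)}")
    if df.isna().any().any():
        row, col = next(zip(*np.nonzero(df.isna().to_numpy())))
        raise FormatError(
            f"{path}: missing value at row {df.index[row]!r}, column {df.columns[col]!r} "
            "(ragged or incomplete table)"
        )
    return df


def read_expression(path: str | Path, transposed: bool = False) -> ExpressionMatrix:
    """Read a delimited expression table (genes x cells unless ``transposed``).

    The file must have a header row of cell IDs and a first column of gene
    IDs (swapped when ``transposed=True``).  The delimiter is sniffed, so
    both CSV and TSV work.  Ragged rows, non-numeric entries and duplicate
    identifiers raise :class:`FormatError` naming the offending row/column.
    """
    df = _read_table(path)
    if transposed:
        df = df.T
    return ExpressionMatrix.from_frame(df)


def write_expression(E: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    # %.17g keeps write->read round trips bit-identical
    E.to_frame().to_csv(path, sep=sep, index_label="gene", float_format="%.17g")


def read_embedding(path: str | Path, method_tag: str = "external") -> Embedding:
    """Read a delimited cell x P coordinate table (cell IDs in column one)."""
    df = _read_table(path)
    return Embedding(df.to_numpy(dtype=float), tuple(df.index.astype(str)), method_tag)


def write_embedding(X: Embedding, path: str | Path, sep: str = "\t") -> None:
    X.to_frame().to_csv(path, sep=sep, index_label="cell", float_format="%.17g")


def select_genes(
    E: ExpressionMatrix,
    min_detect_frac: float = 0.0,
    n_top: int | None = None,
) -> ExpressionMatrix:
    """Keep genes detected (>0) in >= ``min_detect_frac`` of cells, then the
    ``n_top`` highest-variance genes.

    The relative (original) gene ordering is preserved among kept genes.
    Variance ties at the ``n_top`` cutoff are broken deterministically by
    gene ID (lexicographically smaller ID wins).
    """
    if not 0.0 <= min_detect_frac <= 1.0:
        raise ValueError("min_detect_frac must be in [0, 1]")
    detect = (E.values > 0).mean(axis=1)
    keep = detect >= min_detect_frac
    idx = np.nonzero(keep)[0]
    if n_top is not None:
        if n_top < 1:
            raise ValueError("n_top must be positive")
        variances = E.values[idx].var(axis=1)
        order = sorted(
            range(len(idx)),
            key=lambda i: (-variances[i], E.gene_ids[idx[i]]),
        )
        idx = np.sort(idx[order[:n_top]])
    if len(idx) == 0:
        raise EmptySelectionError(
            "no genes survive filtering; lower min_detect_frac or raise n_top"
        )
    return ExpressionMatrix(
        E.values[idx],
        tuple(E.gene_ids[i] for i in idx),
        E.cell_ids,
    )


def _orient_components(coords: np.ndarray) -> np.ndarray:
    """Flip each component's sign so its correlation with cell input order is
    nonnegative (a cosmetic determinism convention)."""
    order = np.arange(coords.shape[0], dtype=float)
    order = order - order.mean()
    out = coords.copy()
    for j in range(out.shape[1]):
        if out[:, j] @ order < 0:
            out[:, j] = -out[:, j]
    return out


def pca_embed(E: ExpressionMatrix, n_components: int = 2) -> Embedding:
    """Project cells onto the top principal components of the cell x gene
    matrix (each gene centred).  Component variances are non-increasing."""
    if E.n_cells <= n_components:
        raise ValueError(f"need more than {n_components} cells for {n_components} components")
    data = E.values.T  # cells x genes
    if np.allclose(data.var(axis=0), 0.0):
        raise DegenerateInputError("expression matrix is constant; PCA undefined")
    coords = PCA(n_components=n_components, svd_solver="full").fit_transform(data)
    return Embedding(_orient_components(coords), E.cell_ids, method_tag=f"pca{n_components}")


def default_n_neighbors(n_cells: int) -> int:
    return max(10, int(np.ceil(0.05 * n_cells)))


def laplacian_eigenmaps(
    E: ExpressionMatrix,
    n_neighbors: int | None = None,
    n_components: int = 2,
) -> Embedding:
    """Spectral embedding of cells from a symmetric k-NN graph.

    Builds a binary symmetric k-nearest-neighbour adjacency on cells
    (Euclidean distance over the current gene set), forms the normalized
    graph Laplacian and returns the eigenvectors of its ``n_components``
    smallest nonzero eigenvalues.  A disconnected graph is an error telling
    the user to raise ``n_neighbors``.
    """
    n = E.n_cells
    if n_neighbors is None:
        n_neighbors = default_n_neighbors(n)
    n_neighbors = min(n_neighbors, n - 1)
    data = E.values.T
    A = kneighbors_graph(data, n_neighbors=n_neighbors, mode="connectivity")
    A = A.maximum(A.T)  # symmetrize: binary union of directed k-NN edges
    n_comp, _ = connected_components(A, directed=False)
    if n_comp > 1:
        raise DisconnectedGraphError(
            f"k-NN graph has {n_comp} connected components with "
            f"n_neighbors={n_neighbors}; raise n_neighbors"
        )
    deg = np.asarray(A.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(n) - d_inv_sqrt[:, None] * A.toarray() * d_inv_sqrt[None, :]
    eigvals, eigvecs = eigh((L + L.T) / 2.0)
    # drop (near-)zero eigenvalues: the trivial constant direction(s)
    nonzero = eigvals > 1e-10
    if nonzero.sum() < n_components:
        raise DegenerateInputError("not enough nonzero Laplacian eigenvalues")
    coords = eigvecs[:, nonzero][:, :n_components]
    return Embedding(_orient_components(coords), E.cell_ids, method_tag=f"le{n_components}")


def standardize(X: Embedding) -> Embedding:
    """Centre and scale each embedding dimension to unit standard deviation.

    The trajectory model uses a unit-amplitude kernel, which presumes the
    embedding dimensions live on comparable scales.
    """
    coords = X.coords
    sd = coords.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateInputError("embedding has a constant dimension; cannot standardize")
    return replace(X, coords=(coords - coords.mean(axis=0)) / sd)
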