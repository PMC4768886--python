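"""Regular grid geometry, cardinal-neighbor adjacency, and areal overlap weights.

The composition model lives on a regular lattice of square cells.  An
optional buffer widens the lattice on every side; buffer cells carry no
observations but participate in the spatial prior so that boundary
artifacts of the Markov random field are pushed away from the region of
interest.  Township (areal) observations are linked to the lattice through
normalized overlap weights.

Linear indexing is row-major over the *buffered* lattice: cell (ix, iy)
maps to ``iy * total_nx + ix``.  Every matrix in the package uses this one
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GridSpec",
    "CellAdjacency",
    "TownshipOverlap",
    "build_grid",
    "cardinal_adjacency",
    "normalize_overlap",
]


@dataclass(frozen=True)
class GridSpec:
    """A buffered regular lattice of square cells.

    Parameters refer to the *core* grid; ``buffer_width`` cells are added on
    every side.  Coordinates are metadata only (used when writing the
    posterior product); the model itself is purely index-based.
    """

    nx: int
    ny: int
    buffer_width: int = 0
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 8000.0

    @property
    def total_nx(self) -> int:
        return self.nx + 2 * self.buffer_width

    @property
    def total_ny(self) -> int:
        return self.ny + 2 * self.buffer_width

    @property
    def n_cells(self) -> int:
        """Total cell count m over the buffered lattice."""
        return self.total_nx * self.total_ny

    def cell_index(self, ix, iy):
        """Linear index of buffered-lattice coordinates (row-major)."""
        ix = np.asarray(ix)
        iy = np.asarray(iy)
        if np.any(ix < 0) or np.any(ix >= self.total_nx) or np.any(iy < 0) or np.any(iy >= self.total_ny):
            raise ValueError("cell coordinates outside the buffered lattice")
        return iy * self.total_nx + ix

    def core_index(self, cx, cy):
        """Linear index of *core* coordinates (0-based, buffer-exclusive)."""
        cx = np.asarray(cx)
        cy = np.asarray(cy)
        if np.any(cx < 0) or np.any(cx >= self.nx) or np.any(cy < 0) or np.any(cy >= self.ny):
            raise ValueError("core cell coordinates outside the core grid")
        return self.cell_index(cx + self.buffer_width, cy + self.buffer_width)

    def cell_coords(self, index):
        """Inverse of :meth:`cell_index`."""
        index = np.asarray(index)
        return index % self.total_nx, index // self.total_nx

    @property
    def core_mask(self) -> np.ndarray:
        """Boolean flag per buffered-lattice cell; True for core cells."""
        ix, iy = self.cell_coords(np.arange(self.n_cells))
        b = self.buffer_width
        return (
            (ix >= b)
            & (ix < b + self.nx)
            & (iy >= b)
            & (iy < b + self.ny)
        )

    def core_centroids(self):
        """(x, y) centroid coordinates of the core cells, in projection units."""
        x = self.origin_x + self.cell_size * np.arange(self.nx)
        y = self.origin_y + self.cell_size * np.arange(self.ny)
        return x, y


@dataclass(frozen=True)
class CellAdjacency:
    """Cardinal-neighbor (rook) adjacency of the buffered lattice.

    ``C`` is the symmetric 0/1 sparse adjacency matrix; ``degrees`` its row
    sums (4 for interior cells, 3 on edges, 2 in corners).
    """

    C: sp.csr_matrix
    degrees: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.C.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.C.nnz // 2)

    def incidence(self) -> sp.csr_matrix:
        """Oriented edge-by-cell incidence matrix B with B.T @ B = D - C.

        Used to draw exact square-root noise for the intrinsic CAR prior.
        """
        coo = sp.triu(self.C, k=1).tocoo()
        ne = coo.nnz
        rows = np.repeat(np.arange(ne), 2)
        cols = np.empty(2 * ne, dtype=np.int64)
        cols[0::2] = coo.row
        cols[1::2] = coo.col
        data = np.empty(2 * ne)
        data[0::2] = 1.0
        data[1::2] = -1.0
        return sp.csr_matrix((data, (rows, cols)), shape=(ne, self.C.shape[0]))


@dataclass
class TownshipOverlap:
    """Normalized township-to-cell overlap weights ψ.

    For each township ``t`` the weights over its supporting cells sum to 1;
    zero-area entries are dropped.  ``cells[t]`` and ``weights[t]`` are
    aligned arrays; ``ids`` maps township position -> external id.
    """

    ids: list = field(default_factory=list)
    cells: list = field(default_factory=list)
    weights: list = field(default_factory=list)

    @property
    def n_townships(self) -> int:
        return len(self.ids)

    def index_of(self, township_id) -> int:
        return self.ids.index(township_id)


def build_grid(
    nx: int,
    ny: int,
    buffer_width: int = 0,
    origin_x: float = 0.0,
    origin_y: float = 0.0,
    cell_size: float = 8000.0,
) -> GridSpec:
    """Build a :class:`GridSpec` for an ``nx`` by ``ny`` core grid.

    Raises ``ValueError`` for nonpositive core dimensions or a negative
    buffer width.
    """
    if int(nx) != nx or int(ny) != ny or nx < 1 or ny < 1:
        raise ValueError(f"grid dimensions must be positive integers, got ({nx}, {ny})")
    if int(buffer_width) != buffer_width or buffer_width < 0:
        raise ValueError(f"buffer_width must be a nonnegative integer, got {buffer_width}")
    return GridSpec(int(nx), int(ny), int(buffer_width), origin_x, origin_y, cell_size)


def cardinal_adjacency(grid: GridSpec) -> CellAdjacency:
    """Four-cardinal-neighbor adjacency over the buffered lattice."""
    nx, ny = grid.total_nx, grid.total_ny
    m = nx * ny
    idx = np.arange(m).reshape(ny, nx)
    rows = []
    cols = []
    # horizontal edges
    if nx > 1:
        a = idx[:, :-1].ravel()
        b = idx[:, 1:].ravel()
        rows.append(a)
        cols.append(b)
    # vertical edges
    if ny > 1:
        a = idx[:-1, :].ravel()
        b = idx[1:, :].ravel()
        rows.append(a)
        cols.append(b)
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        data = np.ones(r.size)
        C = sp.csr_matrix((data, (r, c)), shape=(m, m))
        C = C + C.T
    else:
        C = sp.csr_matrix((m, m))
    degrees = np.asarray(C.sum(axis=1)).ravel()
    return CellAdjacency(C=C.tocsr(), degrees=degrees)


def normalize_overlap(raw, grid: GridSpec | None = None) -> TownshipOverlap:
    """Normalize raw (township, cell, area) overlaps into ψ weights.

    ``raw`` is an iterable of ``(township_id, cell_index, area)`` triples or
    a DataFrame with columns ``township_id, cell_x, cell_y, area`` (core
    coordinates; requires ``grid``).  Areas must be nonnegative and each
    township must have at least one positive-area cell.  Idempotent on
    already-normalized input.
    """
    if isinstance(raw, pd.DataFrame):
        if grid is None:
            raise ValueError("a GridSpec is required to resolve cell coordinates")
        cell_idx = grid.core_index(raw["cell_x"].to_numpy(), raw["cell_y"].to_numpy())
        triples = zip(raw["township_id"], np.asarray(cell_idx), raw["area"].to_numpy())
    else:
        triples = raw

    by_town: dict = {}
    order: list = []
    for tid, cell, area in triples:
        if area < 0:
            raise ValueError(f"negative overlap area for township {tid!r}, cell {cell}")
        if tid not in by_town:
            by_town[tid] = {}
            order.append(tid)
        by_town[tid][int(cell)] = by_town[tid].get(int(cell), 0.0) + float(area)

    ov = TownshipOverlap()
    m = grid.n_cells if grid is not None else None
    for tid in order:
        items = [(c, a) for c, a in sorted(by_town[tid].items()) if a > 0]
        total = sum(a for _, a in items)
        if total <= 0:
            raise ValueError(f"township {tid!r} has no positive overlap area")
        cells = np.array([c for c, _ in items], dtype=np.int64)
        if m is not None and (cells.min() < 0 or cells.max() >= m):
            raise ValueError(f"township {tid!r} references a cell outside the grid")
        ov.ids.append(tid)
        ov.cells.append(cells)
        ov.weights.append(np.array([a / total for _, a in items]))
    return ov
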