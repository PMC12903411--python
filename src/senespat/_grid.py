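"""Rook-adjacency helpers for square spot grids."""

from __future__ import annotations

import numpy as np


def grid_edges(rows: int, cols: int) -> np.ndarray:
    """Edges (i, j) with i < j of the 4-neighbor lattice on a rows x cols grid.

    Spots are indexed in row-major order: ``idx = r * cols + c``.
    """
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                edges.append((i, i + 1))
            if r + 1 < rows:
                edges.append((i, i + cols))
    return np.asarray(edges, dtype=int).reshape(-1, 2)


def edges_from_coords(row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Rook-adjacency edges among spots given integer grid coordinates.

    Returns index pairs (i, j), i < j, for spots one step apart
    horizontally or vertically. Raises on duplicate coordinates.
    """
    row = np.asarray(row, dtype=int)
    col = np.asarray(col, dtype=int)
    coord_to_idx: dict[tuple[int, int], int] = {}
    for i, rc in enumerate(zip(row.tolist(), col.tolist())):
        if rc in coord_to_idx:
            raise ValueError(f"duplicate grid coordinate {rc}")
        coord_to_idx[rc] = i
    edges = []
    for (r, c), i in coord_to_idx.items():
        for rc2 in ((r, c + 1), (r + 1, c)):
            j = coord_to_idx.get(rc2)
            if j is not None:
                edges.append((min(i, j), max(i, j)))
    return np.asarray(edges, dtype=int).reshape(-1, 2)


def laplacian(n: int, edges: np.ndarray) -> np.ndarray:
    """Dense graph Laplacian for n nodes and an (m, 2) edge array."""
    L = np.zeros((n, n))
    if len(edges):
        i, j = edges[:, 0], edges[:, 1]
        np.add.at(L, (i, i), 1.0)
        np.add.at(L, (j, j), 1.0)
        np.add.at(L, (i, j), -1.0)
        np.add.at(L, (j, i), -1.0)
    return L
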