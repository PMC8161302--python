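"""Areal adjacency structures for conditional autoregressive models.

Small-area models of the kind used in disease and crime mapping operate on a
contiguity graph over areal units (census block groups, municipalities, grid
cells).  The intrinsic CAR prior needs, for every area *i*, the set of
adjacent areas and their count ``n_i``; the conditional mean of the spatial
field at *i* is the average over these neighbours and the conditional
variance is ``sigma**2 / n_i``.  This module builds, reads, writes and
validates such graphs.

Supported sources are regular lattices (rook or queen contiguity, useful as
synthetic stand-ins for a real city map), undirected edge-list CSV files and
GAL-style neighbour files.  Islands (areas with no neighbour) are rejected at
load time because the CAR conditional is undefined for them; users must merge
or connect such areas before fitting.
"""

from __future__ import annotations

import csv
import warnings
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

__all__ = [
    "AreaGraph",
    "GraphValidationError",
    "AdjacencyParseError",
    "build_lattice",
    "read_adjacency",
    "write_adjacency",
    "connected_components",
]


class GraphValidationError(ValueError):
    """An adjacency structure violates a CAR-model requirement."""


class AdjacencyParseError(ValueError):
    """An adjacency file is malformed or references unknown ids."""


class AreaGraph:
    """Undirected, loop-free contiguity graph over ordered areal units.

    Parameters
    ----------
    area_ids : sequence of str
        Labels of the areas.  The order given here is the canonical order
        used for every per-area vector in the package (0-based internally).
    edges : iterable of (int, int)
        Unordered index pairs of adjacent areas.  Duplicates and reversed
        copies of the same pair are merged; self-loops raise.

    Raises
    ------
    GraphValidationError
        On self-loops, duplicate area ids, islands (areas with no
        neighbour) or out-of-range indices.
    """

    def __init__(self, area_ids: Sequence[str], edges: Iterable[tuple[int, int]]):
        ids = [str(a) for a in area_ids]
        if len(set(ids)) != len(ids):
            raise GraphValidationError("duplicate area ids")
        n = len(ids)
        pairs: set[tuple[int, int]] = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise GraphValidationError(
                    f"self-loop on area {ids[u]!r} is not a valid adjacency"
                )
            if not (0 <= u < n and 0 <= v < n):
                raise GraphValidationError(f"edge ({u},{v}) out of range for {n} areas")
            pairs.add((min(u, v), max(u, v)))
        self.area_ids: tuple[str, ...] = tuple(ids)
        self.edges: np.ndarray = (
            np.array(sorted(pairs), dtype=np.int64)
            if pairs
            else np.empty((0, 2), dtype=np.int64)
        )
        nbrs: list[list[int]] = [[] for _ in range(n)]
        for u, v in self.edges:
            nbrs[u].append(int(v))
            nbrs[v].append(int(u))
        self.neighbors: tuple[np.ndarray, ...] = tuple(
            np.array(sorted(b), dtype=np.int64) for b in nbrs
        )
        self.n_neighbors: np.ndarray = np.array([len(b) for b in nbrs], dtype=np.int64)
        islands = [ids[i] for i in range(n) if self.n_neighbors[i] == 0]
        if islands:
            raise GraphValidationError(
                "island areas (no neighbours) are not allowed under the CAR "
                f"prior: {islands}"
            )

    # ------------------------------------------------------------------ #
    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @cached_property
    def adjacency_matrix(self) -> sparse.csr_matrix:
        """Binary symmetric adjacency matrix W (CSR)."""
        n = self.n_areas
        u, v = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(u))
        w = sparse.coo_matrix(
            (data, (np.r_[u, v], np.r_[v, u])), shape=(n, n)
        )
        return w.tocsr()

    @cached_property
    def laplacian(self) -> sparse.csr_matrix:
        """Graph Laplacian D - W, the unscaled ICAR precision."""
        d = sparse.diags(self.n_neighbors.astype(float))
        return (d - self.adjacency_matrix).tocsr()

    @cached_property
    def laplacian_eigh(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (clipped at 0) and eigenvectors of the Laplacian.

        Used by the samplers to draw exactly from Gaussian conditionals
        whose precision is ``a * L + b * I`` (diagonal in this basis).
        """
        lam, vec = np.linalg.eigh(self.laplacian.toarray())
        return np.clip(lam, 0.0, None), vec

    @cached_property
    def components(self) -> list[np.ndarray]:
        """Connected components as index arrays, in order of first member."""
        n_comp, labels = csgraph.connected_components(
            self.adjacency_matrix, directed=False
        )
        return [np.flatnonzero(labels == c) for c in range(n_comp)]

    @cached_property
    def coloring(self) -> list[np.ndarray]:
        """Greedy proper colouring as groups of mutually non-adjacent areas.

        Areas in one group share no edge, so single-site Metropolis updates
        of a CAR field can be applied to a whole group simultaneously.
        """
        colors = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        n_colors = max(colors.values()) + 1
        return [
            np.array(sorted(i for i, c in colors.items() if c == k), dtype=np.int64)
            for k in range(n_colors)
        ]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(map(tuple, self.edges))
        return g

    # ------------------------------------------------------------------ #
    def index_of(self, area_id: str) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise KeyError(f"unknown area id {area_id!r}") from None

    def reindex(self, area_ids: Sequence[str]) -> "AreaGraph":
        """Return the same graph with areas re-ordered to ``area_ids``.

        Useful when an edge-list file (which carries no canonical order)
        must be aligned with a data table.  Raises if the id sets differ.
        """
        ids = [str(a) for a in area_ids]
        if set(ids) != set(self.area_ids) or len(ids) != self.n_areas:
            diff = set(ids).symmetric_difference(self.area_ids)
            raise GraphValidationError(f"area id sets differ: {sorted(diff)}")
        old_index = {a: i for i, a in enumerate(self.area_ids)}
        new_pos = {old_index[a]: j for j, a in enumerate(ids)}
        return AreaGraph(ids, [(new_pos[int(u)], new_pos[int(v)]) for u, v in self.edges])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AreaGraph):
            return NotImplemented
        return self.area_ids == other.area_ids and np.array_equal(
            self.edges, other.edges
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AreaGraph(n_areas={self.n_areas}, n_edges={self.n_edges}, "
            f"n_components={len(self.components)})"
        )

    # ------------------------------------------------------------------ #
    def write_edge_csv(self, path: str | Path) -> None:
        """Write the graph as an undirected edge list (`src,dst` header)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["src", "dst"])
            for u, v in self.edges:
                writer.writerow([self.area_ids[u], self.area_ids[v]])

    def write_gal(self, path: str | Path) -> None:
        """Write the graph in the GAL neighbour-list dialect."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_areas}\n")
            for i, area in enumerate(self.area_ids):
                nbrs = self.neighbors[i]
                fh.write(f"{area} {len(nbrs)}\n")
                fh.write(" ".join(self.area_ids[j] for j in nbrs) + "\n")


# ---------------------------------------------------------------------- #
def build_lattice(rows: int, cols: int, contiguity: str = "rook") -> AreaGraph:
    """Regular lattice graph with rook (4-) or queen (8-) contiguity.

    Areas are ordered row-major and labelled ``A1 .. A{rows*cols}``.
    Used as a synthetic stand-in for a real areal map.
    """
    rows, cols = int(rows), int(cols)
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice needs rows*cols >= 2")
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"contiguity must be 'rook' or 'queen', got {contiguity!r}")
    ids = [f"A{i * cols + j + 1}" for i in range(rows) for j in range(cols)]
    steps = [(0, 1), (1, 0)]
    if contiguity == "queen":
        steps += [(1, 1), (1, -1)]
    edges = []
    for i in range(rows):
        for j in range(cols):
            for di, dj in steps:
                ni, nj = i + di, j + dj
                if 0 <= ni < rows and 0 <= nj < cols:
                    edges.append((i * cols + j, ni * cols + nj))
    return AreaGraph(ids, edges)


def _read_edge_list_csv(path: Path) -> AreaGraph:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["src", "dst"]:
            raise AdjacencyParseError(
                f"{path}: edge-list CSV must start with a 'src,dst' header"
            )
        raw = [(row[0].strip(), row[1].strip()) for row in reader if row]
    ids: list[str] = []
    index: dict[str, int] = {}
    for a, b in raw:
        for x in (a, b):
            if x not in index:
                index[x] = len(ids)
                ids.append(x)
    try:
        return AreaGraph(ids, [(index[a], index[b]) for a, b in raw])
    except GraphValidationError as exc:
        raise GraphValidationError(f"{path}: {exc}") from None


def _read_gal(path: Path) -> AreaGraph:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise AdjacencyParseError(f"{path}: empty GAL file")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise AdjacencyParseError(f"{path}: first GAL line must be the area count")
    ids: list[str] = []
    neighbor_names: list[list[str]] = []
    pos = 1
    for _ in range(n):
        if pos >= len(lines):
            raise AdjacencyParseError(f"{path}: truncated GAL file")
        head = lines[pos].split()
        if len(head) != 2:
            raise AdjacencyParseError(
                f"{path}: expected 'id n_i' header line, got {lines[pos]!r}"
            )
        area, k = head[0], int(head[1])
        if k > 0:
            if pos + 1 >= len(lines):
                raise AdjacencyParseError(f"{path}: truncated GAL file")
            nbrs = lines[pos + 1].split()
            pos += 2
        else:
            nbrs, pos = [], pos + 1
        if len(nbrs) != k:
            raise AdjacencyParseError(
                f"{path}: area {area!r} declares {k} neighbours but lists {len(nbrs)}"
            )
        ids.append(area)
        neighbor_names.append(nbrs)
    index = {a: i for i, a in enumerate(ids)}
    directed: set[tuple[int, int]] = set()
    for i, nbrs in enumerate(neighbor_names):
        for name in nbrs:
            if name not in index:
                raise AdjacencyParseError(
                    f"{path}: area {ids[i]!r} lists unknown neighbour id {name!r}"
                )
            directed.add((i, index[name]))
    asymmetric = [(u, v) for u, v in directed if (v, u) not in directed]
    if asymmetric:
        u, v = asymmetric[0]
        warnings.warn(
            f"{path}: {len(asymmetric)} asymmetric neighbour pairs "
            f"(e.g. {ids[u]!r} -> {ids[v]!r}); symmetrizing by union",
            stacklevel=2,
        )
    try:
        return AreaGraph(ids, list(directed))
    except GraphValidationError as exc:
        raise GraphValidationError(f"{path}: {exc}") from None


def read_adjacency(path: str | Path, dialect: str = "edge_list_csv") -> AreaGraph:
    """Read an adjacency file.

    Parameters
    ----------
    path : path
    dialect : {'edge_list_csv', 'gal'}
        ``edge_list_csv``: header ``src,dst``, one undirected edge per row.
        ``gal``: first line the area count, then per area a ``id n_i``
        header line followed by a whitespace-separated neighbour line.
        Asymmetric GAL neighbour lists are symmetrized (union) with a
        warning, since contiguity is inherently symmetric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "edge_list_csv":
        return _read_edge_list_csv(path)
    if dialect == "gal":
        return _read_gal(path)
    raise ValueError(f"unknown adjacency dialect {dialect!r}")


def write_adjacency(graph: AreaGraph, path: str | Path, dialect: str = "edge_list_csv") -> None:
    """Write an adjacency file in either supported dialect."""
    if dialect == "edge_list_csv":
        graph.write_edge_csv(path)
    elif dialect == "gal":
        graph.write_gal(path)
    else:
        raise ValueError(f"unknown adjacency dialect {dialect!r}")


def connected_components(graph: AreaGraph) -> list[set[int]]:
    """Connected components as sets of area indices.

    One sum-to-zero constraint per component is required when handling the
    intrinsic CAR prior, whose precision has a null vector per component.
    """
    return [set(map(int, comp)) for comp in graph.components]
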