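"""Circuit-theory (effective resistance) distances on raster landscapes.

Each non-nodata cell is a node of a resistor network; neighbouring cells
are joined by a resistor whose resistance is the mean of the two cell
resistances, scaled by √2 for diagonal neighbours (the extra centre-to-
centre distance).  The effective resistance between two focal cells —
voltage per unit current injected at one and extracted at the other —
integrates conduction over *all* paths, which is what makes it a useful
dispersal-cost distance: adding habitat corridors lowers it, and
Rayleigh monotonicity guarantees that degrading any cell can only raise
it.

The solver grounds one node, factorizes the reduced graph Laplacian once
(sparse LU) and reuses the factorization across all focal pairs.  A dense
pseudoinverse oracle is provided for cross-checking on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .distance import DistanceMatrix
from .raster import ResistanceSurface, uniform_surface

_SQRT2 = np.sqrt(2.0)


@dataclass
class GridGraph:
    """Resistor network over the non-nodata cells of a surface.

    ``node_of[r, c]`` is the node index of cell (r, c), or -1 for nodata.
    ``laplacian`` is the weighted graph Laplacian (conductances off the
    diagonal, negated), in CSR form.
    """

    node_of: np.ndarray
    cells: np.ndarray  # (n_nodes, 2) row/col per node
    laplacian: sp.csr_matrix
    connectivity: int

    @property
    def n_nodes(self) -> int:
        return self.cells.shape[0]

    def adjacency(self) -> sp.csr_matrix:
        a = -self.laplacian.copy()
        a.setdiag(0)
        a.eliminate_zeros()
        return a


def grid_graph(surface: ResistanceSurface, connectivity: int = 8) -> GridGraph:
    """Build the resistor network of a resistance surface.

    Cardinal edges get conductance ``1 / mean(r_i, r_j)``; diagonal edges
    (connectivity 8) get ``1 / (sqrt(2) * mean(r_i, r_j))``.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    res = surface.resistance
    usable = np.isfinite(res)
    n_nodes = int(usable.sum())
    if n_nodes < 2:
        raise ValueError("surface has fewer than 2 usable cells")
    node_of = np.full(res.shape, -1, dtype=np.int64)
    node_of[usable] = np.arange(n_nodes)
    cells = np.argwhere(usable)

    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    rows_i, rows_j, conds = [], [], []
    for dr, dc in offsets:
        # slices of overlapping cell pairs for this offset
        r0 = slice(max(0, -dr), res.shape[0] - max(0, dr))
        c0 = slice(max(0, -dc), res.shape[1] - max(0, dc))
        r1 = slice(max(0, dr), res.shape[0] - max(0, -dr))
        c1 = slice(max(0, dc), res.shape[1] - max(0, -dc))
        a = node_of[r0, c0].ravel()
        b = node_of[r1, c1].ravel()
        ra = res[r0, c0].ravel()
        rb = res[r1, c1].ravel()
        ok = (a >= 0) & (b >= 0)
        mean_r = 0.5 * (ra[ok] + rb[ok])
        g = 1.0 / mean_r
        if dr != 0 and dc != 0:
            g = g / _SQRT2
        rows_i.append(a[ok])
        rows_j.append(b[ok])
        conds.append(g)
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    g = np.concatenate(conds)
    adj = sp.coo_matrix((g, (i, j)), shape=(n_nodes, n_nodes))
    adj = (adj + adj.T).tocsr()
    lap = sp.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj
    return GridGraph(node_of, cells, lap.tocsr(), connectivity)


class DisconnectedError(RuntimeError):
    """Focal nodes lie in different connected components (infinite resistance)."""


def _pairwise_from_factor(graph: GridGraph, focal: np.ndarray) -> np.ndarray:
    """All pairwise effective resistances among ``focal`` node indices.

    Grounds node 0 of the graph, factorizes the reduced Laplacian once
    and solves one right-hand side per focal node.  Infinite entries mark
    disconnected pairs.
    """
    n = graph.n_nodes
    labels_cc = connected_components(graph.laplacian, directed=False)[1]
    ground = 0
    keep = np.arange(n) != ground
    lred = graph.laplacian[keep][:, keep].tocsc()
    lu = None
    reduced_index = np.cumsum(keep) - 1  # position of node in reduced system
    sols = {}
    out = np.zeros((len(focal), len(focal)))
    for a_i, na in enumerate(focal):
        for b_i in range(a_i + 1, len(focal)):
            nb = focal[b_i]
            if labels_cc[na] != labels_cc[nb]:
                out[a_i, b_i] = out[b_i, a_i] = np.inf
                continue
            for node in (na, nb):
                if node not in sols and node != ground:
                    if lu is None:
                        lu = splu(lred)
                    e = np.zeros(n - 1)
                    e[reduced_index[node]] = 1.0
                    sols[node] = lu.solve(e)

            def pot(k: int, at: int) -> float:
                if k == ground:
                    return 0.0
                v = sols[k]
                return 0.0 if at == ground else float(v[reduced_index[at]])

            r = pot(na, na) + pot(nb, nb) - pot(na, nb) - pot(nb, na)
            out[a_i, b_i] = out[b_i, a_i] = r
    return out


def effective_resistance(graph: GridGraph, focal: tuple[int, int]) -> float:
    """Two-point effective resistance between two node indices.

    Raises :class:`DisconnectedError` if the nodes are in different
    components.
    """
    a, b = focal
    if a == b:
        raise ValueError("focal nodes must be distinct")
    r = _pairwise_from_factor(graph, np.array([a, b]))[0, 1]
    if np.isinf(r):
        raise DisconnectedError(f"nodes {a} and {b} are disconnected")
    return float(r)


def effective_resistance_dense_oracle(graph: GridGraph, focal: tuple[int, int]) -> float:
    """(e_s − e_t)ᵀ L⁺ (e_s − e_t) via a dense pseudoinverse (test oracle).

    Limited to small graphs; independent of the sparse solver path.
    """
    if graph.n_nodes > 2000:
        raise ValueError("dense oracle limited to graphs with <= 2000 nodes")
    a, b = focal
    n = graph.n_nodes
    # for a connected graph, (L + J/n)^-1 = L+ + J/n and J e = 0, so
    # e' L+ e = e' (L + J/n)^-1 e; a dense solve avoids the singular-value
    # truncation a plain pseudoinverse would apply
    m = graph.laplacian.toarray() + 1.0 / n
    e = np.zeros(n)
    e[a], e[b] = 1.0, -1.0
    return float(e @ np.linalg.solve(m, e))


def _snap_sites(surface: ResistanceSurface, sites_xy: pd.DataFrame) -> np.ndarray:
    graph_nodes = []
    usable = np.isfinite(surface.resistance)
    for sid, row in sites_xy.iterrows():
        r, c = surface.nearest_cell(row["x"], row["y"])
        if not usable[r, c]:
            # search outward for nearest usable cell centre; ties (row, col)
            rr, cc = np.nonzero(usable)
            xs = surface.xll + (cc + 0.5) * surface.cellsize
            ys = surface.yll + (surface.nrows - 1 - rr + 0.5) * surface.cellsize
            d2 = (xs - row["x"]) ** 2 + (ys - row["y"]) ** 2
            best = np.lexsort((cc, rr, d2))[0]
            r, c = int(rr[best]), int(cc[best])
        graph_nodes.append((r, c))
    if len(set(graph_nodes)) != len(graph_nodes):
        raise ValueError("two sites map to the same raster cell")
    return np.array(graph_nodes)


def resistance_matrix(
    surface: ResistanceSurface,
    sites_xy: pd.DataFrame,
    connectivity: int = 8,
    kind: str = "resistance",
) -> DistanceMatrix:
    """All pairwise effective resistances between site locations.

    Sites (a DataFrame with x, y columns indexed by id) snap to the
    nearest usable cell centre.  Disconnected pairs are reported as
    ``inf``.
    """
    graph = grid_graph(surface, connectivity)
    cells = _snap_sites(surface, sites_xy)
    focal = graph.node_of[cells[:, 0], cells[:, 1]]
    vals = _pairwise_from_factor(graph, focal)
    return DistanceMatrix(list(sites_xy.index.astype(str)), vals, kind=kind)


def flat_resistance_matrix(
    sites_xy: pd.DataFrame,
    cellsize: float,
    buffer: float = 10_000.0,
    connectivity: int = 8,
) -> DistanceMatrix:
    """Effective resistances on a uniform landscape (every cell resistance 1).

    The raster covers the sites' bounding box extended by ``buffer``
    metres on each side, the null model against which heterogeneous
    scenarios are compared.
    """
    xmin, xmax = sites_xy["x"].min(), sites_xy["x"].max()
    ymin, ymax = sites_xy["y"].min(), sites_xy["y"].max()
    ncols = int(np.ceil((xmax - xmin + 2 * buffer) / cellsize))
    nrows = int(np.ceil((ymax - ymin + 2 * buffer) / cellsize))
    surface = uniform_surface(
        nrows, ncols, cellsize, xll=xmin - buffer, yll=ymin - buffer
    )
    return resistance_matrix(
        surface, sites_xy, connectivity=connectivity, kind="flat_resistance"
    )
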