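"""River rasterisation, the water-cell movement graph and along-river distances.

The channel polygon is converted to a boolean 50 m raster (a cell is water
iff its centre lies inside the polygon), the water cells become nodes of an
8-connected graph with centre-to-centre Euclidean edge weights (cell size,
or cell size * sqrt(2) on diagonals), and along-river distances are shortest
paths through that graph — so distances never cross land.  Fixes that fall
on the bank through GPS error are snapped to the nearest water cell, with
the snap distance reported for quality control.

Grids use a cell-centre registration: cell (row, col) has centre
``(origin_x + (col + 0.5) * cell, origin_y + (row + 0.5) * cell)`` with row 0
at the southern edge.  Mask I/O uses the plain-text ESRI ASCII grid format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import shapely
from scipy import ndimage, sparse
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

DEFAULT_CELL_M = 50.0
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class RiverMask:
    """Boolean water raster on a cell-centre-registered grid."""

    origin_x: float
    origin_y: float
    cell_size_m: float
    water: np.ndarray           # bool, (n_rows, n_cols), row 0 = south

    def __post_init__(self):
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be > 0")
        self.water = np.asarray(self.water, dtype=bool)
        if not self.water.any():
            raise ValueError("mask contains no water cells")
        _, n = ndimage.label(self.water, structure=_CONN8)
        if n > 1:
            log.warning(
                "river mask has %d connected components; analyses use the "
                "largest", n)

    @property
    def n_rows(self) -> int:
        return self.water.shape[0]

    @property
    def n_cols(self) -> int:
        return self.water.shape[1]

    @cached_property
    def component(self) -> np.ndarray:
        """Largest 8-connected water component (bool array)."""
        lab, n = ndimage.label(self.water, structure=_CONN8)
        if n == 1:
            return self.water
        sizes = np.bincount(lab.ravel())[1:]
        return lab == (int(np.argmax(sizes)) + 1)

    def cell_centre(self, row, col) -> np.ndarray:
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size_m
        y = self.origin_y + (np.asarray(row) + 0.5) * self.cell_size_m
        return np.stack([x, y], axis=-1)

    def area_km2(self) -> float:
        return float(self.water.sum()) * self.cell_size_m**2 / 1e6


def rasterize_river(polygon, cell_size_m: float = DEFAULT_CELL_M,
                    bounds: tuple[float, float, float, float] | None = None,
                    ) -> RiverMask:
    """Rasterise a channel polygon: water iff the cell centre is inside.

    ``bounds`` (minx, miny, maxx, maxy) default to the polygon envelope
    rounded outward to whole cells.
    """
    if polygon.is_empty:
        raise ValueError("river polygon is empty")
    if bounds is None:
        minx, miny, maxx, maxy = polygon.bounds
        minx = np.floor(minx / cell_size_m) * cell_size_m
        miny = np.floor(miny / cell_size_m) * cell_size_m
    else:
        minx, miny, maxx, maxy = bounds
    n_cols = max(1, int(np.ceil((maxx - minx) / cell_size_m)))
    n_rows = max(1, int(np.ceil((maxy - miny) / cell_size_m)))
    xs = minx + (np.arange(n_cols) + 0.5) * cell_size_m
    ys = miny + (np.arange(n_rows) + 0.5) * cell_size_m
    gx, gy = np.meshgrid(xs, ys)
    shapely.prepare(polygon)
    water = shapely.contains_xy(polygon, gx.ravel(), gy.ravel()).reshape(n_rows, n_cols)
    if not water.any():
        raise ValueError("rasterisation produced no water cells")
    return RiverMask(float(minx), float(miny), float(cell_size_m), water)


# --------------------------------------------------------------------------- #
# ESRI ASCII grid I/O (cell-centre registered via xllcorner/yllcorner)

def write_ascii_grid(mask: RiverMask, path: str) -> None:
    header = (f"ncols {mask.n_cols}\nnrows {mask.n_rows}\n"
              f"xllcorner {mask.origin_x}\nyllcorner {mask.origin_y}\n"
              f"cellsize {mask.cell_size_m}\nNODATA_value -9999\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, mask.water[::-1].astype(np.int8), fmt="%d")


def read_ascii_grid(path: str) -> RiverMask:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    arr = np.atleast_2d(data)[::-1] > 0.5
    return RiverMask(header["xllcorner"], header["yllcorner"],
                     header["cellsize"], arr)


# --------------------------------------------------------------------------- #
# movement graph

@dataclass
class MovementGraph:
    """Water-cell graph of the largest river component.

    ``nodes`` holds (row, col) per node in row-major order; ``weights`` is a
    symmetric sparse matrix of centre-to-centre distances in metres.
    """

    mask: RiverMask
    nodes: np.ndarray              # (k, 2) int
    node_id: np.ndarray            # (n_rows, n_cols) int, -1 off-graph
    weights: sparse.csr_matrix
    _dist_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Undirected edges (a < b, weight), for inspection and testing."""
        coo = sparse.triu(self.weights).tocoo()
        return [(int(a), int(b), float(w))
                for a, b, w in zip(coo.row, coo.col, coo.data)]

    def node_xy(self, node=None) -> np.ndarray:
        rc = self.nodes if node is None else self.nodes[node]
        return self.mask.cell_centre(rc[..., 0], rc[..., 1])

    def distances_from(self, node: int) -> np.ndarray:
        """Single-source shortest-path distances (m) to every node."""
        if node not in self._dist_cache:
            if len(self._dist_cache) >= 16:
                self._dist_cache.pop(next(iter(self._dist_cache)))
            self._dist_cache[node] = csgraph.dijkstra(
                self.weights, directed=False, indices=node)
        return self._dist_cache[node]

    def distance(self, a: int, b: int) -> float:
        d = float(self.distances_from(a)[b])
        if not np.isfinite(d):
            raise ValueError(f"nodes {a} and {b} are not connected")
        return d

    @cached_property
    def _kdtree(self) -> cKDTree:
        return cKDTree(self.node_xy())

    def snap(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Snap planar points to nearest graph nodes.

        Returns (node indices, snap distances in metres).  Ties resolve to
        the lowest (row, col) cell, which is the lowest node index.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dist, idx = self._kdtree.query(pts, k=4)
        dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)
        ties = dist <= dist[:, [0]] + 1e-9
        masked = np.where(ties, idx, self.n_nodes)
        best = masked.min(axis=1)
        return best, dist[:, 0]


def build_graph(mask: RiverMask, connectivity: int = 8) -> MovementGraph:
    """Build the movement graph over the largest connected water component."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    comp = mask.component
    node_id = np.full(mask.water.shape, -1, dtype=np.int64)
    nodes = np.argwhere(comp)
    node_id[comp] = np.arange(len(nodes))

    cell = mask.cell_size_m
    offsets = [(0, 1, cell), (1, 0, cell)]
    if connectivity == 8:
        d = cell * np.sqrt(2.0)
        offsets += [(1, 1, d), (1, -1, d)]

    rows, cols, data = [], [], []
    nr, nc = comp.shape
    for dr, dc, w in offsets:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        both = comp[r0:r1, c0:c1] & comp[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        src = node_id[r0:r1, c0:c1][both]
        dst = node_id[r0 + dr:r1 + dr, c0 + dc:c1 + dc][both]
        rows.append(src)
        cols.append(dst)
        data.append(np.full(len(src), w))
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    d = np.concatenate(data)
    w = sparse.coo_matrix((d, (r, c)), shape=(len(nodes), len(nodes)))
    w = (w + w.T).tocsr()
    return MovementGraph(mask, nodes, node_id, w)


def snap_to_river(point, mask: RiverMask,
                  graph: MovementGraph | None = None
                  ) -> tuple[tuple[int, int], float]:
    """Snap one planar point to the nearest water cell of the largest component.

    Returns ((row, col), snap distance in metres); ties break to the lowest
    (row, col).
    """
    if graph is None:
        graph = build_graph(mask)
    node, dist = graph.snap(np.asarray(point, dtype=float)[None, :])
    r, c = graph.nodes[int(node[0])]
    return (int(r), int(c)), float(dist[0])


def river_distance(a: int, b: int, graph: MovementGraph) -> float:
    """Along-river (least-cost) distance in metres between two graph nodes."""
    if a == b:
        return 0.0
    return graph.distance(a, b)
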