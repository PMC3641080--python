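"""Synthetic branching estuarine river networks.

A river is represented by its centreline tree: a meandering main channel
(arclength coordinate ``s`` measured in metres from the river mouth) plus
``n_tributaries`` side branches attached part-way along.  Each segment
carries a channel width, and the wetted channel polygon is the union of the
centrelines buffered by half their width.  The geometry is planar (metres)
throughout; no datum or projection arithmetic is performed.

The network doubles as a tiny edge graph (nodes at the mouth, confluences
and channel ends) used by the nomadic-agent random walk and for converting
1-D along-river positions to map coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import shapely
from shapely.geometry import LineString, mapping
from shapely.ops import unary_union

#: smallest channel width accepted, metres.  Narrower channels risk breaking
#: into disconnected cells on the 50 m analysis raster (need >= 2 cells).
MIN_CHANNEL_WIDTH_M = 100.0

_STEP_M = 250.0          # centreline vertex spacing
_MAX_HEADING_RAD = 1.2   # keeps each segment monotone along its own axis


@dataclass(frozen=True)
class RiverSpec:
    """Parameters of a synthetic river network.

    ``main_channel_length_km`` is the mouth-to-head arclength of the main
    channel; each tributary adds ``tributary_length_km`` of channel.
    ``bend_amplitude_m`` sets the lateral scale of the meanders.
    """

    main_channel_length_km: float = 150.0
    n_tributaries: int = 6
    channel_width_m: float = 300.0
    bend_amplitude_m: float = 2000.0
    tributary_length_km: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.main_channel_length_km <= 0:
            raise ValueError("main_channel_length_km must be > 0")
        if self.n_tributaries < 0:
            raise ValueError("n_tributaries must be >= 0")
        if self.channel_width_m < MIN_CHANNEL_WIDTH_M:
            raise ValueError(
                f"channel_width_m={self.channel_width_m} is below "
                f"{MIN_CHANNEL_WIDTH_M} m; the rasterised channel could "
                "disconnect"
            )


@dataclass
class Segment:
    """One polyline branch of the centreline tree."""

    seg_id: int
    coords: np.ndarray            # (n, 2) planar metres
    width_m: float
    attach_s_m: float | None      # arclength on the MAIN channel, None = main

    @cached_property
    def cum_m(self) -> np.ndarray:
        d = np.hypot(*np.diff(self.coords, axis=0).T)
        return np.concatenate([[0.0], np.cumsum(d)])

    @property
    def length_m(self) -> float:
        return float(self.cum_m[-1])

    def xy_at(self, s) -> np.ndarray:
        """Interpolate position(s) at arclength ``s`` along this segment."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length_m)
        x = np.interp(s, self.cum_m, self.coords[:, 0])
        y = np.interp(s, self.cum_m, self.coords[:, 1])
        return np.stack([x, y], axis=-1)


@dataclass
class Edge:
    """Graph edge between two junction/end nodes, with its own geometry."""

    edge_id: int
    node_a: int                   # nearer the mouth
    node_b: int
    coords: np.ndarray
    width_m: float

    @cached_property
    def cum_m(self) -> np.ndarray:
        d = np.hypot(*np.diff(self.coords, axis=0).T)
        return np.concatenate([[0.0], np.cumsum(d)])

    @property
    def length_m(self) -> float:
        return float(self.cum_m[-1])

    def xy_at(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length_m)
        x = np.interp(s, self.cum_m, self.coords[:, 0])
        y = np.interp(s, self.cum_m, self.coords[:, 1])
        return np.stack([x, y], axis=-1)


class RiverNetwork:
    """A generated river: segments, channel polygon and junction graph."""

    def __init__(self, spec: RiverSpec, segments: list[Segment]):
        self.spec = spec
        self.segments = segments
        self._build_graph()

    # ------------------------------------------------------------------ geometry

    @property
    def main(self) -> Segment:
        return self.segments[0]

    @property
    def main_length_m(self) -> float:
        return self.main.length_m

    @property
    def total_length_m(self) -> float:
        return float(sum(s.length_m for s in self.segments))

    def xy_on_main(self, s) -> np.ndarray:
        """Map along-main-channel arclength (m from the mouth) to x/y."""
        return self.main.xy_at(s)

    @cached_property
    def polygon(self):
        """Wetted channel polygon: union of buffered centrelines."""
        parts = [
            LineString(seg.coords).buffer(seg.width_m / 2.0, quad_segs=8)
            for seg in self.segments
        ]
        return unary_union(parts)

    def to_geojson(self) -> dict:
        return mapping(self.polygon)

    def to_wkt(self) -> str:
        return shapely.to_wkt(self.polygon, rounding_precision=2)

    # ------------------------------------------------------------------ graph

    def _build_graph(self) -> None:
        main = self.main
        attach = sorted(
            (seg.attach_s_m, seg.seg_id) for seg in self.segments[1:]
        )
        # nodes along the main channel: mouth, confluences, head
        s_nodes = [0.0] + [s for s, _ in attach] + [main.length_m]
        self.node_xy: list[np.ndarray] = []
        self.node_along_m: list[float] = []   # tree distance from the mouth
        main_node_of: dict[float, int] = {}
        for s in s_nodes:
            if s in main_node_of:
                continue
            main_node_of[s] = len(self.node_xy)
            self.node_xy.append(main.xy_at(s))
            self.node_along_m.append(s)

        self.edges: list[Edge] = []
        self.adjacency: dict[int, list[tuple[int, int]]] = {}

        def _add_edge(a: int, b: int, coords: np.ndarray, width: float):
            e = Edge(len(self.edges), a, b, coords, width)
            self.edges.append(e)
            self.adjacency.setdefault(a, []).append((e.edge_id, 0))
            self.adjacency.setdefault(b, []).append((e.edge_id, 1))

        # split the main channel at confluences
        bounds = sorted(main_node_of)
        for s0, s1 in zip(bounds[:-1], bounds[1:]):
            inner = main.coords[(main.cum_m > s0) & (main.cum_m < s1)]
            coords = np.vstack([main.xy_at(s0)[None], inner, main.xy_at(s1)[None]])
            _add_edge(main_node_of[s0], main_node_of[s1], coords, main.width_m)

        # tributary edges (node_a = confluence)
        for seg in self.segments[1:]:
            a = main_node_of[seg.attach_s_m]
            b = len(self.node_xy)
            self.node_xy.append(seg.coords[-1].astype(float))
            self.node_along_m.append(seg.attach_s_m + seg.length_m)
            _add_edge(a, b, seg.coords, seg.width_m)

    def along_from_mouth(self, edge_id: int, s_on_edge: float) -> float:
        """Tree distance (m) from the river mouth of a point on an edge."""
        e = self.edges[edge_id]
        return self.node_along_m[e.node_a] + float(s_on_edge)


def _meander_headings(s: np.ndarray, amplitude_m: float, rng: np.random.Generator,
                      scale: float = 1.0) -> np.ndarray:
    """Heading profile of a meandering channel, radians about its base axis."""
    lam1, lam2 = 15_000.0, 4_000.0
    a1 = scale * 2.0 * np.pi * amplitude_m / lam1
    a2 = 0.3 * a1
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    h = a1 * np.sin(2 * np.pi * s / lam1 + p1) + a2 * np.sin(2 * np.pi * s / lam2 + p2)
    return np.clip(h, -_MAX_HEADING_RAD, _MAX_HEADING_RAD)


def _walk(origin: np.ndarray, base_heading: float, length_m: float,
          amplitude_m: float, rng: np.random.Generator,
          scale: float = 1.0) -> np.ndarray:
    n_full = int(length_m // _STEP_M)
    steps = np.full(n_full, _STEP_M)
    rem = length_m - n_full * _STEP_M
    if rem > 1e-9:
        steps = np.append(steps, rem)
    s_mid = np.concatenate([[0.0], np.cumsum(steps)[:-1]])
    head = base_heading + _meander_headings(s_mid, amplitude_m, rng, scale)
    dxy = steps[:, None] * np.stack([np.cos(head), np.sin(head)], axis=1)
    return np.vstack([origin[None], origin[None] + np.cumsum(dxy, axis=0)])


def generate_river(spec: RiverSpec) -> RiverNetwork:
    """Generate a branching synthetic river from ``spec``.

    Deterministic for a fixed seed.  The main channel meanders about the
    +x axis; tributaries attach between 25% and 80% of the way upriver and
    head off at 60-100 degrees to the local channel direction, retrying the
    random draws if the candidate centreline crosses an existing one.
    """
    rng = np.random.default_rng(spec.seed)
    main_len = spec.main_channel_length_km * 1000.0
    main_coords = _walk(np.zeros(2), 0.0, main_len, spec.bend_amplitude_m, rng)
    segments = [Segment(0, main_coords, spec.channel_width_m, None)]
    lines = [LineString(main_coords)]

    main_seg = segments[0]
    trib_len = spec.tributary_length_km * 1000.0
    trib_width = max(MIN_CHANNEL_WIDTH_M, 0.6 * spec.channel_width_m)
    attach_fracs = np.linspace(0.15, 0.85, spec.n_tributaries) if spec.n_tributaries else []
    for k in range(spec.n_tributaries):
        placed = False
        for _ in range(40):
            frac = float(attach_fracs[k] + rng.uniform(-0.04, 0.04))
            s_attach = float(np.clip(frac, 0.05, 0.95)) * main_len
            # snap to the nearest main-channel vertex so graph cutting is exact
            i = int(np.argmin(np.abs(main_seg.cum_m - s_attach)))
            i = int(np.clip(i, 1, len(main_seg.cum_m) - 2))
            s_attach = float(main_seg.cum_m[i])
            origin = main_seg.coords[i].astype(float)
            tang = main_seg.coords[i + 1] - main_seg.coords[i - 1]
            local_head = float(np.arctan2(tang[1], tang[0]))
            side = 1.0 if rng.random() < 0.5 else -1.0
            base = local_head + side * np.deg2rad(rng.uniform(60.0, 100.0))
            coords = _walk(origin, base, trib_len, spec.bend_amplitude_m, rng,
                           scale=0.5)
            cand = LineString(coords[1:])  # skip the shared attach vertex
            if any(cand.intersects(ln) for ln in lines):
                continue
            segments.append(Segment(len(segments), coords, trib_width, s_attach))
            lines.append(LineString(coords))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place tributary {k} without crossing the network"
            )
    return RiverNetwork(spec, segments)
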