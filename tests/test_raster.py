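"""Rasterisation, the water-cell graph and along-river distances."""

import logging

import numpy as np
import pytest
from scipy.sparse import csgraph
from shapely.geometry import box

import crocrange as cr
from crocrange.raster import (RiverMask, build_graph, rasterize_river,
                              read_ascii_grid, river_distance, snap_to_river,
                              write_ascii_grid)

SQRT2 = np.sqrt(2.0)


def test_rectangle_rasterises_to_analytic_block(straight_mask):
    assert straight_mask.water.shape == (2, 20)
    assert straight_mask.water.all()
    assert straight_mask.area_km2() == pytest.approx(0.1)


def test_halved_cell_size_refines_consistently():
    fine = rasterize_river(box(0, 0, 1000, 100), 25.0, bounds=(0, 0, 1000, 100))
    assert fine.water.sum() == 4 * 40
    assert fine.area_km2() == pytest.approx(0.1)


def test_empty_rasterisation_rejected():
    with pytest.raises(ValueError, match="no water"):
        rasterize_river(box(0, 0, 10, 10), 50.0, bounds=(5000, 5000, 6000, 6000))


def test_strip_graph_edges():
    mask = RiverMask(0, 0, 50.0, np.ones((1, 3), dtype=bool))
    edges = build_graph(mask).edge_list()
    assert len(edges) == 2
    assert all(w == pytest.approx(50.0) for _, _, w in edges)


def test_square_block_graph_edges():
    mask = RiverMask(0, 0, 50.0, np.ones((2, 2), dtype=bool))
    weights = sorted(w for _, _, w in build_graph(mask).edge_list())
    assert len(weights) == 6
    assert weights[:4] == pytest.approx([50.0] * 4)
    assert weights[4:] == pytest.approx([50.0 * SQRT2] * 2)


def test_four_connectivity_has_no_diagonals():
    mask = RiverMask(0, 0, 50.0, np.ones((2, 2), dtype=bool))
    weights = [w for _, _, w in build_graph(mask, connectivity=4).edge_list()]
    assert len(weights) == 4
    assert weights == pytest.approx([50.0] * 4)


def test_disjoint_blobs_keep_largest_with_warning(caplog):
    water = np.zeros((3, 7), dtype=bool)
    water[0, :4] = True            # 4-cell blob
    water[2, 5:7] = True           # 2-cell blob
    with caplog.at_level(logging.WARNING):
        mask = RiverMask(0, 0, 50.0, water)
        graph = build_graph(mask)
    assert graph.n_nodes == 4
    assert any("connected components" in r.message for r in caplog.records)


def test_snap_at_cell_centre_is_exact(straight_mask):
    (r, c), d = snap_to_river((125.0, 25.0), straight_mask)
    assert (r, c) == (0, 2) and d == 0.0


def test_snap_tie_breaks_to_lower_row_col():
    mask = RiverMask(0, 0, 50.0, np.ones((1, 3), dtype=bool))
    (r, c), d = snap_to_river((75.0, 25.0), mask)   # exactly on (0, 1)
    assert (r, c) == (0, 1) and d == 0.0
    (r, c), d = snap_to_river((100.0, 25.0), mask)  # equidistant (0,1)/(0,2)
    assert (r, c) == (0, 1)
    assert d == pytest.approx(25.0)


def test_snap_distance_from_inland_point(straight_mask):
    # 80 m inland of the northern bank (y = 100)
    (_, _), d = snap_to_river((525.0, 180.0), straight_mask)
    assert d == pytest.approx(80.0, abs=50.0 / SQRT2)


def test_adjacent_and_identical_cell_distances(strip_graph):
    _, graph = strip_graph
    assert river_distance(3, 4, graph) == pytest.approx(50.0)
    assert river_distance(3, 3, graph) == 0.0


def _l_shaped_graph():
    water = np.zeros((10, 10), dtype=bool)
    water[:, 0] = True
    water[0, :] = True             # 19 cells in an L
    return build_graph(RiverMask(0, 0, 50.0, water))


def test_river_distance_matches_floyd_warshall_oracle():
    graph = _l_shaped_graph()
    dense = csgraph.floyd_warshall(graph.weights.toarray(), directed=False)
    for a in range(graph.n_nodes):
        ours = graph.distances_from(a)
        np.testing.assert_allclose(ours, dense[a], rtol=1e-12)


def test_distance_at_least_euclidean(strip_graph):
    mask, graph = strip_graph
    rng = np.random.default_rng(0)
    xy = graph.node_xy()
    for _ in range(200):
        a, b = rng.integers(0, graph.n_nodes, 2)
        assert graph.distances_from(int(a))[b] >= \
            np.hypot(*(xy[a] - xy[b])) - 1e-9


def test_metric_axioms_on_random_triples():
    net = cr.generate_river(cr.RiverSpec(20.0, 1, tributary_length_km=5.0,
                                         seed=13))
    graph = build_graph(rasterize_river(net.polygon))
    rng = np.random.default_rng(1)
    nodes = rng.choice(graph.n_nodes, 20, replace=False)
    d = {int(a): graph.distances_from(int(a)) for a in nodes}
    triples = rng.choice(nodes, size=(1000, 3))
    for a, b, c in triples:
        a, b, c = int(a), int(b), int(c)
        assert d[a][a] == 0.0
        assert d[a][b] == pytest.approx(d[b][a], rel=1e-12)
        assert d[a][c] <= d[a][b] + d[b][c] + 1e-9


def test_distance_stable_under_cell_refinement():
    coarse = rasterize_river(box(0, 0, 1000, 100), 50.0, bounds=(0, 0, 1000, 100))
    fine = rasterize_river(box(0, 0, 1000, 100), 25.0, bounds=(0, 0, 1000, 100))
    gc, gf = build_graph(coarse), build_graph(fine)
    # end-to-end distance along the channel
    dc = gc.distances_from(0).max()
    df = gf.distances_from(0).max()
    assert df == pytest.approx(dc, rel=0.10)


def test_ascii_grid_round_trip(tmp_path, straight_mask):
    path = tmp_path / "mask.asc"
    write_ascii_grid(straight_mask, path)
    back = read_ascii_grid(path)
    assert back.origin_x == straight_mask.origin_x
    assert back.cell_size_m == straight_mask.cell_size_m
    np.testing.assert_array_equal(back.water, straight_mask.water)
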