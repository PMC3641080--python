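"""Along-river step distances, rates of movement, centroid series, overlap."""

import numpy as np
import pandas as pd
import pytest

import crocrange as cr
from crocrange.metrics import (pairwise_overlap, rate_of_movement, snap_track,
                               step_distances)


def _strip_track(cells, start="2010-09-01 08:00"):
    """Fixes at given column indices of the 1 x 200 strip, 10 h/14 h apart."""
    times, t = [], pd.Timestamp(start)
    for i in range(len(cells)):
        times.append(t)
        t += pd.Timedelta(hours=10 if t.hour == 8 else 14)
    return pd.DataFrame({"id": "A", "timestamp": times,
                         "x_m": [25.0 + 50.0 * c for c in cells],
                         "y_m": 25.0, "sdop": 1.0})


def test_step_distance_same_cell_is_zero(strip_graph):
    _, graph = strip_graph
    steps = step_distances(snap_track(_strip_track([5, 5]), graph), graph)
    assert steps["distance_m"].tolist() == [0.0]


def test_step_distance_along_straight_channel(strip_graph):
    _, graph = strip_graph
    steps = step_distances(snap_track(_strip_track([10, 38]), graph), graph)
    assert steps["distance_m"].iloc[0] == pytest.approx(1400.0)
    assert steps["label"].iloc[0] == "day"       # closed by the 18:00 fix
    assert steps["duration_h"].iloc[0] == pytest.approx(10.0)


def test_total_distance_is_sum_of_steps(strip_graph):
    _, graph = strip_graph
    track = snap_track(_strip_track([0, 10, 4, 30, 30, 12]), graph)
    steps = step_distances(track, graph)
    rom = rate_of_movement(steps)
    assert rom.total_distance_km * 1000 == pytest.approx(
        steps["distance_m"].sum())


def test_rom_arithmetic():
    steps = pd.DataFrame({
        "t_start": [pd.Timestamp("2010-09-01 18:00"),
                    pd.Timestamp("2010-09-02 08:00")],
        "t_end": [pd.Timestamp("2010-09-02 08:00"),
                  pd.Timestamp("2010-09-02 18:00")],
        "duration_h": [14.0, 10.0],
        "distance_m": [1400.0, 1000.0],
        "label": ["night", "day"],
        "is_gap": [False, False],
    })
    rom = rate_of_movement(steps)
    assert rom.night_rom_m_per_h == pytest.approx(100.0)
    assert rom.day_rom_m_per_h == pytest.approx(100.0)
    assert rom.daily_rom_km_per_day.loc[pd.Timestamp("2010-09-02").date()] \
        == pytest.approx(2.4)


def test_gap_intervals_excluded_from_rom_but_not_total(strip_graph):
    _, graph = strip_graph
    track = _strip_track([0, 20])
    track.loc[1, "timestamp"] += pd.Timedelta(days=3)   # 82 h gap
    steps = step_distances(snap_track(track, graph), graph)
    assert steps["is_gap"].iloc[0]
    rom = rate_of_movement(steps)
    assert np.isnan(rom.day_rom_m_per_h) and np.isnan(rom.night_rom_m_per_h)
    assert rom.total_distance_km == pytest.approx(1.0)


def test_rom_invariant_to_row_order(strip_graph):
    _, graph = strip_graph
    track = snap_track(_strip_track([0, 5, 2, 17, 9, 30]), graph)
    shuffled = track.sample(frac=1.0, random_state=1)
    a = rate_of_movement(step_distances(track, graph))
    b = rate_of_movement(step_distances(shuffled, graph))
    assert a.day_rom_m_per_h == pytest.approx(b.day_rom_m_per_h)
    assert a.total_distance_km == pytest.approx(b.total_distance_km)


def test_constant_speed_agent_recovers_true_speed():
    river = cr.generate_river(cr.RiverSpec(200.0, 0, seed=3))
    agent = cr.AgentSpec("N", "male", "nomadic_male", 4.0,
                         territory_centre_km=100.0, persistence=1.0,
                         step_scale_day_m_per_h=200.0,
                         step_scale_night_m_per_h=200.0)
    traj = cr.simulate_agent(agent, river, "2010-09-01", "2010-09-14", seed=2)
    fixes = cr.observe_gps(traj, cr.ObservationModel(
        good_fix_error_sd_m=0.0, bad_fix_fraction=0.0, seed=1))
    fixes["id"] = "N"
    mask = cr.rasterize_river(river.polygon)
    graph = cr.build_graph(mask)
    steps = step_distances(snap_track(fixes, graph), graph)
    rom = rate_of_movement(steps)
    assert rom.day_rom_m_per_h == pytest.approx(200.0, rel=0.10)
    assert rom.night_rom_m_per_h == pytest.approx(200.0, rel=0.10)


def test_distance_from_centroid_series(mini_results, mini_sim):
    res = mini_results.individuals["SF1"]
    series = res.dist_series
    # a fix snapped to the centroid cell itself is at distance zero
    assert series.min() == pytest.approx(0.0, abs=0.2)
    assert series.max() == pytest.approx(res.max_dist_centroid_km)
    assert res.max_dist_centroid_km >= series.mean()


def test_site_fidelic_ranges_far_less_than_nomad(mini_results):
    sf = mini_results.individuals["SF1"].max_dist_centroid_km
    nomad = mini_results.individuals["NO1"].max_dist_centroid_km
    assert sf < nomad / 2


def _contour(cols, n=1, origin_x=0.0):
    cells = np.zeros((n, 60), dtype=bool)
    cells[:, cols] = True
    return cr.VolumeContour(0.5, origin_x, 0.0, 50.0, cells)


def test_overlap_identical_and_disjoint():
    a = _contour(range(10))
    assert pairwise_overlap(a, _contour(range(10))) == (100.0, 100.0)
    assert pairwise_overlap(a, _contour(range(20, 30))) == (0.0, 0.0)


def test_overlap_subset_arithmetic():
    small = _contour(range(10))     # 10 cells
    big = _contour(range(40))       # 40 cells, contains small
    assert pairwise_overlap(small, big) == (100.0, 25.0)


def test_overlap_across_offset_grids():
    a = _contour(range(10))                       # global cols 0..9
    b = _contour(range(5), origin_x=250.0)        # global cols 5..9
    assert pairwise_overlap(a, b) == (50.0, 100.0)
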