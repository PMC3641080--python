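"""Agent simulation and the GPS observation model."""

import numpy as np
import pandas as pd
import pytest

import crocrange as cr
from crocrange.simulate import Trajectory


@pytest.fixture(scope="module")
def long_river():
    return cr.generate_river(cr.RiverSpec(200.0, 0, seed=3))


def _agent(behaviour="site_fidelic_male", **kw):
    defaults = dict(id="A", sex="male", total_length_m=4.0,
                    territory_centre_km=100.0, territory_scale_km=2.0,
                    step_scale_day_m_per_h=160.0,
                    step_scale_night_m_per_h=330.0)
    defaults.update(kw)
    return cr.AgentSpec(behaviour=behaviour, **defaults)


def test_site_fidelic_stays_within_three_scales(long_river):
    traj = cr.simulate_agent(_agent(), long_river, "2010-09-01", "2011-02-28",
                             seed=3)
    frac = np.mean(np.abs(traj.along_m - 100_000.0) <= 6_000.0)
    assert frac >= 0.95


def test_site_fidelic_variance_bounded(long_river):
    traj = cr.simulate_agent(_agent(), long_river, "2010-09-01", "2011-02-28",
                             seed=9)
    assert traj.along_m.std() < 2 * 2_000.0


def test_fully_persistent_nomad_moves_monotonically(long_river):
    agent = _agent("nomadic_male", persistence=1.0, territory_centre_km=100.0,
                   step_scale_day_m_per_h=200.0, step_scale_night_m_per_h=200.0)
    traj = cr.simulate_agent(agent, long_river, "2010-09-01", "2010-09-10",
                             seed=4)
    diffs = np.diff(traj.along_m)
    assert (diffs >= 0).all() or (diffs <= 0).all()


def test_nomad_displacement_grows_with_duration(long_river):
    agent = _agent("nomadic_male", persistence=0.995,
                   step_scale_day_m_per_h=230.0, step_scale_night_m_per_h=380.0)
    full = cr.simulate_agent(agent, long_river, "2010-09-01", "2011-02-28",
                             seed=5)
    disp = np.abs(full.along_m - full.along_m[0])
    assert disp.max() > disp[:len(disp) // 2].max()


def test_female_excursion_shape(long_river):
    plan = cr.ExcursionPlan("2010-10-01 00:00", 130.0, 48.0, True)
    agent = _agent("breeding_female", sex="female", territory_scale_km=1.0,
                   excursion_schedule=(plan,))
    traj = cr.simulate_agent(agent, long_river, "2010-09-01", "2010-11-30",
                             seed=6)
    # exactly one far-from-territory run, containing a dwell at the destination
    away = np.abs(traj.along_m - 100_000.0) > 10_000.0
    runs = np.flatnonzero(np.diff(away.astype(int)) != 0)
    assert len(runs) == 2
    at_dest = np.abs(traj.along_m - 130_000.0) < 2_000.0
    assert at_dest.sum() >= 48
    assert not away[-1]


def test_excursion_beyond_river_rejected(long_river):
    plan = cr.ExcursionPlan("2010-10-01", 500.0, 10.0, True)
    agent = _agent("breeding_female", sex="female", excursion_schedule=(plan,))
    with pytest.raises(ValueError, match="beyond the river"):
        cr.simulate_agent(agent, long_river, "2010-09-01", "2010-11-30", seed=1)


def test_invalid_dt_rejected(long_river):
    with pytest.raises(ValueError, match="dt_h"):
        cr.simulate_agent(_agent(), long_river, "2010-09-01", "2010-09-10",
                          dt_h=-1.0)
    with pytest.raises(ValueError, match="divide"):
        cr.simulate_agent(_agent(), long_river, "2010-09-01", "2010-09-10",
                          dt_h=7.0)


# ---------------------------------------------------------------------- observation

def _flat_trajectory(n_days: int) -> Trajectory:
    times = pd.date_range("2010-09-01", periods=24 * n_days, freq="1h")
    n = len(times)
    return Trajectory(times, np.zeros(n), np.zeros((n, 2)))


def test_study_schedule_yields_362_fixes():
    fixes = cr.observe_gps(_flat_trajectory(181), cr.ObservationModel(seed=0))
    assert len(fixes) == 362


def test_noiseless_observation_recovers_truth(long_river):
    traj = cr.simulate_agent(_agent(), long_river, "2010-09-01", "2010-09-30",
                             seed=2)
    model = cr.ObservationModel(good_fix_error_sd_m=0.0, bad_fix_fraction=0.0,
                                seed=1)
    fixes = cr.observe_gps(traj, model)
    np.testing.assert_array_equal(fixes["x_m"], fixes["true_x_m"])
    assert (fixes["sdop"] <= 3.0).all()


def test_bad_fix_fraction_and_error_scale():
    fixes = cr.observe_gps(_flat_trajectory(5000), cr.ObservationModel(seed=11))
    flagged = (fixes["sdop"] > 3.0).mean()
    assert flagged == pytest.approx(0.07, abs=0.01)
    good = fixes[fixes["sdop"] <= 3.0]
    err = np.concatenate([good["x_m"], good["y_m"]])  # truth is the origin
    assert err.std() == pytest.approx(12.0, rel=0.10)


def test_scenario_yaml_round_trip(mini_scenario, tmp_path):
    path = tmp_path / "scenario.yaml"
    cr.save_scenario(mini_scenario, path)
    back = cr.load_scenario(path)
    assert back.river == mini_scenario.river
    assert back.agents == mini_scenario.agents
    assert back.observation == mini_scenario.observation
    t1, _, _ = cr.simulate_cohort(mini_scenario)
    t2, _, _ = cr.simulate_cohort(back)
    pd.testing.assert_frame_equal(t1, t2)


def test_simulation_chain_is_reproducible(mini_scenario):
    t1, m1, _ = cr.simulate_cohort(mini_scenario)
    t2, m2, _ = cr.simulate_cohort(mini_scenario)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(m1, m2)
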