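"""Shared fixtures: tiny analytic masks and a small simulated cohort.

The mini scenario uses a 20 km river and three agents (one per behavioural
regime) over the full study period, kept session-scoped because several
modules exercise different stages of the same end-to-end run.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

import crocrange as cr
from crocrange.raster import RiverMask, build_graph, rasterize_river


@pytest.fixture(scope="session")
def straight_mask() -> RiverMask:
    """A 1000 m x 100 m axis-aligned channel: 20 x 2 water cells."""
    return rasterize_river(box(0, 0, 1000, 100), 50.0, bounds=(0, 0, 1000, 100))


@pytest.fixture(scope="session")
def strip_graph():
    """Single-row straight channel, 200 cells of 50 m, with its graph."""
    mask = RiverMask(0.0, 0.0, 50.0, np.ones((1, 200), dtype=bool))
    return mask, build_graph(mask)


def _mini_agents():
    return (
        cr.AgentSpec("SF1", "male", "site_fidelic_male", 4.1,
                     territory_centre_km=10.0, territory_scale_km=1.0,
                     step_scale_day_m_per_h=160.0,
                     step_scale_night_m_per_h=330.0),
        cr.AgentSpec("NO1", "male", "nomadic_male", 3.7,
                     territory_centre_km=5.0, persistence=0.995,
                     step_scale_day_m_per_h=230.0,
                     step_scale_night_m_per_h=380.0),
        cr.AgentSpec("FE1", "female", "breeding_female", 2.9,
                     territory_centre_km=12.0, territory_scale_km=0.5,
                     step_scale_day_m_per_h=50.0,
                     step_scale_night_m_per_h=50.0,
                     excursion_schedule=(
                         cr.ExcursionPlan("2010-12-08 20:00", 3.0, 36.0, True),
                         cr.ExcursionPlan("2010-12-26 20:00", 3.0, 2000.0, False),
                     )),
    )


@pytest.fixture(scope="session")
def mini_scenario() -> cr.Scenario:
    return cr.Scenario(
        river=cr.RiverSpec(main_channel_length_km=20.0, n_tributaries=1,
                           tributary_length_km=6.0, seed=11),
        agents=_mini_agents(),
        observation=cr.ObservationModel(seed=21),
        seed=7,
    )


@pytest.fixture(scope="session")
def mini_sim(mini_scenario, tmp_path_factory):
    """Simulated mini cohort materialised to disk plus in-memory objects."""
    out = tmp_path_factory.mktemp("mini_sim")
    arts = cr.run_simulation(mini_scenario, out)
    arts["out_dir"] = out
    return arts


@pytest.fixture(scope="session")
def mini_results(mini_sim) -> cr.CohortResults:
    return cr.analyze_cohort(mini_sim["telemetry"], mini_sim["metadata"],
                             mini_sim["mask"])
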