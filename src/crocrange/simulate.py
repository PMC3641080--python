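"""Movement simulation for the three crocodile behavioural regimes.

Movement is simulated in one dimension along the river centreline and mapped
to planar coordinates afterwards, since the animals' movement is confined to
the channel.  Three regimes are modelled:

``site_fidelic_male``
    a discrete-time mean-reverting (Ornstein-Uhlenbeck-like) walk about a
    territory centre on the main channel, whose stationary standard
    deviation equals ``territory_scale_km``;
``nomadic_male``
    a persistent directional walk over the whole channel network, choosing
    branches uniformly at confluences and reflecting at channel ends;
``breeding_female``
    the mean-reverting walk plus scheduled long-range excursions: directed
    travel to a destination, a dwell, and either a return leg or permanent
    relocation of the attraction centre (nesting).

Step sizes scale with time of day (08:00-18:00 local is "day"), mirroring
the twice-daily fix schedule of the GPS loggers.  Observation adds isotropic
Gaussian positional error and an SDOP quality value: a fraction of fixes are
"bad" (SDOP > 3) with a much larger error scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .river import RiverNetwork, RiverSpec, generate_river

DAY_START_HOUR = 8
DAY_END_HOUR = 18


@dataclass(frozen=True)
class ExcursionPlan:
    """One scheduled long-range trip for a breeding female."""

    start: pd.Timestamp
    destination_km: float
    dwell_h: float
    returns: bool

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))


@dataclass(frozen=True)
class AgentSpec:
    id: str
    sex: str                              # 'male' | 'female'
    behaviour: str                        # regime name, see module docstring
    total_length_m: float
    territory_centre_km: float = 50.0     # along-river, km from the mouth
    territory_scale_km: float = 2.0
    step_scale_day_m_per_h: float = 150.0
    step_scale_night_m_per_h: float = 300.0
    persistence: float = 0.97             # nomadic: P(keep direction) per step
    branch_bias: str = "least_visited"    # nomadic confluence rule, or 'uniform'
    range_crossing_h: float = 12.0        # reverting: territory mixing time
    excursion_schedule: tuple[ExcursionPlan, ...] = ()
    excursion_speed_m_per_h: float = 2500.0

    def __post_init__(self):
        if self.step_scale_day_m_per_h < 0 or self.step_scale_night_m_per_h < 0:
            raise ValueError("step scales must be >= 0")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
        object.__setattr__(self, "excursion_schedule",
                           tuple(self.excursion_schedule))


@dataclass(frozen=True)
class ObservationModel:
    """Twice-daily GPS fixing with quality-dependent positional error."""

    fix_times_local: tuple[str, ...] = ("08:00", "18:00")
    good_fix_error_sd_m: float = 12.0
    bad_fix_fraction: float = 0.07
    bad_fix_error_sd_m: float = 250.0
    sdop_good_max: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.bad_fix_fraction < 1.0:
            raise ValueError("bad_fix_fraction must lie in [0, 1)")
        if self.good_fix_error_sd_m < 0 or self.bad_fix_error_sd_m < 0:
            raise ValueError("error SDs must be >= 0")


@dataclass
class Trajectory:
    """True (error-free) positions of one agent on the simulation grid."""

    times: pd.DatetimeIndex
    along_m: np.ndarray          # tree distance from the river mouth
    xy: np.ndarray               # (n, 2) planar metres

    def __len__(self) -> int:
        return len(self.times)


def _is_day(times: pd.DatetimeIndex) -> np.ndarray:
    return (times.hour >= DAY_START_HOUR) & (times.hour < DAY_END_HOUR)


def _time_grid(start_date, end_date, dt_h: float) -> pd.DatetimeIndex:
    if dt_h <= 0:
        raise ValueError("dt_h must be > 0")
    if abs(24.0 / dt_h - round(24.0 / dt_h)) > 1e-9:
        raise ValueError("dt_h must divide 24")
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if start >= end:
        raise ValueError("start_date must precede end_date")
    return pd.date_range(start, end + pd.Timedelta(hours=24 - dt_h),
                         freq=pd.Timedelta(hours=dt_h))


def _simulate_reverting(agent: AgentSpec, river: RiverNetwork,
                        times: pd.DatetimeIndex, dt_h: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Mean-reverting main-channel walk, with excursions for females.

    Discrete OU with autoregression phi = exp(-dt / range_crossing_h), so
    the territory is traversed on a sub-daily time scale (the observed
    patrolling behaviour) and the stationary SD equals the territory scale.
    The day/night step scales modulate the innovation variance around its
    stationary-consistent base, preserving the diurnal activity contrast.
    """
    main_len = river.main_length_m
    scale_m = agent.territory_scale_km * 1000.0
    centre = agent.territory_centre_km * 1000.0
    if not 0.0 <= centre <= main_len:
        raise ValueError("territory_centre_km lies beyond the river extent")
    for plan in agent.excursion_schedule:
        if not 0.0 <= plan.destination_km * 1000.0 <= main_len:
            raise ValueError(
                f"excursion destination {plan.destination_km} km is beyond "
                "the river extent"
            )

    day = _is_day(times)
    phi = float(np.exp(-dt_h / agent.range_crossing_h))
    sigma_base = np.sqrt(max(0.0, 1.0 - phi * phi))
    w = np.where(day, agent.step_scale_day_m_per_h,
                 agent.step_scale_night_m_per_h)
    w_mean = w.mean()
    weights = w / w_mean if w_mean > 0 else np.ones_like(w)
    sig = sigma_base * weights            # per-step innovation, units of scale
    eps = rng.standard_normal(len(times))
    plans = sorted(agent.excursion_schedule, key=lambda p: p.start)
    plan_i = 0
    state = "range"
    target = 0.0
    dwell_until = times[0]
    dwell_scale = 0.0

    s = np.empty(len(times))
    s[0] = centre
    for i in range(1, len(times)):
        t = times[i]
        if state == "range" and plan_i < len(plans) and t >= plans[plan_i].start:
            state = "out"
            target = plans[plan_i].destination_km * 1000.0
        if state in ("out", "back"):
            v = agent.excursion_speed_m_per_h * dt_h
            step = np.sign(target - s[i - 1]) * v
            nxt = s[i - 1] + step
            if (target - s[i - 1]) * (target - nxt) <= 0:  # arrived
                nxt = target
                if state == "out":
                    state = "dwell"
                    dwell_until = t + pd.Timedelta(hours=plans[plan_i].dwell_h)
                    dwell_scale = min(scale_m, 500.0)
                else:
                    state = "range"
                    plan_i += 1
            s[i] = nxt
        elif state == "dwell":
            s[i] = target + phi * (s[i - 1] - target) \
                + sig[i] * dwell_scale * eps[i]
            if t >= dwell_until:
                if plans[plan_i].returns:
                    state = "back"
                    target = centre
                else:
                    centre = target  # nesting: the range relocates
                    state = "range"
                    plan_i += 1
        else:
            s[i] = centre + phi * (s[i - 1] - centre) \
                + sig[i] * scale_m * eps[i]
        s[i] = min(max(s[i], 0.0), main_len)
    return s


def _simulate_nomadic(agent: AgentSpec, river: RiverNetwork,
                      times: pd.DatetimeIndex, dt_h: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Persistent directional walk over the junction graph.

    Returns (along_from_mouth, xy).  At a confluence the walker picks among
    the other incident edges — uniformly when ``branch_bias='uniform'``, or
    (the default) uniformly among the least-traversed ones, the sustained
    mate-searching exploration that keeps a nomad's cumulative range
    growing instead of re-patrolling already-searched water.  Dead ends
    reflect the walker.
    """
    day = _is_day(times)
    speed = np.where(day, agent.step_scale_day_m_per_h,
                     agent.step_scale_night_m_per_h) * dt_h
    # start on the edge containing the requested along-river position
    start_m = agent.territory_centre_km * 1000.0
    edge_id, s_on = 0, 0.0
    for e in river.edges:
        a = river.node_along_m[e.node_a]
        if a <= start_m <= a + e.length_m:
            edge_id, s_on = e.edge_id, start_m - a
            break
    direction = 1 if rng.random() < 0.5 else -1

    along = np.empty(len(times))
    xy = np.empty((len(times), 2))
    along[0] = river.along_from_mouth(edge_id, s_on)
    xy[0] = river.edges[edge_id].xy_at(s_on)
    flips = rng.random(len(times)) > agent.persistence
    jitter = rng.uniform(0.5, 1.5, len(times))
    choices = rng.random(len(times))
    visits = np.zeros(len(river.edges), dtype=np.int64)
    visits[edge_id] = 1

    for i in range(1, len(times)):
        if flips[i]:
            direction = -direction
        remaining = speed[i] * jitter[i]
        while remaining > 0:
            e = river.edges[edge_id]
            if direction > 0:
                room = e.length_m - s_on
            else:
                room = s_on
            if remaining <= room:
                s_on += direction * remaining
                remaining = 0.0
            else:
                remaining -= room
                node = e.node_b if direction > 0 else e.node_a
                incident = river.adjacency[node]
                others = [(ei, end) for ei, end in incident if ei != edge_id]
                if not others:
                    # dead end: reflect on the same edge
                    direction = -direction
                    s_on = e.length_m if direction < 0 else 0.0
                else:
                    if agent.branch_bias == "least_visited":
                        fewest = min(visits[ei] for ei, _ in others)
                        others = [(ei, end) for ei, end in others
                                  if visits[ei] == fewest]
                    j = int(choices[i] * len(others)) % len(others)
                    edge_id, end = others[j]
                    visits[edge_id] += 1
                    ne = river.edges[edge_id]
                    # enter at the shared node, head away from it
                    s_on = 0.0 if end == 0 else ne.length_m
                    direction = 1 if end == 0 else -1
        along[i] = river.along_from_mouth(edge_id, s_on)
        xy[i] = river.edges[edge_id].xy_at(s_on)
    return along, xy


def simulate_agent(agent: AgentSpec, river: RiverNetwork, start_date, end_date,
                   dt_h: float = 1.0, seed: int | None = None) -> Trajectory:
    """Simulate one agent's true trajectory on an hourly (``dt_h``) grid."""
    times = _time_grid(start_date, end_date, dt_h)
    rng = np.random.default_rng(seed)
    if agent.behaviour == "nomadic_male":
        along, xy = _simulate_nomadic(agent, river, times, dt_h, rng)
    elif agent.behaviour in ("site_fidelic_male", "breeding_female"):
        along = _simulate_reverting(agent, river, times, dt_h, rng)
        xy = river.xy_on_main(along)
    else:
        raise ValueError(f"unknown behaviour {agent.behaviour!r}")
    return Trajectory(times, np.asarray(along, float), np.asarray(xy, float))


def observe_gps(trajectory: Trajectory, model: ObservationModel) -> pd.DataFrame:
    """Sample GPS fixes at the scheduled clock times and add positional error.

    Returns one row per scheduled fix with columns ``timestamp``, ``x_m``,
    ``y_m``, ``sdop`` plus the error-free truth (``true_x_m``, ``true_y_m``,
    ``true_along_m``) for validation.  Deterministic under ``model.seed``.
    """
    fix_times = {tuple(int(v) for v in ft.split(":")) for ft in model.fix_times_local}
    t = trajectory.times
    sched = np.array([(h, m) in fix_times for h, m in zip(t.hour, t.minute)])
    idx = np.flatnonzero(sched)
    n_days = len(np.unique(t.normalize()))
    if len(idx) != n_days * len(fix_times):
        raise ValueError("trajectory does not cover every scheduled fix time")

    rng = np.random.default_rng(model.seed)
    n = len(idx)
    bad = rng.random(n) < model.bad_fix_fraction
    sd = np.where(bad, model.bad_fix_error_sd_m, model.good_fix_error_sd_m)
    err = rng.standard_normal((n, 2)) * sd[:, None]
    sdop = np.where(bad,
                    rng.uniform(model.sdop_good_max + 0.2, 8.0, n),
                    rng.uniform(0.5, model.sdop_good_max, n))
    truth = trajectory.xy[idx]
    return pd.DataFrame({
        "timestamp": t[idx],
        "x_m": truth[:, 0] + err[:, 0],
        "y_m": truth[:, 1] + err[:, 1],
        "sdop": sdop,
        "true_x_m": truth[:, 0],
        "true_y_m": truth[:, 1],
        "true_along_m": trajectory.along_m[idx],
    })


# --------------------------------------------------------------------------- #
# default study scenario

STUDY_START = pd.Timestamp("2010-09-01")
STUDY_END = pd.Timestamp("2011-02-28")


@dataclass(frozen=True)
class Scenario:
    """A complete simulation configuration: river, cohort and observation."""

    river: RiverSpec
    agents: tuple[AgentSpec, ...]
    observation: ObservationModel
    start_date: pd.Timestamp = STUDY_START
    end_date: pd.Timestamp = STUDY_END
    dt_h: float = 1.0
    seed: int = 0


def default_scenario(seed: int = 0) -> Scenario:
    """The default cohort mirroring the study design.

    Five site-fidelic males holding territories around the female range
    areas, three nomadic males ranging over the whole network, and four
    breeding females whose scheduled Dec-Jan excursions include one 54 km
    downstream trip and one permanent 40 km upstream relocation.  Step
    scales follow the magnitudes of the observed day/night movement rates.
    """
    sf = [
        # (id, TL, centre_km, day, night)
        ("SM1", 4.3, 25.0, 290.0, 589.0),
        ("SM2", 3.9, 37.0, 67.0, 118.0),
        ("SM3", 3.7, 49.0, 84.0, 248.0),
        ("SM4", 4.1, 61.0, 166.0, 447.0),
        ("SM5", 4.5, 73.0, 200.0, 270.0),
    ]
    nomads = [
        ("NM1", 3.2, 30.0, 301.0, 352.0),
        ("NM2", 3.7, 55.0, 153.0, 428.0),
        ("NM3", 3.9, 80.0, 245.0, 373.0),
    ]
    females = [
        ("F1", 3.0, 30.0, 123.0, 56.0,
         (ExcursionPlan("2011-01-10 02:00", 70.0, 2000.0, False),)),
        ("F2", 2.9, 45.0, 17.0, 39.0,
         (ExcursionPlan("2010-12-08 20:00", 5.0, 36.0, True),
          ExcursionPlan("2010-12-26 20:00", 5.0, 2000.0, False))),
        ("F3", 3.2, 60.0, 34.0, 92.0,
         (ExcursionPlan("2010-12-12 20:00", 6.0, 40.0, True),
          ExcursionPlan("2011-01-02 20:00", 6.0, 2000.0, False))),
        ("F4", 2.6, 70.0, 27.0, 23.0,
         (ExcursionPlan("2010-12-05 20:00", 48.0, 30.0, True),
          ExcursionPlan("2010-12-20 20:00", 48.0, 2000.0, False))),
    ]
    agents: list[AgentSpec] = []
    for aid, tl, centre, d, n in sf:
        agents.append(AgentSpec(aid, "male", "site_fidelic_male", tl,
                                territory_centre_km=centre,
                                territory_scale_km=2.0,
                                step_scale_day_m_per_h=d,
                                step_scale_night_m_per_h=n))
    for aid, tl, centre, d, n in nomads:
        agents.append(AgentSpec(aid, "male", "nomadic_male", tl,
                                territory_centre_km=centre,
                                step_scale_day_m_per_h=d,
                                step_scale_night_m_per_h=n,
                                persistence=0.995))
    for aid, tl, centre, d, n, plans in females:
        agents.append(AgentSpec(aid, "female", "breeding_female", tl,
                                territory_centre_km=centre,
                                territory_scale_km=0.5,
                                step_scale_day_m_per_h=d,
                                step_scale_night_m_per_h=n,
                                excursion_schedule=plans))
    return Scenario(
        river=RiverSpec(seed=seed % 2**31),
        agents=tuple(agents),
        observation=ObservationModel(seed=(seed * 31 + 5) % 2**31),
        seed=seed,
    )


def scenario_to_dict(scenario: Scenario) -> dict:
    """Plain key-value representation of a scenario (YAML-serialisable)."""
    from dataclasses import asdict
    d = asdict(scenario)
    d["start_date"] = str(scenario.start_date.date())
    d["end_date"] = str(scenario.end_date.date())
    for agent in d["agents"]:
        agent["excursion_schedule"] = [
            {"start": str(p["start"]), "destination_km": p["destination_km"],
             "dwell_h": p["dwell_h"], "returns": p["returns"]}
            for p in agent["excursion_schedule"]]
    return d


def scenario_from_dict(d: dict) -> Scenario:
    agents = []
    for a in d.get("agents", []):
        a = dict(a)
        a["excursion_schedule"] = tuple(
            ExcursionPlan(**p) for p in a.get("excursion_schedule", []))
        agents.append(AgentSpec(**a))
    return Scenario(
        river=RiverSpec(**d["river"]),
        agents=tuple(agents),
        observation=ObservationModel(
            **{**d["observation"],
               "fix_times_local": tuple(d["observation"]["fix_times_local"])}),
        start_date=pd.Timestamp(d.get("start_date", STUDY_START)),
        end_date=pd.Timestamp(d.get("end_date", STUDY_END)),
        dt_h=float(d.get("dt_h", 1.0)),
        seed=int(d.get("seed", 0)),
    )


def save_scenario(scenario: Scenario, path) -> None:
    """Write a scenario as a plain-text YAML key-value file."""
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    import yaml
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def simulate_cohort(scenario: Scenario,
                    river: RiverNetwork | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full simulate-then-observe chain for every agent.

    Returns (telemetry, metadata, truth): telemetry holds the observed fixes
    of all individuals in the standard CSV layout plus truth columns;
    truth maps individual id to its generating regime and schedule.
    """
    if river is None:
        river = generate_river(scenario.river)
    base = (scenario.seed * 100_003 + 17) % 2**31
    frames, meta, truth = [], [], {}
    for i, agent in enumerate(scenario.agents):
        traj = simulate_agent(agent, river, scenario.start_date,
                              scenario.end_date, scenario.dt_h,
                              seed=(base + 2 * i) % 2**31)
        obs = observe_gps(traj, replace(scenario.observation,
                                        seed=(base + 2 * i + 1) % 2**31))
        obs.insert(0, "id", agent.id)
        frames.append(obs)
        meta.append({"id": agent.id, "sex": agent.sex,
                     "total_length_m": agent.total_length_m,
                     "snout_vent_length_m": round(agent.total_length_m / 2, 2)})
        truth[agent.id] = {
            "behaviour": agent.behaviour,
            "territory_centre_km": agent.territory_centre_km,
            "excursions": agent.excursion_schedule,
        }
    telemetry = pd.concat(frames, ignore_index=True)
    metadata = pd.DataFrame(meta)
    return telemetry, metadata, truth
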