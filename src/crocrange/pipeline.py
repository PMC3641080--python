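"""End-to-end orchestration: simulate → filter → rasterise → KUD → metrics →
classify → report.

``analyze_cohort`` runs every analysis stage for each individual of a
telemetry set against a river mask and returns all artefacts in memory;
``write_outputs`` serialises them (CSV tables, GeoJSON contours, a stage
log).  ``run_simulation`` materialises a synthetic scenario to the same
file formats the analysis consumes, so the two halves compose through
plain files exactly as a field study would.

The distance-from-centroid series is anchored at the centroid of the FIRST
analysis window's clipped KUD-50 (the early-season core area), so
late-season exploratory movement registers as distance from the breeding
range rather than shifting the reference point with it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .classify import (Excursion, StabilityCriterion, StrategyLabel,
                       classify_strategy, detect_excursions)
from .kud import (AnalysisWindows, KdeConfig, KudCentroid, MIN_FIXES,
                  VolumeContour, clip_to_river, cumulative_kuds, default_windows,
                  estimate_kde, kud_centroid, volume_contour)
from .metrics import (RomSummary, distance_from_centroid_series,
                      rate_of_movement, snap_track, step_distances)
from .raster import (MovementGraph, RiverMask, build_graph, rasterize_river,
                     write_ascii_grid)
from .report import group_summary
from .simulate import Scenario, simulate_cohort
from .telemetry import FilterConfig, filter_fixes, tracks, write_telemetry
from .river import generate_river

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable of the analysis half of the pipeline."""

    filter: FilterConfig = FilterConfig()
    kde: KdeConfig = KdeConfig()
    windows: AnalysisWindows = field(default_factory=default_windows)
    stability: StabilityCriterion = StabilityCriterion()
    excursion_multiplier: float = 3.0
    excursion_baseline: tuple[str, str] = ("2010-09-01", "2010-11-30")
    max_interval_h: float = 36.0
    compute_rom: bool = True             # step/ROM metrics are the slow stage
    detect_excursions_for_sex: str = "female"


@dataclass
class IndividualResult:
    id: str
    sex: str
    total_length_m: float
    removed_fraction: float
    n_fixes: int
    kud95: VolumeContour | None = None          # clipped, full study
    kud50: VolumeContour | None = None
    kud95_unclipped: VolumeContour | None = None
    kud50_unclipped: VolumeContour | None = None
    centroid: KudCentroid | None = None         # first-window KUD-50 centroid
    cumulative: pd.DataFrame | None = None
    strategy: StrategyLabel | None = None
    rom: RomSummary | None = None
    dist_series: pd.Series | None = None
    max_dist_centroid_km: float = float("nan")
    excursions: list[Excursion] = field(default_factory=list)
    mean_snap_m: float = float("nan")


@dataclass
class CohortResults:
    individuals: dict[str, IndividualResult]
    summary: pd.DataFrame
    groups: pd.DataFrame
    kud_areas: pd.DataFrame
    classification: pd.DataFrame
    excursions: pd.DataFrame
    mask: RiverMask


def _analyze_individual(aid: str, meta_row, track: pd.DataFrame,
                        mask: RiverMask, graph: MovementGraph,
                        cfg: AnalysisConfig) -> IndividualResult:
    retained, removed = filter_fixes(track, cfg.filter)
    retained = snap_track(retained, graph)
    res = IndividualResult(aid, str(meta_row["sex"]),
                           float(meta_row["total_length_m"]),
                           removed, len(retained))
    res.mean_snap_m = float(retained["snap_m"].mean())

    xy = retained[["x_m", "y_m"]].to_numpy()
    surface = estimate_kde(xy, cfg.kde, align_to=mask)
    res.kud95_unclipped = volume_contour(surface, 0.95)
    res.kud50_unclipped = volume_contour(surface, 0.50)
    res.kud95 = clip_to_river(res.kud95_unclipped, mask)
    res.kud50 = clip_to_river(res.kud50_unclipped, mask)

    res.cumulative = cumulative_kuds(retained, cfg.windows, cfg.kde, mask)
    res.strategy = classify_strategy(res.cumulative["kud95_km2"],
                                     cfg.stability)

    # centroid of the first-window core area anchors the distance series
    ts = pd.to_datetime(retained["timestamp"])
    end0 = cfg.windows.ends[0] + pd.Timedelta(days=1) - pd.Timedelta(seconds=1)
    first = retained[(ts >= cfg.windows.start) & (ts <= end0)]
    if len(first) >= MIN_FIXES:
        surf0 = estimate_kde(first[["x_m", "y_m"]].to_numpy(), cfg.kde,
                             align_to=mask)
        k50_0 = clip_to_river(volume_contour(surf0, 0.50), mask)
        res.centroid = kud_centroid(k50_0, surf0, mask, graph)
        res.dist_series = distance_from_centroid_series(retained,
                                                        res.centroid, graph)
        res.max_dist_centroid_km = float(res.dist_series.max())
    else:
        log.warning("%s: <%d fixes in the first window; no centroid metrics",
                    aid, MIN_FIXES)

    if cfg.compute_rom:
        steps = step_distances(retained, graph, cfg.max_interval_h)
        res.rom = rate_of_movement(steps)

    if (res.dist_series is not None
            and res.sex == cfg.detect_excursions_for_sex):
        res.excursions = detect_excursions(
            res.dist_series, cfg.excursion_baseline[0],
            cfg.excursion_baseline[1], cfg.excursion_multiplier)
    return res


def analyze_cohort(telemetry: pd.DataFrame, metadata: pd.DataFrame,
                   mask: RiverMask,
                   cfg: AnalysisConfig = AnalysisConfig()) -> CohortResults:
    """Run the full analysis for every individual in a telemetry set."""
    graph = build_graph(mask)
    meta = metadata.set_index("id")
    individuals: dict[str, IndividualResult] = {}
    for aid, track in tracks(telemetry):
        if aid not in meta.index:
            raise ValueError(f"individual {aid!r} missing from metadata")
        log.info("analysing %s (%d raw fixes)", aid, len(track))
        individuals[aid] = _analyze_individual(
            aid, meta.loc[aid], track, mask, graph, cfg)

    summary_rows, area_rows, class_rows, exc_rows = [], [], [], []
    for aid, res in individuals.items():
        strategy = ""
        if res.sex == "male" and res.strategy is not None:
            strategy = res.strategy.label
        summary_rows.append({
            "id": aid, "sex": res.sex, "total_length_m": res.total_length_m,
            "day_rom_m_per_h": res.rom.day_rom_m_per_h if res.rom else np.nan,
            "night_rom_m_per_h": res.rom.night_rom_m_per_h if res.rom else np.nan,
            "total_distance_km": res.rom.total_distance_km if res.rom else np.nan,
            "kud95_km2": res.kud95.area_km2 if res.kud95 else np.nan,
            "kud50_km2": res.kud50.area_km2 if res.kud50 else np.nan,
            "max_dist_centroid_km": res.max_dist_centroid_km,
            "strategy": strategy,
            "removed_fraction": res.removed_fraction,
            "reduction95_percent": (res.kud95.reduction_percent
                                    if res.kud95 else np.nan),
            "reduction50_percent": (res.kud50.reduction_percent
                                    if res.kud50 else np.nan),
        })
        if res.cumulative is not None:
            cum = res.cumulative.copy()
            cum.insert(0, "id", aid)
            area_rows.append(cum)
        if res.strategy is not None:
            class_rows.append({
                "id": aid, "label": res.strategy.label,
                "growth_stat": res.strategy.growth_stat,
                "tau": res.strategy.tau,
                "windows_used": res.strategy.windows_used,
            })
        for e in res.excursions:
            exc_rows.append({
                "id": aid, "start": e.start, "end": e.end,
                "peak_dist_km": e.peak_dist_km, "duration_h": e.duration_h,
                "returned": e.returned,
            })

    summary = pd.DataFrame(summary_rows)
    groups = group_summary(summary)
    return CohortResults(
        individuals=individuals,
        summary=summary,
        groups=groups,
        kud_areas=(pd.concat(area_rows, ignore_index=True)
                   if area_rows else pd.DataFrame()),
        classification=pd.DataFrame(class_rows),
        excursions=pd.DataFrame(
            exc_rows, columns=["id", "start", "end", "peak_dist_km",
                               "duration_h", "returned"]),
        mask=mask,
    )


def _contour_geojson(results: CohortResults) -> dict:
    features = []
    for aid, res in results.individuals.items():
        for level, cont in ((0.95, res.kud95), (0.50, res.kud50)):
            if cont is None:
                continue
            rr, cc = np.nonzero(cont.cells)
            cell = cont.cell_size_m
            x0 = cont.origin_x + cc * cell
            y0 = cont.origin_y + rr * cell
            boxes = shapely.box(x0, y0, x0 + cell, y0 + cell)
            geom = shapely.coverage_union_all(boxes)
            features.append({
                "type": "Feature",
                "properties": {"id": aid, "level": level, "clipped": True,
                               "area_km2": cont.area_km2},
                "geometry": json.loads(shapely.to_geojson(geom)),
            })
    return {"type": "FeatureCollection", "features": features}


def write_outputs(results: CohortResults, out_dir) -> None:
    """Serialise every analysis artefact to ``out_dir``."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.summary.to_csv(out / "summary.csv", index=False)
    results.groups.to_csv(out / "groups.csv", index=False)
    results.kud_areas.to_csv(out / "kud_areas.csv", index=False)
    results.classification.to_csv(out / "classification.csv", index=False)
    results.excursions.to_csv(out / "excursions.csv", index=False)
    with open(out / "contours.geojson", "w") as fh:
        json.dump(_contour_geojson(results), fh)
    with open(out / "pipeline.log", "w") as fh:
        for aid, res in results.individuals.items():
            fh.write(
                f"{aid}: fixes_retained={res.n_fixes} "
                f"removed_fraction={res.removed_fraction:.4f} "
                f"mean_snap_m={res.mean_snap_m:.1f} "
                f"reduction95={res.kud95.reduction_percent:.1f}% "
                f"reduction50={res.kud50.reduction_percent:.1f}%\n")


def run_simulation(scenario: Scenario, out_dir) -> dict:
    """Materialise a synthetic scenario: telemetry, metadata, river, truth."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    river = generate_river(scenario.river)
    telemetry, metadata, truth = simulate_cohort(scenario, river)
    write_telemetry(telemetry, out / "fixes.csv")
    metadata.to_csv(out / "metadata.csv", index=False)
    mask = rasterize_river(river.polygon)
    write_ascii_grid(mask, out / "river_mask.asc")
    with open(out / "river.geojson", "w") as fh:
        fh.write(shapely.to_geojson(river.polygon))
    truth_df = pd.DataFrame(
        [{"id": aid, "behaviour": t["behaviour"],
          "territory_centre_km": t["territory_centre_km"],
          "n_excursions": len(t["excursions"])}
         for aid, t in truth.items()])
    truth_df.to_csv(out / "truth.csv", index=False)
    return {"river": river, "mask": mask, "telemetry": telemetry,
            "metadata": metadata, "truth": truth}
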