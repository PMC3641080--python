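"""Along-river movement metrics: steps, rates of movement, centroid distances.

All distances are least-cost paths through the water-cell graph, so a step
between two fixes is the minimum distance the animal must have swum along
the river.  Fix-to-fix intervals inherit a day/night label from the CLOCK
TIME OF THE CLOSING FIX: under the twice-daily schedule the 08:00 fix
closes the 14 h night interval and the 18:00 fix closes the 10 h day
interval.  Rates of movement (ROM, m/h) divide each interval's distance by
its actual duration; intervals longer than a configurable gap threshold
(default 36 h, i.e. more than two missed fixes) are excluded from ROM means
but still count toward the total distance moved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kud import KudCentroid, VolumeContour
from .raster import MovementGraph

DAY_CLOSE_START_H = 8    # a closing fix with 8 < hour <= 18 closes a day interval
DAY_CLOSE_END_H = 18


def snap_track(track: pd.DataFrame, graph: MovementGraph) -> pd.DataFrame:
    """Attach graph node and snap distance columns to a track."""
    nodes, snap_d = graph.snap(track[["x_m", "y_m"]].to_numpy())
    out = track.copy()
    out["node"] = nodes
    out["snap_m"] = snap_d
    return out


def _interval_label(ts: pd.Timestamp) -> str:
    return "day" if DAY_CLOSE_START_H < ts.hour <= DAY_CLOSE_END_H else "night"


def step_distances(track: pd.DataFrame, graph: MovementGraph,
                   max_interval_h: float = 36.0) -> pd.DataFrame:
    """Along-river distances between consecutive fixes of one individual.

    ``track`` must carry a ``node`` column (see :func:`snap_track`).
    Returns one row per consecutive pair: closing timestamp, duration,
    distance, day/night label and a gap flag for intervals longer than
    ``max_interval_h``.
    """
    if "node" not in track.columns:
        raise ValueError("track must be snapped first (snap_track)")
    track = track.sort_values("timestamp", kind="stable")  # canonical order
    t = pd.to_datetime(track["timestamp"]).reset_index(drop=True)
    nodes = track["node"].to_numpy()
    rows = []
    for i in range(1, len(track)):
        dur_h = (t[i] - t[i - 1]).total_seconds() / 3600.0
        dist = 0.0 if nodes[i] == nodes[i - 1] else float(
            graph.distances_from(int(nodes[i - 1]))[int(nodes[i])])
        rows.append({
            "t_start": t[i - 1], "t_end": t[i], "duration_h": dur_h,
            "distance_m": dist, "label": _interval_label(t[i]),
            "is_gap": dur_h > max_interval_h,
        })
    return pd.DataFrame(rows, columns=["t_start", "t_end", "duration_h",
                                       "distance_m", "label", "is_gap"])


@dataclass(frozen=True)
class RomSummary:
    day_rom_m_per_h: float
    night_rom_m_per_h: float
    total_distance_km: float
    daily_rom_km_per_day: pd.Series   # indexed by calendar date


def rate_of_movement(steps: pd.DataFrame) -> RomSummary:
    """Day/night mean ROM, total distance, and the daily-distance series.

    ROM per interval = distance / actual duration; the per-label value is
    the mean over valid (non-gap) intervals, NaN when a label has none.
    Daily ROM sums each calendar day's valid interval distances (km/day,
    attributed to the closing fix's date).  Total distance includes gaps.
    """
    total_km = float(steps["distance_m"].sum()) / 1000.0 if len(steps) else 0.0
    valid = steps[~steps["is_gap"]]
    roms = {}
    for label in ("day", "night"):
        sub = valid[valid["label"] == label]
        roms[label] = float((sub["distance_m"] / sub["duration_h"]).mean()) \
            if len(sub) else float("nan")
    if len(valid):
        daily = (valid.groupby(valid["t_end"].dt.date)["distance_m"].sum()
                 / 1000.0)
    else:
        daily = pd.Series(dtype=float)
    return RomSummary(roms["day"], roms["night"], total_km, daily)


def distance_from_centroid_series(track: pd.DataFrame, centroid: KudCentroid,
                                  graph: MovementGraph) -> pd.Series:
    """Along-river distance (km) of every fix from the KUD-50 centroid.

    ``track`` must be snapped.  The series is indexed by fix timestamp; its
    maximum is the "max distance from centroid" summary value.
    """
    if "node" not in track.columns:
        raise ValueError("track must be snapped first (snap_track)")
    track = track.sort_values("timestamp", kind="stable")
    cnode = int(graph.node_id[centroid.row, centroid.col])
    if cnode < 0:
        raise ValueError("centroid does not lie on a graph water cell")
    dist = graph.distances_from(cnode)
    vals = dist[track["node"].to_numpy()] / 1000.0
    return pd.Series(vals, index=pd.to_datetime(track["timestamp"]),
                     name="dist_from_centroid_km")


def pairwise_overlap(a: VolumeContour, b: VolumeContour) -> tuple[float, float]:
    """Percentage overlap of two contours, in both directions.

    Returns (overlap of a on b, overlap of b on a) where
    ``overlap(a|b) = 100 * area(a ∩ b) / area(a)``.  Contours may live on
    different (lattice-aligned) grids.
    """
    if abs(a.cell_size_m - b.cell_size_m) > 1e-9:
        raise ValueError("contours use different cell sizes")
    ca, cb = a.global_cells(), b.global_cells()
    if not ca or not cb:
        raise ValueError("empty contour")
    inter = len(ca & cb)
    return 100.0 * inter / len(ca), 100.0 * inter / len(cb)
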