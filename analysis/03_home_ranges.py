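"""Fixed-kernel home ranges clipped to the river channel.

For every individual: the full-study KUD 95%/50% volume contours (h =
750 m, 50 m grid), their river-clipped areas and clipping reductions, the
cumulative monthly area series, and the first-window KUD-50 centroid that
anchors the distance-from-centroid metrics.  Writes home_ranges.csv,
kud_areas.csv and centroids.csv under results/.
"""

from pathlib import Path

import pandas as pd

from crocrange import (KdeConfig, build_graph, clip_to_river, cumulative_kuds,
                       default_windows, estimate_kde, kud_centroid,
                       read_ascii_grid, tracks, volume_contour)
from crocrange.kud import MIN_FIXES

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    mask = read_ascii_grid(ROOT / "sim" / "river_mask.asc")
    graph = build_graph(mask)
    fixes = pd.read_csv(ROOT / "filtered_fixes.csv",
                        parse_dates=["timestamp"])
    cfg, windows = KdeConfig(), default_windows()

    ranges, areas, centroids = [], [], []
    for aid, track in tracks(fixes):
        surface = estimate_kde(track[["x_m", "y_m"]].to_numpy(), cfg,
                               align_to=mask)
        k95 = clip_to_river(volume_contour(surface, 0.95), mask)
        k50 = clip_to_river(volume_contour(surface, 0.50), mask)
        ranges.append({"id": aid, "kud95_km2": k95.area_km2,
                       "kud50_km2": k50.area_km2,
                       "reduction95_percent": k95.reduction_percent,
                       "reduction50_percent": k50.reduction_percent})
        cum = cumulative_kuds(track, windows, cfg, mask)
        cum.insert(0, "id", aid)
        areas.append(cum)

        ts = track["timestamp"]
        first = track[ts <= windows.ends[0] + pd.Timedelta(days=1, seconds=-1)]
        if len(first) >= MIN_FIXES:
            surf0 = estimate_kde(first[["x_m", "y_m"]].to_numpy(), cfg,
                                 align_to=mask)
            c = kud_centroid(clip_to_river(volume_contour(surf0, 0.50), mask),
                             surf0, mask, graph)
            centroids.append({"id": aid, "row": c.row, "col": c.col,
                              "x": c.x, "y": c.y})
        print(f"{aid}: KUD95 {k95.area_km2:.1f} km2 "
              f"(clipping -{k95.reduction_percent:.0f}%), "
              f"KUD50 {k50.area_km2:.1f} km2 "
              f"(-{k50.reduction_percent:.0f}%)")

    pd.DataFrame(ranges).to_csv(ROOT / "home_ranges.csv", index=False)
    pd.concat(areas, ignore_index=True).to_csv(ROOT / "kud_areas.csv",
                                               index=False)
    pd.DataFrame(centroids).to_csv(ROOT / "centroids.csv", index=False)
    mean95 = pd.DataFrame(ranges)["reduction95_percent"].mean()
    mean50 = pd.DataFrame(ranges)["reduction50_percent"].mean()
    print(f"mean clipping reduction: KUD95 {mean95:.1f}% (study 90.7±4.1), "
          f"KUD50 {mean50:.1f}% (study 71.4±3.2)")


if __name__ == "__main__":
    main()
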