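# crocrange

River-constrained home-range analysis for GPS-tracked estuarine crocodiles
(*Crocodylus porosus*), with a synthetic river-and-movement simulator that
makes every stage of the pipeline verifiable against a known ground truth.

## The problem

Estuarine crocodiles live in branching tidal rivers, so their space use is
one-dimensional in character but recorded as planar GPS fixes.  Naive
home-range estimators smear probability mass across land the animal cannot
occupy, and straight-line movement metrics undersell how far an animal must
actually swim.  This package implements the analysis chain used to study
breeding-season space use from twice-daily GPS telemetry:

1. **Quality filtering** — fixes with satellite dilution of precision
   (SDOP) above 3 are dropped (stationary tests put sub-3 accuracy at
   ~12 m); the removed fraction is reported.
2. **Kernel utilisation distributions (KUD)** — a fixed-kernel density
   estimate with smoothing parameter *h* = 750 m on a 50 m grid.  The
   "KUD 95%"/"KUD 50%" are the smallest cell sets containing 95%/50% of
   the UD mass (volume contours).
3. **River clipping** — contours are intersected with a 50 m boolean
   raster of the channel, removing inaccessible habitat; the percentage
   reduction is reported.
4. **Along-river metrics** — water cells form an 8-connected graph with
   centre-to-centre edge weights; step distances, day/night rates of
   movement (ROM, m/h) and distances from the KUD-50 centroid are
   shortest paths through that graph, never crossing land.
5. **Strategy classification** — an individual is *site-fidelic* when its
   cumulative monthly KUD-95 area grows ≤ 15% over the last three of six
   monthly windows, *nomadic* otherwise.
6. **Excursion detection** — female nesting trips appear as runs of fixes
   more than 3× the breeding-season (Sep–Nov) 95th-percentile distance
   from the KUD-50 centroid; a run that ends before the record does is a
   returning trip, an open run is a permanent relocation.

Because the original field data are not public, the package ships a
synthetic-data module (`crocrange.river`, `crocrange.simulate`) that
generates a branching estuarine river and simulates the three behavioural
regimes of the study — site-fidelic males, nomadic males, and breeding
females with scheduled nesting excursions — under the study's observation
model (fixes at 08:00/18:00, 12 m error on good fixes, 7% poor fixes).
The published per-individual summary table is packaged verbatim
(`crocrange.report.load_table1`) for the group-statistics stage.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (12 animals, 181 days, seed 42) and write their tables under
`results/`:

```bash
python analysis/01_simulate_cohort.py    # river + telemetry + truth
python analysis/02_filter_fixes.py       # SDOP filter
python analysis/03_home_ranges.py        # KUDs, clipping, centroids
python analysis/04_movement_metrics.py   # along-river ROM and distances
python analysis/05_classify_strategies.py
python analysis/06_group_summaries.py
```

`02` prints `pooled SDOP removal: 7.09% (study: 7.1±0.4%)`; `03` ends with
`mean clipping reduction: KUD95 89.4% (study 90.7±4.1)` — clipping an
*h* = 750 m kernel to a ~300 m channel removes almost all of its area.
`05` prints one line per animal, e.g.

```
NM2: nomadic       growth +0.63 (truth nomadic)
SM5: site_fidelic  growth -0.03 (truth site_fidelic)
F3: round trip 2010-12-13 -> 2010-12-15, peak 55.4 km
F3: relocation 2011-01-03 -> 2011-02-28, peak 55.9 km
male labels recovered: 8/8; 7 excursions detected (scheduled: 7)
```

i.e. every male's generating strategy is recovered from the cumulative
KUD-95 series alone, and each female's scheduled reconnaissance trip and
final nesting relocation are found with the correct returned-flag.

The same pipeline is exposed as a CLI:

```bash
crocrange simulate --seed 42 --out sim/
crocrange analyze --telemetry sim/fixes.csv --metadata sim/metadata.csv \
                  --river sim/river_mask.asc --out out/
crocrange table1-check        # group statistics over the packaged table
```

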