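# Methods

## Space-use model

The utilisation distribution of an individual is estimated with the fixed
kernel method: an isotropic bivariate Gaussian of standard deviation
*h* = 750 m centred on every retained fix, evaluated at the centres of a
50 m grid and normalised to unit mass.  The choice of a fixed, fairly
large *h* follows the logic of the original study system: data-driven
selectors misbehave on river-confined points (least-squares cross
validation fragments the range into disjoint islands, the reference
bandwidth inflates it far beyond the outermost fixes), while 750 m yields
a contiguous band along the channel.  Both selectors are available as
diagnostics (`reference_bandwidth`, `lscv_score`) but are never defaults.

Volume contours are defined on the grid: cells are accumulated in
decreasing density order (ties broken by row, then column) until the
target mass fraction is reached.  A contour is therefore a cell set; its
area is the cell count times 2 500 m².  Contours are computed first and
intersected with the river raster afterwards (contour-then-clip), and both
the clipped area and the percentage reduction are reported.  The KUD-50
centroid is the density-weighted mean of the clipped KUD-50 cell centres,
snapped to the nearest water cell so it can serve as a graph source; a
geometric (unweighted) variant is available.

Along-river distances are shortest paths through the water-cell graph:
8-connectivity with √2-weighted diagonals (pure 4-connectivity
systematically overestimates distances along sinuous channels).  Fixes
that fall on land through GPS error are snapped to the nearest water cell
of the largest connected component, ties resolved to the lowest (row,
column), and the snap distance is kept for quality control rather than
discarding the fix.

Movement intervals inherit a day/night label from the clock time of the
closing fix: under the 08:00/18:00 schedule the 08:00 fix closes the 14 h
night interval and the 18:00 fix the 10 h day interval.  Rates of
movement divide each interval's along-river distance by its actual
duration; intervals longer than 36 h (two or more missed fixes) are
excluded from ROM means, because a long gap hides back-and-forth movement
and would bias speed downward, but still count toward total distance.
The distance-from-centroid series is anchored at the centroid of the
*first* monthly window's clipped KUD-50 — the early-season core area — so
that late-season exploration registers as distance from the breeding
range instead of dragging the reference point along.

## Classification and excursions

Stability of the cumulative home range is operationalised as relative
tail growth: with cumulative clipped KUD-95 areas *A₁…A₆* over the six
monthly windows, the statistic is (A₆ − A₃)/A₃ and an individual is
site-fidelic iff it is ≤ τ = 0.15 (τ and the tail length are
configurable and reported with every label; the criterion in the source
study was visual).  The statistic is scale-invariant and monotone in τ.

Excursions are maximal runs of the distance-from-centroid series above
3× the 95th percentile of its Sep–Nov baseline (the breeding season,
before the nesting period).  The multiplier-of-baseline form adapts the
threshold to each female's range size; `returned` distinguishes round
trips from permanent relocations by whether the series comes back below
threshold before the record ends.  Nesting itself is not inferred — the
pipeline reports the movements neutrally.

## Synthetic data: what it emulates, and what it does not

The simulator provides ground-truthed inputs in place of the undeposited
field data.  Movement is one-dimensional along the river centreline
(mapped to planar coordinates afterwards), mirroring channel-confined
movement:

* **Site-fidelic males and (outside excursions) females** follow a
  discrete mean-reverting (Ornstein–Uhlenbeck-type) walk about a
  territory centre.  The autoregression is parameterised by a
  range-crossing time (default 12 h), so the territory is traversed on a
  sub-daily scale — the patrolling behaviour that makes a real cumulative
  KUD-95 stabilise within the first month — and the stationary SD equals
  `territory_scale_km` (default 2 km for males, 0.5 km for females, whose
  breeding ranges span under a kilometre of river).  Day/night step
  scales set the diurnal contrast of the innovation variance.
* **Nomadic males** follow a persistent directional walk over the whole
  junction graph: per-hour direction-keeping probability 0.995 (multi-day
  unidirectional legs), reflection at channel ends, and branch choice at
  confluences biased to the least-traversed incident edge (uniform among
  ties; a plain uniform rule is available via `branch_bias`).  The bias
  encodes sustained mate-searching: without it a bounded network makes
  the walk recurrent and a noticeable fraction of nomads settle, losing
  the defining non-stabilising cumulative-range signature.
* **Breeding females** add scheduled excursions: directed travel at
  2 500 m/h to an on-river destination, a dwell, and either a return leg
  or a permanent shift of the attraction centre (nesting).  The default
  schedule places one returning reconnaissance trip and one final
  relocation per female in Dec–Jan (destinations 22–54 km away, one
  40 km upstream), matching the study's phenology.

The default river is 150 km of meandering main channel plus six 50 km
tributaries (450 km of network, 300 m channel width).  The network is
deliberately much larger than a nomad's six-month exploration span;
on a small network every regime eventually saturates and the regimes
become indistinguishable.  Observation draws fixes at 08:00 and 18:00
local, adds isotropic Gaussian error (SD 12 m), and flags 7% of fixes as
poor quality (SDOP > 3, error SD 250 m — large enough that filtering
measurably improves accuracy).

Simulator parameters were calibrated only to reproduce the qualitative
regime signatures (stable vs growing cumulative ranges, low female
mobility, Dec–Jan excursion spikes), not the published per-individual
magnitudes; simulated home-range areas and ROM values therefore differ
from the published table, and passing tests demonstrate that the
*pipeline* recovers generating structure, not that the simulator
reproduces the real river system.  Not modelled at all: tides, salinity,
agent interactions, energetics, real geography.

## Numerical choices

* KDE grids cover the fix bounding box padded by 4 h (tail mass loss
  < 10⁻⁴) and are registered on the river-mask lattice so clipping is an
  exact cell-wise intersection.  Kernels are truncated at 8 SD
  (contribution < 10⁻¹⁴ of the peak); the truncation-free path is exact
  against a double-loop oracle to 10⁻¹⁰ relative.
* Surfaces need ≥ 5 fixes; cumulative windows below that emit missing
  values with a warning, and classification needs k_tail + 1 usable
  windows.
* Rasterisation marks a cell as water iff its centre lies inside the
  channel polygon; fragmented masks warn and analyses use the largest
  8-connected component.
* Shortest paths use Dijkstra on a sparse symmetric weight matrix with a
  small per-graph cache of single-source solutions; identical values are
  returned regardless of caching.
* Group statistics report mean and SE with SE = sample SD (n−1
  denominator)/√n; single-member groups report a missing SE.

## Problem sizes

The recovery experiment runs 20 independent cohorts of 12 agents × 362
scheduled fixes on freshly generated rivers (≈ 3.5 min on one CPU);
recovery is scored as the fraction of males whose generating strategy
label is returned and the fraction of scheduled excursions detected with
the correct returned-flag.  Unit and property tests use small analytic
masks (straight rectangles, L-shapes, U-shapes) and a 20 km mini-cohort.

## Known limitations

* The movement graph is cell-based; distances are discretisation-exact
  only up to the 50 m lattice (≈ 8% corridor inflation worst-case on
  diagonal channels).
* The day/night interval labelling is a convention; with missed fixes an
  interval can span both periods yet carries a single label.
* The stability threshold τ = 0.15 is a design choice on a continuous
  statistic; individuals near the boundary flip under resampling, which
  is why labels always carry their growth statistic.
* Published group SEs are not always recoverable from the published
  per-individual table; only group means are used as fixed points.
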