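# Methods

## Scope and design

The package covers the computation around droplet-array experiments on an
active-matrix EWOD chip: planning (step-cost models, activation schedules,
routing) and analysis (segmentation, uniformity, split success, cell
occupancy, detector metrics). It deliberately excludes what lives in
hardware or trained weights: electrowetting physics, TFT drive
electronics, and neural-network training. Wherever a deep model would sit
in a production pipeline (droplet segmentation, droplet/cell detection)
the package defines a plain data contract — `image → integer label mask`,
or a list of center-format boxes — and ships a classical reference backend
behind it, so the downstream analytics are exercised end to end and any
trained model can be swapped in.

## Coordinate and area conventions

All modules share one convention: pixel coordinates, origin top-left, x
rightward, y downward; pixel `(row i, col j)` covers the half-open square
`[j, j+1) × [i, i+1)`, so its center is `(j+0.5, i+0.5)`. Boxes and
centroids are continuous. The authoritative per-droplet area is the pixel
count of its label; the shoelace area of the traced boundary (vertices on
half-integer positions) is reported alongside and may differ by the
boundary discretisation. One authoritative area matters because the
uniformity statistic is a ratio of moments of exactly these areas.

## Synthetic scenes

`synth.render_scene` emulates a camera view of a droplet array:
disc-shaped droplets of roughly one-electrode footprint over a periodic
grid-line background, a thin slightly darker rim per droplet, small dark
cells inside droplets, then Gaussian blur and additive Gaussian sensor
noise, clipped to [0, 1]. Ground truth is exhaustive: label mask,
per-droplet center/radius/area, per-cell coordinates and owning droplet,
and tight bounding boxes (w = h = 2r) for droplets and cells.

Randomness uses one `SeedSequence` per scene with four spawned substreams
(radii, cell counts, placement, noise), so truth is reproducible and
independent of draw order. Cell counts are Poisson(λ) per droplet —
the standard model for passive encapsulation; λ defaults to 1.3, which
puts the single-cell fraction λ·e^(−λ) near 35% and, at the published
scale, is the regime in which roughly a quarter to a third of droplets
hold exactly one cell. Cells are placed uniformly in the disc eroded by
the cell radius plus 3 px so the blurred rim is never broken by a cell.

Default visual parameters (pitch 16 px, radius 7 px, radius CV 3%,
brightness 0.25/0.85, rim at 75% of the contrast, blur 1 px, noise 0.02)
were chosen once so that the classical segmentation chain recovers the
truth with a wide margin (per-droplet area within 2%, centroids within
0.2 px on easy scenes); all are overridable. `merged_ids` renders chosen
droplets at double footprint area (radius ×√2), emulating failed splits
exactly — this drives the split-success recovery tests. The generator
refuses overlapping discs (naming the colliding pair) unless
`allow_contact=True`.

What the generator does *not* emulate: reflective vs transparent electrode
optics, illumination gradients, real droplet shape irregularity, debris,
and focus variation. Tests passing on these scenes therefore demonstrate
correctness of the analytics and the recovery of generator parameters,
not robustness to real chip imagery.

## Segmentation

The classical chain: global threshold (Otsu, or fixed), optional
inversion, morphological opening/closing (disk radius 1), hole filling
(cells are darker than the droplet interior and would otherwise punch
holes), small-component removal (default 20 px), and an optional
distance-transform watershed for touching droplets whose seeds are local
maxima separated by at least half the median equivalent radius. Labels are
renumbered 1..K in raster order of first pixel so output is deterministic.
A uniform image yields an all-zero mask (not an error); non-finite pixels
are an error. Ellipses are least-squares conic fits to the traced
boundary; labels with fewer than five distinct boundary vertices carry no
ellipse.

## Uniformity

Parallel-plate volume model: a droplet squeezed between the two plates
occupies its footprint area times the gap, `V = A·(pitch_um/pitch_px)²·gap·1e-6`
nanolitres. A 100 µm electrode footprint under a 200 µm gap is 2 nL. The
cohort statistic is the sample (n−1) CV in percent — appropriate for the
small cohorts (n = 16) of one split array — and is invariant to the
calibration since volume is proportional to area under constant gap.
Absolute volumes need `pitch_um` and `gap_um` from the chip config; the
gap of any particular chip is a measured quantity, not something the
package can infer.

## Split success

Verdicts are a pure area-band rule on the segmentation's pixel-count
areas. The default band `[0.5, 1.5]·nominal` sits halfway between the 1×
and 2× populations, so a 2× merge can only fail; a one-sided variant
(only oversized droplets fail) is available. The nominal area estimator is
the median, robust as long as merges are a minority. Success rate is
`100·n_success/n`.

## Cell counting

Membership is center containment (point-in-polygon via shapely for
contours, point-in-box for boxes) — cells are small relative to droplets,
and this matches how a point annotation is judged. A cell inside no
droplet increments `unassigned_cells`; a cell inside several (overlap
pathology) goes to the nearest centroid. Occupancy is reported in bins
{0, 1, 2, >2}; section reports partition droplet ids exactly and are
bin-wise additive. With ground-truth inputs the report is exact — no
statistical tolerance.

## Detection metrics

IoU is computed on continuous box geometry. NMS is class-wise greedy by
descending confidence (threshold default 0.45, the common detector
default). Matching is greedy in confidence order against the unmatched
same-class ground truth of highest IoU ≥ threshold, ties to the lower
ground-truth index — the detection-community convention. Greedy matching
can differ from the exhaustive maximum matching by a pair on adversarial
overlaps; the test suite bounds the difference (≤ 1 on random 20-box
instances) using scipy's maximum bipartite matching as the oracle. AP is
the area under the precision envelope versus recall over all observed
confidence thresholds (all-point interpolation; a fixed-grid 101-point
variant is available via `n_points`), and mAP averages classes and the
IoU ladder 0.50:0.05:0.95. Confusion matrices are built from
class-agnostic IoU matching so class confusions land off-diagonal, with
`background` row/column for misses and false alarms; the confusion-matrix
IoU threshold defaults to 0.5.

## Step-count models and schedules

The models are linear in the subdroplet count for the squeezing
(4 tear steps + 1 wait per droplet, plus one initial step: `5x+1`) and
one-to-three (2 + 4 waits: `6x+1`) strategies, and a measured ladder
`{1:1, 2:2, 4:6, 8:10, 16:13}` for one-to-two, whose droplet count doubles
each round. Outside their stated domains (`0 < x ≤ 16`; ladder x) the
model functions raise.

Each strategy compiles to explicit activation maps. The simulator is a
cellular abstraction, not fluid dynamics: a droplet is a 4-connected set
of electrodes carrying a scalar volume; per step it re-wets the activated
electrodes within one electrode of its support (no activation in reach =
rest), a support torn into disconnected components splits with volume
shared by component size, and supports that come within 8-adjacency merge.
Its only contract is count/position/merge correctness, which is what
validating a schedule needs. Volume is conserved exactly through moves,
splits, and merges.

The shipped schedules are reconstructions (only the end states and step
totals are fixed by the models): squeezing and one-to-three run along one
electrode row — extend the reservoir, tear off a subdroplet two electrodes
clear of it, retract five electrodes, wait — depositing subdroplets at
five-electrode center spacing; one-to-two runs on a 16×16 electrode patch
as stretch-and-tear rounds (the droplet is elongated across electrodes and
torn in the middle, the physical signature of that strategy), ending on a
4×4 lattice at five-electrode spacing in exactly 13 steps for x = 16.
Waits are explicit empty activation maps so step accounting matches the
models. `build_schedule` refuses grids smaller than the schedule's
footprint (reporting the minimum), simulates every plan before returning
it, and asserts the final count, the ≥ 4-electrode pairwise separation,
and the model step count. During a run the enforced safety property is
"never within merging range" (8-adjacency); a freshly torn subdroplet
necessarily sits about two electrodes from its reservoir, so the full
working spacing holds at the end state, not at every intermediate step.
For x outside the ladder, a generalized doubling-then-trim schedule runs
the next ladder plan but withholds the final tear for the surplus
droplets; its step count is reported, not asserted against the ladder.
The schedules realize the four-electrode working spacing; other spacings
are not compiled.

## Routing

Assignment minimizes total Manhattan distance (Hungarian algorithm, with
an index-ordered epsilon tie-break for determinism). Paths come from
prioritized planning — longest-distance droplet first — with per-droplet
space-time A* (4-neighbour moves or wait) against a reservation table of
already-planned trajectories; droplets park at their targets, and a goal
is accepted only if it stays clear of every reserved trajectory for the
rest of the horizon. Deadlocks trigger priority rotation (8 retries)
before an error naming the blocked droplet. Prioritized planning was
chosen over optimal multi-agent search because chips are large (640×280
electrodes) and droplet counts modest; no optimality is claimed, only the
validated lower bound makespan ≥ max Manhattan distance. The default
`min_separation` of 2 (Chebyshev) is exactly "no 8-adjacency", the merge
condition of the droplet model; it is configurable up to the 4-electrode
working spacing. `validate_plan` replays any plan step-synchronously and
returns violations as data, and every plan the planner emits is replayed
through it in the tests.

## Dataset bookkeeping

`split_dataset` shuffles indices with a seeded generator and assigns
`round(0.2·n)` (half-up) each to validation and test, remainder to train —
the only simple rounding rule consistent with the published
3234 → 1940/647/647, 5083 → 3049/1017/1017 and 4046 → 2428/809/809 rows.

## Problem sizes used in the tests

The suite runs on scenes of 16 droplets (default pipeline checks), one
10⁴-droplet scene for occupancy statistics (3σ Poisson bands), 500+
random box instances for the metric oracles, all x ≤ 16 for every
schedule, and routing instances up to 16 droplets on a 40×40 grid — sizes
at which the brute-force oracles (exhaustive assignment, O(n²)
suppression, maximum matching) remain exact and fast.

## Known limitations

- The classical segmenter is tuned for high-contrast, well-separated
  discs; it is a reference backend, not a competitor to a trained model on
  real imagery.
- The grid simulator has no notion of droplet inertia, contact-angle
  hysteresis, or partial electrode wetting; schedules validated here still
  need hardware timing validation.
- One-to-two intermediate droplet positions are a reconstruction
  constrained by the end state and the step ladder.
- Routing is sequentialized-concurrent (all droplets move each step) with
  no online replanning.
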