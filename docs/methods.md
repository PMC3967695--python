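# Methods

## Coordinate frame and geometry

All geometry lives in a local tangent plane centred on the radar: x east,
y north, metres.  Polar fixes (compass bearing θ clockwise from north,
range ρ) project as (ρ sin θ, ρ cos θ); at a 6-km scene radius the error
from ignoring Earth curvature is far below the radar's 35-m range
resolution.  A trajectory is the two-segment polyline through its
start/mid/end fixes.

The farm perimeter is the convex hull of the turbine coordinates.  The true
perimeter ring of a farm is rarely published, and the hull is the canonical
simple closed ring containing every turbine; an explicit user ring can be
passed to `FarmPolygon` to override it.  Intersection uses closed-region
semantics — crossing the boundary, touching it, or lying entirely inside
all count — which is tie-free for continuous random inputs and stated for
determinism on constructed cases.  Each trajectory contributes at most one
intersection to the index ("how many trajectories intersected"), matching
a count of 90 events against 193 trajectories; a per-crossing-event count
is available behind `per_crossing_counting` for sensitivity analysis.
Degenerate (zero-length) trajectories are retained, contribute 0 km and —
if their point lies inside the polygon — one intersection, and are listed
in the run report.

Segment–polygon predicates are delegated to shapely 2 (vectorized,
prepared geometries).  The test suite arbitrates them against an
independent brute-force oracle: even–odd ray casting plus dense sampling
along each segment at 0.1 m spacing.

## Null models and the randomization test

Models 1–3 and 5 sample free points uniformly *by area* in the detection
disk (radius R·√u at a uniform angle).  Uniform-in-disk is the
least-informative placement consistent with "completely random trajectories
within the detection radius".  Model 4's mid-point is uniform in the
axis-aligned bounding rectangle of the retained start and end; when those
share a coordinate the rectangle degenerates and the draw collapses to the
segment (or the shared point) naturally.  Model 5's "south of both" is y
strictly less than min(y_start, y_mid), implemented by rejection sampling
inside the disk with a 10⁶-attempt guard; the feasible region is empty only
when a retained point sits on the southern rim, which raises an error.
Simulated trajectories may exit the disk between retained and free points;
only generated points are constrained to it.

Each replicate's index divides that replicate's intersection count by that
replicate's own total simulated length, because the models alter lengths;
dividing by the observed total instead is available via
`per_replicate_denominator=False`.  The 95% null range is the k-th smallest
to k-th largest replicate value with k = ⌊0.025·R⌋ floored at 1 (order
statistics, not interpolated percentiles — one consistent reading of a
"range holding 95% of the values").  The two-tailed test rejects when the
observed index is ≤ the k-th smallest or ≥ the k-th largest null value;
ties count toward rejection (conservative).  With R = 10,000 at α = 0.05
each tail holds exactly 250 values.  α/2·R < 1 is a configuration error
rather than a silent no-op.

Randomness derives from one root seed; each model draws from a
deterministic substream (`SeedSequence(entropy=seed, spawn_key=(model_id,))`),
so adding or removing a model never perturbs another model's draws and
identical inputs and seed reproduce results byte-for-byte.

Model 5 encodes a southbound seasonal tendency and is therefore only valid
for seasons with a marked directional pattern; the pipeline enforces this
with an explicit `allow_model5` override rather than skipping silently, so
the asymmetry between seasons stays visible in the interface.  No
multiple-testing correction is applied across models, and no closed-form
null distributions are attempted — the engine is Monte-Carlo only.

## Circular statistics

Flight direction is the compass bearing of the start→end displacement,
ignoring the mid-point; a trajectory with start = end has no bearing and is
flagged and excluded from summaries.  The summary is the unweighted
circular mean: r = √(S²+C²), μ = atan2(S, C) on [0, 360), with S, C the
means of sin/cos of the bearings.  μ is flagged undefined when r < 1e-12.
An equal-weight per-segment bearing variant exists behind a flag; note that
weighting segment directions by segment *length* reproduces the
displacement bearing exactly, so the equal-weight mean is the only distinct
alternative.

## Synthetic generator

The generator emulates what the analysis needs from radar data and nothing
more:

- **Bearings.**  One heading per trajectory from a von Mises distribution.
  The concentration κ is calibrated from a target mean resultant length by
  inverting A(κ) = I₁(κ)/I₀(κ): the fall-like profile targets r = 0.91
  (κ ≈ 5.9, mean 143.9°), the spring-like profile r = 0.42 (κ ≈ 0.92,
  mean 184.8°).  Leg bearings wiggle around the heading with κ = 60 so the
  polyline is realistically bent but the emitted start→end bearings still
  track the target concentration.
- **Start points** cluster in a configurable disk sector, default bearings
  280–350° at ranges 3.5–5.8 km — a northwest departure region emulating a
  ridgeline that concentrates soaring birds.
- **Leg lengths** are lognormal (median 3.2 km, σ_log = 0.35), giving
  ~6.4 km trajectories — the same order as published seasonal means of
  7.5 km (fall) and 3.0 km (spring).  These are placeholders chosen for
  realism and test stability, never estimates of any field dataset.
- **Disk containment.**  Containment failures redraw only the leg geometry,
  keeping the heading; as a last resort the polyline is shrunk about its
  start, which preserves the start→end bearing exactly.  This matters:
  redrawing headings near the rim would condition bearings toward the disk
  centre and bias r upward (severely so for the diffuse spring profile).
- **Avoidance** (`deflect`) rotates any trajectory that would cross the
  buffered farm polygon (default buffer 200 m) about its start point, away
  from the farm centroid, in 5° steps up to 360°; if no rotation clears,
  the trajectory is regenerated and the event logged.  This is a minimal
  mechanism to manufacture an avoidance signal, not a behavioural model.
- **Turbine layout.**  n turbines split as evenly as possible over w–e rows
  (98 → 25/25/24/24); every row spans the same fixed width (4.8 km), and
  the row spacing is derived from the target hull footprint, so the default
  hull area is exactly 9.49 km² by construction (height = area/width ≈
  1.98 km) rather than fitted.
- A **Model 1 preset** draws all three fixes i.i.d. area-uniform in the
  disk through the same sampler the Model 1 simulator uses, so generator
  and null model coincide by construction — the type-I-error calibration
  path.

What the generator does *not* emulate: flight altitude, radar detection
bias, target misidentification, flock size, weather- or updraft-driven
route structure, temporal autocorrelation between trajectories.  Passing
tests therefore demonstrate the correctness and calibration of the
*analysis machinery*, not that any particular field population avoided any
particular farm.

## Problem sizes used in the tests

The default suite runs the Monte-Carlo engine at 1,000 replicates and the
calibration/avoidance batteries at 100–200 outer repetitions with 50–193
trajectories per set; these sizes give binomial/Monte-Carlo error well
inside the asserted bands while keeping the suite fast.  The pipeline
defaults remain 10,000 replicates, which is what the worked example and any
real analysis use.

## Known limitations

- The convex hull overestimates a concave farm footprint; supply an
  explicit ring when the true perimeter is known.
- The per-trajectory binary intersection count saturates for very long
  trajectories that weave repeatedly through a farm; the per-crossing mode
  exists precisely to probe this.
- The rank test's empirical rejection rate is 2⌊α/2·R⌋/(R+1) ≈ α − α/R
  under exchangeability, i.e. negligibly conservative at R = 1,000 and
  above.
- Rejection sampling for Model 5 becomes slow when retained points lie very
  close to the southern rim (tiny feasible cap); the attempt guard turns
  pathological cases into errors instead of hangs.
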