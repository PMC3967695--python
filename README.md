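# windtraj

Do migrating soaring birds avoid a wind farm?  `windtraj` answers that
question from marine-radar track data: each bird (or flock) trajectory is
recorded as three polar fixes — start-, mid- and end-point bearings and
ranges around the radar station — and the wind farm is a polygon around its
turbine positions.  The package computes an avoidance index, simulates
Monte-Carlo null models of trajectory placement, and decides avoidance with
a two-tailed rank-based randomization test.  It is written for movement
ecologists and wind-energy impact analysts, and ships a synthetic-data
generator so the whole pipeline runs without any field data.

## The statistic and the test

For a season's trajectory set the observed **avoidance index** is

    I_obs = (# trajectories intersecting the farm polygon) / (total trajectory length in km)

where a trajectory intersects if either of its two segments crosses, touches
or lies inside the closed polygon (each trajectory counts at most once).
The null hypothesis — placement indifferent to the farm — is made concrete
by five nested re-simulation models inside the 6-km detection disk:

| model | retained fixes | free fixes |
|-------|----------------|-----------|
| 1 | none | all three uniform in the disk |
| 2 | start | mid, end uniform in the disk |
| 3 | start, mid | end uniform in the disk |
| 4 | start, end | mid uniform in the axis-aligned rectangle spanned by start and end |
| 5 | start, mid | end uniform in the disk, strictly south of both retained points (directional seasons only) |

Each of R = 10,000 replicates re-simulates every trajectory and yields one
null index value I* (the denominator is each replicate's own total length,
since the models change lengths).  The test rejects at α = 0.05 when I_obs
falls among the ⌊α/2·R⌋ = 250 smallest or largest null values; the central
95% range of the null distribution is reported as the k-th smallest to k-th
largest order statistic with k = 250.

Flight directions are summarised with circular statistics: the mean
direction μ (degrees clockwise from north) and mean resultant length
r ∈ [0, 1] of the start→end bearings.

## Worked example

Generate a synthetic fall-like scene — 193 trajectories departing a
northwest sector with tightly clustered southeast bearings, deflecting
around a 98-turbine, four-row farm — and analyse it:

```sh
windtraj simulate --n 193 --avoidance deflect --seed 11 --out-dir scene
windtraj analyze --trajectories scene/trajectories.csv \
                 --turbines scene/turbines.csv \
                 --replicates 10000 --models 1,2,3,4,5 --seed 11 \
                 --out-dir run
```

which prints

```
wrote 193 trajectories (1224.3 km), 98 turbines (hull 9.49 km^2) to scene
season=fall n=193 length=1224.26 km intersections=0 index=0.0000 /km
  model 1: 95% null range [0.0589, 0.0707] rejected=True tail=low
  model 2: 95% null range [0.0529, 0.0643] rejected=True tail=low
  model 3: 95% null range [0.0537, 0.0693] rejected=True tail=low
  model 4: 95% null range [0.0125, 0.0244] rejected=True tail=low
  model 5: 95% null range [0.0575, 0.0710] rejected=True tail=low
report written to run/report.json
```

The avoiding birds never cross the farm (index 0.0000 /km), while randomly
re-placed trajectories of the same lengths would cross it at 0.013–0.071
intersections/km depending on how much observed structure the null model
retains — so all five models reject the no-avoidance hypothesis in the low
tail.  `run/summary.tsv` adds the circular summary (here μ = 141.1°,
r = 0.85: a concentrated southeast passage), `run/models.tsv` is the
machine-readable null-model table, and `windtraj report` re-renders a saved
run as TSV/JSON/GeoJSON.

The same analysis is available as a library:

```python
import windtraj as wt

turbines = wt.generate_layout(wt.LayoutConfig())
farm = wt.build_farm_polygon(turbines)
ts = wt.generate_trajectories(wt.SyntheticConfig(avoidance="deflect", seed=11),
                              wt.DetectionDisk(), farm)
report = wt.analyze_set(ts, farm, wt.RunConfig(replicates=10_000, seed=11))
```

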