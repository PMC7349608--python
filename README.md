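# hexsense

A desk-scale crowdsensing noise-mapping backend.  Crowds of smartphone
users submit geolocated sound-level measurements (LAeq, LCpeak, TWA in
dB) as GeoJSON point features; `hexsense` validates and anonymizes
them, buckets them on a hierarchical hexagonal grid, aggregates them
per grid cell and tumbling time window, and answers
boundary/window/resolution queries as GeoJSON FeatureCollections of
hexagon polygons — the data behind a live noise map that, e.g.,
tinnitus or stress patients can use to avoid loud places.

It is aimed at people studying or prototyping crowdsensing pipelines:
the whole distributed architecture (broker topics, stream processors,
document store, access API) is modelled in-process behind pluggable
interfaces, so every end-to-end property is testable on a laptop.

## The core computations

**Energetic averaging.** Decibels are logarithmic, so means are taken
in the linear power domain:

    L_mean = 10 · log10( (1/n) · Σ 10^(L_i/10) )

Averaging 50 and 70 dB gives 67.03 dB, not 60 — loud events dominate.
Aggregates carry `(min, max, count, mean_energy)` with the linear
`mean_energy` as the incremental carrier, so streaming folds and
count-weighted merges equal a from-scratch batch mean to ~1e-14 dB in
any order.

**Hexagonal hierarchy.** Points are indexed into hexagonal cells at
resolutions 0–15 (aperture-7 refinement: each cell has 7 children,
every coarse center is exactly a fine center; ≈ 66 m cells at
resolution 10).  Membership is hierarchical by assignment, which makes
`parent(index(p, 10), 5) == index(p, 5)` hold for *every* point — the
invariant that keeps the fine- and coarse-resolution aggregation
streams consistent.

**Windowed streaming with retention.** Records fall into epoch-aligned
tumbling windows (default 15/60/1440 min at resolution 10, 60/1440 at
resolution 5).  Each aggregation log accepts late records until
`window.end + retention` (default one day); later arrivals are counted
and dropped per log, so a record can miss the 15-min window yet still
update the daily one.  Missing combinations — e.g. resolution 5 at
15 min — are derived at query time by merging finer cells and shorter
aligned windows, and must equal the raw-record recomputation.

**Privacy.** User ids live only in a separate user→measurement mapping
log; anonymized records, aggregates and query responses structurally
cannot carry one, and raw measurements are returned only for the
owner's token.

**Load-test methodology.** The bench module releases n simultaneous
requests, takes the run's median response time as one measurement, and
repeats until the distribution-free binomial order-statistic 95% CI of
the run-medians is within ±5% of their median (≥ 20 repeats), then
fits a linear trend over user counts.  Absolute times are
hardware-bound and never asserted; the methodology is.

## Worked example

```
$ hexsense simulate --seed 7 --hours 4 --out measurements.ndjson
wrote 938 measurements to measurements.ndjson

$ hexsense ingest --in measurements.ndjson --state state
ingested 938 measurements (0 rejected) -> state/topics

$ hexsense run --state state
processed 938 raw records; counters={'ingested': 0, 'rejected': 0,
'prepared': 938, 'dropped_invalid': 0, 'late_dropped': 0};
store=938 raw, 5506 aggregates
```

`simulate` generates a seeded synthetic city (uniform user homes, two
+20 dB hotspots, a ±5 dB diurnal cycle, 1 dB measurement noise),
`ingest` validates each feature and appends it to the raw log, and
`run` executes preparator, aggregator and sink: 938 records become
5,506 (cell, window, kind) aggregates across the five pre-aggregated
combinations.  Querying hourly aggregates at the coarse resolution:

```
$ hexsense query --state state --res 5 --window 1h --from 0 --to 14400000 \
      --bbox 9.90,48.35,10.05,48.45
```

returns a GeoJSON FeatureCollection of 8 hexagon features; the busiest
cell reads

```
cell 57ffff9e6000002e  window 0        LAeq min=52.6 max=75.4 mean=58.47 count=109
cell 57ffff9e6000002e  window 3600000  LAeq min=53.8 max=59.1 mean=57.07 count=113
cell 57ffff9e6000002e  window 7200000  LAeq min=55.7 max=76.9 mean=60.99 count=81
```

i.e. per hour: the quietest and loudest of the cell's measurements,
their energetic mean (note 58.47 dB sits well above the mid-range —
the 75.4 dB peak dominates the energy), and how many measurements
contributed.  No user-related field appears anywhere in the output.

In Python the same pipeline is three objects:

```python
from hexsense import CityModel, Pipeline, Store, generate_workload
from hexsense.store_access import AccessService, QueryRequest, bbox_ring

store = Store()
pipe = Pipeline(store=store)
for item in generate_workload(CityModel(seed=7), (0, 4 * 3_600_000)):
    pipe.ingest(item.feature, now=item.arrival)
pipe.run()
fc = AccessService(store).query(QueryRequest(
    resolution=5, window_length_min=60, time_range=(0, 14_400_000),
    boundary=bbox_ring(9.90, 48.35, 10.05, 48.45)))
```

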