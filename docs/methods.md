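# Methods

`hexsense` is a desk-scale model of a crowdsensing noise-mapping
backend: a stream of geolocated smartphone noise measurements is
ingested, anonymized, bucketed on a hierarchical hexagonal grid, and
aggregated per grid cell and tumbling time window on the energetic
decibel scale; an access layer answers boundary/window/resolution
queries with on-the-fly re-aggregation and privacy filtering.  This
note records the models, the defaults, and the reasoning behind the
genuinely open design choices.

## Energetic (dB-scale) aggregation

Sound levels are logarithmic.  The mean that matters for exposure is
the *energetic* mean — the level of the constant signal carrying the
same acoustic energy:

    L_mean = 10 log10( (1/n) Σ_i 10^(L_i/10) )   [dB]

Two samples of 50 and 70 dB average to ≈ 67.03 dB, not 60: a loud
event dominates the energy.  By Jensen's inequality the energetic mean
is never below the arithmetic mean, with equality only when all
samples are equal.

The running aggregate per (cell, window, kind) is
`(min, max, count, mean_energy)` with `mean_energy` the linear-domain
carrier; the dB mean is derived on read.  Carrying the linear mean
avoids log/exp round trips on every update, so an incremental fold over
any permutation of a value multiset agrees with a one-shot batch
recomputation to ~1e-14 dB (the tests require 1e-9 dB).  Merging two
aggregates is the count-weighted linear combination, which is exactly
commutative and associative up to float rounding — this is what makes
query-time re-aggregation across cells and windows legitimate.

`LAeq` over a uniformly sampled capture (e.g. 30 s at 1 Hz) is the
energetic mean of the samples; `LCpeak` is the maximum sample.  Inputs
are already frequency-weighted dB values; no A/C filtering is done
here.  `TWA` and unknown kinds aggregate with the same energetic rule
— the kind set is open and nothing about the rule is LAeq-specific.

Valid levels are [0, 194] dB: 194 dB SPL is the physical maximum of an
undistorted sound wave in air at sea level, so the bound rejects
corrupt payloads without excluding any real measurement.

## The hexagonal grid

Cells form a 16-level hierarchy (resolution 0 coarsest, 15 finest)
over the WGS84 lon/lat plane.  Each refinement is an aperture-7
subdivision: scale 1/√7, rotation α = atan(√3/5) ≈ 19.107°, chosen so
the integer child matrix [[2, −1], [1, 3]] (determinant 7) maps coarse
axial coordinates into the fine lattice — every coarse center is
*exactly* a fine center, and each coarse cell owns itself plus its six
fine neighbours.  The base circumradius is 10°, giving ≈ 66 m cells at
resolution 10 and sub-metre cells at 15 — the scales used for fine and
intermediate aggregation.  Tokens are 64-bit hex strings (4 bits
resolution, two 30-bit biased axial coordinates), stable across
platforms.

Membership is **hierarchical by assignment**: a point is placed
geometrically only at resolution 15; its cell at any coarser
resolution is that cell's ancestor chain.  No hexagonal hierarchy
nests geometrically (children always overhang their parent), so
geometric membership per resolution and exact hierarchy consistency
are mutually exclusive.  Assignment-based membership makes

    parent(index(p, 10), 5) == index(p, 5)

an identity for every point — the property the aggregation topology
relies on (a record's res-10 and res-5 routing keys must never
disagree).  The price: a point can fall outside the drawn hexagon of
its coarse cell, by at most √7/(√7−1) ≈ 1.61 circumradii (geometric
series over the refinement steps; tests observe ≤ 1.03).  At the
finest resolution containment is exact, and the boundary/centroid
round trip `index(centroid(cell)) == cell` is exact at every
resolution because coarse centers are lattice points of every finer
lattice.

Boundary cover uses centroid-in-polygon membership (deterministic,
monotone in the polygon).  Antimeridian-crossing query polygons are
rejected outright — a single city never crosses it, and silent
mishandling would be worse than an error.  The equirectangular plane
distorts cell shape at extreme latitudes; for the city-scale use case
this is irrelevant, and all hierarchy/round-trip guarantees are
latitude-independent.

## Streaming pipeline

Topics are in-process append-only keyed logs (NDJSON on disk), a
deliberate stand-in for a distributed broker behind the same
interface.  Default topology: a raw log keyed by client timestamp, a
user→measurement mapping log keyed by user id, two anonymized logs
keyed by cell token at resolutions 10 and 5, and five average logs for
(10, 15 min), (10, 60), (5, 60), (10, 1440), (5, 1440).  The (5, 15)
combination is intentionally absent: those queries must exercise the
re-aggregation path.

Stages:

1. **Ingress** — parse, validate (coordinates in range, values in
   [0, 194] dB, client timestamp within `max_age` = 7 d back /
   `max_clock_skew` = 5 min forward; both configurable), stamp
   `received_at`, resolve the auth token (invalid tokens are rejected
   rather than silently downgraded to anonymous, so a client with a
   stale token learns about it), assign a random 128-bit id if absent,
   append to the raw log.  Rejection is atomic: nothing is appended.
2. **Preparator** — re-validate, split off the user mapping (the only
   place a user id survives), strip the user id, index the point at
   both resolutions.  The two routing keys are hierarchy-consistent by
   construction.
3. **Aggregator** — per average log, assign the record's *client*
   timestamp to an epoch-aligned tumbling window and fold it in;
   emit the updated aggregate feature.
4. **Sink** — upsert emitted aggregates into the store (last write
   wins; the latest emission per key carries the complete state).

Windows are epoch-aligned: the window parameters (length, retention)
do not themselves fix an alignment, and anchoring to the UTC epoch
makes windows reproducible across runs and machines.  Lateness is judged
per log against the record's `received_at` — a record can be late for
the 15-min log yet still update the hourly and daily logs, since their
windows close later.  Late records are dropped with a counter, never
errored: loss of one late point is normal streaming behaviour, a
poison-pill crash is not.  Using `received_at` (not wall clock) for
the late decision makes replays deterministic: re-running a raw log
from scratch yields byte-identical store snapshots, and processing a
stream in two halves equals one run over the whole.

## Store and access service

The store is in-memory maps with NDJSON snapshot/load — a document
database sits naturally behind the same five-method interface but is
not required at desk scale.  Queries name a resolution, a window
length, a time range and a boundary; the service covers the boundary
with cells, serves pre-aggregated combinations verbatim, and derives
anything else by merging finer cells (grouping by ancestor) and
shorter aligned windows (grouping by containment).  Window coarsening
runs only along the aligned ladder 15 → 60 → 1440 min; other lengths
(e.g. 45 min) are refused as unsupported rather than given ad-hoc
semantics.  Both derivation paths — from stored finer aggregates and
from raw records — are implemented, and the tests require them to
agree within 1e-9 dB.

Privacy is structural, not a filter bolted on: aggregates and
anonymized records never contain a user field (the serializer has no
code path for one), the mapping log is separate, and raw measurements
are released only against the owner's token.  The auth registry is an
opaque token→user map standing in for a token service; signature
validation is out of scope.

## Synthetic city

Defaults model one day in one mid-sized city (~0.15° × 0.10°,
~11 km × 11 km):
60 users × 4 measurements/h × 24 h ≈ 5,760 expected records (Poisson),
baseline 55 dB, two hard-disc hotspots of radius 300 m and +20 dB
boost, a ±5 dB sinusoidal diurnal cycle, and i.i.d. Gaussian
measurement noise of sd 1 dB, clamped to [0, 194].  Positions are a
home/roaming mixture: with probability 0.5 near a fixed per-user home
(Gaussian scatter, 150 m), else uniform in the city — per-user
locality plus full map coverage, which a home-only model does not give
(entire districts, hotspots included, can go unsampled).  30% of
users contribute anonymously; ingest delay is uniform within 60 s, far
inside every retention horizon.  The PRNG is NumPy's PCG64 with an
explicit seed; identical seeds give byte-identical NDJSON streams.

`ground_truth` is the deliberate second path: it regenerates the
stream and aggregates it by one-shot NumPy batch statistics, touching
neither the incremental update nor the pipeline, so pipeline-vs-oracle
comparisons are two genuinely independent computations.  The +20 dB
boost against 1 dB noise makes hotspot cells separable in daily means
(observed margin ≈ 8 dB); with comparable magnitudes the top-k
recovery would not be expected to be exact, and that regime is not
claimed.

What passing tests show: bookkeeping, windowing, anonymization and
dB-correct aggregation are exact under realistic-shaped load.  What
they do not show: behaviour under adversarial clocks, correlated
device bias, or real mobility — the generator does not model those.

## Benchmark harness

The load harness releases n simultaneous requests (threads behind a
barrier) and treats the run's *median* response time as one
measurement.  Runs repeat until (a) at least 20 repeats by default and
(b) the 95% confidence interval of the run-medians lies within ±5% of
their median; a cap (default 200) flags non-convergence instead of
looping forever.  The CI is the distribution-free binomial
order-statistic interval: with n sorted medians, take rank l = the
largest k with P(X < k) ≤ α/2 for X ~ Binomial(n, ½), and u = n+1−l;
coverage is ≥ 1−α by construction and needs n > 5 to be non-trivial.
A least-squares trend over (user count, median) reports slope,
intercept and R² as a scaling diagnostic.  Absolute response times are
a property of the hardware, not of this code, and are never asserted —
only the methodology (CI exactness, stopping behaviour, table shape,
trend fit) is testable.  The endpoint is any callable; the in-process
access service or a latency stub both fit.

## Numerical and degenerate-input choices

- Aggregate equality compares min/max/count exactly and the dB mean to
  1e-12 (one JSON serialize/parse cycle perturbs it by < 2e-15 dB).
- Hex rounding operates on cube coordinates; parent steps divide by 7,
  whose fractional parts (k/7) sit ≥ 1/14 from rounding boundaries, so
  float noise (~1e-8 at the 30-bit coordinate range) cannot flip a
  cell assignment.
- Empty inputs are errors where a value is demanded (energetic mean of
  nothing, empty sample series, trend on < 3 points, CI on ≤ 5
  samples) and data where absence is meaningful (validation returns a
  violation list; empty query regions return an empty collection;
  empty cells simply have no aggregate — never a zero-count entry).
- Measurement ids are random 128-bit tokens; uniqueness is assumed,
  collisions are not handled.

## Problem sizes

The default test and acceptance workload is one synthetic day
(~5,700–5,800 measurements, ~31,000 aggregate entries across the five
combinations), 10,000-point hierarchy sweeps, and benchmark runs of
8–24 simultaneous stub requests — sizes chosen so the whole suite
exercises every path in well under a minute each while keeping
every count-based check (conservation, disjointness, top-k) exact.
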