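"""Seeded synthetic-city noise workload with brute-force ground truth.

Emulates a crowd of users submitting smartphone noise measurements in
one city: each user has a fixed home location (uniform in the city
bounding box), submits a Poisson number of measurements at uniformly
random times, at positions drawn from a home/roaming mixture: with
probability ``home_fraction`` near home (Gaussian scatter), otherwise
uniformly anywhere in the city (commutes, errands) — so the crowd
covers the whole map while still showing per-user locality.  The
sound level at (position, time) is

    baseline + sum of hotspot boosts (hard-disc, within radius)
             + diurnal_amplitude * sin(2*pi*hour/24)
             + Gaussian(0, noise_sd)        clamped to [0, 194] dB

The PRNG is NumPy's PCG64 seeded explicitly, so the same model
produces a byte-identical NDJSON stream on every platform.

What this emulates: spatial hotspots (construction sites, arterial
roads), a diurnal level cycle, uneven user density, anonymous vs
authenticated contributors, and bounded ingest delay.  What it does
not: mobility traces, acoustic propagation, correlated device bias —
so pipeline tests establish bookkeeping and aggregation correctness,
not acoustic realism.

``ground_truth`` recomputes per-(cell, window) aggregates by plain
batch evaluation over the generated stream, independent of the
streaming pipeline, and is the end-to-end oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .acoustics import AggregateStats, DB_MAX, DB_MIN
from .geodata import GeoPoint, Measurement, SingleValue, measurement_to_feature
from .spatial_index import index_point

__all__ = [
    "Hotspot",
    "CityModel",
    "WorkItem",
    "generate_workload",
    "generate",
    "noiseless_level",
    "ground_truth",
    "hotspot_cells",
    "MS_PER_HOUR",
]

MS_PER_HOUR = 3_600_000
_M_PER_DEG_LAT = 111_320.0


@dataclass(frozen=True)
class Hotspot:
    lon: float
    lat: float
    radius_m: float
    boost_db: float

    def __post_init__(self):
        if self.radius_m <= 0:
            raise ValueError("hotspot radius must be positive")


@dataclass(frozen=True)
class CityModel:
    """Study conditions for one synthetic city (defaults: a mid-sized town).

    ``n_users * rate_per_hour * 24 h`` is the expected daily stream
    size (~5,760 with the defaults).  ``noise_sd`` is per-measurement
    dB noise; hotspot boosts are large (20 dB) relative to it so that
    hotspot cells are recoverable from daily means.
    """

    bbox: tuple[float, float, float, float] = (9.90, 48.35, 10.05, 48.45)
    baseline_db: float = 55.0
    hotspots: tuple[Hotspot, ...] = (
        Hotspot(lon=9.975, lat=48.415, radius_m=300.0, boost_db=20.0),
        Hotspot(lon=10.020, lat=48.380, radius_m=300.0, boost_db=20.0),
    )
    diurnal_amplitude_db: float = 5.0
    noise_sd_db: float = 1.0
    n_users: int = 60
    rate_per_hour: float = 4.0
    scatter_m: float = 150.0
    home_fraction: float = 0.5  # rest of the positions roam uniformly
    anonymous_fraction: float = 0.3
    max_ingest_delay_ms: int = 60_000
    seed: int = 1

    def __post_init__(self):
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        lon1, lat1, lon2, lat2 = self.bbox
        if not (lon2 > lon1 and lat2 > lat1):
            raise ValueError("bbox must be (lon_min, lat_min, lon_max, lat_max)")


@dataclass(frozen=True)
class WorkItem:
    """One generated submission: the wire feature plus its auth token."""

    feature: dict
    token: Optional[str]
    arrival: int  # server-side arrival time, epoch ms
    noiseless_db: float  # model level without measurement noise


def _dist_m(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Equirectangular metre distance, adequate at city scale."""
    my = (lat2 - lat1) * _M_PER_DEG_LAT
    mx = (lon2 - lon1) * _M_PER_DEG_LAT * math.cos(math.radians(0.5 * (lat1 + lat2)))
    return math.hypot(mx, my)


def noiseless_level(model: CityModel, lon: float, lat: float, t_ms: int) -> float:
    """Model sound level at a point and time, without measurement noise."""
    level = model.baseline_db
    for h in model.hotspots:
        if _dist_m(lon, lat, h.lon, h.lat) <= h.radius_m:
            level += h.boost_db
    hour = (t_ms % (24 * MS_PER_HOUR)) / MS_PER_HOUR
    level += model.diurnal_amplitude_db * math.sin(2.0 * math.pi * hour / 24.0)
    return level


def generate_workload(
    model: CityModel, time_range: tuple[int, int]
) -> list[WorkItem]:
    """Chronological synthetic submissions for ``[start, end)`` epoch ms."""
    start, end = int(time_range[0]), int(time_range[1])
    if not end > start:
        raise ValueError("time_range must be a non-empty [start, end)")
    rng = np.random.default_rng(model.seed)
    lon1, lat1, lon2, lat2 = model.bbox
    hours = (end - start) / MS_PER_HOUR

    events: list[tuple[int, int, float, float]] = []  # (t, user, lon, lat)
    for u in range(model.n_users):
        home_lon = rng.uniform(lon1, lon2)
        home_lat = rng.uniform(lat1, lat2)
        anonymous = rng.random() < model.anonymous_fraction
        n_u = rng.poisson(model.rate_per_hour * hours)
        times = np.sort(rng.integers(start, end, size=n_u))
        dlat = rng.normal(0.0, model.scatter_m / _M_PER_DEG_LAT, size=n_u)
        coslat = math.cos(math.radians(home_lat))
        dlon = rng.normal(0.0, model.scatter_m / (_M_PER_DEG_LAT * coslat), size=n_u)
        at_home = rng.random(size=n_u) < model.home_fraction
        roam_lon = rng.uniform(lon1, lon2, size=n_u)
        roam_lat = rng.uniform(lat1, lat2, size=n_u)
        for k in range(n_u):
            if at_home[k]:
                lon = min(max(home_lon + dlon[k], lon1), lon2)
                lat = min(max(home_lat + dlat[k], lat1), lat2)
            else:
                lon, lat = roam_lon[k], roam_lat[k]
            events.append((int(times[k]), -1 if anonymous else u, lon, lat))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    items: list[WorkItem] = []
    for seq, (t, u, lon, lat) in enumerate(events):
        clean = noiseless_level(model, lon, lat, t)
        laeq_db = clean + rng.normal(0.0, model.noise_sd_db)
        laeq_db = min(max(laeq_db, DB_MIN), DB_MAX)
        lcpeak_db = min(laeq_db + rng.uniform(2.0, 8.0), DB_MAX)
        m = Measurement(
            id=f"syn-{model.seed}-{seq:07d}",
            geometry=GeoPoint(lon, lat),
            sensor_type="smartphone-mic",
            trigger="manual",
            created_at=t,
            values=[
                SingleValue("LAeq", float(laeq_db)),
                SingleValue("LCpeak", float(lcpeak_db)),
            ],
        )
        feature = measurement_to_feature(m)
        delay = int(rng.integers(0, model.max_ingest_delay_ms + 1))
        items.append(
            WorkItem(
                feature=feature,
                token=None if u < 0 else f"tok-{u:04d}",
                arrival=t + delay,
                noiseless_db=clean,
            )
        )
    return items


def generate(model: CityModel, time_range: tuple[int, int]) -> list[dict]:
    """The GeoJSON features of the workload, in chronological order."""
    return [w.feature for w in generate_workload(model, time_range)]


def user_tokens(model: CityModel) -> dict[str, str]:
    """token -> user id for every (potential) authenticated user."""
    return {f"tok-{u:04d}": f"user-{u:04d}" for u in range(model.n_users)}


def ground_truth(
    model: CityModel,
    time_range: tuple[int, int],
    resolution: int,
    window_length_min: int,
) -> dict[tuple[str, int, str], AggregateStats]:
    """Brute-force per-(cell, window, kind) aggregates of the stream.

    Recomputed directly from the generated features with plain NumPy
    batch statistics — no incremental update, no pipeline — so it can
    serve as an independent end-to-end oracle.  Cells with no
    measurements do not appear (never a zero-count aggregate).
    """
    wlen_ms = window_length_min * 60_000
    groups: dict[tuple[str, int, str], list[float]] = {}
    for feature in generate(model, time_range):
        lon, lat = feature["geometry"]["coordinates"][:2]
        t = feature["properties"]["createdAt"]
        cell = index_point(lon, lat, resolution).token
        wstart = (t // wlen_ms) * wlen_ms
        for v in feature["properties"]["values"]:
            groups.setdefault((cell, wstart, v["type"]), []).append(v["value"])
    out: dict[tuple[str, int, str], AggregateStats] = {}
    for key, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        out[key] = AggregateStats(
            min=float(arr.min()),
            max=float(arr.max()),
            count=int(arr.size),
            mean_energy=float(np.mean(10.0 ** (arr / 10.0))),
            kind=key[2],
        )
    return out


def hotspot_cells(
    model: CityModel, time_range: tuple[int, int], resolution: int
) -> set[str]:
    """Cells that received at least one hotspot-boosted measurement."""
    out: set[str] = set()
    for feature in generate(model, time_range):
        lon, lat = feature["geometry"]["coordinates"][:2]
        if any(
            _dist_m(lon, lat, h.lon, h.lat) <= h.radius_m for h in model.hotspots
        ):
            out.add(index_point(lon, lat, resolution).token)
    return out
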