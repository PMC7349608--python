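"""Aggregate/raw persistence and the query-side access service.

The store is an in-memory document store behind a small interface
(NDJSON snapshot/load for persistence): aggregates keyed by
(resolution, window length, cell, window start, kind), anonymized raw
measurements keyed by id, and the user->measurement mapping kept apart
from all measurement payloads.  Queries specify a grid resolution, a
window length, a time range and a geo-boundary; combinations that are
pre-aggregated are served from the store, anything else is derived on
the fly by merging finer cells (via the grid hierarchy) and shorter
aligned windows.  Responses are aggregate Features only — user
identifiers cannot appear in them, and raw measurements are released
exclusively to their owner's token.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from . import geodata
from .acoustics import AggregateStats, merge_stats
from .geodata import AverageFeature, Measurement
from .spatial_index import CellId, cover_boundary, parent_cell

__all__ = [
    "AuthError",
    "UnsupportedCombinationError",
    "AuthRegistry",
    "Store",
    "QueryRequest",
    "AccessService",
    "bbox_ring",
]

AggKey = tuple[str, int, str]  # (cell token, window start, kind)


class AuthError(PermissionError):
    pass


class UnsupportedCombinationError(ValueError):
    """The requested (resolution, window length) cannot be derived."""


class AuthRegistry:
    """Opaque-token -> user-id registry (stand-in auth service).

    Tokens are plain opaque strings; registering and resolving is all
    the pipeline and access service need.
    """

    def __init__(self):
        self._tokens: dict[str, str] = {}

    def register(self, token: str, user_id: str) -> None:
        self._tokens[token] = user_id

    def resolve(self, token: str) -> Optional[str]:
        return self._tokens.get(token)


class Store:
    """In-memory persistence for aggregates, raw records and mappings."""

    def __init__(self):
        # (res, window length) -> (cell, window start, kind) -> stats
        self.aggregates: dict[tuple[int, int], dict[AggKey, AggregateStats]] = {}
        self.raw: dict[str, Measurement] = {}
        self.mappings: dict[str, set[str]] = {}

    # -- writes --------------------------------------------------------

    def upsert_aggregate(
        self,
        resolution: int,
        window_length_min: int,
        cell_token: str,
        window_start: int,
        kind: str,
        stats: AggregateStats,
    ) -> None:
        """Last write wins per (cell, window, kind)."""
        bucket = self.aggregates.setdefault((resolution, window_length_min), {})
        bucket[(cell_token, window_start, kind)] = stats

    def put_raw(self, m: Measurement) -> None:
        if m.user_id is not None:
            raise ValueError("raw store accepts only anonymized measurements")
        if m.id is None:
            raise ValueError("raw store requires an id")
        self.raw[m.id] = m

    def add_mapping(self, user_id: str, measurement_id: str) -> None:
        self.mappings.setdefault(user_id, set()).add(measurement_id)

    # -- reads ---------------------------------------------------------

    def combos(self) -> list[tuple[int, int]]:
        return sorted(self.aggregates)

    def entries(self, resolution: int, window_length_min: int) -> dict[AggKey, AggregateStats]:
        return self.aggregates.get((resolution, window_length_min), {})

    # -- persistence ---------------------------------------------------

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "aggregates.ndjson"), "w", encoding="utf-8") as fh:
            for (res, wlen), bucket in sorted(self.aggregates.items()):
                for (cell, wstart, kind), s in sorted(bucket.items()):
                    fh.write(
                        json.dumps(
                            {
                                "resolution": res,
                                "windowLength": wlen,
                                "cell": cell,
                                "windowStart": wstart,
                                "kind": kind,
                                "min": s.min,
                                "max": s.max,
                                "mean": s.mean,
                                "count": s.count,
                            },
                            sort_keys=True,
                            separators=(",", ":"),
                        )
                        + "\n"
                    )
        geodata.write_ndjson(
            [self.raw[k] for k in sorted(self.raw)],
            os.path.join(directory, "raw.ndjson"),
        )
        with open(os.path.join(directory, "mappings.ndjson"), "w", encoding="utf-8") as fh:
            for user in sorted(self.mappings):
                fh.write(
                    json.dumps(
                        {"userId": user, "measurementIds": sorted(self.mappings[user])},
                        sort_keys=True,
                        separators=(",", ":"),
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, directory) -> "Store":
        store = cls()
        agg_path = os.path.join(directory, "aggregates.ndjson")
        if os.path.exists(agg_path):
            with open(agg_path, encoding="utf-8") as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    d = json.loads(line)
                    store.upsert_aggregate(
                        d["resolution"],
                        d["windowLength"],
                        d["cell"],
                        d["windowStart"],
                        d["kind"],
                        AggregateStats(
                            min=d["min"],
                            max=d["max"],
                            count=d["count"],
                            mean_energy=10.0 ** (d["mean"] / 10.0),
                            kind=d["kind"],
                        ),
                    )
        raw_path = os.path.join(directory, "raw.ndjson")
        if os.path.exists(raw_path):
            for m in geodata.read_ndjson(raw_path):
                store.put_raw(m)
        map_path = os.path.join(directory, "mappings.ndjson")
        if os.path.exists(map_path):
            with open(map_path, encoding="utf-8") as fh:
                for line in fh:
                    if line.strip():
                        d = json.loads(line)
                        for mid in d["measurementIds"]:
                            store.add_mapping(d["userId"], mid)
        return store


def bbox_ring(lon1: float, lat1: float, lon2: float, lat2: float) -> list[tuple[float, float]]:
    """Closed ring of a lon/lat bounding box (corners in either order)."""
    xlo, xhi = sorted((float(lon1), float(lon2)))
    ylo, yhi = sorted((float(lat1), float(lat2)))
    return [(xlo, ylo), (xhi, ylo), (xhi, yhi), (xlo, yhi), (xlo, ylo)]


@dataclass
class QueryRequest:
    """Boundary/window/resolution query against the access service."""

    resolution: int
    window_length_min: int
    time_range: tuple[int, int]  # [start, end) epoch ms
    boundary: Sequence[tuple[float, float]]  # closed or open lon/lat ring
    token: Optional[str] = None
    limit: Optional[int] = None
    offset: int = 0

    def __post_init__(self):
        start, end = self.time_range
        if not end > start:
            raise ValueError("time_range must be a non-empty [start, end)")
        if not 0 <= self.resolution <= 15:
            raise ValueError("resolution must be in [0, 15]")


class AccessService:
    """Serves aggregate queries and owner-only raw access."""

    #: window lengths (minutes) a query may ask for; coarsening runs
    #: only along this aligned ladder, not arbitrary multiples
    DEFAULT_WINDOW_LADDER = (15, 60, 1440)

    def __init__(
        self,
        store: Store,
        auth: Optional[AuthRegistry] = None,
        window_ladder: Sequence[int] = DEFAULT_WINDOW_LADDER,
    ):
        self.store = store
        self.auth = auth if auth is not None else AuthRegistry()
        self.window_ladder = tuple(window_ladder)

    # -- re-aggregation -------------------------------------------------

    def _source_combo(self, resolution: int, window_length_min: int) -> tuple[int, int]:
        """Best stored combo from which the target can be derived.

        A source works if it is at the same or a finer resolution
        (coarsening goes through the cell hierarchy) and its window
        length divides the target's (epoch-aligned windows then nest
        exactly).  Prefer the same resolution and the longest usable
        window to minimize merge work.
        """
        if window_length_min not in self.window_ladder:
            raise UnsupportedCombinationError(
                f"window length {window_length_min} min is not on the aligned "
                f"ladder {self.window_ladder}"
            )
        candidates = [
            (res, wlen)
            for (res, wlen) in self.store.combos()
            if res >= resolution and window_length_min % wlen == 0
        ]
        if not candidates:
            raise UnsupportedCombinationError(
                f"({resolution}, {window_length_min} min) is not derivable from "
                f"stored combinations {self.store.combos()}"
            )
        return min(candidates, key=lambda c: (c[0] - resolution, window_length_min // c[1]))

    def reaggregate(
        self,
        resolution: int,
        window_length_min: int,
        cells: Optional[set[str]] = None,
        time_range: Optional[tuple[int, int]] = None,
    ) -> dict[AggKey, AggregateStats]:
        """Derive (resolution, window length) aggregates on the fly.

        Groups stored finer-resolution cells by their ancestor at the
        target resolution and shorter aligned windows by containment,
        merging with the count-weighted energetic combination.
        """
        src_res, src_wlen = self._source_combo(resolution, window_length_min)
        if (src_res, src_wlen) == (resolution, window_length_min):
            out = dict(self.store.entries(src_res, src_wlen))
            return self._filter(out, cells, time_range, window_length_min)
        target_ms = window_length_min * 60_000
        out: dict[AggKey, AggregateStats] = {}
        for (cell_token, wstart, kind), s in self.store.entries(src_res, src_wlen).items():
            if src_res > resolution:
                tcell = parent_cell(CellId.from_token(cell_token), resolution).token
            else:
                tcell = cell_token
            tstart = (wstart // target_ms) * target_ms
            key = (tcell, tstart, kind)
            out[key] = merge_stats(out[key], s) if key in out else s
        return self._filter(out, cells, time_range, window_length_min)

    @staticmethod
    def _filter(
        entries: dict[AggKey, AggregateStats],
        cells: Optional[set[str]],
        time_range: Optional[tuple[int, int]],
        window_length_min: int,
    ) -> dict[AggKey, AggregateStats]:
        wlen_ms = window_length_min * 60_000
        out = {}
        for (cell, wstart, kind), s in entries.items():
            if cells is not None and cell not in cells:
                continue
            if time_range is not None:
                start, end = time_range
                if not (wstart < end and wstart + wlen_ms > start):
                    continue
            out[(cell, wstart, kind)] = s
        return out

    # -- queries --------------------------------------------------------

    def query_aggregates(self, q: QueryRequest) -> list[AverageFeature]:
        cell_ids = cover_boundary(q.boundary, q.resolution)
        cells = {c.token for c in cell_ids}
        if (q.resolution, q.window_length_min) in self.store.combos():
            entries = self._filter(
                self.store.entries(q.resolution, q.window_length_min),
                cells,
                q.time_range,
                q.window_length_min,
            )
        else:
            entries = self.reaggregate(
                q.resolution, q.window_length_min, cells=cells, time_range=q.time_range
            )
        wlen_ms = q.window_length_min * 60_000
        grouped: dict[tuple[str, int], dict[str, AggregateStats]] = {}
        for (cell, wstart, kind), s in entries.items():
            grouped.setdefault((cell, wstart), {})[kind] = s
        features = [
            AverageFeature(
                cell=CellId.from_token(cell),
                window_start=wstart,
                window_end=wstart + wlen_ms,
                stats=stats,
            )
            for (cell, wstart), stats in sorted(grouped.items())
        ]
        if q.offset:
            features = features[q.offset:]
        if q.limit is not None:
            features = features[: q.limit]
        return features

    def query(self, q: QueryRequest) -> dict:
        """RFC 7946 FeatureCollection of aggregate features."""
        return geodata.write_feature_collection(self.query_aggregates(q))

    # -- owner-only raw access ------------------------------------------

    def fetch_user_measurements(self, token: Optional[str]) -> list[Measurement]:
        """Exactly the owner's measurements, ids re-joined; never anyone else's."""
        if token is None:
            raise AuthError("raw measurement access requires a token")
        user = self.auth.resolve(token)
        if user is None:
            raise AuthError("unknown or expired token")
        ids = self.store.mappings.get(user, set())
        return [self.store.raw[mid] for mid in sorted(ids) if mid in self.store.raw]
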