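"""In-process streaming pipeline over keyed append-only logs.

Mirrors a message-broker topology with one Python object per topic:
an ingress stage validates and timestamps incoming GeoJSON features
and appends them to a raw log; a preparator re-validates, anonymizes
(user ids go to a separate mapping log only the owner can read) and
grid-indexes each record at the configured resolutions; a windowed
aggregator folds records into per-(cell, window, kind) energetic
statistics for each (resolution, window-length) combination; a sink
upserts the emitted aggregates into the store.

Windows are epoch-aligned tumbling intervals.  Each aggregation log
has a retention: a record whose window closed more than ``retention``
ago at arrival time is dropped for that log (counted, never errored)
— late data may still update a longer window whose retention horizon
is later.  Lateness is judged against the record's server arrival
time (``received_at``), which makes replays deterministic.

The default topic layout matches a deployment with resolutions 10
(fine, ~60 m cells) and 5 (intermediate, ~15 km cells) and window
lengths 15/60/1440 min in five combinations; (5, 15) is deliberately
absent and must be answered by query-time re-aggregation.
"""

from __future__ import annotations

import json
import os
import uuid
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Union

from . import geodata
from .acoustics import AggregateStats, init_stats, update_stats
from .geodata import AverageFeature, Measurement, Violation
from .spatial_index import CellId, index_point

__all__ = [
    "LATE",
    "WindowSpec",
    "WindowInstance",
    "assign_window",
    "TopicRecord",
    "TopicLog",
    "Broker",
    "TopicLayout",
    "UserMapping",
    "Confirmation",
    "Rejection",
    "Pipeline",
    "DEFAULT_RETENTION_MIN",
]

DEFAULT_RETENTION_MIN = 1440  # one day of retrospective updates

_MS_PER_MIN = 60_000


class _Late:
    """Sentinel: the record arrived after the window's retention."""

    def __repr__(self) -> str:  # pragma: no cover
        return "LATE"


LATE = _Late()


@dataclass(frozen=True)
class WindowSpec:
    """Tumbling-window length and retention, both in minutes."""

    length_min: int
    retention_min: int = DEFAULT_RETENTION_MIN

    def __post_init__(self):
        if self.length_min <= 0:
            raise ValueError("window length must be positive")
        if self.retention_min < self.length_min:
            raise ValueError("retention must be >= window length")

    @property
    def length_ms(self) -> int:
        return self.length_min * _MS_PER_MIN

    @property
    def retention_ms(self) -> int:
        return self.retention_min * _MS_PER_MIN


@dataclass(frozen=True)
class WindowInstance:
    """A concrete half-open interval [start, end), epoch ms UTC."""

    start: int
    end: int


def assign_window(
    ts: int, spec: WindowSpec, now: int
) -> Union[WindowInstance, _Late]:
    """Epoch-aligned tumbling window containing ``ts``, or LATE.

    LATE iff, at time ``now``, the window has been closed for at least
    the retention period (``now >= end + retention``).
    """
    start = (ts // spec.length_ms) * spec.length_ms
    end = start + spec.length_ms
    if now >= end + spec.retention_ms:
        return LATE
    return WindowInstance(start=start, end=end)


# --- keyed append-only logs ------------------------------------------

@dataclass(frozen=True)
class TopicRecord:
    topic: str
    key: str
    value: dict
    timestamp: int
    offset: int


class TopicLog:
    """Append-only, offset-ordered record log for one topic."""

    def __init__(self, name: str):
        self.name = name
        self._records: list[TopicRecord] = []

    def append(self, key: str, value: dict, timestamp: int) -> TopicRecord:
        rec = TopicRecord(
            topic=self.name,
            key=key,
            value=value,
            timestamp=int(timestamp),
            offset=len(self._records),
        )
        self._records.append(rec)
        return rec

    def read_from(self, offset: int) -> list[TopicRecord]:
        return self._records[offset:]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)


class Broker:
    """A set of named topic logs with NDJSON persistence."""

    def __init__(self):
        self._topics: dict[str, TopicLog] = {}

    def topic(self, name: str) -> TopicLog:
        if name not in self._topics:
            self._topics[name] = TopicLog(name)
        return self._topics[name]

    @property
    def topic_names(self) -> list[str]:
        return sorted(self._topics)

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        for name, log in self._topics.items():
            path = os.path.join(directory, f"{name}.ndjson")
            with open(path, "w", encoding="utf-8") as fh:
                for rec in log:
                    fh.write(
                        json.dumps(
                            {
                                "key": rec.key,
                                "timestamp": rec.timestamp,
                                "offset": rec.offset,
                                "value": rec.value,
                            },
                            sort_keys=True,
                            separators=(",", ":"),
                        )
                        + "\n"
                    )

    @classmethod
    def load(cls, directory) -> "Broker":
        broker = cls()
        for fname in sorted(os.listdir(directory)):
            if not fname.endswith(".ndjson"):
                continue
            log = broker.topic(fname[: -len(".ndjson")])
            with open(os.path.join(directory, fname), encoding="utf-8") as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        d = json.loads(line)
                        log.append(d["key"], d["value"], d["timestamp"])
        return broker


# --- topic layout -----------------------------------------------------

@dataclass(frozen=True)
class TopicLayout:
    """Names and key rules of the pipeline's topics.

    ``averages`` maps (resolution, window length in minutes) to a topic
    name; its keys are cell tokens at that resolution.  The raw log is
    keyed by the client timestamp, the mapping log by user id.
    """

    raw: str = "noise-raw-measurements"
    mapping: str = "noise-user-measurement-mapping"
    anonymized: tuple[tuple[int, str], ...] = (
        (10, "noise-anonymized-hex-10-indexed"),
        (5, "noise-anonymized-hex-5-indexed"),
    )
    averages: tuple[tuple[tuple[int, int], str], ...] = (
        ((10, 15), "noise-average-r10w15"),
        ((10, 60), "noise-average-r10w60"),
        ((5, 60), "noise-average-r5w60"),
        ((10, 1440), "noise-average-r10w1440"),
        ((5, 1440), "noise-average-r5w1440"),
    )
    retention_min: int = DEFAULT_RETENTION_MIN

    @property
    def resolutions(self) -> list[int]:
        return [res for res, _ in self.anonymized]

    @property
    def average_combos(self) -> list[tuple[int, int]]:
        return [combo for combo, _ in self.averages]

    def anonymized_topic(self, res: int) -> str:
        for r, name in self.anonymized:
            if r == res:
                return name
        raise KeyError(f"no anonymized topic for resolution {res}")

    def average_topic(self, res: int, length_min: int) -> str:
        for (r, l), name in self.averages:
            if (r, l) == (res, length_min):
                return name
        raise KeyError(f"no average topic for ({res}, {length_min})")

    def window_spec(self, length_min: int) -> WindowSpec:
        return WindowSpec(length_min=length_min, retention_min=self.retention_min)

    def all_topics(self) -> list[str]:
        return [self.raw, self.mapping] + [n for _, n in self.anonymized] + [
            n for _, n in self.averages
        ]


@dataclass(frozen=True)
class UserMapping:
    user_id: str
    measurement_id: str


@dataclass(frozen=True)
class Confirmation:
    id: str


@dataclass(frozen=True)
class Rejection:
    violations: tuple[Violation, ...]

    @staticmethod
    def of(*violations: Violation) -> "Rejection":
        return Rejection(violations=tuple(violations))


# --- pipeline ---------------------------------------------------------

class Pipeline:
    """Ingress -> preparator -> aggregator -> sink over a Broker.

    ``auth`` resolves opaque tokens to user ids (any object with a
    ``resolve(token) -> user_id | None`` method); ``store`` receives
    aggregate upserts, anonymized raw measurements and user mappings
    (duck-typed, see the store module).  Both are optional: without a
    store the aggregates only live in the average logs.
    """

    def __init__(
        self,
        broker: Optional[Broker] = None,
        layout: Optional[TopicLayout] = None,
        auth=None,
        store=None,
    ):
        self.broker = broker if broker is not None else Broker()
        self.layout = layout if layout is not None else TopicLayout()
        self.auth = auth
        self.store = store
        # consumer cursors, keyed by (stage, topic)
        self._cursors: dict[tuple[str, str], int] = {}
        # live aggregation state: topic -> (cell token, window start, kind) -> stats
        self.state: dict[str, dict[tuple[str, int, str], AggregateStats]] = {
            name: {} for _, name in self.layout.averages
        }
        self.counters: dict[str, int] = {
            "ingested": 0,
            "rejected": 0,
            "prepared": 0,
            "dropped_invalid": 0,
            "late_dropped": 0,
        }

    # -- ingress (validate, timestamp, append to the raw log) ---------

    def ingest(
        self, text: Union[str, dict], token: Optional[str] = None, *, now: int
    ) -> Union[Confirmation, Rejection]:
        try:
            m = geodata.parse_measurement(text)
        except geodata.ParseError as e:
            self.counters["rejected"] += 1
            return Rejection.of(Violation("$", str(e)))
        user_id = None
        if token is not None:
            user_id = self.auth.resolve(token) if self.auth is not None else None
            if user_id is None:
                self.counters["rejected"] += 1
                return Rejection.of(Violation("token", "unknown or expired token"))
        violations = geodata.validate_measurement(m, now=now)
        if violations:
            self.counters["rejected"] += 1
            return Rejection(violations=tuple(violations))
        m.received_at = int(now)
        m.user_id = user_id
        if m.id is None:
            m.id = uuid.uuid4().hex  # random 128-bit token
        self.broker.topic(self.layout.raw).append(
            key=str(m.created_at),
            value=geodata.measurement_to_feature(m),
            timestamp=m.received_at,
        )
        self.counters["ingested"] += 1
        return Confirmation(id=m.id)

    # -- preparator (re-validate, anonymize, grid-index) ---------------

    def prepare(
        self, m: Measurement
    ) -> Optional[tuple[dict[int, tuple[CellId, Measurement]], Optional[UserMapping]]]:
        """Anonymize and index one raw measurement.

        Returns per-resolution (cell, anonymized measurement) plus the
        user mapping if the record carried a user id; None if the
        record fails re-validation (counted as dropped).
        """
        now = m.received_at if m.received_at is not None else m.created_at
        if geodata.validate_measurement(m, now=now):
            self.counters["dropped_invalid"] += 1
            return None
        mapping = (
            UserMapping(user_id=m.user_id, measurement_id=m.id)
            if m.user_id is not None
            else None
        )
        anon = replace(m, user_id=None)
        out: dict[int, tuple[CellId, Measurement]] = {}
        for res in self.layout.resolutions:
            cell = index_point(m.geometry.lon, m.geometry.lat, res)
            out[res] = (cell, anon)
        return out, mapping

    def prepare_pending(self) -> int:
        """Run the preparator over unseen raw records; returns count."""
        raw_log = self.broker.topic(self.layout.raw)
        cursor_key = ("prepare", self.layout.raw)
        start = self._cursors.get(cursor_key, 0)
        n = 0
        for rec in raw_log.read_from(start):
            m = geodata.parse_measurement(rec.value)
            prepared = self.prepare(m)
            self._cursors[cursor_key] = rec.offset + 1
            if prepared is None:
                continue
            by_res, mapping = prepared
            if mapping is not None:
                self.broker.topic(self.layout.mapping).append(
                    key=mapping.user_id,
                    value={
                        "userId": mapping.user_id,
                        "measurementId": mapping.measurement_id,
                    },
                    timestamp=rec.timestamp,
                )
                if self.store is not None:
                    self.store.add_mapping(mapping.user_id, mapping.measurement_id)
            for res, (cell, anon) in by_res.items():
                self.broker.topic(self.layout.anonymized_topic(res)).append(
                    key=cell.token,
                    value={
                        "cell": cell.token,
                        "resolution": res,
                        "feature": geodata.measurement_to_feature(anon),
                    },
                    timestamp=rec.timestamp,
                )
            if self.store is not None:
                self.store.put_raw(replace(m, user_id=None))
            n += 1
        self.counters["prepared"] += n
        return n

    # -- windowed aggregator -------------------------------------------

    def _aggregate_record(self, res: int, rec: TopicRecord) -> None:
        m = geodata.parse_measurement(rec.value["feature"])
        cell_token = rec.value["cell"]
        arrival = m.received_at if m.received_at is not None else rec.timestamp
        for combo_res, length_min in self.layout.average_combos:
            if combo_res != res:
                continue
            spec = self.layout.window_spec(length_min)
            window = assign_window(m.created_at, spec, now=arrival)
            if window is LATE:
                self.counters["late_dropped"] += 1
                continue
            topic = self.layout.average_topic(res, length_min)
            state = self.state[topic]
            for sv in m.values:
                key = (cell_token, window.start, sv.kind)
                if key in state:
                    state[key] = update_stats(state[key], sv.value)
                else:
                    state[key] = init_stats(sv.value, kind=sv.kind)
                feature = AverageFeature(
                    cell=CellId.from_token(cell_token),
                    window_start=window.start,
                    window_end=window.end,
                    stats={sv.kind: state[key]},
                )
                self.broker.topic(topic).append(
                    key=cell_token,
                    value=geodata.aggregate_to_feature(feature),
                    timestamp=arrival,
                )

    def aggregate_pending(self) -> int:
        n = 0
        for res in self.layout.resolutions:
            name = self.layout.anonymized_topic(res)
            cursor_key = ("aggregate", name)
            start = self._cursors.get(cursor_key, 0)
            for rec in self.broker.topic(name).read_from(start):
                self._aggregate_record(res, rec)
                self._cursors[cursor_key] = rec.offset + 1
                n += 1
        return n

    # -- sink -----------------------------------------------------------

    def sink_pending(self) -> int:
        if self.store is None:
            return 0
        n = 0
        for (res, length_min), name in self.layout.averages:
            cursor_key = ("sink", name)
            start = self._cursors.get(cursor_key, 0)
            for rec in self.broker.topic(name).read_from(start):
                agg = geodata.parse_average_feature(rec.value)
                for kind, stats in agg.stats.items():
                    self.store.upsert_aggregate(
                        res, length_min, agg.cell.token, agg.window_start, kind, stats
                    )
                self._cursors[cursor_key] = rec.offset + 1
                n += 1
        return n

    def run(self) -> int:
        """Process all pending records through prepare/aggregate/sink.

        Incremental (safe to call repeatedly) and deterministic: a
        fresh Pipeline replaying the same raw log reaches an identical
        final state.
        """
        n = self.prepare_pending()
        self.aggregate_pending()
        self.sink_pending()
        return n
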