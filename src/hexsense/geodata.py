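"""Measurement data model and GeoJSON (RFC 7946) serialization.

One crowdsensed noise measurement is a GeoJSON Point Feature: the
geometry is the WGS84 location ([longitude, latitude] coordinate
order), the properties carry sensor metadata and one or more typed dB
values (LAeq, LCpeak, TWA, or any open-set kind).  Aggregates are
Polygon Features whose geometry is a hexagonal grid-cell boundary and
whose properties hold min/max/energetic-mean/count per kind — and,
deliberately, never any user identifier.

Wire-level property names are camelCase (``sensorType``, ``createdAt``,
``values``); timestamps are integer epoch milliseconds UTC, with
ISO-8601 strings accepted on input and normalized.  Unknown properties
pass through a preserved bag so parse/write round-trips are lossless.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Iterable, Optional, Union

from .acoustics import AggregateStats, DB_MAX, DB_MIN
from .spatial_index import CellId, cell_boundary

__all__ = [
    "GeodataError",
    "ParseError",
    "UnsupportedGeometryError",
    "GeoPoint",
    "SingleValue",
    "Measurement",
    "AverageFeature",
    "Violation",
    "canonical_kind",
    "parse_measurement",
    "parse_average_feature",
    "parse_feature",
    "validate_measurement",
    "measurement_to_feature",
    "aggregate_to_feature",
    "write_feature_collection",
    "dumps",
    "read_ndjson",
    "write_ndjson",
    "MAX_AGE_MS",
    "MAX_CLOCK_SKEW_MS",
]

# Ingress validity bounds (configurable per call): reject stale client
# timestamps and clocks running ahead of the server.
MAX_AGE_MS = 7 * 24 * 60 * 60 * 1000  # 7 days
MAX_CLOCK_SKEW_MS = 5 * 60 * 1000  # 5 minutes

_KNOWN_KINDS = {"laeq": "LAeq", "lcpeak": "LCpeak", "twa": "TWA"}


class GeodataError(ValueError):
    pass


class ParseError(GeodataError):
    """Malformed document; the message names the offending path."""

    def __init__(self, path: str, reason: str):
        self.path = path
        super().__init__(f"{path}: {reason}")


class UnsupportedGeometryError(ParseError):
    pass


def canonical_kind(label: str) -> str:
    """Normalize a measurement-kind label.

    The three standard kinds are matched case-insensitively and
    canonicalized; unknown labels are preserved verbatim (the kind set
    is open).
    """
    if not isinstance(label, str) or not label.strip():
        raise GeodataError("measurement kind must be a non-empty token")
    return _KNOWN_KINDS.get(label.strip().lower(), label.strip())


@dataclass(frozen=True)
class GeoPoint:
    lon: float
    lat: float
    alt: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "lon", float(self.lon))
        object.__setattr__(self, "lat", float(self.lat))
        if self.alt is not None:
            object.__setattr__(self, "alt", float(self.alt))

    @property
    def in_range(self) -> bool:
        return -180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0


@dataclass(frozen=True)
class SingleValue:
    kind: str
    value: float

    def __post_init__(self):
        object.__setattr__(self, "kind", canonical_kind(self.kind))
        object.__setattr__(self, "value", float(self.value))


@dataclass
class Measurement:
    """One noise measurement, pre- or post-anonymization."""

    id: Optional[str]
    geometry: GeoPoint
    sensor_type: str
    trigger: str
    created_at: int
    values: list[SingleValue]
    received_at: Optional[int] = None
    user_id: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def value_of(self, kind: str) -> Optional[float]:
        kind = canonical_kind(kind)
        for sv in self.values:
            if sv.kind == kind:
                return sv.value
        return None


@dataclass
class AverageFeature:
    """Aggregated stats for one (grid cell, time window).

    The geometry is derived from the cell token; no user data can
    appear here by construction.
    """

    cell: CellId
    window_start: int
    window_end: int
    stats: dict[str, AggregateStats]

    @property
    def resolution(self) -> int:
        return self.cell.resolution

    @property
    def geometry_ring(self) -> list[tuple[float, float]]:
        return cell_boundary(self.cell)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AverageFeature):
            return NotImplemented
        return (
            self.cell == other.cell
            and self.window_start == other.window_start
            and self.window_end == other.window_end
            and self.stats == other.stats
        )


@dataclass(frozen=True)
class Violation:
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.field}: {self.rule}"


# --- parsing ----------------------------------------------------------

def _parse_timestamp(value: Any, path: str) -> int:
    if isinstance(value, bool):
        raise ParseError(path, "timestamp must be epoch ms or ISO-8601")
    if isinstance(value, (int, float)):
        return int(value)
    if isinstance(value, str):
        try:
            dt = datetime.fromisoformat(value.replace("Z", "+00:00"))
        except ValueError:
            raise ParseError(path, f"unparseable timestamp {value!r}") from None
        if dt.tzinfo is None:
            dt = dt.replace(tzinfo=timezone.utc)
        return int(dt.timestamp() * 1000)
    raise ParseError(path, "timestamp must be epoch ms or ISO-8601")


def _as_document(text: Union[str, dict]) -> dict:
    if isinstance(text, str):
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as e:
            raise ParseError("$", f"not valid JSON: {e}") from None
    else:
        doc = text
    if not isinstance(doc, dict):
        raise ParseError("$", "document must be a JSON object")
    return doc


def _parse_point_geometry(doc: dict) -> GeoPoint:
    geom = doc.get("geometry")
    if not isinstance(geom, dict):
        raise ParseError("geometry", "missing or not an object")
    gtype = geom.get("type")
    if gtype != "Point":
        raise UnsupportedGeometryError(
            "geometry.type", f"only Point measurements are ingested, got {gtype!r}"
        )
    coords = geom.get("coordinates")
    if not isinstance(coords, (list, tuple)) or len(coords) not in (2, 3):
        raise ParseError("geometry.coordinates", "expected [lon, lat] or [lon, lat, alt]")
    try:
        lon, lat = float(coords[0]), float(coords[1])
        alt = float(coords[2]) if len(coords) == 3 else None
    except (TypeError, ValueError):
        raise ParseError("geometry.coordinates", "coordinates must be numbers") from None
    return GeoPoint(lon=lon, lat=lat, alt=alt)


_MEASUREMENT_KEYS = {"sensorType", "trigger", "createdAt", "receivedAt", "userId", "values"}


def parse_measurement(text: Union[str, dict]) -> Measurement:
    """Parse a GeoJSON Point Feature into a Measurement.

    Unknown properties are preserved in ``extra``; the writer restores
    them, so parse/write round-trips are lossless up to key order and
    float formatting.
    """
    doc = _as_document(text)
    if doc.get("type") != "Feature":
        raise ParseError("type", f"expected 'Feature', got {doc.get('type')!r}")
    geometry = _parse_point_geometry(doc)
    props = doc.get("properties")
    if not isinstance(props, dict):
        raise ParseError("properties", "missing or not an object")
    raw_values = props.get("values")
    if not isinstance(raw_values, list) or not raw_values:
        raise ParseError("properties.values", "must be a non-empty array")
    values = []
    for k, rv in enumerate(raw_values):
        path = f"properties.values[{k}]"
        if not isinstance(rv, dict):
            raise ParseError(path, "must be an object with type and value")
        if "type" not in rv or "value" not in rv:
            raise ParseError(path, "must contain 'type' and 'value'")
        try:
            values.append(SingleValue(kind=rv["type"], value=rv["value"]))
        except (TypeError, ValueError) as e:
            raise ParseError(path, str(e)) from None
    if "createdAt" not in props:
        raise ParseError("properties.createdAt", "missing")
    created_at = _parse_timestamp(props["createdAt"], "properties.createdAt")
    received_at = (
        _parse_timestamp(props["receivedAt"], "properties.receivedAt")
        if "receivedAt" in props
        else None
    )
    mid = doc.get("id")
    extra = {k: v for k, v in props.items() if k not in _MEASUREMENT_KEYS}
    return Measurement(
        id=str(mid) if mid is not None else None,
        geometry=geometry,
        sensor_type=str(props.get("sensorType", "")),
        trigger=str(props.get("trigger", "")),
        created_at=created_at,
        received_at=received_at,
        user_id=str(props["userId"]) if props.get("userId") is not None else None,
        values=values,
        extra=extra,
    )


def parse_average_feature(text: Union[str, dict]) -> AverageFeature:
    doc = _as_document(text)
    if doc.get("type") != "Feature":
        raise ParseError("type", f"expected 'Feature', got {doc.get('type')!r}")
    props = doc.get("properties")
    if not isinstance(props, dict) or "cell" not in props:
        raise ParseError("properties.cell", "aggregate features require a cell token")
    cell = CellId.from_token(str(props["cell"]))
    stats: dict[str, AggregateStats] = {}
    raw = props.get("stats")
    if not isinstance(raw, dict) or not raw:
        raise ParseError("properties.stats", "must be a non-empty object")
    for kind, s in raw.items():
        try:
            stats[canonical_kind(kind)] = AggregateStats(
                min=float(s["min"]),
                max=float(s["max"]),
                count=int(s["count"]),
                mean_energy=10.0 ** (float(s["mean"]) / 10.0),
                kind=canonical_kind(kind),
            )
        except (KeyError, TypeError, ValueError) as e:
            raise ParseError(f"properties.stats.{kind}", str(e)) from None
    return AverageFeature(
        cell=cell,
        window_start=_parse_timestamp(props["windowStart"], "properties.windowStart"),
        window_end=_parse_timestamp(props["windowEnd"], "properties.windowEnd"),
        stats=stats,
    )


def parse_feature(text: Union[str, dict]) -> Union[Measurement, AverageFeature]:
    doc = _as_document(text)
    props = doc.get("properties") or {}
    if isinstance(props, dict) and "stats" in props and "cell" in props:
        return parse_average_feature(doc)
    return parse_measurement(doc)


# --- validation -------------------------------------------------------

def validate_measurement(
    m: Measurement,
    now: int,
    max_age_ms: int = MAX_AGE_MS,
    max_clock_skew_ms: int = MAX_CLOCK_SKEW_MS,
) -> list[Violation]:
    """Ingress validity check; an empty list means the record is OK.

    Violations are data, not exceptions: each names the field and the
    broken rule so rejections can be reported back to the client.
    """
    out: list[Violation] = []
    if not -180.0 <= m.geometry.lon <= 180.0:
        out.append(Violation("lon", "lon out of range [-180, 180]"))
    if not -90.0 <= m.geometry.lat <= 90.0:
        out.append(Violation("lat", "lat out of range [-90, 90]"))
    if not m.values:
        out.append(Violation("values", "at least one value required"))
    seen: set[str] = set()
    for k, sv in enumerate(m.values):
        if not (DB_MIN <= sv.value <= DB_MAX) or not math.isfinite(sv.value):
            out.append(
                Violation(f"values[{k}].value", f"value out of range [{DB_MIN:g}, {DB_MAX:g}] dB")
            )
        if sv.kind in seen:
            out.append(Violation(f"values[{k}].type", f"duplicate kind {sv.kind}"))
        seen.add(sv.kind)
    if m.created_at < now - max_age_ms:
        out.append(Violation("createdAt", "stale timestamp (older than max age)"))
    elif m.created_at > now + max_clock_skew_ms:
        out.append(Violation("createdAt", "timestamp in the future beyond clock skew"))
    if m.received_at is not None and m.received_at < 0:
        out.append(Violation("receivedAt", "must be >= 0"))
    return out


# --- writing ----------------------------------------------------------

def measurement_to_feature(m: Measurement) -> dict:
    coords: list[float] = [m.geometry.lon, m.geometry.lat]
    if m.geometry.alt is not None:
        coords.append(m.geometry.alt)
    props: dict[str, Any] = {
        "sensorType": m.sensor_type,
        "trigger": m.trigger,
        "createdAt": m.created_at,
        "values": [{"type": sv.kind, "value": sv.value} for sv in m.values],
    }
    if m.received_at is not None:
        props["receivedAt"] = m.received_at
    if m.user_id is not None:
        props["userId"] = m.user_id
    props.update(m.extra)
    feature: dict[str, Any] = {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": coords},
        "properties": props,
    }
    if m.id is not None:
        feature["id"] = m.id
    return feature


def aggregate_to_feature(a: AverageFeature) -> dict:
    """Serialize an aggregate as a Polygon Feature.

    Properties carry, per kind, exactly min/max/mean/count; the mean is
    the energetic mean in dB.  No user-related key can appear.
    """
    ring = [[lon, lat] for lon, lat in a.geometry_ring]
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring]},
        "properties": {
            "cell": a.cell.token,
            "resolution": a.resolution,
            "windowStart": a.window_start,
            "windowEnd": a.window_end,
            "stats": {
                kind: {"min": s.min, "max": s.max, "mean": s.mean, "count": s.count}
                for kind, s in sorted(a.stats.items())
            },
        },
    }


def _to_feature(x: Union[Measurement, AverageFeature]) -> dict:
    if isinstance(x, Measurement):
        return measurement_to_feature(x)
    if isinstance(x, AverageFeature):
        return aggregate_to_feature(x)
    raise GeodataError(f"cannot serialize {type(x).__name__} as a feature")


def write_feature_collection(features: Iterable[Union[Measurement, AverageFeature]]) -> dict:
    return {"type": "FeatureCollection", "features": [_to_feature(x) for x in features]}


def dumps(obj: Union[dict, Measurement, AverageFeature]) -> str:
    """Stable JSON text (sorted keys, no whitespace padding)."""
    if isinstance(obj, (Measurement, AverageFeature)):
        obj = _to_feature(obj)
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), allow_nan=False)


def write_ndjson(features: Iterable[Union[Measurement, AverageFeature]], path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for x in features:
            fh.write(dumps(x) + "\n")
            n += 1
    return n


def read_ndjson(path) -> list[Union[Measurement, AverageFeature]]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_feature(line))
    return out
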