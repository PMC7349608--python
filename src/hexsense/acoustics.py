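"""Decibel-correct statistics for sound-level aggregation.

Sound levels are logarithmic: averaging LAeq values in dB directly
understates loud events.  All means here are *energetic* — computed in
the linear relative-power domain and converted back:

    L_mean = 10 * log10( (1/n) * sum_i 10^(L_i / 10) )

The running aggregate carries the linear ``mean_energy`` so that
incremental updates and merges do not accumulate log/exp drift; the dB
mean is derived on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "AcousticsError",
    "SampleSeries",
    "AggregateStats",
    "energetic_mean",
    "laeq",
    "lc_peak",
    "init_stats",
    "update_stats",
    "merge_stats",
    "batch_stats",
    "DB_MIN",
    "DB_MAX",
]

# Physical validity range for sound pressure levels in air: 194 dB SPL
# is the theoretical undistorted maximum at sea level.
DB_MIN = 0.0
DB_MAX = 194.0


class AcousticsError(ValueError):
    pass


def _to_energy(level_db: float) -> float:
    return 10.0 ** (level_db / 10.0)


def _to_db(energy: float) -> float:
    return 10.0 * math.log10(energy)


def energetic_mean(levels: Sequence[float]) -> float:
    """Energetic (power-domain) mean of dB levels.

    Always lies in [min(levels), max(levels)] and is >= the arithmetic
    mean (Jensen's inequality), with equality iff all levels are equal.
    """
    levels = list(levels)
    if not levels:
        raise AcousticsError("energetic_mean requires at least one level")
    return _to_db(sum(_to_energy(v) for v in levels) / len(levels))


@dataclass(frozen=True)
class SampleSeries:
    """Uniformly spaced sound-level samples, e.g. a 30 s capture."""

    levels: tuple[float, ...]
    interval: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        if not self.levels:
            raise AcousticsError("sample series must be non-empty")
        if not self.interval > 0:
            raise AcousticsError("sample interval must be positive")


def laeq(series: SampleSeries) -> float:
    """Equivalent continuous sound level over the series.

    For uniform sampling this is the energetic mean of the samples: the
    constant level carrying the same acoustic energy as the varying
    signal over the capture period.
    """
    return energetic_mean(series.levels)


def lc_peak(series: SampleSeries) -> float:
    """Peak sound level over the series (the maximum sample)."""
    return max(series.levels)


@dataclass(frozen=True, eq=False)
class AggregateStats:
    """Mergeable min/max/energetic-mean/count for one measurement kind.

    ``mean_energy`` is the linear relative-power carrier of the mean;
    ``mean`` (dB) is derived.  Equality compares min, max, count
    exactly and the dB mean to within 1e-12 (one JSON serialization
    cycle perturbs the mean by < 1e-14 dB).
    """

    min: float
    max: float
    count: int
    mean_energy: float
    kind: Optional[str] = None

    @property
    def mean(self) -> float:
        return _to_db(self.mean_energy)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AggregateStats):
            return NotImplemented
        return (
            self.min == other.min
            and self.max == other.max
            and self.count == other.count
            and self.kind == other.kind
            and abs(self.mean - other.mean) <= 1e-12
        )

    def __hash__(self) -> int:
        return hash((self.min, self.max, self.count, self.kind))


def init_stats(value: float, kind: Optional[str] = None) -> AggregateStats:
    """Aggregate of a single observation."""
    value = float(value)
    return AggregateStats(
        min=value, max=value, count=1, mean_energy=_to_energy(value), kind=kind
    )


def update_stats(stats: AggregateStats, value: float) -> AggregateStats:
    """Fold one new observation into an aggregate.

    Equivalent (to ~1e-15 dB) to recomputing the batch energetic mean
    over the full multiset, in any fold order.
    """
    value = float(value)
    n = stats.count
    return AggregateStats(
        min=min(stats.min, value),
        max=max(stats.max, value),
        count=n + 1,
        mean_energy=(n * stats.mean_energy + _to_energy(value)) / (n + 1),
        kind=stats.kind,
    )


def merge_stats(a: AggregateStats, b: AggregateStats) -> AggregateStats:
    """Count-weighted combination of two aggregates.

    Commutative, and associative to within float rounding; equals the
    batch recomputation over the union multiset.  Both operands must
    describe the same measurement kind.
    """
    if a.kind is not None and b.kind is not None and a.kind != b.kind:
        raise AcousticsError(f"cannot merge stats of kinds {a.kind!r} and {b.kind!r}")
    n = a.count + b.count
    return AggregateStats(
        min=min(a.min, b.min),
        max=max(a.max, b.max),
        count=n,
        mean_energy=(a.count * a.mean_energy + b.count * b.mean_energy) / n,
        kind=a.kind if a.kind is not None else b.kind,
    )


def batch_stats(values: Iterable[float], kind: Optional[str] = None) -> AggregateStats:
    """From-scratch aggregate over a value multiset (batch oracle path)."""
    values = [float(v) for v in values]
    if not values:
        raise AcousticsError("batch_stats requires at least one value")
    return AggregateStats(
        min=min(values),
        max=max(values),
        count=len(values),
        mean_energy=sum(_to_energy(v) for v in values) / len(values),
        kind=kind,
    )
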