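"""Load-test harness: simultaneous requests, median CIs, stopping rule.

Methodology: a run releases ``n_users`` requests simultaneously
(threads behind a barrier) against an endpoint and records per-request
wall time; the run's *median* is treated as one measurement.  Runs are
repeated, the median-of-medians and its distribution-free confidence
interval recomputed after each run, until both a minimum repeat count
is reached (default 20) and the CI lies within a tolerance band around
the median (default 5% at confidence 0.95).  A least-squares trend
over (user count, median) diagnoses scaling behaviour; absolute times
are hardware-bound and never asserted.

The CI is the exact binomial order-statistic interval for the median:
with n sorted run-medians x_(1..n), the interval [x_(l), x_(u)] with
l the largest rank whose lower binomial(n, 1/2) tail is <= alpha/2 and
u = n + 1 - l covers the true median with probability >= 1 - alpha.
At least 6 samples are required for a non-trivial interval at 0.95.
"""

from __future__ import annotations

import csv
import statistics
import threading
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import binom

__all__ = [
    "BenchError",
    "ConnectivityError",
    "BenchConfig",
    "BenchRow",
    "BenchResult",
    "run_load",
    "median_ci",
    "run_benchmark",
    "trend",
    "inversions",
    "sleep_endpoint",
]

Endpoint = Callable[[], object]


class BenchError(ValueError):
    pass


class ConnectivityError(BenchError):
    """The endpoint failed; no partial result is reported."""


@dataclass(frozen=True)
class BenchConfig:
    user_counts: tuple[int, ...] = tuple(range(500, 5001, 500))
    repeats: int = 20
    confidence: float = 0.95
    ci_tolerance: float = 0.05  # CI must lie within +-5% of the median
    max_runs: int = 200

    def __post_init__(self):
        if self.repeats <= 5:
            raise BenchError("repeats must be > 5 so that CIs are computable")
        if not 0.0 < self.confidence < 1.0:
            raise BenchError("confidence must be in (0, 1)")


@dataclass(frozen=True)
class BenchRow:
    users: int
    median_ms: float
    ci_low_ms: float
    ci_high_ms: float
    runs: int
    converged: bool


@dataclass
class BenchResult:
    rows: list[BenchRow] = field(default_factory=list)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["users", "median_ms", "ci_low_ms", "ci_high_ms", "runs", "converged"])
            for r in self.rows:
                w.writerow(
                    [r.users, r.median_ms, r.ci_low_ms, r.ci_high_ms, r.runs, int(r.converged)]
                )


def run_load(endpoint: Endpoint, n_users: int) -> list[float]:
    """One run: ``n_users`` simultaneous requests; per-request ms times.

    All workers block on a barrier and are released at once, modelling
    users that hit the service at the same instant.  Any endpoint
    exception aborts the run with a ConnectivityError.
    """
    if n_users < 1:
        raise BenchError("n_users must be >= 1")
    barrier = threading.Barrier(n_users)
    times: list[Optional[float]] = [None] * n_users
    errors: list[BaseException] = []

    def worker(i: int) -> None:
        try:
            barrier.wait()
            t0 = time.perf_counter()
            endpoint()
            times[i] = (time.perf_counter() - t0) * 1000.0
        except BaseException as e:  # noqa: BLE001 - reported as connectivity failure
            errors.append(e)
            barrier.abort()

    threads = [threading.Thread(target=worker, args=(i,)) for i in range(n_users)]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    if errors or any(t is None for t in times):
        raise ConnectivityError(f"endpoint failed during load run: {errors[:1]}")
    return [float(t) for t in times]


def median_ci(samples: Sequence[float], confidence: float = 0.95) -> tuple[float, float, float]:
    """(median, ci_low, ci_high) by the binomial order-statistic method."""
    n = len(samples)
    if n <= 5:
        raise BenchError("more than 5 samples are required to compute the CI")
    xs = sorted(float(v) for v in samples)
    alpha = 1.0 - confidence
    # largest rank l (1-based) with P(X < l) <= alpha/2 for X ~ B(n, 1/2)
    l = 1
    for k in range(1, n // 2 + 1):
        if binom.cdf(k - 1, n, 0.5) <= alpha / 2.0:
            l = k
        else:
            break
    u = n + 1 - l
    return statistics.median(xs), xs[l - 1], xs[u - 1]


def run_benchmark(config: BenchConfig, endpoint: Endpoint) -> BenchResult:
    """Full protocol over every configured user count.

    Per user count: repeat load runs, keep each run's median, and stop
    once at least ``config.repeats`` runs were taken *and* the CI lies
    within ``ci_tolerance`` of the median; give up (flagged
    non-converged) at ``max_runs``.
    """
    result = BenchResult()
    for users in config.user_counts:
        medians: list[float] = []
        converged = False
        while len(medians) < config.max_runs:
            medians.append(statistics.median(run_load(endpoint, users)))
            if len(medians) < max(config.repeats, 6):
                continue
            med, lo, hi = median_ci(medians, config.confidence)
            if med > 0 and lo >= med * (1 - config.ci_tolerance) and hi <= med * (
                1 + config.ci_tolerance
            ):
                converged = True
                break
        med, lo, hi = median_ci(medians, config.confidence)
        result.rows.append(
            BenchRow(
                users=users,
                median_ms=med,
                ci_low_ms=lo,
                ci_high_ms=hi,
                runs=len(medians),
                converged=converged,
            )
        )
    return result


def trend(result: BenchResult) -> tuple[float, float, float]:
    """(slope ms/user, intercept ms, R^2) of the median vs. user count.

    Least squares over the result rows; a diagnostic of (near-)linear
    scaling, not a statement about absolute response times.  Also
    available: ``inversions`` to flag non-monotone medians.
    """
    if len(result.rows) < 3:
        raise BenchError("trend needs at least 3 user counts")
    x = np.array([r.users for r in result.rows], dtype=float)
    y = np.array([r.median_ms for r in result.rows], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)


def inversions(result: BenchResult) -> list[tuple[int, int]]:
    """User-count pairs where the median *decreased* with more load."""
    out = []
    rows = result.rows
    for a, b in zip(rows, rows[1:]):
        if b.median_ms < a.median_ms:
            out.append((a.users, b.users))
    return out


def sleep_endpoint(
    base_ms: float, jitter_frac: float = 0.0, seed: Optional[int] = None
) -> Endpoint:
    """Stub endpoint sleeping ``base_ms`` (+- uniform jitter fraction).

    Deterministic jitter sequence per seed; thread-safe.
    """
    rng = np.random.default_rng(seed)
    lock = threading.Lock()

    def call() -> None:
        if jitter_frac:
            with lock:
                f = 1.0 + rng.uniform(-jitter_frac, jitter_frac)
        else:
            f = 1.0
        time.sleep(base_ms * f / 1000.0)

    return call
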