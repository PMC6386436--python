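"""Benchmark harness: reduction factor, speedup, and the Amdahl view.

Timings use a monotonic clock, best-of-repeats.  With t_n the hull time on
the full set, t_r the reduction time, and t_s the hull time on the reduced
set, the measured speedup is t_n / (t_r + t_s).  Framing the preprocessing
as Amdahl's law with enhanced fraction f = p_r = 1 - s/n and enhanced
speedup k estimated as

    k = t_n (n - s) / (n (t_r + t_s) - s t_n)

gives the prediction 1 / ((1 - p_r) + p_r / k) — which is algebraically
identical to the measured speedup, a closed-form identity the test suite
asserts to floating-point tolerance.  Wall-clock numbers are reported,
never asserted: they are hardware facts, not method facts.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, fields

from .errors import ValidationError
from .hulls import HullPolygon, chan_hull, jarvis_hull, monotone_chain_hull
from .pointset import PointSet
from .reduction import reduce_points

__all__ = [
    "HULL_ALGORITHMS",
    "BenchRecord",
    "reduction_factor",
    "measure_speedup",
    "amdahl_decompose",
    "write_bench_csv",
]

HULL_ALGORITHMS = {
    "monotone": monotone_chain_hull,
    "chan": chan_hull,
    "jarvis": jarvis_hull,
}

_CSV_COLUMNS = [
    "algorithm", "n", "m", "s", "p_r",
    "t_r", "t_s", "t_n", "speedup", "k", "predicted_speedup",
]


@dataclass(frozen=True)
class BenchRecord:
    algorithm: str
    n: int
    m: int
    s: int
    p_r: float
    t_r: float
    t_s: float
    t_n: float
    speedup: float
    k: float
    predicted_speedup: float


def reduction_factor(n: int, s: int) -> float:
    """p_r = 1 - s/n, the fraction of points removed."""
    if not 1 <= s <= n:
        raise ValidationError(f"need 1 <= s <= n, got s={s}, n={n}")
    return 1.0 - s / n


def _best_time(fn, repeats: int) -> float:
    best = float("inf")
    for _ in range(repeats):
        start = time.perf_counter()
        fn()
        best = min(best, time.perf_counter() - start)
    return best


def measure_speedup(
    points: PointSet, m: int | str = "auto", algorithm: str = "monotone",
    repeats: int = 3,
) -> BenchRecord:
    """Time the hull with and without preprocessing and fill a BenchRecord.

    The hulls with and without preprocessing are verified to be identical
    before any timing is reported; a mismatch is a hard error because
    correctness precedes timing.
    """
    if algorithm not in HULL_ALGORITHMS:
        raise ValidationError(
            f"unknown hull algorithm {algorithm!r}; "
            f"choose from {', '.join(HULL_ALGORITHMS)}"
        )
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    hull_fn = HULL_ALGORITHMS[algorithm]

    result = reduce_points(points, m)
    reduced = points.take(result.indices)
    full_hull = hull_fn(points)
    reduced_hull = hull_fn(reduced)
    if not _same_hull(full_hull, reduced_hull):
        raise ValidationError(
            "hull of the reduced set differs from the hull of the full set"
        )

    t_r = _best_time(lambda: reduce_points(points, m), repeats)
    t_n = _best_time(lambda: hull_fn(points), repeats)
    t_s = _best_time(lambda: hull_fn(reduced), repeats)

    n, s = result.n, result.s
    p_r = reduction_factor(n, s)
    speedup = t_n / (t_r + t_s) if t_r + t_s > 0 else float("inf")
    try:
        k, predicted = amdahl_from_times(n, s, t_n, t_r, t_s)
    except ValidationError:
        k, predicted = float("nan"), float("nan")
    return BenchRecord(
        algorithm, n, result.m_used, s, p_r, t_r, t_s, t_n, speedup, k, predicted
    )


def _same_hull(a: HullPolygon, b: HullPolygon) -> bool:
    return a.h == b.h and bool(
        (a.x == b.x).all() and (a.y == b.y).all()
    )


def amdahl_from_times(
    n: int, s: int, t_n: float, t_r: float, t_s: float
) -> tuple[float, float]:
    """Enhanced-speedup estimate k and the Amdahl speedup prediction."""
    denom = n * (t_r + t_s) - s * t_n
    if denom == 0:
        raise ValidationError("Amdahl decomposition undefined: n(t_r+t_s) = s*t_n")
    k = t_n * (n - s) / denom
    p_r = 1.0 - s / n
    if p_r == 0.0:
        return k, 1.0  # nothing was enhanced: the Amdahl limit for any k
    predicted = 1.0 / ((1.0 - p_r) + p_r / k)
    return k, predicted


def amdahl_decompose(record: BenchRecord) -> tuple[float, float]:
    """k and predicted speedup recomputed from a record's own fields."""
    return amdahl_from_times(record.n, record.s, record.t_n, record.t_r, record.t_s)


def write_bench_csv(records, path) -> None:
    """One BenchRecord per row; columns fixed by the harness schema."""
    assert _CSV_COLUMNS == [f.name for f in fields(BenchRecord)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for rec in records:
            writer.writerow([getattr(rec, c) for c in _CSV_COLUMNS])
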