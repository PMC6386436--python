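"""Synthetic point sets: uniform samples inside convex superellipses and
deterministic degenerate fixtures.

The superellipse |x/a|^t + |y/b|^t <= 1 is convex for t >= 1 and sweeps
from a rhombus (t = 1) to a rectangle with rounded corners (t -> inf),
which makes it a convenient family of convex supports whose boundary
curvature — and hence hull vertex count — varies widely.  Sampling is by
rejection from the bounding box, which is exactly uniform on the region;
the worst-case acceptance rate is 1/2 at t = 1.

``random_superellipse`` draws the shape exponent t ~ Uniform[1.5, 8] and
the aspect ratio a/b ~ Uniform[0.5, 2]; these ranges are this package's
choice of "random convex superellipse" for its parameter-sweep and
acceptance experiments.  ``random_instance`` provides the randomized
point-set families (uniform, Gaussian, clustered, collinear-heavy,
duplicate-heavy, integer-grid, superellipse) used by the property tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .pointset import PointSet

__all__ = [
    "SuperellipseSpec",
    "sample_superellipse",
    "random_superellipse",
    "make_fixture",
    "FIXTURE_NAMES",
    "FAMILIES",
    "random_instance",
]


@dataclass(frozen=True)
class SuperellipseSpec:
    """Parameters of one uniform-superellipse sample."""

    a: float = 1.0  # x semi-axis
    b: float = 1.0  # y semi-axis
    t: float = 2.0  # shape exponent; >= 1 keeps the region convex
    n: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t < 1.0:
            raise ValidationError(
                f"shape exponent t must be >= 1 for a convex region, got {self.t}"
            )
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("semi-axes must be positive")
        if self.n < 0:
            raise ValidationError("sample count must be non-negative")


def sample_superellipse(
    spec: SuperellipseSpec, rng: np.random.Generator | None = None
) -> PointSet:
    """n i.i.d. uniform points in |x/a|^t + |y/b|^t <= 1 by rejection."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    remaining = spec.n
    while remaining > 0:
        batch = max(1024, int(2.2 * remaining))
        x = rng.uniform(-spec.a, spec.a, batch)
        y = rng.uniform(-spec.b, spec.b, batch)
        inside = np.abs(x / spec.a) ** spec.t + np.abs(y / spec.b) ** spec.t <= 1.0
        x, y = x[inside], y[inside]
        if x.shape[0] > remaining:
            x, y = x[:remaining], y[:remaining]
        xs.append(x)
        ys.append(y)
        remaining -= x.shape[0]
    return PointSet(np.concatenate(xs), np.concatenate(ys))


def random_superellipse(n: int, rng: np.random.Generator) -> PointSet:
    """Uniform sample in a randomly shaped convex superellipse.

    t ~ Uniform[1.5, 8]; aspect a/b ~ Uniform[0.5, 2] with b = 1.
    """
    t = rng.uniform(1.5, 8.0)
    a = rng.uniform(0.5, 2.0)
    spec = SuperellipseSpec(a=a, b=1.0, t=t, n=n)
    return sample_superellipse(spec, rng)


_FIXTURES = {
    "square_plus_center": [(0, 0), (4, 0), (4, 4), (0, 4), (2, 2)],
    "collinear_horizontal": [(0, 1), (1, 1), (2, 1), (3, 1), (4, 1)],
    "vertical_line": [(1, -2), (1, 0), (1, 3), (1, 7), (1, 5)],
    "duplicates": [(0, 0), (1, 2), (1, 2), (3, 0), (0, 0), (2, 5)],
    "integer_grid": [(i, j) for i in range(5) for j in range(4)],
    "xtie_extremes": [(0, 3), (0, -1), (0, 1), (5, 2), (5, 4), (5, -2), (2, 0)],
    "fig1_like": [
        (0.0, 5.0), (1.0, 2.5), (2.0, 1.0), (3.0, 4.0), (4.0, 6.0),
        (4.5, 0.5), (5.5, 3.0), (6.0, 7.0), (7.0, 2.0), (8.0, 0.0),
        (8.5, 5.0), (9.0, 4.0), (3.5, 3.0), (5.0, 4.5), (6.5, 4.0),
    ],
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> PointSet:
    """Named deterministic fixture point sets for degenerate-path testing."""
    try:
        pairs = _FIXTURES[name]
    except KeyError:
        raise ValidationError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return PointSet.from_pairs(pairs)


FAMILIES = (
    "uniform",
    "gaussian",
    "clustered",
    "collinear",
    "duplicates",
    "grid",
    "superellipse",
)


def random_instance(family: str, n: int, rng: np.random.Generator) -> PointSet:
    """One random point set from a named family, for randomized testing."""
    if family == "uniform":
        return PointSet(rng.uniform(0, 1, n), rng.uniform(0, 1, n))
    if family == "gaussian":
        return PointSet(rng.normal(0, 1, n), rng.normal(0, 1, n))
    if family == "clustered":
        k = max(1, min(5, n // 3))
        centers = rng.uniform(-10, 10, size=(k, 2))
        which = rng.integers(0, k, n)
        return PointSet(
            centers[which, 0] + rng.normal(0, 0.3, n),
            centers[which, 1] + rng.normal(0, 0.3, n),
        )
    if family == "collinear":
        # most points exactly on a line with small-integer direction; all
        # coordinates are integers so collinearity is exact in float64
        # (the predicates are non-robust by design, so the degenerate
        # family must be exactly degenerate, not epsilon-degenerate)
        dx = int(rng.integers(1, 8))
        dy = int(rng.integers(-7, 8))
        s = rng.integers(-1000, 1001, n)
        x = (s * dx).astype(float)
        y = (s * dy).astype(float)
        off = rng.random(n) < 0.15
        y = np.where(off, y + rng.integers(1, 200, n), y)
        return PointSet(x, y)
    if family == "duplicates":
        base = max(1, n // 3)
        x = rng.uniform(0, 1, base)
        y = rng.uniform(0, 1, base)
        pick = rng.integers(0, base, n)
        return PointSet(x[pick], y[pick])
    if family == "grid":
        lim = max(2, int(np.sqrt(n)) + 1)
        return PointSet(
            rng.integers(0, lim, n).astype(float),
            rng.integers(0, lim, n).astype(float),
        )
    if family == "superellipse":
        return random_superellipse(n, rng)
    raise ValidationError(
        f"unknown family {family!r}; valid families: {', '.join(FAMILIES)}"
    )
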