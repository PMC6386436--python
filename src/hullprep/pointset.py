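"""The planar point-set container used throughout the package.

Points live in two parallel coordinate vectors so that every downstream
result (fences, hulls, reduced subsets) can be expressed as stable 0-based
indices into the original input — the natural contract for a preprocessor
whose output is "the indices of the points you still need".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["PointSet"]


@dataclass(frozen=True)
class PointSet:
    """A set of n 2D points stored as parallel ``x`` and ``y`` vectors.

    Coordinates are float64; point order is meaningful (it defines the
    0-based index of each point) and is never changed by any operation.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.ascontiguousarray(self.x, dtype=np.float64)
        y = np.ascontiguousarray(self.y, dtype=np.float64)
        if x.ndim != 1 or y.ndim != 1:
            raise ValidationError("coordinate vectors must be one-dimensional")
        if x.shape[0] != y.shape[0]:
            raise ValidationError(
                f"coordinate vectors differ in length: {x.shape[0]} vs {y.shape[0]}"
            )
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @classmethod
    def from_pairs(cls, pairs) -> "PointSet":
        """Build from an iterable of (x, y) pairs."""
        arr = np.asarray(list(pairs), dtype=np.float64)
        if arr.size == 0:
            return cls(np.empty(0), np.empty(0))
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError("expected an iterable of (x, y) pairs")
        return cls(arr[:, 0].copy(), arr[:, 1].copy())

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def __len__(self) -> int:
        return self.n

    def point(self, i: int) -> tuple[float, float]:
        return float(self.x[i]), float(self.y[i])

    def take(self, indices) -> "PointSet":
        """Subset by point indices (the subset keeps its own 0-based order)."""
        idx = np.asarray(indices, dtype=np.intp)
        return PointSet(self.x[idx], self.y[idx])

    def validate_finite(self) -> None:
        """Reject NaN/Inf coordinates, naming the first offending row."""
        bad = ~(np.isfinite(self.x) & np.isfinite(self.y))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"non-finite coordinate at row {row}: "
                f"({self.x[row]!r}, {self.y[row]!r})"
            )

    def require_nonempty(self) -> None:
        if self.n == 0:
            raise ValidationError("point set is empty")
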