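"""Half-open time-interval sets.

Behavioral epochs (object-exploration bouts, tone blocks) and stimulation
on-phases are all represented as ordered, disjoint half-open intervals
``[start_s, end_s)`` in seconds.  Half-open intervals make adjacency
unambiguous: ``[0, 1)`` and ``[1, 2)`` touch but do not overlap, and their
union has measure exactly 2.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator

import numpy as np


class IntervalSet:
    """An ordered set of disjoint half-open intervals [start, end) in seconds.

    Overlapping or touching input intervals are merged on construction, so
    the stored representation is canonical: two IntervalSets are equal iff
    they cover the same set of time points.
    """

    __slots__ = ("_arr",)

    def __init__(self, intervals: Iterable[tuple[float, float]] = ()):
        arr = np.asarray(list(intervals), dtype=float)
        if arr.size == 0:
            self._arr = np.empty((0, 2), dtype=float)
            return
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("intervals must be (start, end) pairs")
        if not np.all(np.isfinite(arr)):
            raise ValueError("interval bounds must be finite")
        if np.any(arr[:, 1] <= arr[:, 0]):
            raise ValueError("each interval must satisfy end > start")
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        merged = [arr[0].copy()]
        for start, end in arr[1:]:
            if start <= merged[-1][1]:  # overlap or touch: merge
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append(np.array([start, end]))
        self._arr = np.vstack(merged)

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._arr)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(map(tuple, self._arr))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._arr.shape == other._arr.shape and np.allclose(
            self._arr, other._arr
        )

    def __repr__(self) -> str:
        inner = ", ".join(f"[{s:g}, {e:g})" for s, e in self)
        return f"IntervalSet({{{inner}}})"

    @property
    def array(self) -> np.ndarray:
        """(n, 2) float array of [start, end) bounds; a copy."""
        return self._arr.copy()

    # -- measure theory ----------------------------------------------------
    def measure(self) -> float:
        """Total covered time in seconds."""
        if len(self._arr) == 0:
            return 0.0
        return float(np.sum(self._arr[:, 1] - self._arr[:, 0]))

    def span(self) -> tuple[float, float] | None:
        """(first start, last end), or None when empty."""
        if len(self._arr) == 0:
            return None
        return float(self._arr[0, 0]), float(self._arr[-1, 1])

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other))

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        a, b = self._arr, other._arr
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i, 0], b[j, 0])
            hi = min(a[i, 1], b[j, 1])
            if lo < hi:
                out.append((lo, hi))
            if a[i, 1] <= b[j, 1]:
                i += 1
            else:
                j += 1
        return IntervalSet(out)

    def contains(self, t: float) -> bool:
        """Whether time point ``t`` lies inside the set."""
        idx = np.searchsorted(self._arr[:, 0], t, side="right") - 1
        return idx >= 0 and t < self._arr[idx, 1]

    def shift(self, dt: float) -> "IntervalSet":
        return IntervalSet((s + dt, e + dt) for s, e in self)
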