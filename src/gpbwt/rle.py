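"""Run-length-compressed integer array with rank-before and positional insert.

Backs the B[] arrays of the haplotype index.  Linkage makes neighbouring B[]
entries identical, so maximal runs of (value, length) pairs compress well and
run count, not logical length, governs storage and query cost.

Rank and random access use binary search over lazily rebuilt cumulative run
offsets plus per-value cumulative counts; inserts invalidate the caches, so
the contract is O(log runs) amortized over query-heavy workloads.
"""

from __future__ import annotations

import struct
from bisect import bisect_left, bisect_right
from typing import Iterable, Iterator


class RLEError(ValueError):
    pass


class RunLengthArray:
    """Integer array stored as maximal runs of equal values.

    Values are small non-negative integers (local-alphabet codes); adjacent
    runs always carry distinct values and every run has positive length.
    """

    __slots__ = ("_values", "_lengths", "_length", "_ends", "_vruns", "_vprefix")

    def __init__(self, runs: Iterable[tuple[int, int]] = ()) -> None:
        self._values: list[int] = []
        self._lengths: list[int] = []
        self._length = 0
        self._ends: list[int] | None = None
        self._vruns: dict[int, list[int]] | None = None
        self._vprefix: dict[int, list[int]] | None = None
        for value, length in runs:
            if length <= 0:
                raise RLEError("run length must be positive")
            if value < 0:
                raise RLEError("run value must be non-negative")
            if self._values and self._values[-1] == value:
                raise RLEError("adjacent runs must have distinct values")
            self._values.append(value)
            self._lengths.append(length)
            self._length += length

    # -- caches -----------------------------------------------------------

    def _invalidate(self) -> None:
        self._ends = None
        self._vruns = None
        self._vprefix = None

    def _ensure_ends(self) -> list[int]:
        if self._ends is None:
            ends: list[int] = []
            total = 0
            for n in self._lengths:
                total += n
                ends.append(total)
            self._ends = ends
        return self._ends

    def _ensure_value_index(self) -> tuple[dict[int, list[int]], dict[int, list[int]]]:
        if self._vruns is None:
            vruns: dict[int, list[int]] = {}
            vprefix: dict[int, list[int]] = {}
            for j, (v, n) in enumerate(zip(self._values, self._lengths)):
                runs = vruns.setdefault(v, [])
                pref = vprefix.setdefault(v, [0])
                runs.append(j)
                pref.append(pref[-1] + n)
            self._vruns, self._vprefix = vruns, vprefix
        return self._vruns, self._vprefix  # type: ignore[return-value]

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return self._length

    @property
    def run_count(self) -> int:
        return len(self._values)

    @property
    def runs(self) -> list[tuple[int, int]]:
        return list(zip(self._values, self._lengths))

    def _run_of(self, i: int) -> int:
        """Index of the run containing logical position i (0 <= i < length)."""
        ends = self._ensure_ends()
        return bisect_right(ends, i)

    def value_at(self, i: int) -> int:
        if not 0 <= i < self._length:
            raise RLEError(f"index {i} out of range [0, {self._length})")
        return self._values[self._run_of(i)]

    def rank_before(self, value: int, i: int) -> int:
        """Number of positions j < i holding ``value`` (0 for absent values)."""
        if not 0 <= i <= self._length:
            raise RLEError(f"rank position {i} out of range [0, {self._length}]")
        if i == 0:
            return 0
        vruns, vprefix = self._ensure_value_index()
        if value not in vruns:
            return 0
        ends = self._ensure_ends()
        j = bisect_right(ends, i - 1)  # run containing position i-1
        runs = vruns[value]
        k = bisect_left(runs, j)  # value-runs fully before run j
        count = vprefix[value][k]
        if self._values[j] == value:
            run_start = ends[j] - self._lengths[j]
            count += i - run_start
        return count

    def __iter__(self) -> Iterator[int]:
        for v, n in zip(self._values, self._lengths):
            yield from (v,) * n

    def to_list(self) -> list[int]:
        return list(self)

    # -- updates ----------------------------------------------------------

    def insert_at(self, i: int, value: int) -> None:
        """Insert ``value`` at logical position i, keeping runs maximal."""
        if value < 0:
            raise RLEError("run value must be non-negative")
        if not 0 <= i <= self._length:
            raise RLEError(f"insert position {i} out of range [0, {self._length}]")
        vals, lens = self._values, self._lengths
        if i == self._length:  # append
            if vals and vals[-1] == value:
                lens[-1] += 1
            else:
                vals.append(value)
                lens.append(1)
        else:
            j = self._run_of(i)
            ends = self._ensure_ends()
            run_start = ends[j] - lens[j]
            if vals[j] == value:
                lens[j] += 1
            elif i == run_start:
                if j > 0 and vals[j - 1] == value:
                    lens[j - 1] += 1
                else:
                    vals.insert(j, value)
                    lens.insert(j, 1)
            else:  # split run j around the new element
                left = i - run_start
                right = lens[j] - left
                vals[j : j + 1] = [vals[j], value, vals[j]]
                lens[j : j + 1] = [left, 1, right]
        self._length += 1
        self._invalidate()

    # -- serialization ----------------------------------------------------

    _HEADER = struct.Struct("<Q")
    _RUN = struct.Struct("<IQ")

    def serialize(self) -> bytes:
        """Length-prefixed little-endian (u32 value, u64 length) run list."""
        out = [self._HEADER.pack(len(self._values))]
        for v, n in zip(self._values, self._lengths):
            out.append(self._RUN.pack(v, n))
        return b"".join(out)

    @classmethod
    def deserialize(cls, data: bytes, offset: int = 0) -> tuple["RunLengthArray", int]:
        """Read one array starting at ``offset``; returns (array, next offset)."""
        try:
            (n_runs,) = cls._HEADER.unpack_from(data, offset)
            offset += cls._HEADER.size
            runs = []
            for _ in range(n_runs):
                v, n = cls._RUN.unpack_from(data, offset)
                offset += cls._RUN.size
                runs.append((v, n))
        except struct.error as exc:
            raise RLEError(f"truncated run-length serialization: {exc}") from exc
        return cls(runs), offset

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RunLengthArray):
            return NotImplemented
        return self._values == other._values and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"RunLengthArray({self.runs!r})"
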