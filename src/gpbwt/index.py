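"""The graph positional Burrows-Wheeler transform (gPBWT).

For each side ``s`` of the graph, the index keeps an array ``B[s]`` with one
entry per visit of an embedded thread orientation to ``s``.  Visits are sorted
by the reverse of their history (the sides traversed before arrival), so
orientations that recently travelled together sit in contiguous blocks — the
graph analogue of the PBWT's positional sort.  Each entry records the side on
which the orientation enters its *next* node, or the null side if the thread
ends here.

The companion ``c()`` function maps an oriented edge ``(x, s')`` to the
smallest ``B[s']`` index of a visit arriving through ``{x, s'}``; together with
rank queries over ``B[]`` it supports LF-mapping-style navigation (where_to),
thread extraction, O(length) subthread-occurrence counting, and incremental
thread embedding.

Entries are stored as small local-alphabet codes (0 for the null side, k >= 1
for the k-th side adjacent to the node's exit side in ascending side order)
inside run-length arrays, which compress well because linkage keeps
neighbouring entries identical.
"""

from __future__ import annotations

import struct
from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Sequence

from .graph import BidirectedGraph, GraphError, opposite
from .rle import RLEError, RunLengthArray
from .threads import Thread, Orientation, reverse_orientation, validate


class IndexError_(GraphError):
    """Raised on structurally invalid index operations or corruption."""


class LocalAlphabetCodec:
    """Per-side encoding of next-entry sides as small integers.

    For the array ``B[s]`` the possible next-entry sides are the sides
    adjacent to ``opposite(s)`` (the exit side of the node entered through
    ``s``).  Code 0 is the null side; code k >= 1 is the k-th adjacent side in
    ascending side order.  The ordering is fixed by the (frozen) graph.
    """

    def __init__(self, graph: BidirectedGraph) -> None:
        self._graph = graph
        self._by_side: dict[int, tuple[list[int], dict[int, int]]] = {}

    def _table(self, side: int) -> tuple[list[int], dict[int, int]]:
        tab = self._by_side.get(side)
        if tab is None:
            nxt = self._graph.adjacent_sides(opposite(side))
            tab = (nxt, {s: k + 1 for k, s in enumerate(nxt)})
            self._by_side[side] = tab
        return tab

    def encode(self, side: int, next_side: int) -> int:
        if next_side == 0:
            return 0
        code = self._table(side)[1].get(next_side)
        if code is None:
            raise IndexError_(
                f"side {next_side} is not reachable from the exit of side {side}"
            )
        return code

    def decode(self, side: int, code: int) -> int:
        if code == 0:
            return 0
        nxt = self._table(side)[0]
        if not 1 <= code <= len(nxt):
            raise IndexError_(f"code {code} out of range for side {side}")
        return nxt[code - 1]


@dataclass(frozen=True)
class SearchRange:
    """Half-open interval [f, g) of visit slots in B[side] for a query prefix."""

    side: int
    f: int
    g: int

    @property
    def is_empty(self) -> bool:
        return self.f >= self.g

    def __len__(self) -> int:
        return max(0, self.g - self.f)


class GPBWTIndex:
    """B[] arrays plus start/edge-usage counts realizing c().

    ``starts[s]`` counts thread orientations beginning at side ``s`` and
    ``edge_uses[(x, s)]`` counts visits to ``s`` arriving through ``{x, s}``;
    ``c(x, s)`` is recovered as ``starts[s]`` plus the uses of all smaller
    incident edges, so the invariant len(B[s]) == starts[s] + sum of uses
    holds at every step of embedding.
    """

    def __init__(self, graph: BidirectedGraph) -> None:
        graph.freeze()
        self.graph = graph
        self.codec = LocalAlphabetCodec(graph)
        self.B: dict[int, RunLengthArray] = {}
        self.starts: dict[int, int] = {}
        self.edge_uses: dict[tuple[int, int], int] = {}
        self.n_orientations = 0

    def _b(self, side: int) -> RunLengthArray:
        arr = self.B.get(side)
        if arr is None:
            arr = RunLengthArray()
            self.B[side] = arr
        return arr

    def b_length(self, side: int) -> int:
        arr = self.B.get(side)
        return 0 if arr is None else len(arr)

    def b_entry(self, side: int, i: int) -> int:
        """Decoded B[side][i] as a side id (0 for the null side)."""
        arr = self.B.get(side)
        if arr is None:
            raise IndexError_(f"B[{side}] is empty")
        return self.codec.decode(side, arr.value_at(i))

    def b_array(self, side: int) -> list[int]:
        """The whole decoded B[side] as side ids."""
        arr = self.B.get(side)
        if arr is None:
            return []
        return [self.codec.decode(side, code) for code in arr]

    # -- c() and navigation ----------------------------------------------

    def c_value(self, x: int, s_prime: int) -> int:
        """Smallest B[s'] index of a visit arriving via the edge {x, s'}.

        Computed as starts[s'] plus the uses of incident edges with smaller
        far endpoints; when no visit arrives via {x, s'} this is where one
        would be inserted.
        """
        if not self.graph.has_edge(x, s_prime):
            raise IndexError_(f"{{{x}, {s_prime}}} is not an edge")
        total = self.starts.get(s_prime, 0)
        for x_other in self.graph.adjacent_sides(s_prime):
            if x_other >= x:
                break
            total += self.edge_uses.get((x_other, s_prime), 0)
        return total

    def starts_at(self, side: int) -> int:
        """How many thread orientations begin at ``side``.

        The minimum of c(x, side) over incident edges, or len(B[side]) for an
        isolated side.
        """
        adj = self.graph.adjacent_sides(side)
        if not adj:
            return self.b_length(side)
        return self.c_value(adj[0], side)

    def where_to(self, side: int, i: int, next_side: int) -> int:
        """LF-mapping step: the B[next_side] index matching slot i of B[side].

        ``next_side`` must be reachable from the exit of ``side`` by one edge.
        Equals c(opposite(side), next_side) plus the next_side-rank of i in
        B[side].
        """
        if next_side == 0:
            raise IndexError_("cannot continue to the null side")
        c = self.c_value(opposite(side), next_side)
        code = self.codec.encode(side, next_side)
        return c + self._b(side).rank_before(code, i)

    # -- embedding --------------------------------------------------------

    def _start_rank(self, t: tuple[int, ...]) -> int:
        """Suffix-lexicographic rank of ``t`` among the starts at t[0].

        Ties between visits with identical histories are broken by the
        orientations' onward side sequences, so within any tie block the B[]
        entries appear in code order and runs merge maximally — embedding a
        duplicate thread only lengthens existing runs.  The rank is found by
        narrowing the start block of B[t0] along ``t``, counting at each step
        the tied entries that diverge to a smaller next side (the null side,
        a terminated proper prefix of ``t``, counts as smallest).  Entries
        identical to ``t`` in full are not counted, so a duplicate lands at
        the front of its equal block (reverse insertion order; the entries
        are equal, so the index state does not depend on that choice).
        """
        side = t[0]
        f, g = 0, self.starts.get(side, 0)
        rank = 0
        j = 0
        while f < g:
            next_side = t[2 * j + 2] if 2 * j + 2 < len(t) else 0
            c = self.codec.encode(side, next_side)
            arr = self._b(side)
            for v in range(c):
                rank += arr.rank_before(v, g) - arr.rank_before(v, f)
            if c == 0:
                break
            f = self.where_to(side, f, next_side)
            g = self.where_to(side, g, next_side)
            side = next_side
            j += 1
        return rank

    def embed_orientation(self, t: Sequence[int]) -> None:
        """Insert one thread orientation, keeping all B[] arrays sorted.

        The start entry goes into the start block of B[t0] (before all
        edge-arrival entries) at its suffix-lexicographic rank among the
        existing starts; every subsequent visit's entry lands at the index
        computed by where_to after the corresponding edge-usage count is
        bumped.
        """
        problem = validate(t, self.graph)
        if problem is not None:
            raise IndexError_(
                f"invalid orientation at index {problem.index}: {problem.reason}"
            )
        t = tuple(t)
        n_visits = len(t) // 2
        first = t[0]
        next_side = t[2] if n_visits > 1 else 0
        k = self._start_rank(t)
        self._b(first).insert_at(k, self.codec.encode(first, next_side))
        self.starts[first] = self.starts.get(first, 0) + 1
        for j in range(1, n_visits):
            prev_entry = t[2 * j - 2]
            via = t[2 * j - 1]  # exit side of the previous node
            s = t[2 * j]
            self.edge_uses[(via, s)] = self.edge_uses.get((via, s), 0) + 1
            k = self.where_to(prev_entry, k, s)
            next_side = t[2 * j + 2] if j + 1 < n_visits else 0
            self._b(s).insert_at(k, self.codec.encode(s, next_side))
        self.n_orientations += 1

    def embed_thread(self, thread: Thread | Sequence[int]) -> None:
        """Embed a thread: its canonical orientation, then the reverse."""
        if not isinstance(thread, Thread):
            thread = Thread.from_orientation(thread)
        fwd, rev = thread.orientations
        self.embed_orientation(fwd)
        self.embed_orientation(rev)

    # -- extraction -------------------------------------------------------

    def extract_orientations(self) -> list[Orientation]:
        """Trace every stored thread orientation out of the B[] arrays."""
        out: list[Orientation] = []
        for side in self.graph.sides():
            for i in range(self.starts_at(side)):
                out.append(self._trace(side, i))
        if len(out) != self.n_orientations:
            raise IndexError_(
                f"extracted {len(out)} orientations, expected {self.n_orientations}"
            )
        return out

    def _trace(self, side: int, i: int) -> Orientation:
        t = [side, opposite(side)]
        cur, k = side, i
        while True:
            arr = self.B.get(cur)
            if arr is None or k >= len(arr):
                raise IndexError_(
                    f"dangling continuation at side {cur}, index {k}"
                )
            code = arr.value_at(k)
            if code == 0:
                return tuple(t)
            nxt = self.codec.decode(cur, code)
            k = self.where_to(cur, k, nxt)
            t.append(nxt)
            t.append(opposite(nxt))
            cur = nxt

    def extract_threads(self) -> Counter[Thread]:
        """The embedded thread multiset (each thread stored as 2 orientations)."""
        counts: Counter[Thread] = Counter()
        for orientation in self.extract_orientations():
            counts[Thread.from_orientation(orientation)] += 1
        result: Counter[Thread] = Counter()
        for thread, n in counts.items():
            if n % 2 != 0:
                raise IndexError_(
                    f"thread {thread.canonical} has odd multiplicity {n}"
                )
            result[thread] = n // 2
        return result

    # -- counting ---------------------------------------------------------

    def search_start(self, side: int) -> SearchRange:
        """Range selecting every visit to ``side`` (the whole B[side])."""
        return SearchRange(side, 0, self.b_length(side))

    def extend_search(self, r: SearchRange, next_visit: int) -> SearchRange:
        """Narrow a range by one more visit of the query orientation.

        Returns an empty range (never raises) when the query side pair is not
        joined by an edge or no stored thread continues that way, so streaming
        callers can keep extending prefixes.
        """
        if r.is_empty:
            return SearchRange(next_visit, 0, 0)
        if not self.graph.has_edge(opposite(r.side), next_visit):
            return SearchRange(next_visit, 0, 0)
        f = self.where_to(r.side, r.f, next_visit)
        g = self.where_to(r.side, r.g, next_visit)
        return SearchRange(next_visit, f, g)

    def count_subthread(self, t: Sequence[int]) -> int:
        """Occurrences of orientation ``t`` as a subthread of stored threads.

        A query that is not a valid walk in the graph (missing side, missing
        edge, bad side pairing) counts 0 — "consistent with no haplotype" —
        rather than erroring, since query paths may come from read mappings.
        A single-node query counts every visit to that node through t[0].
        """
        if len(t) < 2 or len(t) % 2 != 0:
            return 0
        for i in range(0, len(t), 2):
            if t[i] < 1 or not self.graph.has_side(t[i]):
                return 0
            if opposite(t[i]) != t[i + 1]:
                return 0
        r = self.search_start(t[0])
        for i in range(2, len(t), 2):
            r = self.extend_search(r, t[i])
            if r.is_empty:
                return 0
        return len(r)

    # -- serialization ----------------------------------------------------

    _MAGIC = b"gPBWT\x01"
    _U64 = struct.Struct("<Q")
    _PAIR = struct.Struct("<QQ")
    _TRIPLE = struct.Struct("<QQQ")

    def serialize(self) -> bytes:
        """Versioned little-endian envelope; bit-exact across platforms.

        Layout: magic+version, graph SHA-256, orientation count, then per
        side (in side order): starts count and the B[] run list; then the
        oriented-edge usage table in key order.
        """
        sides = self.graph.sides()
        out = [self._MAGIC, self.graph.checksum(), self._U64.pack(self.n_orientations)]
        out.append(self._U64.pack(len(sides)))
        for s in sides:
            out.append(self._PAIR.pack(s, self.starts.get(s, 0)))
            out.append(self._b(s).serialize())
        uses = sorted(
            (x, s, n) for (x, s), n in self.edge_uses.items() if n > 0
        )
        out.append(self._U64.pack(len(uses)))
        for x, s, n in uses:
            out.append(self._TRIPLE.pack(x, s, n))
        return b"".join(out)

    @classmethod
    def deserialize(cls, data: bytes, graph: BidirectedGraph) -> "GPBWTIndex":
        if data[: len(cls._MAGIC)] != cls._MAGIC:
            raise IndexError_("not a gPBWT index (bad magic)")
        offset = len(cls._MAGIC)
        checksum = data[offset : offset + 32]
        offset += 32
        if checksum != graph.checksum():
            raise IndexError_("index was built over a different graph")
        idx = cls(graph)
        try:
            (idx.n_orientations,) = cls._U64.unpack_from(data, offset)
            offset += cls._U64.size
            (n_sides,) = cls._U64.unpack_from(data, offset)
            offset += cls._U64.size
            for _ in range(n_sides):
                s, n_start = cls._PAIR.unpack_from(data, offset)
                offset += cls._PAIR.size
                arr, offset = RunLengthArray.deserialize(data, offset)
                if n_start:
                    idx.starts[s] = n_start
                if len(arr):
                    idx.B[s] = arr
            (n_uses,) = cls._U64.unpack_from(data, offset)
            offset += cls._U64.size
            for _ in range(n_uses):
                x, s, n = cls._TRIPLE.unpack_from(data, offset)
                offset += cls._TRIPLE.size
                idx.edge_uses[(x, s)] = n
        except (struct.error, RLEError) as exc:
            raise IndexError_(f"malformed index file: {exc}") from exc
        return idx

    # -- diagnostics ------------------------------------------------------

    def total_runs(self) -> int:
        return sum(arr.run_count for arr in self.B.values())

    def total_entries(self) -> int:
        return sum(len(arr) for arr in self.B.values())

    def check_conservation(self) -> None:
        """Assert len(B[s]) == starts[s] + sum of edge uses into s."""
        for s in self.graph.sides():
            expected = self.starts.get(s, 0) + sum(
                self.edge_uses.get((x, s), 0) for x in self.graph.adjacent_sides(s)
            )
            if self.b_length(s) != expected:
                raise IndexError_(
                    f"conservation violated at side {s}: "
                    f"len(B)={self.b_length(s)}, starts+uses={expected}"
                )
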