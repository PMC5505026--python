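"""Batch gPBWT construction for DAG-orientable graphs.

When every edge joins the right side of one node to the left side of another
and the induced directed graph is acyclic, the whole index can be built
without any dynamic inserts: forward orientations (entering nodes on left
sides) are processed over left sides in topological order, reverse
orientations over right sides in reverse topological order.  At each entry
side, the B[] order is obtained by concatenating the newly starting
orientations with the pre-sorted lists arriving over each incident edge (in
ascending order of the edge's far endpoint); the list is then partitioned
stably by next entry side into the outgoing lists handed to later sides.

This produces byte-for-byte the same index as embedding the threads one at a
time with :meth:`GPBWTIndex.embed_thread` — including the tie order among
orientations with identical histories, which is suffix-lexicographic (see
:meth:`GPBWTIndex._start_rank`), with fully identical orientations kept in
reverse embedding order.
"""

from __future__ import annotations

from typing import Sequence

from .graph import BidirectedGraph, GraphError, dag_orientation, is_left, left_side, opposite, right_side
from .index import GPBWTIndex
from .rle import RunLengthArray
from .threads import Thread, Orientation, validate


class BatchError(GraphError):
    pass


def batch_embed(
    graph: BidirectedGraph, threads: Sequence[Thread | Sequence[int]]
) -> GPBWTIndex:
    """Build a gPBWT over ``graph`` holding ``threads`` in one batch pass.

    Requires :func:`dag_orientation` to succeed; otherwise raises
    :class:`BatchError` directing the caller to the incremental embedder.
    Thread order matters only for ties and matches the incremental build.
    """
    order = dag_orientation(graph)
    if not order:
        raise BatchError(
            f"graph is not DAG-orientable ({order.reason}); "
            "use GPBWTIndex.embed_thread instead"
        )

    normalized = [
        t if isinstance(t, Thread) else Thread.from_orientation(t) for t in threads
    ]
    # Global embedding order: canonical orientation then reverse, per thread.
    orientations: list[Orientation] = []
    for t in normalized:
        fwd, rev = t.orientations
        orientations.extend((fwd, rev))
    for t in orientations:
        problem = validate(t, graph)
        if problem is not None:
            raise BatchError(
                f"invalid thread at index {problem.index}: {problem.reason}"
            )

    idx = GPBWTIndex(graph)
    idx.n_orientations = len(orientations)

    # In a DAG-orientable graph an orientation enters every node on the same
    # kind of side as its first one: left-entering orientations move with the
    # topological order, right-entering ones against it.
    left_oris = [(g, t) for g, t in enumerate(orientations) if is_left(t[0])]
    right_oris = [(g, t) for g, t in enumerate(orientations) if not is_left(t[0])]

    _pass(idx, left_oris, [left_side(n) for n in order])
    _pass(idx, right_oris, [right_side(n) for n in reversed(order)])
    return idx


def _pass(
    idx: GPBWTIndex,
    oris: list[tuple[int, Orientation]],
    entry_sides: list[int],
) -> None:
    """One sweep filling B[] for ``entry_sides`` from the given orientations.

    ``oris`` carries (global embedding rank, orientation); each orientation in
    this pass enters nodes exclusively through sides in ``entry_sides``, which
    are supplied so that every edge's far side is processed before its near
    side.  Pending lists hold (rank, orientation, visit number) records in
    B[] order, keyed by the oriented edge they travel.
    """
    starts_by_side: dict[int, list[tuple[int, Orientation]]] = {}
    for g, t in oris:
        starts_by_side.setdefault(t[0], []).append((g, t))

    pending: dict[tuple[int, int], list[tuple[int, Orientation, int]]] = {}

    for s in entry_sides:
        block: list[tuple[int, Orientation, int]] = []
        # Newly starting orientations, in suffix-lexicographic order (the
        # incremental tie rule); fully identical orientations latest-first.
        for g, t in sorted(starts_by_side.get(s, ()), key=lambda gt: (gt[1], -gt[0])):
            block.append((g, t, 0))
        idx.starts[s] = len(block)
        for x in idx.graph.adjacent_sides(s):
            arrivals = pending.pop((x, s), [])
            idx.edge_uses[(x, s)] = len(arrivals)
            block.extend(arrivals)

        if not block:
            continue
        arr = RunLengthArray()
        buckets: dict[int, list[tuple[int, Orientation, int]]] = {}
        for g, t, v in block:
            nxt = t[2 * v + 2] if 2 * v + 2 < len(t) else 0
            arr.insert_at(len(arr), idx.codec.encode(s, nxt))
            if nxt:
                buckets.setdefault(nxt, []).append((g, t, v + 1))
        idx.B[s] = arr
        exit_side = opposite(s)
        for nxt, records in buckets.items():
            pending.setdefault((exit_side, nxt), []).extend(records)

    if pending:
        (x, s), _ = next(iter(pending.items()))
        raise BatchError(f"unprocessed arrivals on oriented edge ({x}, {s})")
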