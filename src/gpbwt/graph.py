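"""Bidirected genome graph: nodes with DNA labels, edges joining node *sides*.

Every node has a left (5') and a right (3') side.  Node ``k`` (k >= 1) owns
side ``2k - 1`` on the left and side ``2k`` on the right, so sides are plain
integers and the total order on sides is integer order.  Side ``0`` is the
distinguished *null side*: it belongs to no node and compares less than every
real side; it marks thread termination in the haplotype index.

Edges are unordered pairs of sides (self-loops ``{s, s}`` allowed); at most one
edge may join a given pair of sides.
"""

from __future__ import annotations

import hashlib
import heapq
from dataclasses import dataclass
from typing import Sequence

NULL_SIDE = 0

_DNA = frozenset("ACGTN")


class GraphError(ValueError):
    """Raised for structurally invalid graph operations."""


def opposite(side: int) -> int:
    """The other side of the same node (left <-> right).

    An involution on real sides; the null side has no opposite.
    """
    if side < 1:
        raise GraphError(f"side {side} has no opposite (null or invalid)")
    return side + 1 if side % 2 == 1 else side - 1


def node_of(side: int) -> int:
    """The node id owning ``side`` (ceil(side / 2))."""
    if side < 1:
        raise GraphError(f"side {side} belongs to no node")
    return (side + 1) // 2


def left_side(node_id: int) -> int:
    return 2 * node_id - 1


def right_side(node_id: int) -> int:
    return 2 * node_id


def is_left(side: int) -> bool:
    return side % 2 == 1


@dataclass(frozen=True)
class VariantSpec:
    """A replacement of a nonempty reference substring by a nonempty alternate.

    ``ref_start`` is a 0-based offset into the reference sequence.
    """

    ref_start: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise GraphError("variant ref_start must be non-negative")
        if not self.ref_allele or not self.alt_allele:
            raise GraphError("variant alleles must be nonempty")

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.ref_allele)


@dataclass(frozen=True)
class DagFailure:
    """Explicit failure value from :func:`dag_orientation`.

    Either ``offending_edge`` names an edge that does not run right-side to
    left-side between distinct nodes, or ``cycle`` lists node ids on a
    directed cycle.
    """

    reason: str
    offending_edge: tuple[int, int] | None = None
    cycle: tuple[int, ...] | None = None

    def __bool__(self) -> bool:  # failure is falsy
        return False


class BidirectedGraph:
    """A bidirected sequence graph.

    Nodes carry DNA-sequence labels over {A, C, G, T, N}; edges are unordered
    pairs of sides.  ``adjacent_sides`` returns neighbours in ascending side
    order — the haplotype index's c() function depends on this ordering, so a
    graph must not be mutated after an index is built over it (see
    :meth:`freeze`).
    """

    def __init__(self) -> None:
        self.nodes: dict[int, str] = {}
        self._edges: set[frozenset[int]] = set()
        self._adj: dict[int, list[int]] = {}
        self._frozen = False

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: int, sequence: str) -> None:
        self._check_mutable()
        if node_id < 1:
            raise GraphError(f"node id must be positive, got {node_id}")
        if node_id in self.nodes:
            raise GraphError(f"duplicate node id {node_id}")
        if not sequence:
            raise GraphError(f"node {node_id} has an empty sequence label")
        seq = sequence.upper()
        if not set(seq) <= _DNA:
            raise GraphError(f"node {node_id} label has non-DNA characters")
        self.nodes[node_id] = seq

    def add_edge(self, side_a: int, side_b: int) -> None:
        self._check_mutable()
        for s in (side_a, side_b):
            if s < 1 or node_of(s) not in self.nodes:
                raise GraphError(f"side {s} is not present in the graph")
        key = frozenset((side_a, side_b))
        if key in self._edges:
            raise GraphError(f"duplicate edge {{{side_a}, {side_b}}}")
        self._edges.add(key)
        self._adj.setdefault(side_a, []).append(side_b)
        if side_b != side_a:
            self._adj.setdefault(side_b, []).append(side_a)
        self._adj[side_a].sort()
        if side_b != side_a:
            self._adj[side_b].sort()

    def freeze(self) -> "BidirectedGraph":
        """Make the graph immutable; required before indexing."""
        self._frozen = True
        return self

    def _check_mutable(self) -> None:
        if self._frozen:
            raise GraphError("graph is frozen (an index may depend on it)")

    # -- queries ----------------------------------------------------------

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Edges as sorted (min, max) side pairs, in deterministic order."""
        out = []
        for e in self._edges:
            pair = tuple(sorted(e)) if len(e) == 2 else (next(iter(e)),) * 2
            out.append(pair)
        return sorted(out)

    def has_node(self, node_id: int) -> bool:
        return node_id in self.nodes

    def has_side(self, side: int) -> bool:
        return side >= 1 and node_of(side) in self.nodes

    def has_edge(self, side_a: int, side_b: int) -> bool:
        return frozenset((side_a, side_b)) in self._edges

    def adjacent_sides(self, side: int) -> list[int]:
        """Sides x with {x, side} an edge, ascending.  Self-loops appear once."""
        return list(self._adj.get(side, ()))

    def sides(self) -> list[int]:
        out: list[int] = []
        for nid in sorted(self.nodes):
            out.append(left_side(nid))
            out.append(right_side(nid))
        return out

    def sequence(self, node_id: int) -> str:
        return self.nodes[node_id]

    def checksum(self) -> bytes:
        """SHA-256 over a canonical text rendering of nodes and edges."""
        h = hashlib.sha256()
        for nid in sorted(self.nodes):
            h.update(f"S\t{nid}\t{self.nodes[nid]}\n".encode())
        for a, b in self.edges:
            h.update(f"E\t{a}\t{b}\n".encode())
        return h.digest()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BidirectedGraph):
            return NotImplemented
        return self.nodes == other.nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return (
            f"BidirectedGraph(nodes={len(self.nodes)}, "
            f"edges={len(self._edges)})"
        )


@dataclass(frozen=True)
class AlleleMap:
    """Mapping from a reference + variant-set build to graph nodes.

    ``chain`` is the node-id sequence of an all-reference walk, left to right.
    ``variant_nodes[i]`` gives ``(ref_node, alt_node)`` for the i-th input
    variant; ``ref_node`` also appears in ``chain`` at index
    ``chain_position[i]``.
    """

    chain: tuple[int, ...]
    variant_nodes: tuple[tuple[int, int], ...]
    chain_position: tuple[int, ...]


def build_from_variants(
    reference: str, variants: Sequence[VariantSpec]
) -> tuple[BidirectedGraph, AlleleMap]:
    """Build a graph from a reference sequence plus nonoverlapping variants.

    The reference is broken so each variant's reference allele is exactly one
    node; one extra node per alternate allele is attached to everything the
    reference-allele node's sides attach to.  Node ids are assigned in
    reference order with each alternate node immediately after its reference
    node, so serialized output is deterministic.

    Variants whose reference intervals coincide exactly (split multiallelic
    records) share one reference-allele node; partially overlapping intervals
    are an error, as is a ref allele that does not match the reference.
    """
    reference = reference.upper()
    if not reference:
        raise GraphError("reference sequence is empty")
    order = sorted(range(len(variants)), key=lambda i: variants[i].ref_start)
    prev_end = 0
    prev_interval: tuple[int, int] | None = None
    for i in order:
        v = variants[i]
        iv = (v.ref_start, v.ref_end)
        if v.ref_end > len(reference):
            raise GraphError(f"variant at {v.ref_start} runs off the reference")
        if reference[v.ref_start : v.ref_end] != v.ref_allele.upper():
            raise GraphError(
                f"ref allele mismatch at {v.ref_start}: expected "
                f"{reference[v.ref_start:v.ref_end]!r}, got {v.ref_allele!r}"
            )
        if prev_interval is not None and iv != prev_interval and v.ref_start < prev_end:
            raise GraphError(
                f"overlapping variants at reference offset {v.ref_start}"
            )
        prev_end = max(prev_end, v.ref_end)
        prev_interval = iv

    # Segment the reference at variant boundaries.  Identical intervals are
    # grouped so split multiallelics share a reference-allele node.
    cuts = {0, len(reference)}
    for v in variants:
        cuts.add(v.ref_start)
        cuts.add(v.ref_end)
    bounds = sorted(cuts)
    segments = [
        (bounds[i], bounds[i + 1])
        for i in range(len(bounds) - 1)
        if bounds[i] < bounds[i + 1]
    ]

    by_interval: dict[tuple[int, int], list[int]] = {}
    for i, v in enumerate(variants):
        by_interval.setdefault((v.ref_start, v.ref_end), []).append(i)

    g = BidirectedGraph()
    next_id = 1
    chain: list[int] = []
    chain_pos: dict[int, int] = {}  # variant index -> chain index
    var_nodes: dict[int, tuple[int, int]] = {}
    alt_ids: dict[tuple[int, int], list[int]] = {}  # segment -> alt node ids

    for seg in segments:
        start, end = seg
        ref_node = next_id
        next_id += 1
        g.add_node(ref_node, reference[start:end])
        chain.append(ref_node)
        alts: list[int] = []
        for vi in by_interval.get(seg, ()):
            alt_node = next_id
            next_id += 1
            g.add_node(alt_node, variants[vi].alt_allele)
            var_nodes[vi] = (ref_node, alt_node)
            chain_pos[vi] = len(chain) - 1
            alts.append(alt_node)
        alt_ids[seg] = alts

    # Wire consecutive segments: the right side of every allele node of the
    # previous segment connects to the left side of every allele node of the
    # next (alternate nodes attach to everything their reference node does).
    for si, (prev, cur) in enumerate(zip(segments, segments[1:])):
        left_group = [chain[si]] + alt_ids[prev]
        right_group = [chain[si + 1]] + alt_ids[cur]
        for a in left_group:
            for b in right_group:
                g.add_edge(right_side(a), left_side(b))

    amap = AlleleMap(
        chain=tuple(chain),
        variant_nodes=tuple(var_nodes[i] for i in range(len(variants))),
        chain_position=tuple(chain_pos[i] for i in range(len(variants))),
    )
    return g, amap


def dag_orientation(g: BidirectedGraph) -> list[int] | DagFailure:
    """Topologically order nodes if every edge runs right side -> left side.

    The batch index builder needs the graph to behave as a DAG: each edge must
    join the right side of one node to the left side of a *different* node,
    and the induced directed graph must be acyclic.  On success, returns node
    ids in a topological order (which induces the full side ordering the batch
    pass uses); on failure returns a :class:`DagFailure` naming an offending
    edge or a cycle.  Failure is a value, not an exception.
    """
    succ: dict[int, list[int]] = {nid: [] for nid in g.nodes}
    indeg: dict[int, int] = {nid: 0 for nid in g.nodes}
    for a, b in g.edges:
        lo, hi = min(a, b), max(a, b)
        # need one right side and one left side
        if is_left(lo) == is_left(hi):
            return DagFailure(
                reason="edge does not join a right side to a left side",
                offending_edge=(lo, hi),
            )
        r = lo if not is_left(lo) else hi
        l = hi if is_left(hi) else lo
        u, v = node_of(r), node_of(l)
        if u == v:
            return DagFailure(
                reason="edge joins the two sides of one node",
                offending_edge=(lo, hi),
            )
        succ[u].append(v)
        indeg[v] += 1

    order: list[int] = []
    ready = sorted(nid for nid, d in indeg.items() if d == 0)
    heapq.heapify(ready)
    while ready:
        u = heapq.heappop(ready)
        order.append(u)
        for v in succ[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(ready, v)
    if len(order) != len(g.nodes):
        remaining = tuple(sorted(nid for nid in g.nodes if nid not in set(order)))
        return DagFailure(reason="directed cycle", cycle=remaining)
    return order
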