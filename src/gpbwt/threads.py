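"""Threads: haplotypes (or fragments) as alternating side walks.

A *thread orientation* is a sequence of sides ``[t0, t1, ..., t_{2N+1}]`` of
even length in which ``t_{2i}`` and ``t_{2i+1}`` are the two sides of one node
(a node traversal) and each ``{t_{2i+1}, t_{2i+2}}`` is an edge of the graph
(an edge traversal).  The sides at even positions are the *visits*.

A *thread* is an ambisequence: the orientation and its reverse are the same
object, as a haplotype has no preferred reading direction.  We canonicalize by
taking the lexicographically smaller of the two orientations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .graph import BidirectedGraph, GraphError, is_left, node_of, opposite

Orientation = tuple[int, ...]


@dataclass(frozen=True)
class Violation:
    """First structural problem found when validating an orientation."""

    index: int
    reason: str


def reverse_orientation(t: Sequence[int]) -> Orientation:
    """The reverse reading of an orientation (an involution)."""
    return tuple(reversed(t))


def canonical_orientation(t: Sequence[int]) -> Orientation:
    """Lexicographic minimum of an orientation and its reverse."""
    fwd = tuple(t)
    rev = tuple(reversed(fwd))
    return fwd if fwd <= rev else rev


@dataclass(frozen=True)
class Thread:
    """A haplotype thread: an ambisequence of sides, stored canonically."""

    canonical: Orientation

    @classmethod
    def from_orientation(cls, t: Sequence[int]) -> "Thread":
        return cls(canonical_orientation(t))

    @property
    def orientations(self) -> tuple[Orientation, Orientation]:
        return self.canonical, reverse_orientation(self.canonical)

    def __len__(self) -> int:
        return len(self.canonical)


def validate(t: Sequence[int], g: BidirectedGraph) -> Violation | None:
    """Check an orientation against a graph; ``None`` means valid.

    Checks even positive length, that consecutive side pairs are opposites
    (node traversals), and that each node-to-node step uses an existing edge.
    Returns the first violation instead of raising.
    """
    if len(t) == 0:
        return Violation(0, "orientation is empty")
    if len(t) % 2 != 0:
        return Violation(len(t) - 1, "orientation has odd length")
    for i in range(0, len(t), 2):
        a, b = t[i], t[i + 1]
        if a < 1 or b < 1:
            return Violation(i, "null side inside an orientation")
        if not g.has_side(a):
            return Violation(i, f"side {a} not in graph")
        if opposite(a) != b:
            return Violation(i, f"sides {a} and {b} are not opposites")
    for i in range(1, len(t) - 1, 2):
        if not g.has_edge(t[i], t[i + 1]):
            return Violation(i, f"no edge {{{t[i]}, {t[i + 1]}}}")
    return None


def from_node_path(
    traversals: Sequence[tuple[int, bool]], g: BidirectedGraph
) -> Orientation:
    """Build an orientation from (node_id, forward?) traversals.

    A forward traversal of node k contributes sides (2k-1, 2k); a backward
    traversal contributes (2k, 2k-1).  Consecutive traversals must be joined
    by an edge.
    """
    sides: list[int] = []
    for node_id, forward in traversals:
        if not g.has_node(node_id):
            raise GraphError(f"node {node_id} not in graph")
        entry = 2 * node_id - 1 if forward else 2 * node_id
        if sides and not g.has_edge(sides[-1], entry):
            raise GraphError(f"no edge {{{sides[-1]}, {entry}}} in graph")
        sides.append(entry)
        sides.append(opposite(entry))
    if not sides:
        raise GraphError("empty node path")
    return tuple(sides)


def to_node_path(t: Sequence[int]) -> list[tuple[int, bool]]:
    """Inverse of :func:`from_node_path`: (node, forward?) per traversal."""
    if len(t) % 2 != 0 or not t:
        raise GraphError("malformed orientation")
    return [(node_of(t[i]), is_left(t[i])) for i in range(0, len(t), 2)]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def orientation_sequence(t: Sequence[int], g: BidirectedGraph) -> str:
    """DNA read off along an orientation.

    Entering a node on its left side contributes the label; entering on the
    right side contributes the reverse complement.
    """
    parts: list[str] = []
    for i in range(0, len(t), 2):
        label = g.sequence(node_of(t[i]))
        if is_left(t[i]):
            parts.append(label)
        else:
            parts.append(label.translate(_COMPLEMENT)[::-1])
    return "".join(parts)


def visits(t: Sequence[int]) -> Orientation:
    """The sides at even positions: one per node arrival."""
    return tuple(t[i] for i in range(0, len(t), 2))
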