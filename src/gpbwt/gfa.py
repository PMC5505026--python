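"""GFA 1.0 read/write for graphs (S/L lines) and thread paths (P lines).

Mapping: node <-> S line; edge {s, s'} <-> L line leaving n(s) with
orientation ``+`` iff s is a right side, entering n(s') with orientation
``+`` iff s' is a left side; overlaps are always ``0M``.  Containment (C)
lines are rejected.  P lines carry node-traversal paths and convert to thread
orientations via :func:`gpbwt.threads.from_node_path`.
"""

from __future__ import annotations

from typing import Iterable, Sequence, TextIO

from .graph import BidirectedGraph, GraphError, is_left, left_side, right_side
from .threads import Orientation, to_node_path


class GFAError(GraphError):
    pass


def _edge_to_link(a: int, b: int) -> tuple[int, str, int, str]:
    """Edge {a, b} as (from_node, from_orient, to_node, to_orient)."""
    from_node = (a + 1) // 2
    to_node = (b + 1) // 2
    from_orient = "+" if not is_left(a) else "-"
    to_orient = "+" if is_left(b) else "-"
    return from_node, from_orient, to_node, to_orient


def _link_to_edge(from_node: int, from_orient: str, to_node: int, to_orient: str) -> tuple[int, int]:
    a = right_side(from_node) if from_orient == "+" else left_side(from_node)
    b = left_side(to_node) if to_orient == "+" else right_side(to_node)
    return a, b


def write_gfa(
    g: BidirectedGraph,
    out: TextIO,
    paths: Iterable[tuple[str, Sequence[int]]] = (),
) -> None:
    """Write graph (and optionally named thread orientations) as GFA 1.0."""
    out.write("H\tVN:Z:1.0\n")
    for nid in sorted(g.nodes):
        out.write(f"S\t{nid}\t{g.nodes[nid]}\n")
    for a, b in g.edges:
        fn, fo, tn, to = _edge_to_link(a, b)
        out.write(f"L\t{fn}\t{fo}\t{tn}\t{to}\t0M\n")
    for name, orientation in paths:
        steps = ",".join(
            f"{node}{'+' if fwd else '-'}" for node, fwd in to_node_path(orientation)
        )
        out.write(f"P\t{name}\t{steps}\t*\n")


def read_gfa(src: TextIO) -> tuple[BidirectedGraph, list[tuple[str, list[tuple[int, bool]]]]]:
    """Parse GFA 1.0 into a graph plus named node-traversal paths.

    Paths are returned as (name, [(node_id, forward?), ...]) and can be turned
    into orientations with :func:`gpbwt.threads.from_node_path` once the graph
    is available.  C (containment) lines are rejected; unknown record types
    are ignored.
    """
    g = BidirectedGraph()
    links: list[tuple[int, int]] = []
    paths: list[tuple[str, list[tuple[int, bool]]]] = []
    for lineno, line in enumerate(src, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "H":
            continue
        if tag == "S":
            if len(fields) < 3:
                raise GFAError(f"line {lineno}: malformed S line")
            g.add_node(int(fields[1]), fields[2])
        elif tag == "L":
            if len(fields) < 5:
                raise GFAError(f"line {lineno}: malformed L line")
            links.append(
                _link_to_edge(int(fields[1]), fields[2], int(fields[3]), fields[4])
            )
        elif tag == "C":
            raise GFAError(f"line {lineno}: containment lines are not supported")
        elif tag == "P":
            if len(fields) < 3:
                raise GFAError(f"line {lineno}: malformed P line")
            steps = []
            for step in fields[2].split(","):
                if not step or step[-1] not in "+-":
                    raise GFAError(f"line {lineno}: malformed path step {step!r}")
                steps.append((int(step[:-1]), step[-1] == "+"))
            paths.append((fields[1], steps))
    for a, b in links:
        g.add_edge(a, b)
    return g, paths
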