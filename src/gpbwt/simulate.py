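"""Synthetic inputs: random walks in a graph and correlated haplotype panels.

The panel generator emulates the linkage structure that makes the gPBWT
compress: haplotypes are mosaics copied from earlier haplotypes, switching
template at recombination-like events and flipping alleles at mutation-like
events, so nearby B[] entries repeat and runs form.  It is a copying process,
not a coalescent simulation: it produces realistic run structure but no
calibrated population-genetic quantities (see docs/methods.md).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from .graph import AlleleMap, BidirectedGraph, node_of, opposite
from .threads import Orientation, from_node_path, orientation_sequence


@dataclass(frozen=True)
class WalkFailure:
    """A random walk that hit a dead end before reaching its target length."""

    reached_bp: int

    def __bool__(self) -> bool:
        return False


def random_walk(
    g: BidirectedGraph,
    target_bp: int,
    rng: random.Random | int,
) -> Orientation | WalkFailure:
    """One random walk of at least ``target_bp`` bases of node sequence.

    Starts at a side chosen uniformly among all sides, crosses the node, then
    repeatedly follows a uniformly chosen edge incident to the current exit
    side and crosses the next node, stopping once the accumulated node-label
    length reaches ``target_bp``.  Reaching a dead end first returns a
    :class:`WalkFailure` (falsy) so callers can resample.
    """
    if not g.nodes:
        raise ValueError("cannot walk an empty graph")
    if isinstance(rng, int):
        rng = random.Random(rng)
    sides = g.sides()
    entry = rng.choice(sides)
    t = [entry, opposite(entry)]
    total = len(g.sequence(node_of(entry)))
    while total < target_bp:
        choices = g.adjacent_sides(t[-1])
        if not choices:
            return WalkFailure(reached_bp=total)
        nxt = rng.choice(choices)
        t.append(nxt)
        t.append(opposite(nxt))
        total += len(g.sequence(node_of(nxt)))
    return tuple(t)


def sample_walks(
    g: BidirectedGraph,
    n_walks: int,
    target_bp: int,
    seed: int,
    max_retries: int = 100,
) -> list[Orientation]:
    """``n_walks`` successful random walks, resampling dead-ended ones.

    Raises if any walk fails ``max_retries`` times in a row (a graph whose
    dead ends dominate needs a different sampler, not more retries).
    """
    rng = random.Random(seed)
    walks: list[Orientation] = []
    while len(walks) < n_walks:
        for attempt in range(max_retries + 1):
            w = random_walk(g, target_bp, rng)
            if w:
                walks.append(w)
                break
        else:
            raise RuntimeError(
                f"random walk failed {max_retries} consecutive times"
            )
    return walks


def drop_ambiguous(
    walks: Sequence[Orientation],
    g: BidirectedGraph,
    threshold: int = 2,
) -> list[Orientation]:
    """Remove walks whose sequence contains ``threshold`` or more N's in a row."""
    marker = "N" * threshold
    return [w for w in walks if marker not in orientation_sequence(w, g)]


def random_graph(
    n_nodes: int,
    rng: random.Random | int,
    extra_edge_prob: float = 0.3,
    reversing_edge_prob: float = 0.1,
    self_loop_prob: float = 0.05,
    cyclic: bool = True,
    max_label: int = 5,
    n_prob: float = 0.0,
) -> BidirectedGraph:
    """A random bidirected graph for exercising the index.

    A backbone path (node i's right side to node i+1's left side) keeps the
    graph connected; extra forward edges, side-reversing edges (left-left or
    right-right, so walks flip direction), and self-loops are sprinkled on
    top, and ``cyclic`` closes the backbone so random walks rarely dead-end.
    Labels are 1..``max_label`` bases, each N with probability ``n_prob``.
    """
    if isinstance(rng, int):
        rng = random.Random(rng)
    g = BidirectedGraph()
    for nid in range(1, n_nodes + 1):
        label = "".join(
            "N" if rng.random() < n_prob else rng.choice("ACGT")
            for _ in range(rng.randint(1, max_label))
        )
        g.add_node(nid, label)
    for nid in range(1, n_nodes):
        g.add_edge(2 * nid, 2 * nid + 1)
    if cyclic and n_nodes > 1:
        g.add_edge(2 * n_nodes, 1)
    sides = g.sides()
    n_extra = int(extra_edge_prob * n_nodes)
    for _ in range(n_extra):
        a, b = rng.choice(sides), rng.choice(sides)
        if rng.random() < reversing_edge_prob:
            b = b if (a % 2) != (b % 2) else opposite(b)
        if rng.random() < self_loop_prob:
            b = a
        if not g.has_edge(a, b):
            g.add_edge(a, b)
    return g


@dataclass(frozen=True)
class PanelParams:
    """Conditions for the mosaic haplotype panel generator.

    ``switch_prob`` is the per-variant probability that a copying haplotype
    jumps to a different (uniformly chosen) earlier template, emulating
    recombination; ``flip_prob`` the per-variant probability of copying the
    wrong allele, emulating mutation/genotyping error.  Founders draw each
    variant allele independently with probability 1/2.
    """

    n_haplotypes: int = 50
    n_founders: int = 4
    switch_prob: float = 0.1
    flip_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.switch_prob <= 1 or not 0 <= self.flip_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_founders < 1 or self.n_founders > self.n_haplotypes:
            raise ValueError("need 1 <= n_founders <= n_haplotypes")


def synth_panel(
    g: BidirectedGraph, alleles: AlleleMap, params: PanelParams
) -> list[Orientation]:
    """A panel of haplotype orientations with linkage, one per haplotype.

    Each haplotype is an allele vector over the build's variants: founders are
    independent fair coin flips per variant; each later haplotype copies a
    uniformly chosen earlier one, re-choosing its template with
    ``switch_prob`` at each variant and flipping the copied allele with
    ``flip_prob``.  Haplotypes are returned as left-to-right thread
    orientations over the allele nodes.
    """
    rng = random.Random(params.seed)
    n_variants = len(alleles.variant_nodes)
    haplotypes: list[list[int]] = []
    for h in range(params.n_haplotypes):
        if h < params.n_founders:
            hap = [rng.randrange(2) for _ in range(n_variants)]
        else:
            template = rng.randrange(h)
            hap = []
            for v in range(n_variants):
                if v > 0 and h > 1 and rng.random() < params.switch_prob:
                    template = rng.randrange(h)
                allele = haplotypes[template][v]
                if rng.random() < params.flip_prob:
                    allele = 1 - allele
                hap.append(allele)
        haplotypes.append(hap)
    return [panel_thread(g, alleles, hap) for hap in haplotypes]


def panel_thread(
    g: BidirectedGraph, alleles: AlleleMap, allele_vector: Sequence[int]
) -> Orientation:
    """Left-to-right orientation for one allele vector over the build's chain."""
    if len(allele_vector) != len(alleles.variant_nodes):
        raise ValueError("allele vector length != number of variants")
    node_for_pos: dict[int, int] = {}
    for vi, allele in enumerate(allele_vector):
        if allele:
            node_for_pos[alleles.chain_position[vi]] = alleles.variant_nodes[vi][1]
    path = [
        (node_for_pos.get(pos, node), True)
        for pos, node in enumerate(alleles.chain)
    ]
    return from_node_path(path, g)
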