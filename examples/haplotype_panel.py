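"""Index a synthetic haplotype panel and query it.

Builds a graph from a 2 kb reference with SNPs every ~20 bp, simulates a
50-haplotype panel with linkage (mosaic copying with template switches and
rare allele flips), builds the index with the batch algorithm, and shows how
linkage compresses the B[] arrays: the run count stays far below the entry
count because haplotypes that travelled together keep identical next-side
entries.
"""

import random

from gpbwt import (
    GPBWTIndex,
    PanelParams,
    Thread,
    VariantSpec,
    batch_embed,
    build_from_variants,
    synth_panel,
)

rng = random.Random(7)
reference = "".join(rng.choice("ACGT") for _ in range(2000))
variants = [
    VariantSpec(p, reference[p], rng.choice([b for b in "ACGT" if b != reference[p]]))
    for p in range(10, 1990, 20)
]
graph, alleles = build_from_variants(reference, variants)
panel = synth_panel(graph, alleles, PanelParams(n_haplotypes=50, seed=7))

idx = batch_embed(graph, panel)
entries, runs = idx.total_entries(), idx.total_runs()
print(f"graph: {len(graph.nodes)} nodes, {len(graph.edges)} edges")
print(f"index: {idx.n_orientations // 2} threads, {entries} B[] entries "
      f"in {runs} runs ({runs / entries:.2f} runs/entry)")
print(f"serialized: {len(idx.serialize())} bytes")

# Query with a stored haplotype's first 10 node visits: the count is the
# number of panel haplotypes sharing that subhaplotype.
prefix = panel[0][:20]
print(f"panel haplotypes matching one haplotype's 10-node prefix: "
      f"{idx.count_subthread(prefix)} of {len(panel)}")

# The same query reversed gives the same answer: threads are ambisequences.
print(f"same query, opposite orientation: "
      f"{idx.count_subthread(tuple(reversed(prefix)))}")
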