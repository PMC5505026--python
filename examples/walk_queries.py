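"""Haplotype consistency of random walk queries.

Simulates random 100 bp walks in a variant graph holding a 50-haplotype
panel, filters walks crossing runs of ambiguous (N) bases, and counts for
each walk how many stored haplotypes contain it as a subhaplotype.  A walk
that takes an allele combination no haplotype carries is "consistent with no
haplotype" — the signal a graph read mapper can use to flag unlikely paths.
Counting takes time proportional to the walk length, independent of how many
haplotypes match.
"""

import random
from collections import Counter

from gpbwt import (
    PanelParams,
    VariantSpec,
    batch_embed,
    build_from_variants,
    drop_ambiguous,
    sample_walks,
    synth_panel,
)

SEED = 20170711
rng = random.Random(SEED)
reference = "".join(rng.choice("ACGT") for _ in range(4000))
variants = [
    VariantSpec(p, reference[p], rng.choice([b for b in "ACGT" if b != reference[p]]))
    for p in range(3, 3990, 17)
]
graph, alleles = build_from_variants(reference, variants)
panel = synth_panel(graph, alleles, PanelParams(n_haplotypes=50, seed=SEED))
idx = batch_embed(graph, panel)

walks = drop_ambiguous(sample_walks(graph, 1000, target_bp=100, seed=SEED + 1), graph)
counts = [idx.count_subthread(w) for w in walks]
dist = Counter(counts)

n_inconsistent = dist[0]
print(f"{len(walks)} random 100 bp walks against {len(panel)} haplotypes")
print(f"consistent with no haplotype: {n_inconsistent} "
      f"({100 * n_inconsistent / len(walks):.1f}%)")
print("count distribution (matching haplotypes -> walks):")
for count in sorted(dist):
    print(f"  {count:>3} -> {dist[count]}")
# Random walks choose alleles uniformly at each site, so most 100 bp walks
# cross several variants and quickly leave the set of stored allele
# combinations; the haplotype-consistent minority concentrates at low counts.
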