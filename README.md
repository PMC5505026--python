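# gpbwt — haplotype threads in bidirected genome graphs

`gpbwt` stores a panel of haplotypes *embedded in a genome graph* in a
compressed, searchable form — a graph generalization of the positional
Burrows–Wheeler transform (PBWT). It is aimed at people building or
evaluating graph-based resequencing tools: given a variation graph and a
panel of phased haplotypes, it answers "how many stored haplotypes are
consistent with this path?" in time proportional to the path length,
independent of the number of matches — the signal a graph read mapper or
variant caller can use to spot paths that no known haplotype supports.

## The model

A **genome graph** is a bidirected graph `G = (V, E)`: each node carries a
DNA label and has a left (5′) and right (3′) **side**; edges join sides, not
nodes (node *k* owns sides *2k−1* and *2k*; side 0 is the null side). A
haplotype is a **thread**: an alternating walk
`t = [t₀, t₁, …, t₂ₙ, t₂ₙ₊₁]` in which `t₂ᵢ, t₂ᵢ₊₁` are the two sides of one
node and each `{t₂ᵢ₊₁, t₂ᵢ₊₂}` is an edge. Threads are *ambisequences* — a
thread and its reverse are the same haplotype.

For every side *s* the index keeps an array `B_s[]` with one entry per
**visit** of a thread orientation to *s*, sorted by the reverse of the
visit's history; the entry is the side on which the orientation enters its
*next* node (0 if it ends). The companion function `c(x, s′)` gives the
smallest `B_{s′}[]` index of a visit arriving through the edge `{x, s′}`.
The pair (`B[]`, `c()`) is the gPBWT. Navigation is the LF-mapping analogue

    where_to(s, i, s′) = c(s̄, s′) + rank_{s′}(B_s[], i)

which drives three O(length) algorithms: extraction of all stored threads,
incremental embedding of a new thread, and counting the occurrences of a
query orientation as a subthread (a narrowing `[f, g)` range, exactly as in
FM-index backward search). Because linkage keeps co-travelling haplotypes in
contiguous blocks, the `B[]` arrays are stored run-length compressed: adding
a haplotype that agrees with stored ones only lengthens runs.

For graphs that admit a DAG orientation (every edge right-side → left-side,
acyclic — e.g. any graph built from a reference plus substitutions and
indels), a batch construction algorithm builds the identical index without
dynamic inserts by merging pre-sorted visit lists side by side.

## Worked example

```python
from gpbwt import BidirectedGraph, GPBWTIndex

g = BidirectedGraph()
for node_id in range(1, 6):
    g.add_node(node_id, "A")
for a, b in [(2, 5), (4, 5), (6, 7), (6, 9), (8, 8), (10, 9)]:
    g.add_edge(a, b)

idx = GPBWTIndex(g)
idx.embed_thread((1, 2, 5, 6, 9, 10, 9, 10))
idx.embed_thread((3, 4, 5, 6, 7, 8, 8, 7))

print(idx.b_array(5))                       # [9, 7]
print(idx.c_value(4, 5))                    # 1
print(idx.count_subthread((5, 6)))          # 2
print(idx.count_subthread((5, 6, 9, 10)))   # 1
print(idx.count_subthread((1, 2, 7, 8)))    # 0
```

`B[5] = [9, 7]`: both threads visit side 5; sorted by reversed history the
first continues to side 9, the second to side 7. `c(4, 5) = 1`: the visit
arriving over edge `{4, 5}` sits at slot 1. The counts say: both threads
contain node 3 (entered via side 5); only one continues to node 5 via side 9;
and no stored haplotype supports the path needing the absent edge `{2, 7}` —
it is consistent with no haplotype.

`examples/` contains this script plus end-to-end panel indexing
(`haplotype_panel.py`), random-walk consistency queries (`walk_queries.py`),
and FASTA+VCF import with haplotype splitting (`vcf_workflow.py`). A thin
CLI mirrors the workflow (`gpbwt build / index / extract / count / walk /
stats`) over GFA 1.0, FASTA and VCF files.

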