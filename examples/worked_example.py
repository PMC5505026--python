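"""Embed two threads in a small bidirected graph and inspect the index.

Five single-base nodes (sides 1-10; node k has left side 2k-1, right side 2k)
are joined by six edges, one of them a self-loop on side 8.  Two haplotype
threads are embedded and the per-side B[] arrays and oriented-edge c() values
are printed.  Each B[s] lists, for every visit to side s (sorted by reversed
history), the side on which the thread enters its next node; 0 means the
thread ends there.  c(x, s) is the first B[s] slot of visits arriving via the
edge {x, s}.
"""

from gpbwt import BidirectedGraph, GPBWTIndex, opposite

g = BidirectedGraph()
for node_id in range(1, 6):
    g.add_node(node_id, "A")
for a, b in [(2, 5), (4, 5), (6, 7), (6, 9), (8, 8), (10, 9)]:
    g.add_edge(a, b)

idx = GPBWTIndex(g)
idx.embed_thread((1, 2, 5, 6, 9, 10, 9, 10))
idx.embed_thread((3, 4, 5, 6, 7, 8, 8, 7))

print("B[] arrays (decoded to side ids):")
for side in g.sides():
    print(f"  B[{side:>2}] = {idx.b_array(side)}")

print("c() for each oriented edge (x, s):")
for a, b in g.edges:
    for x, s in {(a, b), (b, a)}:
        print(f"  c({x:>2}, {s:>2}) = {idx.c_value(x, s)}")

print("subthread counts:")
for query in [(5, 6), (5, 6, 9, 10), (1, 2, 7, 8)]:
    print(f"  {query} -> {idx.count_subthread(query)}")

# The two-step query (5,6)->(9,10) matches only the first thread; (1,2,7,8)
# needs an edge {2,7} that the graph lacks, so no haplotype is consistent.
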