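# Methods

## Data model

The graph is bidirected: node *k* (ids start at 1) has left side *2k−1* and
right side *2k*, sides are totally ordered by integer value, and side 0 is
the null side, smaller than every real side. Edges are unordered pairs of
sides; at most one edge per pair, self-loops `{s, s}` allowed. The numbering
convention (odd = left, even = right) is fixed so that serialized output and
the worked example in the README are bit-reproducible; nothing else in the
algorithms depends on it. `adjacent_sides(s)` returns neighbours in
ascending side order — the `c()` function's monotonicity and the arrival
grouping in `B[]` both derive from this ordering, which is why a graph is
frozen (made immutable) the moment an index is constructed over it.

Threads are ambisequences; the canonical orientation is the
lexicographically smaller of the two side sequences. This choice is
arbitrary in principle; fixing it lexicographically makes thread multisets
comparable across runs and implementations.

## Index invariants

For each side *s*, `B_s[]` holds one entry per visit, sorted by reversed
history; entries are stored as local-alphabet codes (0 = null; code *k* =
*k*-th side adjacent to `opposite(s)`, ascending) inside run-length arrays.
The structure maintains two count tables instead of materializing `c()`:
`starts[s]` (orientations beginning at *s*) and `edge_uses[(x, s)]` (visits
arriving at *s* over `{x, s}`), giving

    c(x, s) = starts[s] + Σ_{x' < x adjacent to s} edge_uses[(x', s)]

and the conservation invariant `len(B[s]) = starts[s] + Σ_x edge_uses[(x,s)]`
checked explicitly in tests at every embedding step. An isolated side's
start count falls back to `len(B[s])`.

## Tie order among identical histories

The reverse-prefix sort leaves one freedom: the order of visits whose entire
histories coincide. We order ties by the orientations' *onward* sequences
(suffix-lexicographic), with fully identical orientations kept latest-first.
Two consequences drove this choice:

- within any tie block the `B[]` entries appear in code order, so runs merge
  maximally, and
- embedding an exact duplicate of a stored thread only lengthens existing
  runs — the structural form of the observation that each additional sample
  costs an exponentially diminishing amount of space. A simpler rule
  (new starts always at position 0, i.e. ties in reverse insertion order)
  breaks this: duplicated panels interleave block-wise and run counts double
  per copy.

Concretely, the only change against the naive insertion algorithm is the
*start* entry's position: it is the new orientation's suffix rank among the
existing starts at `t₀`, computed by the same `[f, g)` range-narrowing used
for counting (cost O(thread length × max degree)); every later entry's
position follows from `where_to` unchanged, because equal-history entries
that continue through the same edge keep their relative order.

## Embedding, extraction, counting

Embedding a thread inserts its canonical orientation, then the reverse.
Each visit bumps `edge_uses` for its arrival edge *before* computing the
insertion index — the bump only affects `c()` for larger far endpoints, so
the computed index is unaffected but the tables stay consistent. Extraction
iterates sides in order, starts one orientation per start slot, and follows
`B[]` entries via `where_to` until the null code; the orientation count is
checked against the stored total, and a slot that runs off the end of an
array raises a corruption error naming side and index. Counting initializes
`[f, g) = [0, len(B[t₀]))` and narrows with `where_to` per visit; queries
that are not valid walks (absent side, missing edge, non-opposite pair)
return 0 rather than raising, because query paths from read mappers may
legitimately be graph-invalid and "consistent with no haplotype" is the
informative answer. A single-node query counts every visit through its entry
side. Both orientations of every thread are embedded, so counts are
orientation-symmetric.

## Batch construction

Graphs built from a reference plus substitution/indel variants admit a DAG
orientation: every edge joins a right side to a left side of a different
node and the induced directed graph is acyclic (`dag_orientation` returns a
topological node order, or an explicit failure value naming an offending
edge or cycle — bidirected graphs have no canonical notion of acyclicity, so
this right→left rule is the operational definition used throughout). In such
graphs an orientation enters nodes either always on left sides (moving with
the topological order) or always on right sides (against it), so the batch
builder runs two sweeps: left sides in topological order, right sides in
reverse. At each entry side it concatenates the newly starting orientations
(suffix-lexicographic) with the pre-sorted arrival lists per incident edge
in adjacency order, emits the `B[]` array directly, and stably partitions
the list by next entry side for downstream sides. Equality with the
incremental path is asserted bitwise on the serialized index in a 100-seed
randomized test; the incremental algorithm is the executable ground truth.
Cyclic or non-orientable graphs are refused with a pointer to the
incremental embedder.

## Run-length storage

`B[]` arrays are run-length arrays of (value, length) pairs with maximal
runs. Rank-before and random access binary-search lazily rebuilt cumulative
offsets plus per-value cumulative counts; inserts invalidate the caches, so
cost is O(log runs) amortized on query-heavy workloads and O(runs) right
after an insert. No wavelet tree or bit-vector select is provided — only
the operations the index needs. Serialization is little-endian with fixed
integer widths (u64 lengths, u32 codes), canonical (maximal) runs required,
so equal logical content means equal bytes; the index envelope adds a magic
and version byte, the SHA-256 of the canonical graph rendering (so an index
cannot silently be loaded against a different graph), per-side starts and
`B[]` arrays in side order, and the oriented-edge use table in key order.

## Synthetic data

- **Random walks** start at a uniformly chosen side, cross the node, and
  take uniformly chosen incident edges until the accumulated label length
  reaches the target (default experiments use 100 bp); dead ends return a
  failure value and are resampled (the start/step distributions are a
  package choice — walk-consistency percentages are therefore comparable
  only within this package). Walks whose sequence contains ≥ 2 consecutive
  N bases can be filtered, mirroring how ambiguous-region queries are
  usually discarded.
- **Panels** are mosaics: founders (default 4) draw each variant allele as a
  fair coin; each later haplotype copies a uniformly chosen earlier one,
  re-choosing its template with probability 0.1 per variant and flipping the
  copied allele with probability 0.01. The defaults produce strong linkage
  (runs ≈ 0.1 × entries at 50 haplotypes × 100 sites) while leaving enough
  diversity that subhaplotype counts vary; they emulate the run structure of
  real panels, not their allele-frequency spectrum, recombination maps or
  coalescent genealogy — passing tests show the data structure behaves
  correctly under linkage, not that population-genetic quantities are
  calibrated.
- The seeded mini-experiment in the acceptance suite (1,000 random 100 bp
  walks counted against a 50-haplotype panel over a 4 kb reference with a
  SNP every 17 bp) replaces chromosome-scale benchmarks; sizes were chosen
  so the whole suite stays in the seconds range on a laptop while still
  exercising thousands of index operations.

## VCF import and splitting

Haplotype import walks the reference node chain per sample and haplotype,
substituting alternate nodes where the phased genotype says so. The walk is
split — current piece emitted, a new thread begun — at exactly these
triggers: consecutive chosen alleles not joined by an edge (`no_edge`), a
heterozygous call without phasing (`unphased`), a missing allele
(`missing`), a haploid call (`haploid`), and conflicting alternate calls at
one position (`other`). Sites causing a gap are skipped entirely (the
allele is unknowable), whereas `no_edge` keeps both nodes and breaks between
them. No semantic reconciliation of conflicting records is attempted; the
split-only fallback guarantees every emitted piece validates. Multiallelic
records are split into biallelic variants upstream; variants with identical
reference intervals share one reference-allele node, and partially
overlapping variants are rejected (normalization is out of scope). VCF
positions are 1-based and converted to 0-based internally.

## Known limitations

- Incremental embedding is O(runs) per insert in the worst case, not the
  O(log n) a dynamic wavelet tree would give; the asymptotic contracts are
  honoured in spirit (run count, not length, drives cost) but this is a
  clarity-first reference implementation, not a succinct one.
- Batch construction holds all threads in memory (O(total thread length)).
- Graphs are static once indexed; adding nodes or edges requires rebuilding.
- `random_graph` instances are connected by construction via a backbone;
  pathological disconnected graphs are valid inputs but walks on them
  resample often.
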