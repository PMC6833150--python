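# Methods

## The data model

A variation graph is a set of sequence nodes plus embedded paths; edges
are not stored but implied by adjacent oriented steps within paths.  Four
path classes carry the four kinds of information a browser backend needs:
reference (one per chromosome), variant (one per SV call), read (projected
alignments), and annotation (genes/repeats).  This representation makes an
SV a first-class object: the novel adjacency it creates is witnessed by a
step pair in its own path, and evidence for or against it is a read path
that does or does not contain the same adjacency.

Internal coordinates are uniformly 0-based half-open.  VCF (1-based) and
browser-style `contig:start-end` strings (1-based closed) are converted at
parse time; human-facing CSV output converts back.  This removes off-by-one
ambiguity exactly at junctions, which is where it matters.

A breakend is stored as the 0-based *boundary between two bases* where the
novel adjacency sits, plus which flank of that boundary the event retains
(`left`/`right`).  The four VCF bracket forms map onto this pair
bijectively; same-side pairs are inverted joins.  A deletion of
`[a, b)` has boundaries `a` and `b`; splitting reference nodes at those
coordinates realizes the junction as a node adjacency.

## Graph construction

Construction follows a breakpoint-splitting procedure: collect all
junction boundaries; tile each contig with nodes cut at a fixed 1 Mbp
pitch and at every boundary; add one forward reference path per contig;
synthesize one variant path per event; add one new node per insertion.
Because the final tiling is just the sorted union of pitch multiples and
breakpoints, pitch-then-breakpoint and breakpoint-then-pitch orders
produce identical graphs (asserted in tests).  A breakpoint coinciding
with an existing boundary triggers no split, so no zero-length nodes
arise.  Node ids are dense, ascending in reference order with contigs in
input order, insertion nodes numbered after all reference nodes —
identical inputs give byte-identical GFA output.

The 1 Mbp node-length pitch is retained as a default: it bounds the size
of any node a renderer must draw and keeps flank extents bounded.  Both
the pitch and the maximum flank are configurable (`BuildConfig`).

**Flanks.**  Each variant path includes reference sequence on both sides
of every junction so the defining edge appears between two real nodes.
The flank extends to the farthest existing node boundary within
`max_flank` (default 1 Mbp) of the junction, truncated at contig ends.
With the default configuration such a boundary always exists because of
the pitch; if `max_flank` is set below the pitch, the flank degrades to
the single adjacent node rather than vanishing, since an edge needs two
endpoints.  A junction at a contig edge simply has an empty flank on that
side.

**Duplications** are traversed exactly twice regardless of caller
copy-number annotations; higher copy numbers would need a per-caller CN
convention that is not standardized, and two traversals already witness
the defining back edge.

## VCF dialects and normalization

Symbolic records are interpreted from `SVTYPE` + `END`/`SVLEN`.  Two POS
conventions circulate: POS as the first affected base (affected interval
`[POS−1, END)`) and POS as the padding base before the event
(`[POS, END)`).  When SVLEN is present it arbitrates — `|SVLEN| == END −
POS` selects the padding reading — so both conventions land on the same
0-based interval.  The raw `INFO/END` is read verbatim (via cyvcf2);
htslib's newer habit of recomputing the record end from SVLEN would
otherwise silently shift intervals by one.

Normalization proceeds in three idempotent steps:

1. **mate pairing** — reciprocal BND records (via `MATEID`, else
   coordinate reciprocity within ±10 bp) collapse to one adjacency;
2. **inversion promotion** — an intra-contig adjacency joining equal
   sides (head-to-head or tail-to-tail) is the signature of an inversion
   end and becomes an `INV` spanning its boundaries;
3. **deduplication** — events of the same type whose breakends agree
   within ±10 bp merge, keeping the highest read support.

These three steps collapse all four wild inversion encodings to the same
canonical event.  The ±10 bp tolerance reflects the small junction
asymmetries real callers report; it sits far below the 1 kbp filter
floor, so it cannot merge distinct filtered SVs.  Unmatched inter-contig
or colinear BNDs remain single-ended breakend events.  Multi-allelic
records are split one event per ALT before normalization.  Contig naming
(`chr` prefix vs bare) is reconciled against the attached genome and
logged.

## Filtering

Three removal criteria, attributed first-match: (1) length ≤ 1 kbp
(inclusive — the boundary itself is "small"; breakends without defined
length are exempt), (2) excluded type tags (insertions and composite
tags such as `INVDUP`, `DEL/INV`, `DUP/INS`), (3) a junction point inside
a blacklist interval.  Blacklist overlap is tested on junction *points*,
not event spans: an SV spanning a bad region with both junctions in clean
sequence is still confidently placed, and the narrower reading removes
less.  Kept plus per-criterion counts always partition the input;
monotonicity in `min_length` and blacklist growth is property-tested.

## Projections

Features and alignments project onto reference-origin nodes only.
Annotation paths step forward across every overlapped node; partial
overlap of the terminal nodes is recorded as offsets in metadata rather
than splitting nodes (annotations should not reshape the graph).  Read
segments step across their overlapped nodes, reversed with reverse
orientation on the minus strand; segments of one read concatenate in
query-position order (primary first when query positions are missing), so
a split read across a deletion junction reproduces exactly that
deletion's junction edge.  Reads never traverse insertion nodes: the
input alignments are against the linear reference, and placing reads on
novel sequence would require graph-aware alignment, which is out of
scope.  CIGAR detail is deliberately not retained.

Junction identity is compared orientation-insensitively
(`canonical_edge`): traversing an adjacency forward or in reverse
complement witnesses the same physical junction, which is what makes
reverse-sequenced reads count as evidence.

## Subgraph queries

An interval query returns (a) the reference nodes overlapping the
(optionally padded, default 0) interval, (b) *all* nodes of every variant
path touching (a) — so the remote end of a multi-megabase inversion or a
translocation partner appears in the same response; a fixed-radius rule
would miss it, and flanks already bound variant-path size — and (c) every
path restricted to the included nodes, split into maximal contiguous
runs.  Read and annotation paths are restricted but never trigger
inclusion: reads are evidence, and read-driven expansion would re-create
the hairball the interval restriction exists to avoid.

The cache is a plain LRU keyed on the exact `(contig, start, end,
padding)` tuple, default capacity 128 — matching per-request caching
semantics; containment lookup (serving a sub-interval from a cached
superset) is future work.  Cache transparency (identical result streams
with and without the cache) is asserted over randomized query streams.

## Serialization

GFA1 carries the graph: `S` lines with sequence (or `*` plus `LN` above a
configurable threshold), `L` lines derived from adjacent path steps with
`0M` overlap, `P` lines per path.  Reference origin travels on rGFA-style
`SN`/`SO` tags, path class on `PC`, metadata as a compact JSON `MD` tag.
Deterministic ordering makes serialization reproducible byte-for-byte,
which the round-trip tests rely on.  Foreign GFA without origin tags is
loaded by reconstructing origins from the cumulative walk of untagged
(reference) paths.  Subgraphs serialize to JSON with 0-based coordinates
and stable key order; the schema is this package's own definition.

## Synthetic data

The generator draws uniform-random A/C/G/T genomes (GC ≈ 0.5), implants
non-overlapping DEL/INV/DUP/INS placements (defaults: 1.5–20 kbp long,
≥ 2 kbp apart, ≥ 5 kbp from contig ends — comfortably above the 1 kbp
filter floor and small relative to the test genomes), and writes them as
VCF in the chosen encoding.  Its closure property — parse + canonicalize
of its own output reproduces the truth set exactly — is itself a tested
contract.  Read simulation lays out the ALT haplotype as blocks
(deleted intervals removed, inverted blocks strand-flipped, duplicated
blocks repeated, insertions interposed), samples fixed-length reads
uniformly (default 2 kbp, 20×), maps them back to reference segments, and
drops sub-50 bp stubs a real aligner would not place.  Reads are
error-free and single-haplotype per read; heterozygosity (the default)
draws half the reads from the unrearranged reference.  What this does
*not* emulate: sequencing errors, alignment ambiguity in repeats,
coverage biases, diploid phasing across events, or translocation-spanning
reads — so passing tests demonstrate correctness of the graph machinery,
not robustness to noisy real-world alignment.

## Numerical and edge-case choices

- Position lookup is a binary search over the node tiling; a linear-scan
  oracle backs the property test.
- Breakend positions exactly on contig ends (0 or L) are legal and
  produce truncated flanks, not errors; out-of-bounds positions fail the
  build with the offending event named.
- Ambiguous groupings in normalization resolve deterministically
  (lexicographic id tie-breaks) and are logged; canonical output order is
  independent of input order.
- Graph validation returns violations as data (a report listing the
  invariant and offending ids), not exceptions, so pipelines can log and
  decide.

## Scale of the shipped checks

Default test and acceptance runs use genomes up to 5 Mbp, 100 implanted
SVs, 1,000 cache queries, and 200 round-trip graphs — sizes chosen so the
whole suite completes in seconds while still crossing the 1 Mbp pitch,
multi-node flanks, and every SV type.  Construction is linear in genome
size plus breakpoints, so nothing qualitative changes at chromosome
scale; memory for sequence-bearing graphs is ~2 bytes per base.

## Known limitations

- Inversion promotion treats any intra-contig same-side adjacency as an
  inversion end; a genuinely unmatched single such record is promoted
  too, which is usually the right reading but conflates the two.
- Copy number > 2 duplications are flattened to two traversals.
- Nested insertions (an insertion within an insertion) cannot be
  expressed in the input VCF at all and are out of scope.
- Gene-name lookup resolves only unique exact matches; synonyms and
  fuzzy matching are not attempted.
- The JSON subgraph contract is defined here, not inherited from any
  server implementation; transport (HTTP) is out of scope.
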