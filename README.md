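# svgraph

Structural variants (SVs) called from long reads arrive as VCF files whose
encodings differ caller by caller — the same physical inversion may appear
as one inversion record, two inversion records, one breakend (BND) mate
pair, or four BND records.  `svgraph` normalizes these dialects into
canonical events and builds a **variation graph** in which everything is a
path over sequence nodes:

- **reference paths** spell each chromosome of the linear reference;
- **variant paths** encode one SV each, carrying flanking sequence on both
  sides of every junction so the defining edge is witnessed by a node
  adjacency (a deletion *skips* nodes, an inversion traverses them in
  *reverse*, a duplication passes through them *twice*, an insertion visits
  a *new* node, a fusion jumps between contigs);
- **read paths** project linear-reference alignments, so a split read over
  a deletion reproduces exactly the junction edge of that deletion's path;
- **annotation paths** place genes and repeats on the same graph.

Edges are never stored: they are implied by adjacent steps in paths.  The
graph serializes to GFA1; interval- and gene-name-based subgraph queries
(with LRU caching, the genome-browser backend contract) return JSON.  A
synthetic-data module generates random genomes, implants truth SVs in any
dialect encoding, and simulates error-free split-read alignments, so the
whole pipeline is testable without any external dataset.

The intended users are people building or debugging SV callers and
genome-graph pipelines who need a scriptable way to turn caller output
into an inspectable graph.

## The model in brief

A graph is `(N, P)`: nodes `n ∈ N` hold DNA segments (length ≤ 1 Mbp), and
each path `p ∈ P` is an ordered walk of oriented steps `(n, ±)`.
Reference-origin nodes tile each contig `[0, L)` without gap or overlap;
node boundaries are the union of a 1 Mbp pitch and every SV junction.  For
an SV with junctions at reference boundaries `a < b` on one contig, the
variant path is

| type | steps |
|------|-------|
| DEL  | flank(→a) ++ flank(b→) |
| INV  | flank(→a) ++ reverse([a,b)) ++ flank(b→) |
| DUP  | flank(→a) ++ [a,b) ++ [a,b) ++ flank(b→) |
| INS  | flank(→a) ++ new node ++ flank(a→) |
| BND  | flank into junction on contig A ++ flank out of junction on contig B |

where each flank extends to the farthest existing node boundary within
1 Mbp of the junction (truncated at contig ends).

All internal coordinates are 0-based half-open; VCF positions and
`contig:start-end` strings (1-based) are converted at the boundary.

## Worked example

Generate a synthetic dataset, build the graph, and inspect it:

```bash
$ svgraph fixtures --out demo --seed 5 --length 60000 --n-svs 4
wrote fixture set under demo

$ svgraph build --config demo/config.yaml
INFO svgraph: reference: 1 contig(s), 60000 bp
INFO svgraph: vcf: records read: 4
INFO svgraph: vcf: events parsed: 4
INFO svgraph: canonical events: 4
INFO svgraph: filter: kept 4, removed {}
INFO svgraph: graph: 9 nodes, 5 paths
INFO svgraph: alignments: projected 511 read path(s)
INFO svgraph: wrote demo/graph.gfa

$ svgraph stats demo/graph.gfa
contigs: 1
nodes: 9
node length: min=4201 median=5038 max=16447
reference paths: 1
variant paths: 4
read paths: 511
annotation paths: 0
edges: 24
validation: ok
```

The four implanted SVs became four variant paths; 511 simulated reads were
projected onto the graph.  `demo/events.csv` lists the canonical events in
1-based coordinates:

```
id,type,contig_a,pos_a,contig_b,pos_b,length,support,source
sv0,DUP,c1,5794,c1,12962,7169,10,sniffles
sv1,DEL,c1,20732,c1,37178,16447,10,sniffles
...
```

Querying the junction of the 16 kb deletion returns a JSON subgraph in
which the reference path walks nodes `1+ … 9+` while the deletion's path
`DEL_sv1_c1:20732` skips node 4 — the deleted interval:

```bash
$ svgraph query demo/graph.gfa --interval c1:20733-20800
{ "nodes": [...9 nodes...],
  "paths": [
    {"name": "c1", "class": "reference", "steps": [[1,"+"],[2,"+"],...,[9,"+"]]},
    {"name": "DEL_sv1_c1:20732", "class": "variant",
     "steps": [[1,"+"],[2,"+"],[3,"+"],[5,"+"],[6,"+"],...]},
    ...511 read paths restricted to the window...
  ] }
```

The adjacency `3+ → 5+` in the variant path *is* the deletion; any read
path containing the same edge is junction-spanning evidence, and (the
dataset being heterozygous) read paths walking `3+ → 4+` through the
deleted interval are reference-allele evidence in the same view.

The same operations are available as a library:

```python
import svgraph as sg

genome = sg.make_genome(1, [60_000], seed=5)
truth, vcf_text = sg.implant_svs(genome, sg.random_placements(genome, 4, seed=5))
graph = sg.build_graph(genome, truth)
sub = sg.extract_subgraph(graph, sg.Interval("c1", 20_732, 20_800))
```

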