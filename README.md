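# argkit

A library and command-line tool for **genome ancestral recombination graphs
(gARGs)** — the encoding of genetic ancestry under recombination in which
nodes are haploid genomes and each edge `(c, p, I)` is annotated with the set
of disjoint half-open genomic intervals `I` over which genome `c` inherits
from genome `p`.

Because adjacent nucleotides can have different paths of inheritance, the
genealogical tree for a sample of sequences varies along the genome.  A gARG
captures the whole interwoven structure: formally a directed acyclic graph
`(N, S, E)` over a genome `[0, L)`, with sample set `S ⊆ N` and
interval-annotated edge set `E`.  Compared with the classical *event ARG*
(eARG) encoding — internal nodes as common-ancestor and recombination
events, the latter annotated with a crossover breakpoint — the gARG stores
resolved inheritance locally on every edge, supports any form of homologous
exchange (multiple crossovers, gene conversion) with multi-interval
annotations, and can represent partial and approximate structures such as
polytomies, locally-unary nodes, and uncoalesced regions.

## What it does

- **`argkit.garg`** — the data model (`GARG`, `Node`, `Edge`,
  `IntervalSet`), structural validation, and pastwards propagation of
  **ancestral material**: the loci of each node ancestral to a sample set,
  with Hudson-style truncation at each local MRCA.
- **`argkit.trees`** — recovery of the **local trees** along the genome: an
  efficient sequential sweep over sorted edge endpoints, an independent
  point-wise tracing oracle (`tree_at`), per-tree MRCAs, Newick export.
- **`argkit.simplify`** — the **simplify** algorithm at four precision
  levels: `resolve` (drop non-ancestral material), `prune-sc` (collapse
  unknowable reconverging "diamonds"), `prune-unary` (drop nodes that never
  coalesce), `full` (bypass locally-unary nodes so every node-interval pair
  branches).  Per-node **coalescence spans** quantify how locally-unary a
  node is.
- **`argkit.earg`** — classical event ARGs: local-tree tracing through
  breakpoints, lossless conversion to gARGs (`[0, x)` / `[x, L)` outbound
  annotations), and conversion plus sample resolution in one step.
- **`argkit.wf`** — a prospective diploid **Wright–Fisher recorder**:
  forward-in-time simulation embedded in an explicit pedigree, recording
  inheritance exhaustively generation-by-generation, with optional periodic
  simplification — the package's synthetic-data generator.
- **`argkit.io`** — plain-TSV node/edge table formats with byte-stable
  round trips, plus interval-tagged Newick export.

## Worked example

The bundled pedigree fixture (`fig_pedigree`) is a gARG for four sampled
genomes `a–d` embedded in an inbred pedigree of eight diploids, genome
length 10.  Genome `a` inherits `[0,2)` from `e` and `[2,10)` from `f`;
genome `c` is the complementary recombinant (`[0,7)` from `f`, `[7,10)`
from `e`):

```python
>>> import argkit as ak
>>> g = ak.fig_pedigree()
>>> lab = g.labels()
>>> for f in ak.trees(g, mode="coalescent-only"):
...     print(f.interval, {lab[u]: lab[p] if p is not None else None
...                        for u, p in sorted(f.parent_of.items())})
(0.0, 2.0) {'a': 'i', 'b': 'i', 'c': 'k', 'd': 'k', 'i': 'n', 'k': 'n', 'n': None}
(2.0, 7.0) {'a': 'f', 'b': 'n', 'c': 'f', 'd': 'k', 'f': 'k', 'k': 'n', 'n': None}
(7.0, 10.0) {'a': 'k', 'b': 'i', 'c': 'i', 'd': 'k', 'i': 'n', 'k': 'n', 'n': None}
```

The two recombination breakpoints (2 and 7) delimit three local trees.  In
the middle region samples `a` and `c` coalesce in `f`; `f` is ancestral over
the whole genome but coalescent only on `[2,7)`:

```python
>>> ak.coalescence_spans(g)[g.find("f")]
CoalescenceSpan(coalescent={[2, 7)}, ancestral={[0, 10)}, fraction=0.5)
```

The coalescence-span *fraction* (here 0.5) is the proportion of a node's
ancestral span over which it is a coalescence in the local trees — nodes
with fractions strictly between 0 and 1 are "locally unary", a structural
feature the gARG encoding preserves and the `full` simplification level
removes.

From the shell, the same machinery as a pipeline:

```console
$ argkit simulate --n 5 --gens 10 --L 100 --rho 1.0 --seed 42 \
      --simplify-every 5 -o sim.garg --pedigree sim.ped.tsv
nodes=91 edges=137 samples=10
$ argkit simplify sim.garg sim.full.garg --level full --densify
nodes 91 -> 24, edges 137 -> 52
$ argkit trees sim.full.garg -o sim.nwk --mode coalescent-only
27 local trees over [0, 100)
```

Ten sampled genomes from five diploids: the raw recording holds 91 genomes;
full simplification keeps the 24 that appear in the 27 local trees, written
as interval-tagged Newick (`left<TAB>right<TAB>newick`, one semicolon-
terminated tree per root).

Converting a classical event ARG resolves its samples' ancestral material;
in the bundled three-sample worked example, the grand MRCA `q` and the edge
of the recombination at position 5 (which falls entirely in non-ancestral
material) disappear:

```console
$ argkit convert-earg src/argkit/data/wiuf_hein.earg out.garg
nodes 17 -> 15 (removed: 9,16)
```

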