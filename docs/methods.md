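# Methods

## The data model

A gARG is the triple `(N, S, E)`: nodes `N` are haploid genomes (a diploid
individual carries two), `S ⊆ N` are the sampled genomes, and each edge
`(c, p, I)` records that child genome `c` inherited the interval set `I`
from parent genome `p`.  Coordinates are 0-based, half-open `[left, right)`
reals over a shared genome `[0, L)`; `L` is stored explicitly rather than
inferred from edge extents.  Interval sets are kept canonical — sorted,
disjoint, abutting intervals merged — so annotation equality is exact tuple
equality; the algebra (union, intersection, difference) is validated against
a brute-force per-point membership oracle in the tests.

Node ids are arbitrary nonnegative integers (identifiers, not indices);
optional metadata carries labels, and node times, measured pastwards in
generations, may be absent.  Validation checks acyclicity, per-child
disjointness of parental annotations (a genome inherits any locus from at
most one parent), interval bounds, and — only when every node is dated —
strict parent-older-than-child ordering.  Violations are returned as data,
not raised, so a reader can report them with file line numbers.

Multiple crossovers or gene conversion between one child–parent pair are a
single multi-interval edge; no extra event vocabulary is needed.

## Ancestral material

The loci of a node ancestral to the sample set are computed by a single
children-first pass.  Each node accumulates, per sample, the loci over which
it is ancestral to that sample: the union over child edges of the edge's
annotation intersected with the child's *transmissible* material.  Where a
node's per-sample coverage reaches the full sample set it is the local MRCA:
it keeps those loci, but they are removed from its transmissible material
and so never reach strictly older nodes.  This is the bookkeeping of
Hudson-style coalescent simulation, and it is what makes a "grand MRCA"
above all local roots empty, hence removable.  A node's *coalescent* loci
are those where at least two child-edge lineages carrying ancestral material
meet; the coalescence span of a node is `span(coalescent)/span(ancestral)`
(0 for an empty ancestral span).

Two useful consequences, both property-tested: every sample is ancestral to
itself over `[0, L)` (with a single sample, nothing propagates past it), and
enlarging the sample set never shrinks any node's material (the local MRCA
can only move pastwards).

## Local trees

`trees()` first restricts every edge to the child's transmissible material,
then sweeps left-to-right over the sorted interval endpoints, applying edge
removals before insertions at each breakpoint (removals-first preserves
per-child disjointness mid-sweep).  Forests — not trees: regions that have
not fully coalesced have several roots — are emitted per segment and
adjacent forests with identical parent maps are merged into maximal
intervals.  The number of forests is therefore at most the number of
distinct interior endpoints plus one.

`tree_at(g, x)` is an independent oracle: from each sample it follows the
unique edge covering `x`, merges paths, and truncates above the first node
ancestral to every sample.  The test suite checks sweep ≡ oracle at every
interval midpoint on hundreds of random simulator outputs.

In `coalescent-only` mode each forest is rewritten so nodes with exactly one
child lineage are bypassed, leaving only coalescences within the local tree
— the conventional way local trees are drawn.  Newick export writes one
line per forest (`left`, `right`, then one semicolon-terminated string per
root), with node ids as labels and branch lengths as time differences when
all nodes are dated.

## Simplify levels

`resolve(g, samples, opts)` returns a simplified gARG plus a report (old→new
node map, removed edges, coalescence spans).  Levels, in order of
strictness:

1. **resolve** — every edge annotation becomes `I ∩ transmissible(child)`;
   empty edges are dropped, then non-sample, non-retained nodes without any
   remaining edge.  The output is *sample-resolved*: no edge carries
   non-ancestral material (asserted by re-running propagation on the
   output).
2. **prune-sc** — collapse reconverging pass-through bundles.  A
   pass-through node has exactly one child edge and one parent edge; maximal
   chains of them run from a bottom node to a top node.  Where two or more
   parallel connections (chains, or a chain plus a direct edge) share the
   same (bottom, top) pair, the bundle is replaced by one direct edge
   carrying the union of the arriving intervals, iterating to a fixpoint.
   This removes "diamonds" — recombinations whose products rejoin without
   coalescing, unknowable from data — while leaving simple unary chains
   (which do not reconverge) alone.  The definition is operational; the
   level is specified by example in the literature, and this reading keeps
   it strictly between levels 1 and 3.
3. **prune-unary** — remove every node whose coalescent set is empty,
   reconnecting child edges to the next surviving ancestor per locus by
   composing intersections along the bypassed chains (children-first order).
   Removed nodes' times are discarded.  Note edge *counts* may grow here
   even though node counts shrink: bypassing a locally-unary node with two
   parents splits its child's edge across them.
4. **full** — rebuild the edge table directly from the coalescent-only
   local forests, squashing abutting per-pair intervals.  By construction
   every surviving node-interval pair has at least two children in its
   local tree, and the restricted local trees are preserved exactly — an
   invariant checked at every level, and cross-checked against the
   succinct-tree-sequence library's simplify on raw Wright–Fisher
   recordings.

`retain_nodes` forces nodes to survive (used to keep recombination-event
nodes for clarity after eARG conversion).  `densify_ids` renumbers survivors
`0..n-1` in time order when dated, else topological order with samples
first.  All levels are idempotent.  Uncoalesced regions are represented as
multi-root forests, never an error.

## Event ARGs

An eARG stores sample, common-ancestor, and recombination events;
recombination events carry one breakpoint and exactly two parent edges with
explicit `left`/`right` designation (ordering-rule inference is deliberately
not supported — conventions differ between authors and are a known source
of ambiguity).  Tracing at position `x` follows the left parent iff
`x < breakpoint`; a position exactly at the breakpoint routes rightwards,
consistent with the half-open conversion intervals.  Conversion to a gARG
annotates the outbound edge(s) of each node: `[0, L)` for sample and
common-ancestor events, `[0, x)` and `[x, L)` for a recombination with
breakpoint `x` — a one-to-one correspondence with the eARG's information.
`convert_and_resolve` composes conversion with resolve-level simplification,
retaining the recombination nodes.  The eARG tracer shares no code with the
gARG machinery, so the two routes cross-validate each other on random event
graphs.

## The Wright–Fisher recorder

`simulate(SimParams)` runs a diploid Wright–Fisher model forwards in time,
embedded in an explicit pedigree.  Per generation of `n_diploids`
individuals, each of the `2N` new genomes independently draws a parent
individual uniformly at random (selfing allowed — the simplest WF
convention), a fair-coin phase, a `Poisson(recomb_rate)` number of
crossovers, and uniform crossover positions on `(0, L)`; the genome is the
alternating mosaic of the parent's two genomes and the edges record exactly
the inherited intervals.  Node time is the generation index pastwards
(samples 0, founders `n_generations`); the final generation is flagged as
the sample set.  Founders carry no edges; segments that fail to coalesce
within the simulated span simply end there, which the data model represents
as extra local roots.

Randomness comes from one numpy generator with a documented per-generation
draw order (parents, phases, counts, then per-genome positions), so a seed
reproduces the node and edge tables bit-for-bit, and the simplification
schedule — which consumes no randomness — can be varied without changing
the realized genealogy.  That underpins `periodic_simplify_equivalence`:
simplifying every k generations versus never must yield identical fully
simplified local tree sequences for the same seed.

Defaults (`n_diploids=10`, `n_generations=20`, `L=100`, `recomb_rate=1`)
describe a small population with roughly one crossover per meiosis.  The
calibration tests use `n_diploids ∈ {5, 20}` with `8·n_diploids`
generations (long enough that all but ~2% of pairs coalesce before the
founder horizon, which truncates coalescence times) and 200 replicates —
sizes chosen so the whole randomized suite runs in a few minutes.  The
expected pairwise coalescence time at a locus is geometric with success
probability `1/2N` per generation; rather than asserting the closed form,
the mean is compared within three standard errors against an independent
lineage-tracing oracle that draws parent genomes directly and never touches
the gARG machinery.

What the generator does *not* emulate: mutation and observed sequences
(inheritance only), gene conversion and sex-specific or multi-chromosome
recombination (the data model represents them; the simulator emits single
crossovers per meiosis draw), selection, population structure, and
non-uniform mating.  Passing tests therefore demonstrate correctness of the
graph algorithms under neutral WF inheritance, not realism of any inference
on real data.

## Numerical and formatting choices

Positions are continuous floats; fixtures use integers for readability.
Coincident crossover positions (measure zero) produce empty segments that
are skipped.  File output serializes floats with `repr` (shortest
round-trip form), sorts edge rows by (child, parent, left), and is
byte-stable: writing a canonical gARG twice yields identical files.  Parse
errors report line numbers; structural violations are collected and raised
as a list after parsing.

## Known limitations

- Simplification is implemented for clarity and correctness (interval-set
  arithmetic per node), not at the `O(n log n)` efficiency of the
  production succinct-tree-sequence implementation; it is comfortable at
  the scales of the bundled examples and simulator outputs.
- Level prune-sc detects parallel bundles whose interior nodes are
  pass-through *as stored*; more exotic reconverging subgraphs (e.g. with
  internal branching that carries no coalescence) are only removed at the
  stricter levels.
- The eARG reader supports node-annotated breakpoints with explicit sides
  only; native formats of specific inference tools are out of scope.
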