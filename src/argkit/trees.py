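"""Local genealogical trees along the genome.

The genealogy relating the samples changes at recombination breakpoints; a
gARG induces a sequence of local forests partitioning ``[0, L)``.  Two
independent routes are provided: :func:`tree_at` reconstructs the forest at a
single position by tracing pastwards from each sample, while :func:`trees`
sweeps left-to-right over sorted edge endpoints, applying edge insertions and
removals at each breakpoint — the efficient sequential recovery that makes
the tabular gARG encoding a good substrate for analysis.  The sweep is
checked against the point-wise oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

from .garg import GARG, propagate
from .intervals import IntervalSet

__all__ = [
    "LocalForest",
    "LocalTreeSequence",
    "tree_at",
    "trees",
    "pairwise_mrca",
]


@dataclass
class LocalForest:
    """The genealogy at one genomic interval.

    ``parent_of`` maps every node present in the forest to its parent, or to
    ``None`` for roots.  Regions where the samples have not fully coalesced
    yield several roots, hence a forest rather than a tree.
    """

    interval: Tuple[float, float]
    parent_of: Dict[int, Optional[int]]
    samples: FrozenSet[int] = frozenset()

    @property
    def nodes(self) -> FrozenSet[int]:
        return frozenset(self.parent_of)

    @property
    def roots(self) -> List[int]:
        return sorted(u for u, p in self.parent_of.items() if p is None)

    def children_of(self) -> Dict[int, List[int]]:
        out: Dict[int, List[int]] = {u: [] for u in self.parent_of}
        for u, p in self.parent_of.items():
            if p is not None:
                out[p].append(u)
        return out

    def num_children(self, node: int) -> int:
        return sum(1 for p in self.parent_of.values() if p == node)

    def ancestors(self, node: int) -> List[int]:
        """Root-ward path starting at ``node`` (inclusive)."""
        path = [node]
        seen = {node}
        while True:
            p = self.parent_of.get(path[-1])
            if p is None:
                return path
            if p in seen:  # defensive; cannot happen in a valid forest
                raise ValueError(f"cycle through node {p}")
            path.append(p)
            seen.add(p)

    def mrca(self, u: int, v: int) -> Optional[int]:
        """First common node on the two root-ward paths, or None."""
        if u not in self.parent_of or v not in self.parent_of:
            raise KeyError(f"node {u if u not in self.parent_of else v} not in forest")
        up = set(self.ancestors(u))
        for node in self.ancestors(v):
            if node in up:
                return node
        return None

    def same_topology(self, other: "LocalForest") -> bool:
        return self.parent_of == other.parent_of and self.samples == other.samples

    def newick(self, times: Optional[Dict[int, float]] = None) -> str:
        """One Newick string per root, semicolon-terminated and concatenated.

        Node ids are used as labels.  Branch lengths are parent-child time
        differences when ``times`` is given, otherwise omitted.
        """
        children = self.children_of()

        def render(u: int) -> str:
            kids = sorted(children[u])
            label = str(u)
            body = f"({','.join(render(k) for k in kids)}){label}" if kids else label
            p = self.parent_of[u]
            if times is not None and p is not None:
                body += f":{times[p] - times[u]:g}"
            return body

        return "".join(render(r) + ";" for r in self.roots)


@dataclass
class LocalTreeSequence:
    """Ordered (interval, forest) pairs tiling ``[0, L)`` exactly."""

    L: float
    forests: List[LocalForest] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.forests)

    def __iter__(self):
        return iter(self.forests)

    def at(self, x: float) -> LocalForest:
        for f in self.forests:
            if f.interval[0] <= x < f.interval[1]:
                return f
        raise ValueError(f"position {x} outside [0, {self.L})")

    def breakpoints(self) -> List[float]:
        return [f.interval[0] for f in self.forests] + [self.L]


# ---------------------------------------------------------------------------
# Point-wise oracle
# ---------------------------------------------------------------------------


def tree_at(g: GARG, x: float, samples: Optional[Iterable[int]] = None) -> LocalForest:
    """The local forest at position ``x``, built by per-sample tracing.

    Independent of the sweep in :func:`trees`: from each sample the unique
    parent whose edge covers ``x`` is followed pastwards; paths merge where
    lineages share an ancestor and stop at the first node ancestral to every
    sample (the local MRCA).  Nodes with no ancestral material at ``x`` are
    excluded.
    """
    if not 0 <= x < g.L:
        raise ValueError(f"position {x} outside [0, {g.L})")
    sample_set = frozenset(g.samples if samples is None else samples)
    unknown = sample_set - g.nodes.keys()
    if unknown:
        raise KeyError(f"unknown sample ids: {sorted(unknown)}")

    def parent_at(u: int) -> Optional[int]:
        for e in g.edges_for_child(u):
            if x in e.intervals:
                return e.parent
        return None

    carried: Dict[int, set] = {}
    step: Dict[int, Optional[int]] = {}
    for s in sample_set:
        u = s
        while True:
            carried.setdefault(u, set()).add(s)
            if u not in step:
                step[u] = parent_at(u)
            p = step[u]
            if p is None:
                break
            u = p

    full = {u for u, got in carried.items() if got == sample_set}
    # A node strictly above the local MRCA is full and has a traced child
    # that is already full; it carries no ancestral material at x.
    traced_full_child = {
        p for v, p in step.items() if p is not None and v in full
    }
    kept = {u for u in carried if not (u in full and u in traced_full_child)}
    parent_of = {u: (step[u] if step[u] in kept else None) for u in kept}
    return LocalForest((x, x), parent_of, sample_set & kept)


# ---------------------------------------------------------------------------
# Sequential sweep
# ---------------------------------------------------------------------------


def trees(
    g: GARG,
    samples: Optional[Iterable[int]] = None,
    mode: str = "as-stored",
    *,
    retain: Iterable[int] = (),
) -> LocalTreeSequence:
    """Recover the sequence of local forests along the genome.

    The graph is first restricted to sample-ancestral material, then swept
    left-to-right: at each breakpoint departing edges are removed before
    arriving edges are inserted (preserving per-child disjointness
    mid-sweep), and a forest is emitted per maximal interval.

    mode:
        ``"as-stored"`` keeps every node the resolved graph stores;
        ``"coalescent-only"`` bypasses nodes that are unary within each
        forest, keeping only coalescences within the local tree (plus
        samples and any ``retain`` nodes).
    """
    if mode not in ("as-stored", "coalescent-only"):
        raise ValueError(f"unknown mode {mode!r}")
    violations = g.validate()
    if violations:
        raise ValueError("invalid gARG: " + "; ".join(violations))
    sample_set = frozenset(g.samples if samples is None else samples)
    keep = sample_set | frozenset(retain)
    if not sample_set:
        return LocalTreeSequence(g.L, [LocalForest((0.0, g.L), {}, frozenset())])

    tables = propagate(g, sample_set)
    pieces: List[Tuple[float, float, int, int]] = []
    for e in g.edges:
        resolved = e.intervals & tables.transmissible[e.child]
        for l, r in resolved:
            pieces.append((l, r, e.child, e.parent))

    inserts = sorted(pieces, key=lambda p: p[0])
    removes = sorted(pieces, key=lambda p: p[1])
    breaks = sorted({0.0, g.L} | {p[0] for p in pieces} | {p[1] for p in pieces})
    breaks = [b for b in breaks if 0.0 <= b <= g.L]

    active: Dict[int, int] = {}  # child -> parent
    forests: List[LocalForest] = []
    i = j = 0
    for k in range(len(breaks) - 1):
        left, right = breaks[k], breaks[k + 1]
        while j < len(removes) and removes[j][1] <= left:
            del active[removes[j][2]]
            j += 1
        while i < len(inserts) and inserts[i][0] <= left:
            active[inserts[i][2]] = inserts[i][3]
            i += 1
        parent_of: Dict[int, Optional[int]] = dict(active)
        for c, p in active.items():
            parent_of.setdefault(p, None)
        for s in sample_set:
            parent_of.setdefault(s, None)
        forest = LocalForest((left, right), parent_of, sample_set)
        if mode == "coalescent-only":
            forest = _coalescent_only(forest, keep)
        forests.append(forest)

    return LocalTreeSequence(g.L, _merge_adjacent(forests))


def _coalescent_only(forest: LocalForest, keep: FrozenSet[int]) -> LocalForest:
    """Bypass locally-unary nodes so every internal node has >= 2 children."""
    counts: Dict[int, int] = {}
    for u, p in forest.parent_of.items():
        if p is not None:
            counts[p] = counts.get(p, 0) + 1
    kept = {
        u
        for u in forest.parent_of
        if u in keep or counts.get(u, 0) >= 2
    }

    cache: Dict[int, Optional[int]] = {}

    def eff_parent(u: int) -> Optional[int]:
        if u in cache:
            return cache[u]
        p = forest.parent_of[u]
        while p is not None and p not in kept:
            p = forest.parent_of[p]
        cache[u] = p
        return p

    parent_of = {u: eff_parent(u) for u in kept}
    return LocalForest(forest.interval, parent_of, forest.samples & kept)


def _merge_adjacent(forests: List[LocalForest]) -> List[LocalForest]:
    merged: List[LocalForest] = []
    for f in forests:
        if merged and merged[-1].same_topology(f):
            merged[-1] = LocalForest(
                (merged[-1].interval[0], f.interval[1]), f.parent_of, f.samples
            )
        else:
            merged.append(f)
    return merged


# ---------------------------------------------------------------------------
# Pairwise MRCAs
# ---------------------------------------------------------------------------


def pairwise_mrca(
    lts: LocalTreeSequence, u: int, v: int
) -> List[Tuple[Tuple[float, float], Optional[int]]]:
    """Per local tree, the MRCA of ``u`` and ``v`` (None where uncoalesced)."""
    out = []
    for forest in lts:
        out.append((forest.interval, forest.mrca(u, v)))
    return out
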