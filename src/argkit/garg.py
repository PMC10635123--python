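"""The genome-ARG data model.

A gARG is a directed acyclic graph whose nodes are haploid genomes and whose
edges, annotated with :class:`~argkit.intervals.IntervalSet` inheritance
intervals, record which parts of a child genome were inherited from which
parent genome.  Formally it is the triple (N, S, E) of nodes, sampled nodes
and annotated edges over a genome ``[0, L)``.

This module also implements the pastwards propagation of ancestral material:
the genomic intervals of each node that are ancestral to a designated sample
set.  Propagation follows the coalescent bookkeeping of Hudson-style
simulation: once every sample has found a common ancestor at a locus (the
local MRCA), that locus is no longer transmitted further into the past — the
MRCA node carries it, strictly older nodes do not.  This is the semantics
under which a "grand MRCA" above all local roots carries no ancestral
material and is removed by simplification.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .intervals import IntervalSet

__all__ = [
    "Node",
    "Edge",
    "GARG",
    "AncestryTables",
    "ancestral_material",
]


@dataclass(frozen=True)
class Node:
    """A haploid genome.

    ``time`` is measured pastwards in generations (larger = older) and may be
    ``None`` when node dates are unknown.  ``metadata`` is opaque text; the
    worked-example fixtures store their alphabetical genome labels there.
    """

    id: int
    is_sample: bool = False
    time: Optional[float] = None
    metadata: str = ""


@dataclass(frozen=True)
class Edge:
    """Genetic inheritance of ``intervals`` by ``child`` from ``parent``."""

    child: int
    parent: int
    intervals: IntervalSet


class GARG:
    """A genome ARG: nodes, edges and a sample set over genome ``[0, L)``.

    The constructor canonicalizes edges — multiple edges for the same
    (child, parent) pair are merged into one multi-interval edge, and edges
    are sorted by (child, parent, leftmost coordinate).  Structural problems
    other than duplicate node ids are reported by :meth:`validate`, not
    raised.
    """

    def __init__(
        self,
        L: float,
        nodes: Iterable[Node],
        edges: Iterable[Edge] = (),
        samples: Optional[Iterable[int]] = None,
    ):
        self.L = float(L)
        self.nodes: Dict[int, Node] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise ValueError(f"duplicate node id {node.id}")
            self.nodes[node.id] = node
        merged: Dict[Tuple[int, int], IntervalSet] = {}
        for e in edges:
            key = (e.child, e.parent)
            merged[key] = merged[key] | e.intervals if key in merged else e.intervals
        self.edges: List[Edge] = sorted(
            (Edge(c, p, I) for (c, p), I in merged.items()),
            key=lambda e: (e.child, e.parent, e.intervals.intervals[:1]),
        )
        if samples is None:
            self.samples = frozenset(n.id for n in self.nodes.values() if n.is_sample)
        else:
            self.samples = frozenset(samples)
        self._child_edges: Optional[Dict[int, List[Edge]]] = None
        self._parent_edges: Optional[Dict[int, List[Edge]]] = None

    # -- indexes ------------------------------------------------------------

    def edges_for_child(self, node: int) -> List[Edge]:
        """Edges on which ``node`` is the child (its inheritance pastwards)."""
        if self._parent_edges is None:
            idx: Dict[int, List[Edge]] = {}
            for e in self.edges:
                idx.setdefault(e.child, []).append(e)
            self._parent_edges = idx
        return self._parent_edges.get(node, [])

    def edges_for_parent(self, node: int) -> List[Edge]:
        """Edges on which ``node`` is the parent (material it passes on)."""
        if self._child_edges is None:
            idx = {}
            for e in self.edges:
                idx.setdefault(e.parent, []).append(e)
            self._child_edges = idx
        return self._child_edges.get(node, [])

    def find(self, label: str) -> int:
        """Return the id of the node whose metadata equals ``label``."""
        for node in self.nodes.values():
            if node.metadata == label:
                return node.id
        raise KeyError(f"no node labelled {label!r}")

    def labels(self) -> Dict[int, str]:
        return {u: n.metadata or str(u) for u, n in self.nodes.items()}

    # -- ordering -----------------------------------------------------------

    def topological_order(self) -> List[int]:
        """Node ids, children before parents.  Raises on a cyclic graph."""
        ts: graphlib.TopologicalSorter = graphlib.TopologicalSorter()
        for u in self.nodes:
            ts.add(u)
        for e in self.edges:
            ts.add(e.parent, e.child)
        try:
            return list(ts.static_order())
        except graphlib.CycleError as exc:
            raise ValueError(f"gARG contains a cycle: {exc.args[1]}") from exc

    # -- validation ---------------------------------------------------------

    def validate(self) -> List[str]:
        """Check every structural invariant; return violations as messages.

        An empty list means the object is a valid gARG.
        """
        violations: List[str] = []
        if self.L <= 0:
            violations.append(f"nonpositive genome length L={self.L}")
        for u in self.samples:
            if u not in self.nodes:
                violations.append(f"sample {u} is not a node")
        genome = IntervalSet.single(0, self.L) if self.L > 0 else IntervalSet()
        for e in self.edges:
            if e.child == e.parent:
                violations.append(f"self edge at node {e.child}")
            if not e.intervals:
                violations.append(f"edge {e.child}->{e.parent} has empty intervals")
            elif not e.intervals.issubset(genome):
                violations.append(
                    f"edge {e.child}->{e.parent} outside [0, {self.L}): {e.intervals}"
                )
            for endpoint, role in ((e.child, "child"), (e.parent, "parent")):
                if endpoint not in self.nodes:
                    violations.append(f"edge {role} {endpoint} is not a node")
        # A genome inherits any locus from at most one parent.
        by_child: Dict[int, List[Edge]] = {}
        for e in self.edges:
            by_child.setdefault(e.child, []).append(e)
        for child, es in by_child.items():
            for i in range(len(es)):
                for j in range(i + 1, len(es)):
                    overlap = es[i].intervals & es[j].intervals
                    if overlap:
                        violations.append(
                            f"overlapping parental inheritance for child {child} "
                            f"(parents {es[i].parent} and {es[j].parent}): {overlap}"
                        )
        try:
            self.topological_order()
        except ValueError:
            violations.append("graph is not acyclic")
        if all(n.time is not None for n in self.nodes.values()):
            for e in self.edges:
                tc = self.nodes.get(e.child)
                tp = self.nodes.get(e.parent)
                if tc is not None and tp is not None and not tp.time > tc.time:
                    violations.append(
                        f"edge {e.child}->{e.parent} violates time ordering "
                        f"({tp.time} <= {tc.time})"
                    )
        return violations

    # -- equality / copies --------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, GARG):
            return NotImplemented
        return (
            self.L == other.L
            and self.nodes == other.nodes
            and self.edges == other.edges
            and self.samples == other.samples
        )

    def __repr__(self) -> str:
        return (
            f"GARG(L={self.L:g}, nodes={len(self.nodes)}, "
            f"edges={len(self.edges)}, samples={len(self.samples)})"
        )


# ---------------------------------------------------------------------------
# Ancestral material propagation
# ---------------------------------------------------------------------------


@dataclass
class AncestryTables:
    """Per-node results of propagating a sample set pastwards.

    material:
        Loci at which the node carries material ancestral to the samples.
        Includes loci at which the node is itself the local MRCA.
    transmissible:
        ``material`` minus the loci that fully coalesce in this node — the
        part the node passes on to its own parents.
    coalescent:
        Loci where at least two child-edge lineages carrying ancestral
        material meet in this node.
    descendants:
        Per node, per sample, the loci over which the node is ancestral to
        that sample (subject to local-MRCA truncation).
    """

    material: Dict[int, IntervalSet] = field(default_factory=dict)
    transmissible: Dict[int, IntervalSet] = field(default_factory=dict)
    coalescent: Dict[int, IntervalSet] = field(default_factory=dict)
    descendants: Dict[int, Dict[int, IntervalSet]] = field(default_factory=dict)


def propagate(g: GARG, samples: Iterable[int]) -> AncestryTables:
    """Propagate sample intervals pastwards through the graph.

    Processing nodes children-first, each node accumulates, per sample, the
    loci over which it is ancestral to that sample: the union over child
    edges of the edge's intervals intersected with the child's transmissible
    material.  Where every sample is present the node is the local MRCA and
    the loci stop propagating.
    """
    sample_set = frozenset(samples)
    unknown = sample_set - g.nodes.keys()
    if unknown:
        raise KeyError(f"unknown sample ids: {sorted(unknown)}")
    genome = IntervalSet.single(0, g.L)
    tables = AncestryTables()
    for u in g.topological_order():
        contribs: List[IntervalSet] = []
        acc: Dict[int, IntervalSet] = {}
        for e in g.edges_for_parent(u):
            arriving = e.intervals & tables.transmissible[e.child]
            if not arriving:
                continue
            contribs.append(arriving)
            for s, region in tables.descendants[e.child].items():
                piece = region & arriving
                if piece:
                    acc[s] = acc[s] | piece if s in acc else piece
        if u in sample_set:
            acc[u] = genome
            contribs.append(genome)
        material = IntervalSet()
        for region in acc.values():
            material = material | region
        fully = material
        for s in sample_set:
            fully = fully & acc.get(s, IntervalSet())
            if not fully:
                break
        tables.descendants[u] = acc
        tables.material[u] = material
        tables.transmissible[u] = material - fully
        tables.coalescent[u] = _multicovered(contribs)
    return tables


def _multicovered(interval_sets: List[IntervalSet]) -> IntervalSet:
    """Loci covered by at least two of the given interval sets."""
    if len(interval_sets) < 2:
        return IntervalSet()
    events: List[Tuple[float, int]] = []
    for ivs in interval_sets:
        for l, r in ivs:
            events.append((l, 1))
            events.append((r, -1))
    events.sort()
    out = []
    depth = 0
    start = None
    for pos, delta in events:
        prev = depth
        depth += delta
        if prev < 2 <= depth:
            start = pos
        elif prev >= 2 > depth:
            out.append((start, pos))
            start = None
    return IntervalSet(out)


def ancestral_material(
    g: GARG, node: int, samples: Optional[Iterable[int]] = None
) -> IntervalSet:
    """Genomic intervals of ``node`` ancestral to the sample set.

    Any sample is ancestral to itself over the whole genome.  Loci that have
    fully coalesced below ``node`` are excluded (the local MRCA itself
    retains them); see :func:`propagate`.
    """
    if node not in g.nodes:
        raise KeyError(f"unknown node id {node}")
    sample_set = g.samples if samples is None else frozenset(samples)
    return propagate(g, sample_set).material[node]
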