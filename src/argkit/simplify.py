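"""Sample resolution and simplification of gARGs.

``resolve`` propagates the samples' intervals pastwards, intersects them with
the edge annotations, and removes redundancy, at four precision levels of
increasing strictness:

``resolve``
    Edge annotations are restricted to the child's transmissible ancestral
    material; empty edges, and non-sample nodes left without edges, are
    dropped.  Topology is otherwise preserved.  The output is sample-resolved:
    no edge carries non-ancestral material.
``prune-sc``
    Additionally collapse singly-connected reconverging path bundles
    ("diamonds"): parallel chains of pass-through nodes (one child edge, one
    parent edge) between a shared bottom and top node are replaced by a
    single annotated edge.  Such structures are unknowable from data — the
    split and rejoin leave no trace in any local tree.
``prune-unary``
    Additionally remove every node that never represents a coalescence
    (unary everywhere), reconnecting its children to the next coalescent
    ancestor per locus.
``full``
    Rewrite edges to bypass nodes in each local tree in which they are
    unary, so every surviving node-interval pair has at least two children
    in its local forest (the "fully simplified" form produced by default by
    coalescent simulators).

Restricted local trees over the samples (coalescent-only mode) are preserved
exactly at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .garg import GARG, AncestryTables, Edge, Node, propagate
from .intervals import IntervalSet
from .trees import trees

__all__ = [
    "LEVELS",
    "SimplifyOptions",
    "CoalescenceSpan",
    "SimplifyReport",
    "resolve",
    "coalescence_spans",
]

LEVELS = ("resolve", "prune-sc", "prune-unary", "full")
_LEVEL_ALIASES = {
    "resolve-only": "resolve",
    "prune-singly-connected": "prune-sc",
    "prune-unary-everywhere": "prune-unary",
}


@dataclass(frozen=True)
class SimplifyOptions:
    """Options for :func:`resolve`.

    retain_nodes survive simplification even where the level would remove
    them (e.g. keeping recombination-event nodes for clarity).  densify_ids
    renumbers surviving nodes 0..n-1, in time order when node times exist,
    else in topological order with samples first.
    """

    level: str = "resolve"
    retain_nodes: FrozenSet[int] = frozenset()
    densify_ids: bool = False

    def canonical_level(self) -> str:
        level = _LEVEL_ALIASES.get(self.level, self.level)
        if level not in LEVELS:
            raise ValueError(f"unknown simplify level {self.level!r}")
        return level


@dataclass(frozen=True)
class CoalescenceSpan:
    """A node's coalescent and ancestral intervals and their span ratio."""

    coalescent: IntervalSet
    ancestral: IntervalSet
    fraction: float


@dataclass
class SimplifyReport:
    node_map: Dict[int, Optional[int]] = field(default_factory=dict)
    removed_edges: List[Tuple[int, int]] = field(default_factory=list)
    coalescence_span: Dict[int, CoalescenceSpan] = field(default_factory=dict)


def coalescence_spans(
    g: GARG, samples: Optional[Iterable[int]] = None
) -> Dict[int, CoalescenceSpan]:
    """Per node: coalescent loci, ancestral loci, and coalescence-span ratio.

    A node is coalescent at the loci where at least two child lineages
    carrying ancestral material meet in it; nodes coalescent over part of
    their ancestral span are the "locally unary" nodes that distinguish the
    precision levels.
    """
    sample_set = frozenset(g.samples if samples is None else samples)
    tables = propagate(g, sample_set)
    return _spans_from_tables(g, tables)


def _spans_from_tables(g: GARG, tables: AncestryTables) -> Dict[int, CoalescenceSpan]:
    out = {}
    for u in g.nodes:
        coal = tables.coalescent[u]
        anc = tables.material[u]
        frac = coal.span / anc.span if anc.span > 0 else 0.0
        out[u] = CoalescenceSpan(coal, anc, frac)
    return out


def resolve(
    g: GARG,
    samples: Optional[Iterable[int]] = None,
    opts: Optional[SimplifyOptions] = None,
) -> Tuple[GARG, SimplifyReport]:
    """Simplify ``g`` with respect to ``samples`` at the requested level."""
    opts = opts or SimplifyOptions()
    level = opts.canonical_level()
    sample_set = frozenset(g.samples if samples is None else samples)
    if not sample_set:
        raise ValueError("sample set is empty")
    unknown = sample_set - g.nodes.keys()
    if unknown:
        raise KeyError(f"unknown sample ids: {sorted(unknown)}")
    retain = frozenset(opts.retain_nodes)

    tables = propagate(g, sample_set)
    spans = _spans_from_tables(g, tables)

    # Level 1: restrict annotations to transmissible ancestral material.
    edges: Dict[Tuple[int, int], IntervalSet] = {}
    for e in g.edges:
        resolved = e.intervals & tables.transmissible[e.child]
        if resolved:
            edges[(e.child, e.parent)] = edges.get(
                (e.child, e.parent), IntervalSet()
            ) | resolved

    if level == "prune-sc":
        edges = _collapse_bundles(edges, sample_set | retain)
    elif level == "prune-unary":
        edges = _prune_unary(g, edges, tables, sample_set | retain)
    elif level == "full":
        edges = _fully_simplify(g, sample_set, retain)

    surviving = _surviving_nodes(edges, sample_set, retain, g)
    edges = {
        key: I for key, I in edges.items()
        if key[0] in surviving and key[1] in surviving
    }

    node_map = _make_node_map(g, surviving, sample_set, opts)
    out_nodes = [
        Node(
            id=node_map[u],
            is_sample=u in sample_set,
            time=g.nodes[u].time,
            metadata=g.nodes[u].metadata,
        )
        for u in sorted(surviving, key=lambda u: node_map[u])
    ]
    out_edges = [
        Edge(node_map[c], node_map[p], I) for (c, p), I in edges.items()
    ]
    out = GARG(g.L, out_nodes, out_edges, samples={node_map[s] for s in sample_set})

    input_pairs = {(e.child, e.parent) for e in g.edges}
    removed_edges = sorted(input_pairs - set(edges))
    report = SimplifyReport(
        node_map={u: node_map.get(u) for u in g.nodes},
        removed_edges=removed_edges,
        coalescence_span=spans,
    )
    return out, report


def _surviving_nodes(
    edges: Dict[Tuple[int, int], IntervalSet],
    samples: FrozenSet[int],
    retain: FrozenSet[int],
    g: GARG,
) -> Set[int]:
    incident: Set[int] = set()
    for c, p in edges:
        incident.add(c)
        incident.add(p)
    return (incident | samples | (retain & g.nodes.keys())) & g.nodes.keys()


def _collapse_bundles(
    edges: Dict[Tuple[int, int], IntervalSet], keep: FrozenSet[int]
) -> Dict[Tuple[int, int], IntervalSet]:
    """Collapse parallel pass-through chains that reconverge (diamonds).

    A pass-through node has exactly one child edge and one parent edge and is
    neither a sample nor retained.  Maximal chains of pass-through nodes run
    from a bottom node to a top node; where two or more parallel connections
    (chains, or a chain plus a direct edge) share the same (bottom, top)
    pair, the whole bundle is replaced by one direct edge carrying the union
    of the arriving intervals.  Coalescent-only local trees are unchanged.
    """
    edges = dict(edges)
    while True:
        child_edges: Dict[int, List[Tuple[int, int]]] = {}
        parent_edges: Dict[int, List[Tuple[int, int]]] = {}
        for key in edges:
            c, p = key
            child_edges.setdefault(p, []).append(key)
            parent_edges.setdefault(c, []).append(key)

        def passthrough(u: int) -> bool:
            return (
                u not in keep
                and len(child_edges.get(u, ())) == 1
                and len(parent_edges.get(u, ())) == 1
            )

        nodes = set(child_edges) | set(parent_edges)
        chains: Dict[Tuple[int, int], List[List[int]]] = {}
        visited: Set[int] = set()
        for u in nodes:
            if u in visited or not passthrough(u):
                continue
            chain = [u]
            bottom = child_edges[u][0][0]
            while passthrough(bottom):
                chain.insert(0, bottom)
                bottom = child_edges[bottom][0][0]
            top = parent_edges[u][0][1]
            while passthrough(top):
                chain.append(top)
                top = parent_edges[top][0][1]
            visited.update(chain)
            chains.setdefault((bottom, top), []).append(chain)

        changed = False
        for (bottom, top), group in chains.items():
            n_paths = len(group) + (1 if (bottom, top) in edges else 0)
            if n_paths < 2:
                continue
            changed = True
            arriving = edges.get((bottom, top), IntervalSet())
            for chain in group:
                arriving = arriving | edges[(chain[-1], top)]
                for v in chain:
                    del edges[child_edges[v][0]]
                del edges[(chain[-1], top)]
            edges[(bottom, top)] = arriving
        if not changed:
            return edges


def _prune_unary(
    g: GARG,
    edges: Dict[Tuple[int, int], IntervalSet],
    tables: AncestryTables,
    keep: FrozenSet[int],
) -> Dict[Tuple[int, int], IntervalSet]:
    """Remove nodes that never coalesce, reconnecting children per locus."""
    dead = {
        u
        for u in g.nodes
        if u not in keep and not tables.coalescent[u]
    }
    edges = dict(edges)
    for u in g.topological_order():
        if u not in dead:
            continue
        ins = [(key, I) for key, I in edges.items() if key[1] == u]
        outs = [(key, I) for key, I in edges.items() if key[0] == u]
        for key, _ in ins + outs:
            del edges[key]
        for (c, _), I in ins:
            for (_, p), J in outs:
                piece = I & J
                if piece:
                    edges[(c, p)] = edges.get((c, p), IntervalSet()) | piece
    return edges


def _fully_simplify(
    g: GARG, samples: FrozenSet[int], retain: FrozenSet[int]
) -> Dict[Tuple[int, int], IntervalSet]:
    """Rebuild edges from the coalescent-only local forests."""
    lts = trees(g, samples, mode="coalescent-only", retain=retain)
    edges: Dict[Tuple[int, int], List[Tuple[float, float]]] = {}
    for forest in lts:
        left, right = forest.interval
        for c, p in forest.parent_of.items():
            if p is not None:
                edges.setdefault((c, p), []).append((left, right))
    # IntervalSet canonicalization squashes abutting per-pair intervals.
    return {key: IntervalSet(pieces) for key, pieces in edges.items()}


def _make_node_map(
    g: GARG,
    surviving: Set[int],
    samples: FrozenSet[int],
    opts: SimplifyOptions,
) -> Dict[int, int]:
    if not opts.densify_ids:
        return {u: u for u in surviving}
    if all(g.nodes[u].time is not None for u in surviving):
        order = sorted(surviving, key=lambda u: (g.nodes[u].time, u))
    else:
        samples_first = sorted(u for u in surviving if u in samples)
        rest = [
            u for u in g.topological_order() if u in surviving and u not in samples
        ]
        order = samples_first + rest
    return {u: i for i, u in enumerate(order)}
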