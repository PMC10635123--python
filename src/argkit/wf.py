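"""Prospective recording of a gARG under a diploid Wright-Fisher model.

The simulator runs forwards in time, embedding the ARG in an explicit
pedigree: each generation holds ``n_diploids`` individuals of two genomes
each; every new genome picks a parent individual uniformly at random
(independent draws, selfing allowed), and is the recombined product of that
parent's two genomes with a Poisson number of crossovers at uniform
positions.  Genetic inheritance is recorded exhaustively,
generation-by-generation; the resulting redundancy can be removed
periodically with the simplify algorithm, which is what makes prospective
ARG recording practical.

Node times are generations pastwards: the final generation (the samples)
has time 0, founders have time ``n_generations``.

Randomness comes from a single numpy Generator with a fixed draw order per
generation: (1) parent individual indices for all 2N genomes, (2) phase
coins, (3) crossover counts, (4) per genome, crossover positions.  The
simplify schedule consumes no randomness, so runs with different
``simplify_interval`` settings realise the same genealogy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .garg import GARG, Edge, Node
from .intervals import IntervalSet
from .simplify import SimplifyOptions, resolve
from .trees import trees

__all__ = [
    "SimParams",
    "Individual",
    "Pedigree",
    "simulate",
    "periodic_simplify_equivalence",
    "locus_tmrca",
]


@dataclass(frozen=True)
class SimParams:
    n_diploids: int = 10
    n_generations: int = 20
    L: float = 100.0
    recomb_rate: float = 1.0  # expected crossovers per meiosis (Poisson)
    seed: int = 42
    simplify_interval: int = 0  # generations between simplifications; 0 = never

    def validate(self) -> None:
        if self.n_diploids <= 0 or self.n_generations <= 0:
            raise ValueError("n_diploids and n_generations must be positive")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be nonnegative")
        if self.simplify_interval < 0:
            raise ValueError("simplify_interval must be nonnegative")


@dataclass(frozen=True)
class Individual:
    genomes: Tuple[int, int]
    parents: Tuple[Optional[int], Optional[int]]  # indices in previous generation


@dataclass
class Pedigree:
    """Per generation (forward order, founders first), the diploids."""

    generations: List[List[Individual]] = field(default_factory=list)


def simulate(params: SimParams) -> Tuple[GARG, Pedigree]:
    """Run the simulator, returning the recorded gARG and its pedigree."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    N, G, L = params.n_diploids, params.n_generations, params.L

    nodes: Dict[int, Node] = {}
    edges: List[Edge] = []
    next_id = 0
    pedigree = Pedigree()

    def new_generation(gen: int, parent_inds: Optional[np.ndarray]) -> List[Individual]:
        nonlocal next_id
        individuals = []
        time = float(G - gen)
        for i in range(N):
            g0, g1 = next_id, next_id + 1
            next_id += 2
            for nid in (g0, g1):
                nodes[nid] = Node(id=nid, time=time)
            p0 = int(parent_inds[2 * i]) if parent_inds is not None else None
            p1 = int(parent_inds[2 * i + 1]) if parent_inds is not None else None
            individuals.append(Individual((g0, g1), (p0, p1)))
        return individuals

    pedigree.generations.append(new_generation(0, None))

    for gen in range(1, G + 1):
        parent_inds = rng.integers(0, N, size=2 * N)
        phases = rng.integers(0, 2, size=2 * N)
        n_cross = rng.poisson(params.recomb_rate, size=2 * N)
        prev = pedigree.generations[-1]
        individuals = new_generation(gen, parent_inds)
        for j in range(2 * N):
            child = individuals[j // 2].genomes[j % 2]
            parent = prev[parent_inds[j]]
            cuts = np.sort(rng.uniform(0, L, size=int(n_cross[j])))
            bounds = [0.0] + [float(c) for c in cuts] + [L]
            pieces: Dict[int, List[Tuple[float, float]]] = {}
            for seg in range(len(bounds) - 1):
                lo, hi = bounds[seg], bounds[seg + 1]
                if lo == hi:
                    continue
                donor = parent.genomes[(int(phases[j]) + seg) % 2]
                pieces.setdefault(donor, []).append((lo, hi))
            for donor, ivals in pieces.items():
                edges.append(Edge(child, donor, IntervalSet(ivals)))
        pedigree.generations.append(individuals)

        interval = params.simplify_interval
        if interval and gen % interval == 0 and gen < G:
            current = [g for ind in individuals for g in ind.genomes]
            pruned, _ = resolve(
                GARG(L, nodes.values(), edges, samples=current),
                current,
                SimplifyOptions(level="resolve"),
            )
            nodes = {
                u: Node(id=u, time=n.time, metadata=n.metadata)
                for u, n in pruned.nodes.items()
            }
            edges = list(pruned.edges)

    sample_ids = frozenset(
        g for ind in pedigree.generations[-1] for g in ind.genomes
    )
    final_nodes = [
        Node(id=u, is_sample=u in sample_ids, time=n.time, metadata=n.metadata)
        for u, n in nodes.items()
    ]
    return GARG(L, final_nodes, edges, samples=sample_ids), pedigree


def periodic_simplify_equivalence(params: SimParams, interval: int = 1) -> str:
    """Check that periodic simplification does not change the final ARG.

    Runs the same seed with simplification never and every ``interval``
    generations, fully simplifies both results with respect to the final
    samples, and compares their local tree sequences.  Returns ``"PASS"``
    or ``"FAIL"``.
    """
    runs = []
    for k in (0, interval):
        p = SimParams(
            n_diploids=params.n_diploids,
            n_generations=params.n_generations,
            L=params.L,
            recomb_rate=params.recomb_rate,
            seed=params.seed,
            simplify_interval=k,
        )
        g, _ = simulate(p)
        full, _ = resolve(g, opts=SimplifyOptions(level="full"))
        runs.append(trees(full))
    a, b = runs
    if len(a) != len(b):
        return "FAIL"
    for fa, fb in zip(a, b):
        if fa.interval != fb.interval or not fa.same_topology(fb):
            return "FAIL"
    return "PASS"


def locus_tmrca(g: GARG, u: int, v: int, x: float) -> Optional[float]:
    """Time of the most recent common ancestor of ``u`` and ``v`` at ``x``.

    Walks the unique parent-at-locus pointers pastwards from both genomes;
    returns ``None`` if the lineages never meet within the recorded graph.
    """
    def chain(start: int) -> List[int]:
        path = [start]
        while True:
            node = path[-1]
            nxt = None
            for e in g.edges_for_child(node):
                if x in e.intervals:
                    nxt = e.parent
                    break
            if nxt is None:
                return path
            path.append(nxt)

    seen = set(chain(u))
    for node in chain(v):
        if node in seen:
            return g.nodes[node].time
    return None
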