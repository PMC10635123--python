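"""Event ARGs: tracing, conversion, and cross-oracle equivalence."""

import numpy as np
import pytest

import argkit as ak
from argkit.earg import (
    EARG,
    EargEdge,
    Event,
    convert_and_resolve,
    earg_to_garg,
    earg_tree_at,
    random_earg,
)
from argkit.garg import GARG, Edge, Node
from argkit.intervals import IntervalSet
from argkit.simplify import SimplifyOptions, resolve
from argkit.trees import tree_at, trees


def elabels(e):
    return {u: ev.metadata for u, ev in e.events.items()}


class TestTracing:
    @pytest.mark.parametrize("x,want", [(2.0, "e"), (4.9, "e"), (5.0, "f"), (8.0, "f")])
    def test_recombination_routing(self, fig2, x, want):
        # d takes its left parent strictly left of the breakpoint, else right.
        forest = earg_tree_at(fig2, x)
        lab = elabels(fig2)
        assert lab[forest.parent_of[fig2.find("d")]] == want

    def test_no_recombination_means_one_tree_everywhere(self):
        rng = np.random.default_rng(0)
        e = random_earg(rng, n_samples=4, max_recombs=0)
        ref = earg_tree_at(e, 0.5)
        for x in np.linspace(0, e.L, 7, endpoint=False):
            assert earg_tree_at(e, float(x)).parent_of == ref.parent_of

    def test_position_out_of_range(self, fig2):
        with pytest.raises(ValueError):
            earg_tree_at(fig2, fig2.L)


class TestConversion:
    def test_breakpoint_becomes_interval_pair(self, fig3):
        g = earg_to_garg(fig3)
        gid = fig3.find("g")
        out = {e.parent: e.intervals for e in g.edges_for_child(gid)}
        assert out[fig3.find("l")] == IntervalSet.single(0, 5)
        assert out[fig3.find("j")] == IntervalSet.single(5, 10)

    def test_common_ancestor_edges_cover_genome(self):
        events = [
            Event(0, "sample", time=0.0),
            Event(1, "sample", time=0.0),
            Event(2, "common-ancestor", time=1.0),
        ]
        edges = [EargEdge(0, 2, "only"), EargEdge(1, 2, "only")]
        g = earg_to_garg(EARG(10, events, edges))
        assert all(e.intervals == IntervalSet.single(0, 10) for e in g.edges)

    def test_conversion_is_injective_on_breakpoints(self, fig2):
        a = earg_to_garg(ak.fig_earg_small(x=3.0))
        b = earg_to_garg(ak.fig_earg_small(x=4.0))
        assert a != b

    def test_malformed_earg_rejected(self):
        # recombination with two left parents
        events = [
            Event(0, "sample", time=0.0),
            Event(1, "recombination", breakpoint=5.0, time=1.0),
            Event(2, "common-ancestor", time=2.0),
            Event(3, "common-ancestor", time=3.0),
        ]
        edges = [
            EargEdge(0, 1, "only"),
            EargEdge(1, 2, "left"),
            EargEdge(1, 3, "left"),
        ]
        with pytest.raises(ValueError, match="left and .*right"):
            earg_to_garg(EARG(10, events, edges))

    def test_plain_binary_tree_roundtrips(self):
        rng = np.random.default_rng(1)
        e = random_earg(rng, n_samples=5, max_recombs=0)
        out, _ = convert_and_resolve(e)
        # Same topology back: every sample path matches the event tree.
        forest = trees(out).forests[0]
        ref = earg_tree_at(e, 1.0)
        assert forest.parent_of == ref.parent_of


class TestCrossOracle:
    def breakmids(self, e):
        bps = sorted(
            {0.0, e.L}
            | {ev.breakpoint for ev in e.events.values() if ev.breakpoint is not None}
        )
        return [(a + b) / 2 for a, b in zip(bps, bps[1:])]

    def test_trace_equals_converted_tree_at(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            e = random_earg(
                rng,
                n_samples=int(rng.integers(2, 6)),
                max_recombs=int(rng.integers(0, 7)),
            )
            g = earg_to_garg(e)
            for x in self.breakmids(e):
                assert earg_tree_at(e, x).parent_of == tree_at(g, x).parent_of

    def test_trace_equals_resolved_local_trees(self):
        rng = np.random.default_rng(43)
        for _ in range(30):
            e = random_earg(
                rng,
                n_samples=int(rng.integers(2, 5)),
                max_recombs=int(rng.integers(0, 6)),
            )
            out, _ = convert_and_resolve(e)
            for f in trees(out):
                x = sum(f.interval) / 2
                assert earg_tree_at(e, x).parent_of == f.parent_of


class TestGeneConversion:
    def test_two_recombinations_equal_multiinterval_edge(self):
        """A conversion tract via two chained recombination events.

        The pair of recombination nodes joined by a zero-length edge resolves
        to the same gARG as a single edge carrying a two-interval set.
        """
        x1, x2, L = 3.0, 6.0, 10.0
        # Direct construction: s1 takes [0,x1)+[x2,L) from A and [x1,x2) from B.
        direct = GARG(
            L,
            [
                Node(0, True, 0.0, "s1"),
                Node(1, True, 0.0, "s2"),
                Node(4, False, 3.0, "B"),
                Node(5, False, 4.0, "A"),
            ],
            [
                Edge(0, 5, IntervalSet([(0, x1), (x2, L)])),
                Edge(0, 4, IntervalSet.single(x1, x2)),
                Edge(1, 5, IntervalSet.single(0, L)),
                Edge(4, 5, IntervalSet.single(x1, x2)),
            ],
        )
        events = [
            Event(0, "sample", time=0.0, metadata="s1"),
            Event(1, "sample", time=0.0, metadata="s2"),
            Event(2, "recombination", breakpoint=x1, time=1.0),
            # effectively zero-length edge joining the two recombinations
            Event(3, "recombination", breakpoint=x2, time=1.001),
            Event(4, "common-ancestor", time=3.0, metadata="B"),
            Event(5, "common-ancestor", time=4.0, metadata="A"),
        ]
        edges = [
            EargEdge(0, 2, "only"),
            EargEdge(2, 5, "left"),
            EargEdge(2, 3, "right"),
            EargEdge(3, 4, "left"),
            EargEdge(3, 5, "right"),
            EargEdge(1, 5, "only"),
            EargEdge(4, 5, "only"),
        ]
        g = earg_to_garg(EARG(L, events, edges))
        # Prune the recombination-event nodes; keep B (the tract donor is
        # unary everywhere too, but is part of the target topology).
        out, _ = resolve(
            g, opts=SimplifyOptions(level="prune-unary", retain_nodes=frozenset({4}))
        )
        want, _ = resolve(direct, opts=SimplifyOptions(level="resolve"))
        assert {(e.child, e.parent): e.intervals for e in out.edges} == {
            (e.child, e.parent): e.intervals for e in want.edges
        }
        assert set(out.nodes) == set(want.nodes)


class TestRandomEargGenerator:
    def test_generated_eargs_are_valid(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            e = random_earg(
                rng,
                n_samples=int(rng.integers(2, 7)),
                max_recombs=int(rng.integers(0, 8)),
            )
            assert e.validate() == []
            assert earg_to_garg(e).validate() == []
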