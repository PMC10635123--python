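"""Sample resolution and the four simplification levels."""

import numpy as np
import pytest

import argkit as ak
from argkit.intervals import IntervalSet
from argkit.simplify import LEVELS, SimplifyOptions, coalescence_spans, resolve
from argkit.trees import pairwise_mrca, tree_at, trees

from conftest import labels


def level_opts(level, **kw):
    return SimplifyOptions(level=level, **kw)


def surviving_labels(g, out):
    lab = labels(g)
    return sorted(lab[u] for u in out.nodes)


class TestWorkedExample:
    """Conversion of the three-sample worked eARG (see fixtures)."""

    def test_grand_mrca_and_dead_breakpoint_edge_removed(self, fig3):
        out, report = ak.convert_and_resolve(fig3)
        lab = {u: ev.metadata for u, ev in fig3.events.items()}
        removed = sorted(lab[u] for u, new in report.node_map.items() if new is None)
        assert "q" in removed  # grand MRCA: fully coalesced below, in k and p
        assert "j" in removed  # only material arriving was via the dead edge
        removed_edges = {(lab[c], lab[p]) for c, p in report.removed_edges}
        assert ("g", "j") in removed_edges
        # Every other recombination edge survives.
        for ch in "defhi":
            assert not any(c == ch for c, _ in removed_edges)

    def test_full_coalescence_hosts_are_local_roots(self, fig3):
        out, _ = ak.convert_and_resolve(fig3)
        lab = {u: ev.metadata for u, ev in fig3.events.items()}
        roots = {
            tuple(f.interval): sorted(lab[r] for r in f.roots)
            for f in trees(out)
        }
        assert all(v == ["k"] for k, v in roots.items() if k[1] <= 7)
        assert roots[(7.0, 10.0)] == ["p"]

    def test_retained_recombination_nodes_survive(self, fig3):
        out, _ = ak.convert_and_resolve(fig3)
        lab = {u: ev.metadata for u, ev in fig3.events.items()}
        kept = {lab[u] for u in out.nodes}
        assert {"d", "e", "f", "g", "h", "i"} <= kept


class TestLevels:
    def test_diamond_removed_at_prune_sc(self, fig5):
        out, _ = resolve(fig5, opts=level_opts("prune-sc"))
        kept = surviving_labels(fig5, out)
        assert "l" not in kept and "m" not in kept
        assert "j" in kept and "n" in kept and "r" in kept
        lab = labels(fig5)
        jn = [
            e
            for e in out.edges
            if lab[e.child] == "j" and lab[e.parent] == "n"
        ]
        assert jn and jn[0].intervals == IntervalSet.single(4, 10)

    def test_unary_everywhere_removed_at_prune_unary(self, fig5):
        out, _ = resolve(fig5, opts=level_opts("prune-unary"))
        kept = surviving_labels(fig5, out)
        assert "n" not in kept and "r" not in kept
        assert {"a", "b", "c", "d", "e", "f", "k", "o", "p"} <= set(kept)

    def test_full_level_every_node_interval_branches(self, fig5, random_gargs):
        for g in [fig5] + random_gargs[:6]:
            out, _ = resolve(g, opts=level_opts("full"))
            for f in trees(out):
                for u in f.parent_of:
                    if u not in out.samples:
                        assert f.num_children(u) >= 2

    def test_monotone_node_counts(self, fig5, random_gargs):
        # Node counts never grow with level strictness.  Edge counts usually
        # shrink too but may not: bypassing a locally-unary node with two
        # parents splits its child's edge across them.
        for g in [fig5] + random_gargs[:6]:
            counts = []
            for level in LEVELS:
                out, _ = resolve(g, opts=level_opts(level))
                counts.append(len(out.nodes))
            for n1, n2 in zip(counts, counts[1:]):
                assert n2 <= n1

    def test_level_aliases_accepted(self, fig5):
        a, _ = resolve(fig5, opts=level_opts("prune-singly-connected"))
        b, _ = resolve(fig5, opts=level_opts("prune-sc"))
        assert a == b


class TestResolveContract:
    def test_idempotent_at_every_level(self, fig1, fig5, random_gargs):
        for g in [fig1, fig5] + random_gargs[:6]:
            for level in LEVELS:
                once, _ = resolve(g, opts=level_opts(level))
                twice, _ = resolve(once, opts=level_opts(level))
                assert twice == once

    def test_no_nonancestral_material_remains(self, fig1, fig5, random_gargs):
        for g in [fig1, fig5] + random_gargs[:6]:
            for level in LEVELS:
                out, _ = resolve(g, opts=level_opts(level))
                tables = ak.propagate(out, out.samples)
                for e in out.edges:
                    assert e.intervals.issubset(tables.material[e.child])

    def test_samples_always_survive(self, random_gargs):
        for g in random_gargs[:6]:
            for level in LEVELS:
                out, _ = resolve(g, opts=level_opts(level))
                assert out.samples == g.samples
                for s in out.samples:
                    assert s in out.nodes
                    assert ak.ancestral_material(out, s) == IntervalSet.single(0, g.L)

    def test_empty_and_unknown_sample_sets_rejected(self, fig1):
        with pytest.raises(ValueError):
            resolve(fig1, samples=[])
        with pytest.raises(KeyError):
            resolve(fig1, samples=[999])

    def test_local_trees_preserved_at_every_level(self, fig1, fig5, random_gargs):
        """Coalescent-only forests are invariant under simplification."""
        for g in [fig1, fig5] + random_gargs[:8]:
            ref = trees(g, mode="coalescent-only")
            for level in LEVELS:
                out, _ = resolve(g, opts=level_opts(level))
                got = trees(out, mode="coalescent-only")
                assert len(got) == len(ref)
                for a, b in zip(got, ref):
                    assert a.interval == b.interval
                    assert a.same_topology(b)

    def test_mrca_identities_stable_through_light_levels(self, random_gargs):
        rng = np.random.default_rng(11)
        for g in random_gargs[:6]:
            u, v = (int(x) for x in rng.choice(sorted(g.samples), 2, replace=False))
            ref = pairwise_mrca(trees(g, mode="coalescent-only"), u, v)
            for level in ("resolve", "prune-sc"):
                out, rep = resolve(g, opts=level_opts(level))
                got = pairwise_mrca(trees(out, mode="coalescent-only"), u, v)
                assert got == ref

    def test_densify_renumbers_in_time_order(self, fig5):
        out, report = resolve(fig5, opts=level_opts("full", densify_ids=True))
        assert sorted(out.nodes) == list(range(len(out.nodes)))
        times = [out.nodes[u].time for u in sorted(out.nodes)]
        assert times == sorted(times)
        # node_map covers every input node.
        assert set(report.node_map) == set(fig5.nodes)


class TestCoalescenceSpans:
    def test_partially_coalescent_parent(self, fig1):
        spans = coalescence_spans(fig1)
        f = spans[fig1.find("f")]
        assert f.coalescent == IntervalSet.single(2, 7)
        assert f.ancestral == IntervalSet.single(0, 10)
        assert f.fraction == pytest.approx(0.5)

    def test_sample_leaf_has_zero_span(self, fig1):
        spans = coalescence_spans(fig1)
        a = spans[fig1.find("a")]
        assert a.coalescent == IntervalSet()
        assert a.fraction == 0.0
        assert a.ancestral == IntervalSet.single(0, 10)

    def test_coalescent_loci_match_local_tree_child_counts(self, random_gargs):
        for g in random_gargs[:8]:
            spans = coalescence_spans(g)
            for forest in trees(g):
                x = sum(forest.interval) / 2
                for u in forest.parent_of:
                    expect = forest.num_children(u) >= 2
                    assert (x in spans[u].coalescent) == expect

    def test_fraction_bounds_and_subset(self, random_gargs):
        for g in random_gargs[:8]:
            for span in coalescence_spans(g).values():
                assert span.coalescent.issubset(span.ancestral)
                assert 0.0 <= span.fraction <= 1.0
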