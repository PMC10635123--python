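"""Worked-example ARGs used throughout the documentation and tests.

Each fixture is built in code, edge by edge, so the transcription is fully
auditable.  Genome labels are lowercase letters stored in node metadata
(integer ids are assigned in letter order); genome length is 10 throughout.

``fig_pedigree``
    A gARG for four sampled genomes (a-d) embedded in an inbred pedigree of
    eight diploid individuals (sixteen genomes a-p).  Genome a is the
    recombinant product of the paternal genomes e and f crossing over at
    position 2 (a inherits [0,2) from e and [2,10) from f); genome c is the
    complementary recombinant with breakpoint 7 ([0,7) from f, [7,10) from
    e); b and d are inherited without recombination from g and h.  The two
    breakpoints delimit three local trees; in [2,7) genomes a and c find a
    common ancestor in f, so only three parental-generation genomes (f, g,
    h) carry ancestral material there, while e is blank.  All samples reach
    their most recent common ancestor in node n.

``fig_earg_small``
    A minimal classical eARG: three samples a, b, c, one recombination
    event d with breakpoint x, and three common-ancestor events e, f, g.
    Genome d inherits material left of x from e and right of x from f.

``fig_earg_wiuf_hein``
    A 17-node eARG (a..q) over three samples in the style of the classic
    three-sequence recombination genealogy.  Recombination node g carries
    breakpoint 5 but the lineage reaching it holds ancestral material only
    on [0,4), so after conversion and sample resolution the edge from g to
    the common-ancestor node j carries no ancestral material and is
    dropped.  All genomic segments fully coalesce in k (over [0,7)) and p
    (over [7,10)) before the grand MRCA q is reached, so q (and j) vanish
    under simplification.

``fig_levels``
    An 18-node gARG (a..r) with four samples illustrating the levels of
    simplification: the reconverging diamond j-l/m-n (a recombination whose
    two paths rejoin without coalescing) disappears at level prune-sc; the
    everywhere-unary nodes n and r disappear at level prune-unary; level
    full leaves every node-interval pair with at least two children in its
    local tree.
"""

from __future__ import annotations

import string
from typing import Dict, Union

from .earg import EARG, EargEdge, Event
from .garg import GARG, Edge, Node
from .intervals import IntervalSet

__all__ = [
    "fig_pedigree",
    "fig_earg_small",
    "fig_earg_wiuf_hein",
    "fig_levels",
    "fixtures",
]

_LETTERS = string.ascii_lowercase


def _ids(letters: str) -> Dict[str, int]:
    return {ch: _LETTERS.index(ch) for ch in letters}


def _garg(L, letters, times, samples, edges) -> GARG:
    ids = _ids(letters)
    nodes = [
        Node(id=ids[ch], is_sample=ch in samples, time=times[ch], metadata=ch)
        for ch in letters
    ]
    out = [
        Edge(ids[c], ids[p], IntervalSet(ivals)) for c, p, ivals in edges
    ]
    return GARG(L, nodes, out)


def fig_pedigree() -> GARG:
    """The pedigree-embedded gARG over samples a-d (see module docstring)."""
    letters = _LETTERS[:16]  # a..p
    times = {ch: float(g) for g, group in enumerate(
        ("abcd", "efgh", "ijkl", "mnop")) for ch in group}
    edges = [
        # Current generation: a and c are the two recombinant products of
        # e x f; b and d are unrecombined copies of g and h.
        ("a", "e", [(0, 2)]),
        ("a", "f", [(2, 10)]),
        ("b", "g", [(0, 10)]),
        ("c", "f", [(0, 7)]),
        ("c", "e", [(7, 10)]),
        ("d", "h", [(0, 10)]),
        # Parental generation inherits without recombination.
        ("e", "i", [(0, 10)]),
        ("f", "k", [(0, 10)]),
        ("g", "i", [(0, 10)]),
        ("h", "k", [(0, 10)]),
        # Grandparents: i and k coalesce everything in n.
        ("i", "n", [(0, 10)]),
        ("k", "n", [(0, 10)]),
        # Genomes j and l exist in the pedigree but leave no descendants.
        ("j", "o", [(0, 10)]),
        ("l", "p", [(0, 10)]),
    ]
    return _garg(10.0, letters, times, "abcd", edges)


def fig_earg_small(x: float = 5.0, L: float = 10.0) -> EARG:
    """Three samples, one recombination (node d, breakpoint ``x``)."""
    if not 0 < x < L:
        raise ValueError(f"breakpoint {x} must lie inside (0, {L})")
    names = ["a", "b", "c", "d", "e", "f", "g"]
    kinds = {
        "a": "sample", "b": "sample", "c": "sample",
        "d": "recombination",
        "e": "common-ancestor", "f": "common-ancestor", "g": "common-ancestor",
    }
    times = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 2, "f": 3, "g": 4}
    ids = {ch: i for i, ch in enumerate(names)}
    events = [
        Event(
            ids[ch],
            kinds[ch],
            breakpoint=x if kinds[ch] == "recombination" else None,
            time=float(times[ch]),
            metadata=ch,
        )
        for ch in names
    ]
    edges = [
        EargEdge(ids["a"], ids["d"], "only"),
        EargEdge(ids["d"], ids["e"], "left"),
        EargEdge(ids["d"], ids["f"], "right"),
        EargEdge(ids["b"], ids["e"], "only"),
        EargEdge(ids["c"], ids["f"], "only"),
        EargEdge(ids["e"], ids["g"], "only"),
        EargEdge(ids["f"], ids["g"], "only"),
    ]
    return EARG(L, events, edges)


def fig_earg_wiuf_hein() -> EARG:
    """The 17-node worked eARG (see module docstring for its anatomy)."""
    L = 10.0
    ids = _ids(_LETTERS[:17])  # a..q
    # kind, breakpoint, time
    anatomy = {
        "a": ("sample", None, 0.0),
        "b": ("sample", None, 0.0),
        "c": ("sample", None, 0.0),
        "d": ("recombination", 7.0, 1.0),
        "e": ("recombination", 4.0, 1.5),
        "f": ("recombination", 7.0, 2.0),
        "g": ("recombination", 5.0, 3.0),
        "h": ("recombination", 7.0, 2.5),
        "i": ("recombination", 2.0, 3.5),
        "j": ("common-ancestor", None, 10.0),
        "k": ("common-ancestor", None, 7.0),
        "l": ("common-ancestor", None, 4.0),
        "m": ("common-ancestor", None, 5.0),
        "n": ("common-ancestor", None, 6.0),
        "o": ("common-ancestor", None, 8.0),
        "p": ("common-ancestor", None, 9.0),
        "q": ("common-ancestor", None, 11.0),
    }
    events = [
        Event(ids[ch], kind, breakpoint=bp, time=t, metadata=ch)
        for ch, (kind, bp, t) in anatomy.items()
    ]
    raw_edges = [
        ("a", "d", "only"),
        ("b", "e", "only"),
        ("c", "h", "only"),
        ("d", "i", "left"),   # a's [0,7) splits again at position 2
        ("d", "o", "right"),  # a's [7,10)
        ("e", "g", "left"),   # b's [0,4)
        ("e", "f", "right"),  # b's [4,10) splits again at position 7
        ("f", "n", "left"),
        ("f", "o", "right"),
        ("g", "l", "left"),   # ancestral: [0,5) covers all of [0,4)
        ("g", "j", "right"),  # [5,10): entirely non-ancestral — dropped
        ("h", "k", "left"),
        ("h", "p", "right"),
        ("i", "l", "left"),
        ("i", "m", "right"),
        ("l", "m", "only"),
        ("m", "n", "only"),
        ("n", "k", "only"),
        ("k", "j", "only"),   # [0,7) fully coalesced in k; nothing arrives
        ("o", "p", "only"),
        ("p", "q", "only"),   # [7,10) fully coalesced in p
        ("j", "q", "only"),
    ]
    edges = [EargEdge(ids[c], ids[p], side) for c, p, side in raw_edges]
    return EARG(L, events, edges)


def fig_levels() -> GARG:
    """The 18-node simplification-levels gARG (see module docstring)."""
    letters = _LETTERS[:18]  # a..r
    times = {
        "a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0,
        "e": 1.0, "g": 1.0, "r": 1.0,
        "f": 2.0, "h": 2.0,
        "i": 3.0, "j": 3.0,
        "k": 4.0, "l": 4.0, "m": 4.0,
        "n": 5.0, "o": 6.0, "p": 7.0, "q": 8.0,
    }
    edges = [
        ("a", "e", [(0, 10)]),
        ("b", "e", [(0, 10)]),
        ("c", "r", [(0, 10)]),   # r: unary everywhere
        ("r", "f", [(0, 10)]),
        ("d", "f", [(0, 4)]),
        ("d", "g", [(4, 10)]),
        ("e", "h", [(0, 10)]),
        ("f", "i", [(0, 10)]),
        ("g", "j", [(4, 10)]),
        ("h", "k", [(0, 10)]),
        ("i", "k", [(0, 4)]),
        ("i", "o", [(4, 10)]),
        ("j", "l", [(4, 8)]),    # diamond: j's material takes two paths
        ("j", "m", [(8, 10)]),
        ("l", "n", [(4, 8)]),
        ("m", "n", [(8, 10)]),   # ...which reconverge in n without coalescing
        ("n", "o", [(4, 10)]),
        ("k", "p", [(0, 10)]),
        ("o", "p", [(4, 10)]),
        ("p", "q", [(0, 10)]),
    ]
    return _garg(10.0, letters, times, "abcd", edges)


def fixtures() -> Dict[str, Union[GARG, EARG]]:
    """All worked-example objects keyed by figure role."""
    return {
        "fig1": fig_pedigree(),
        "fig2": fig_earg_small(),
        "fig3": fig_earg_wiuf_hein(),
        "fig5": fig_levels(),
    }
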