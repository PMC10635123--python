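"""Tabular text formats for gARGs and eARGs, plus Newick export.

The gARG format is a single TSV file holding both tables::

    #argkit	garg	1
    #L	10.0
    #N	id	is_sample	time	metadata
    #E	child	parent	left	right
    N	0	1	0.0	a
    ...
    E	0	4	0.0	2.0

One ``E`` row per interval; edge rows are sorted by (child, parent, left)
and positions are serialized with full round-trip precision, so writing the
same canonical gARG twice yields byte-identical files.  A blank time field
means the node is undated.  The eARG format is analogous with ``V`` event
rows (id, kind, breakpoint, time, metadata) and ``E`` rows
(child, parent, side).
"""

from __future__ import annotations

from typing import List, Union

from .earg import EARG, EargEdge, Event
from .garg import GARG, Edge, Node
from .intervals import IntervalSet
from .trees import LocalTreeSequence

__all__ = [
    "GargFormatError",
    "GargValidationError",
    "read_garg",
    "write_garg",
    "read_earg",
    "write_earg",
    "export_newick",
]

_GARG_MAGIC = "#argkit\tgarg\t1"
_EARG_MAGIC = "#argkit\tearg\t1"


class GargFormatError(ValueError):
    """A parse error, carrying the offending line number."""

    def __init__(self, line: int, reason: str):
        self.line = line
        self.reason = reason
        super().__init__(f"line {line}: {reason}")


class GargValidationError(ValueError):
    """The file parsed but the object violates structural invariants."""

    def __init__(self, violations: List[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


def _fmt(x: Union[float, None]) -> str:
    return "" if x is None else repr(float(x))


def _parse_float(token: str, line: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise GargFormatError(line, f"cannot parse {what} {token!r}") from None


def _parse_int(token: str, line: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise GargFormatError(line, f"cannot parse {what} {token!r}") from None


def _read_lines(path) -> List[str]:
    with open(path, "rt", encoding="utf-8") as f:
        return f.read().splitlines()


def _header_L(lines: List[str], magic: str) -> float:
    if not lines or lines[0] != magic:
        raise GargFormatError(1, f"missing header {magic!r}")
    for no, line in enumerate(lines[1:], start=2):
        if line.startswith("#L\t"):
            return _parse_float(line.split("\t", 1)[1], no, "genome length")
        if not line.startswith("#"):
            break
    raise GargFormatError(1, "missing #L header line")


# ---------------------------------------------------------------------------
# gARG
# ---------------------------------------------------------------------------


def write_garg(g: GARG, path) -> None:
    lines = [_GARG_MAGIC, f"#L\t{_fmt(g.L)}"]
    lines.append("#N\tid\tis_sample\ttime\tmetadata")
    lines.append("#E\tchild\tparent\tleft\tright")
    for u in sorted(g.nodes):
        n = g.nodes[u]
        flag = "1" if u in g.samples else "0"
        lines.append(f"N\t{u}\t{flag}\t{_fmt(n.time)}\t{n.metadata}")
    rows = []
    for e in g.edges:
        for l, r in e.intervals:
            rows.append((e.child, e.parent, l, r))
    for c, p, l, r in sorted(rows):
        lines.append(f"E\t{c}\t{p}\t{_fmt(l)}\t{_fmt(r)}")
    with open(path, "wt", encoding="utf-8") as f:
        f.write("\n".join(lines) + "\n")


def read_garg(path) -> GARG:
    lines = _read_lines(path)
    L = _header_L(lines, _GARG_MAGIC)
    nodes: List[Node] = []
    edges: List[Edge] = []
    samples = set()
    for no, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "N":
            if len(fields) != 5:
                raise GargFormatError(no, f"node row needs 5 fields, got {len(fields)}")
            uid = _parse_int(fields[1], no, "node id")
            if fields[2] not in ("0", "1"):
                raise GargFormatError(no, f"is_sample must be 0/1, got {fields[2]!r}")
            is_sample = fields[2] == "1"
            time = None if fields[3] == "" else _parse_float(fields[3], no, "time")
            nodes.append(Node(uid, is_sample, time, fields[4]))
            if is_sample:
                samples.add(uid)
        elif tag == "E":
            if len(fields) != 5:
                raise GargFormatError(no, f"edge row needs 5 fields, got {len(fields)}")
            c = _parse_int(fields[1], no, "child id")
            p = _parse_int(fields[2], no, "parent id")
            l = _parse_float(fields[3], no, "left")
            r = _parse_float(fields[4], no, "right")
            if not l < r:
                raise GargFormatError(no, f"edge interval has left >= right: {l} {r}")
            edges.append(Edge(c, p, IntervalSet.single(l, r)))
        else:
            raise GargFormatError(no, f"unknown row tag {tag!r}")
    try:
        g = GARG(L, nodes, edges, samples=samples)
    except ValueError as exc:
        raise GargValidationError([str(exc)]) from None
    violations = g.validate()
    if violations:
        raise GargValidationError(violations)
    return g


# ---------------------------------------------------------------------------
# eARG
# ---------------------------------------------------------------------------

_KIND_CODES = {"sample": "S", "common-ancestor": "C", "recombination": "R"}
_CODE_KINDS = {v: k for k, v in _KIND_CODES.items()}


def write_earg(e: EARG, path) -> None:
    lines = [_EARG_MAGIC, f"#L\t{_fmt(e.L)}"]
    lines.append("#V\tid\tkind\tbreakpoint\ttime\tmetadata")
    lines.append("#E\tchild\tparent\tside")
    for u in sorted(e.events):
        ev = e.events[u]
        lines.append(
            f"V\t{u}\t{_KIND_CODES[ev.kind]}\t{_fmt(ev.breakpoint)}"
            f"\t{_fmt(ev.time)}\t{ev.metadata}"
        )
    for edge in sorted(e.edges, key=lambda x: (x.child, x.parent, x.side)):
        lines.append(f"E\t{edge.child}\t{edge.parent}\t{edge.side}")
    with open(path, "wt", encoding="utf-8") as f:
        f.write("\n".join(lines) + "\n")


def read_earg(path) -> EARG:
    lines = _read_lines(path)
    L = _header_L(lines, _EARG_MAGIC)
    events: List[Event] = []
    edges: List[EargEdge] = []
    for no, line in enumerate(lines, start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "V":
            if len(fields) != 6:
                raise GargFormatError(no, f"event row needs 6 fields, got {len(fields)}")
            uid = _parse_int(fields[1], no, "event id")
            if fields[2] not in _CODE_KINDS:
                raise GargFormatError(no, f"unknown event kind code {fields[2]!r}")
            kind = _CODE_KINDS[fields[2]]
            bp = None if fields[3] == "" else _parse_float(fields[3], no, "breakpoint")
            time = None if fields[4] == "" else _parse_float(fields[4], no, "time")
            events.append(Event(uid, kind, bp, time, fields[5]))
        elif tag == "E":
            if len(fields) != 4:
                raise GargFormatError(no, f"edge row needs 4 fields, got {len(fields)}")
            c = _parse_int(fields[1], no, "child id")
            p = _parse_int(fields[2], no, "parent id")
            if fields[3] not in ("left", "right", "only"):
                raise GargFormatError(no, f"unknown edge side {fields[3]!r}")
            edges.append(EargEdge(c, p, fields[3]))
        else:
            raise GargFormatError(no, f"unknown row tag {tag!r}")
    try:
        e = EARG(L, events, edges)
    except ValueError as exc:
        raise GargValidationError([str(exc)]) from None
    violations = e.validate()
    if violations:
        raise GargValidationError(violations)
    return e


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def export_newick(lts: LocalTreeSequence, path, times=None) -> None:
    """One line per local forest: ``left<TAB>right<TAB>newick``.

    Multi-root forests emit one semicolon-terminated Newick string per root,
    concatenated on the line.
    """
    with open(path, "wt", encoding="utf-8") as f:
        for forest in lts:
            l, r = forest.interval
            f.write(f"{_fmt(l)}\t{_fmt(r)}\t{forest.newick(times)}\n")
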