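"""Skill-prerequisite topology: the DAG of arithmetic skills.

Skills ("Addition 2,1 with bridging to 10", "Subtraction 3,3", ...) are
nodes; a directed edge A -> B states that mastering A is a necessary
condition for mastering B.  The student model and the pedagogical
controller both operate on this structure.  Graphs can be read and
written as JSON or as DAGitty-style ``dag { "A" -> "B" }`` text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import networkx as nx

OPERATIONS = ("addition", "subtraction", "multiplication")
NUMBER_RANGES = ("0-10", "0-100", "0-1000")
VARIANT_TAGS = ("support", "bridging_to_10", "mental", "none")


class GraphError(ValueError):
    """Raised for structurally invalid graphs or unknown skills."""


@dataclass(frozen=True)
class Skill:
    """One arithmetic skill node.

    ``difficulty_rank`` orders skills within an operation: it must
    strictly increase along every prerequisite path that stays inside
    one operation.  ``variant_tags`` qualify the task format (worked
    support, bridging past ten, mental arithmetic).
    """

    id: str
    name: str
    operation: str
    number_range: str
    difficulty_rank: int
    variant_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.operation not in OPERATIONS:
            raise GraphError(f"unknown operation {self.operation!r}")
        if self.number_range not in NUMBER_RANGES:
            raise GraphError(f"unknown number_range {self.number_range!r}")
        if self.difficulty_rank < 0:
            raise GraphError("difficulty_rank must be >= 0")
        bad = set(self.variant_tags) - set(VARIANT_TAGS)
        if bad:
            raise GraphError(f"unknown variant tags {sorted(bad)}")

    @property
    def digits(self) -> tuple[int, int]:
        """Operand digit counts parsed from the 'a,b' token of the name."""
        m = re.search(r"(\d)\s*,\s*(\d)", self.name)
        if not m:
            return (1, 1)
        return (int(m.group(1)), int(m.group(2)))


@dataclass
class SkillGraph:
    """A prerequisite DAG over :class:`Skill` nodes."""

    skills: list[Skill] = field(default_factory=list)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = set(map(tuple, self.edges))

    # -- lookups -----------------------------------------------------------
    def _index(self) -> dict[str, Skill]:
        return {s.id: s for s in self.skills}

    def skill(self, skill_id: str) -> Skill:
        idx = self._index()
        if skill_id not in idx:
            raise GraphError(f"unknown skill id {skill_id!r}")
        return idx[skill_id]

    def skill_by_name(self, name: str) -> Skill:
        hits = [s for s in self.skills if s.name == name]
        if len(hits) != 1:
            raise GraphError(f"{len(hits)} skills named {name!r}")
        return hits[0]

    def ids(self) -> list[str]:
        return [s.id for s in self.skills]

    def __contains__(self, skill_id: str) -> bool:
        return skill_id in self._index()

    def __len__(self) -> int:
        return len(self.skills)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.ids())
        g.add_edges_from(self.edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SkillGraph):
            return NotImplemented
        return (sorted(self.skills, key=lambda s: s.id)
                == sorted(other.skills, key=lambda s: s.id)
                and self.edges == other.edges)


@dataclass
class ValidationReport:
    """Violations found by :func:`validate`; empty iff the graph is valid."""

    violations: list[tuple[str, str]] = field(default_factory=list)

    def add(self, code: str, message: str) -> None:
        self.violations.append((code, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def validate(graph: SkillGraph) -> ValidationReport:
    """Check all graph invariants; violations are reported, never raised."""
    report = ValidationReport()
    seen: set[str] = set()
    for s in graph.skills:
        if s.id in seen:
            report.add("duplicate_id", f"skill id {s.id!r} appears more than once")
        seen.add(s.id)
    for pre, succ in sorted(graph.edges):
        for end in (pre, succ):
            if end not in seen:
                report.add("dangling_edge", f"edge ({pre!r}, {succ!r}) names unknown skill {end!r}")
    idx = {s.id: s for s in graph.skills}
    g = nx.DiGraph()
    g.add_nodes_from(seen)
    g.add_edges_from(e for e in graph.edges if e[0] in seen and e[1] in seen)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        report.add("cycle", "cycle through " + " -> ".join(a for a, _ in cyc))
    # same-operation edges must go strictly uphill in difficulty; this
    # edgewise check implies monotonicity along whole single-operation paths
    for pre, succ in sorted(graph.edges):
        a, b = idx.get(pre), idx.get(succ)
        if a and b and a.operation == b.operation and a.difficulty_rank >= b.difficulty_rank:
            report.add("non_monotone_difficulty",
                       f"{pre!r} (rank {a.difficulty_rank}) -> {succ!r} (rank {b.difficulty_rank})")
    return report


def topological_order(graph: SkillGraph) -> list[str]:
    """Skill ids with every precursor before its successors.

    Ties are broken by (difficulty_rank, id) so the order is deterministic.
    """
    idx = {s.id: s for s in graph.skills}
    g = graph.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        raise GraphError("graph has a cycle; no topological order exists")
    return list(nx.lexicographical_topological_sort(
        g, key=lambda n: (idx[n].difficulty_rank, n)))


def precursors(graph: SkillGraph, skill_id: str) -> set[str]:
    """Direct (one-hop) prerequisite skills."""
    graph.skill(skill_id)
    return {a for a, b in graph.edges if b == skill_id}


def successors(graph: SkillGraph, skill_id: str) -> set[str]:
    """Direct (one-hop) dependent skills."""
    graph.skill(skill_id)
    return {b for a, b in graph.edges if a == skill_id}


# ---------------------------------------------------------------------------
# default 38-skill roster
# ---------------------------------------------------------------------------

def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", name.lower()).strip("-")

# (digits_a, digits_b, tags, name suffix) per range block; ranks are global
# within an operation so prerequisite chains stay strictly uphill across
# range boundaries.
_BLOCKS: dict[str, list[tuple[int, int, frozenset[str], str]]] = {
    "0-10": [
        (1, 1, frozenset({"support"}), "{d} with support"),
        (1, 1, frozenset(), "{d}"),
        (1, 1, frozenset({"mental"}), "{d} mental"),
        (1, 1, frozenset({"bridging_to_10", "support"}), "{d} with bridging to 10 and support"),
        (1, 1, frozenset({"bridging_to_10"}), "{d} with bridging to 10"),
        (1, 1, frozenset({"bridging_to_10", "mental"}), "{d} with bridging to 10 mental"),
    ],
    "0-100": [
        (2, 1, frozenset({"support"}), "{d} with support"),
        (2, 1, frozenset(), "{d}"),
        (2, 1, frozenset({"bridging_to_10"}), "{d} with bridging to 10"),
        (2, 2, frozenset(), "{d}"),
        (2, 2, frozenset({"bridging_to_10"}), "{d} with bridging to 10"),
        (2, 2, frozenset({"mental"}), "{d} mental"),
    ],
    "0-1000": [
        (3, 2, frozenset({"support"}), "{d} with support"),
        (3, 2, frozenset(), "{d}"),
        (3, 2, frozenset({"bridging_to_10"}), "{d} with bridging to 10"),
        (3, 3, frozenset(), "{d}"),
        (3, 3, frozenset({"bridging_to_10"}), "{d} with bridging to 10"),
        (3, 3, frozenset({"mental"}), "{d} mental"),
    ],
}


def build_default_topology() -> SkillGraph:
    """The packaged 38-skill roster.

    Addition and subtraction each form an 18-skill chain spanning the
    number ranges 0-10, 0-100 and 0-1000 (six skills per range); the
    0-100 addition slice runs 2,1 with support -> 2,1 -> 2,1 with
    bridging to 10 -> 2,2 -> ...  Subtraction mirrors addition
    skill-for-skill ("bridging to 10" meaning a required borrow).  Two
    multiplication skills (1,1 and 2,2) hang off "Addition 2,2".  The
    exact membership of the roster is a documented reconstruction: the
    published description fixes the count (38), the ranges, the variant
    vocabulary and the 0-100 addition chain, but does not print the full
    list.
    """
    skills: list[Skill] = []
    edges: set[tuple[str, str]] = set()
    for op in ("addition", "subtraction"):
        word = op.capitalize()
        prev_id = None
        rank = 0
        for rng in NUMBER_RANGES:
            for da, db, tags, fmt in _BLOCKS[rng]:
                name = f"{word} " + fmt.format(d=f"{da},{db}")
                sid = _slug(name)
                skills.append(Skill(sid, name, op, rng, rank, tags))
                if prev_id is not None:
                    edges.add((prev_id, sid))
                prev_id = sid
                rank += 1
    m11 = Skill(_slug("Multiplication 1,1"), "Multiplication 1,1",
                "multiplication", "0-100", 0, frozenset())
    m22 = Skill(_slug("Multiplication 2,2"), "Multiplication 2,2",
                "multiplication", "0-1000", 1, frozenset())
    skills += [m11, m22]
    edges.add((_slug("Addition 2,2"), m11.id))
    edges.add((m11.id, m22.id))
    return SkillGraph(skills, edges)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Malformed graph text; message names the offending line/token."""


def _skill_to_dict(s: Skill) -> dict:
    return {"id": s.id, "name": s.name, "operation": s.operation,
            "number_range": s.number_range, "difficulty_rank": s.difficulty_rank,
            "variant_tags": sorted(s.variant_tags)}


def _skill_from_dict(d: dict) -> Skill:
    return Skill(d["id"], d["name"], d["operation"], d["number_range"],
                 int(d["difficulty_rank"]), frozenset(d.get("variant_tags", [])))


def write_graph(graph: SkillGraph, dialect: str = "json") -> str:
    """Serialize a graph to JSON or DAGitty text (deterministic output)."""
    if dialect == "json":
        doc = {"skills": [_skill_to_dict(s)
                          for s in sorted(graph.skills, key=lambda s: s.id)],
               "edges": sorted(map(list, graph.edges))}
        return json.dumps(doc, indent=1)
    if dialect == "dagitty":
        lines = ["dag {"]
        for s in sorted(graph.skills, key=lambda s: s.id):
            tags = "|".join(sorted(s.variant_tags)) or "none"
            lines.append(f'"{s.id}" [label="{s.name}" operation="{s.operation}" '
                         f'range="{s.number_range}" rank="{s.difficulty_rank}" '
                         f'tags="{tags}"]')
        for a, b in sorted(graph.edges):
            lines.append(f'"{a}" -> "{b}"')
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


_DAG_NODE = re.compile(r'^\s*"(?P<id>[^"]+)"\s*(?:\[(?P<attrs>[^\]]*)\])?\s*$')
_DAG_EDGE = re.compile(
    r'^\s*(?:"(?P<aq>[^"]+)"|(?P<a>[^\s"]+))\s*->\s*(?:"(?P<bq>[^"]+)"|(?P<b>[^\s"]+))\s*$')
_DAG_ATTR = re.compile(r'(\w+)="([^"]*)"')


def _infer_skill(sid: str, label: str) -> Skill:
    """Reconstruct skill metadata from a bare DAGitty node label."""
    name = label or sid
    low = name.lower()
    op = next((o for o in OPERATIONS if o in low), "addition")
    m = re.search(r"(\d)\s*,\s*(\d)", name)
    digits = max(int(m.group(1)), int(m.group(2))) if m else 1
    rng = {1: "0-10", 2: "0-100"}.get(digits, "0-1000")
    tags = set()
    if "support" in low:
        tags.add("support")
    if "bridging" in low:
        tags.add("bridging_to_10")
    if "mental" in low:
        tags.add("mental")
    return Skill(sid, name, op, rng, 0, frozenset(tags))


def _read_dagitty(text: str) -> SkillGraph:
    body = text.strip()
    if not body.startswith("dag"):
        raise ParseError("line 1: expected text to start with 'dag {'")
    open_i, close_i = body.find("{"), body.rfind("}")
    if open_i < 0 or close_i < 0 or close_i < open_i:
        raise ParseError("unbalanced braces in dag block")
    inner = body[open_i + 1:close_i]
    # statements may be newline- or semicolon-separated
    skills: dict[str, Skill] = {}
    edges: set[tuple[str, str]] = set()
    lineno = text[:open_i].count("\n")
    for raw in re.split(r"[;\n]", inner):
        lineno += 1
        stmt = raw.strip()
        if not stmt:
            continue
        if "->" in stmt:
            m = _DAG_EDGE.match(stmt)
            if not m:
                raise ParseError(f"line {lineno}: malformed edge statement {stmt!r}")
            a = (m.group("aq") or m.group("a")).strip()
            b = (m.group("bq") or m.group("b")).strip()
            for end in (a, b):
                if end not in skills:
                    skills[end] = _infer_skill(end, end)
            edges.add((a, b))
            continue
        m = _DAG_NODE.match(stmt)
        if not m:
            raise ParseError(f"line {lineno}: malformed node statement {stmt!r}")
        sid = m.group("id")
        attrs = dict(_DAG_ATTR.findall(m.group("attrs") or ""))
        if {"operation", "range", "rank"} <= attrs.keys():
            tags = frozenset(t for t in attrs.get("tags", "none").split("|")
                             if t != "none")
            skills[sid] = Skill(sid, attrs.get("label", sid), attrs["operation"],
                                attrs["range"], int(attrs["rank"]), tags)
        else:
            skills[sid] = _infer_skill(sid, attrs.get("label", sid))
    return SkillGraph(list(skills.values()), edges)


def read_graph(source: str, dialect: str = "json") -> SkillGraph:
    """Parse a graph from JSON or DAGitty text."""
    if dialect == "json":
        try:
            doc = json.loads(source)
        except json.JSONDecodeError as exc:
            raise ParseError(f"line {exc.lineno}: {exc.msg}") from exc
        return SkillGraph([_skill_from_dict(d) for d in doc["skills"]],
                          {tuple(e) for e in doc["edges"]})
    if dialect == "dagitty":
        return _read_dagitty(source)
    raise ValueError(f"unknown dialect {dialect!r}")
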