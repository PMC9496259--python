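"""Signed causal DAGs: representation, parsing, serialization, validation.

A :class:`CausalDAG` is a directed acyclic graph whose nodes may carry an
``exposure`` or ``outcome`` role and whose edges may carry a sign (+1 for a
positive causal effect, -1 for negative, ``None`` when unannotated).  The
text format is a dagitty-style dialect::

    # bone remodelling subgraph
    unloading [exposure]
    "bone strength" [outcome]
    unloading -> formation [sign=-]
    formation -> "bone strength" [sign=+]

Statements are separated by newlines or semicolons; ``#`` starts a comment;
names are bare identifiers or double-quoted strings (quoting permits spaces).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "CausalDAG",
    "SignedEdge",
    "DagError",
    "DagSyntaxError",
    "parse_dag",
    "write_dag",
    "topological_order",
]

ROLES = ("exposure", "outcome", "none")


class DagError(ValueError):
    """Structural problem with a DAG (cycle, duplicate edge, unknown node)."""


class DagSyntaxError(DagError):
    """Parse failure; carries 1-based line and column of the offending token."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


@dataclass(frozen=True, order=True)
class SignedEdge:
    source: str
    target: str
    sign: Optional[int] = None  # +1, -1, or None for unknown

    def __post_init__(self):
        if self.sign not in (1, -1, None):
            raise DagError(f"edge sign must be +1, -1 or None, got {self.sign!r}")
        if self.source == self.target:
            raise DagError(f"self-loop on {self.source!r}")


@dataclass
class CausalDAG:
    """Nodes with roles plus signed directed edges; always acyclic."""

    roles: dict[str, str] = field(default_factory=dict)  # name -> role
    edges: dict[tuple[str, str], Optional[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, Optional[int]]],
        roles: Optional[dict[str, str]] = None,
        nodes: Iterable[str] = (),
    ) -> "CausalDAG":
        role_map = {n: "none" for n in nodes}
        edge_map: dict[tuple[str, str], Optional[int]] = {}
        for e in edges:
            s, t, sg = (e if len(e) == 3 else (*e, None))  # type: ignore[misc]
            key = (s, t)
            if key in edge_map:
                raise DagError(f"duplicate edge {s!r} -> {t!r}")
            edge_map[key] = sg
            role_map.setdefault(s, "none")
            role_map.setdefault(t, "none")
        for name, role in (roles or {}).items():
            role_map[name] = role
        return cls(roles=role_map, edges=edge_map)

    # -- interface ------------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.roles)

    @property
    def signed_edges(self) -> list[SignedEdge]:
        return sorted(SignedEdge(s, t, sg) for (s, t), sg in self.edges.items())

    def role(self, name: str) -> str:
        return self.roles[name]

    @property
    def exposures(self) -> list[str]:
        return sorted(n for n, r in self.roles.items() if r == "exposure")

    @property
    def outcomes(self) -> list[str]:
        return sorted(n for n, r in self.roles.items() if r == "outcome")

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self.edges

    def adjacent(self, a: str, b: str) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges

    def parents(self, name: str) -> list[str]:
        return sorted(s for (s, t) in self.edges if t == name)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.roles)
        for (s, t), sg in self.edges.items():
            g.add_edge(s, t, sign=sg)
        return g

    def validate(self) -> None:
        for name, role in self.roles.items():
            if role not in ROLES:
                raise DagError(f"unknown role {role!r} for node {name!r}")
        for (s, t), sg in self.edges.items():
            if s == t:
                raise DagError(f"self-loop on {s!r}")
            if sg not in (1, -1, None):
                raise DagError(f"bad sign {sg!r} on edge {s!r} -> {t!r}")
            for endpoint in (s, t):
                if endpoint not in self.roles:
                    raise DagError(f"undeclared node {endpoint!r} in edge {s!r} -> {t!r}")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(s for s, _ in cycle) + f" -> {cycle[-1][1]}"
            raise DagError(f"cycle detected: {path}")

    def structurally_equal(self, other: "CausalDAG") -> bool:
        return self.roles == other.roles and self.edges == other.edges


# -- text format ---------------------------------------------------------------

_NAME_RE = re.compile(r'"([^"]*)"|([A-Za-z_][A-Za-z0-9_.]*)')
_SIGN_TOKENS = {"+": 1, "-": -1, "−": -1}


def _split_statements(text: str):
    """Yield (statement, line, column) with comments stripped."""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0]
        col = 1
        for part in line.split(";"):
            stripped = part.strip()
            if stripped:
                yield stripped, lineno, col + part.index(stripped[0])
            col += len(part) + 1


def _parse_name(stmt: str, lineno: int, col: int) -> tuple[str, str]:
    m = _NAME_RE.match(stmt)
    if not m:
        raise DagSyntaxError(f"expected a node name, got {stmt[:20]!r}", lineno, col)
    name = m.group(1) if m.group(1) is not None else m.group(2)
    if not name:
        raise DagSyntaxError("empty quoted name", lineno, col)
    return name, stmt[m.end():].lstrip()


def _parse_attrs(stmt: str, lineno: int, col: int) -> tuple[list[str], str]:
    if not stmt.startswith("["):
        return [], stmt
    end = stmt.find("]")
    if end < 0:
        raise DagSyntaxError("unterminated '[' attribute block", lineno, col)
    attrs = [a.strip() for a in stmt[1:end].split(",") if a.strip()]
    return attrs, stmt[end + 1:].lstrip()


def parse_dag(text: str) -> CausalDAG:
    """Parse the dagitty-style dialect into a validated :class:`CausalDAG`."""
    roles: dict[str, str] = {}
    edges: dict[tuple[str, str], Optional[int]] = {}
    for stmt, lineno, col in _split_statements(text):
        name, rest = _parse_name(stmt, lineno, col)
        if rest.startswith("->"):
            target, rest = _parse_name(rest[2:].lstrip(), lineno, col)
            attrs, rest = _parse_attrs(rest, lineno, col)
            if rest:
                raise DagSyntaxError(f"trailing text {rest!r} after edge", lineno, col)
            sign: Optional[int] = None
            for attr in attrs:
                key, _, value = attr.partition("=")
                if key.strip() != "sign":
                    raise DagSyntaxError(f"unknown edge attribute {attr!r}", lineno, col)
                value = value.strip()
                if value not in _SIGN_TOKENS:
                    raise DagSyntaxError(f"edge sign must be + or -, got {value!r}", lineno, col)
                sign = _SIGN_TOKENS[value]
            if (name, target) in edges:
                raise DagSyntaxError(f"duplicate edge {name!r} -> {target!r}", lineno, col)
            if name == target:
                raise DagSyntaxError(f"self-loop on {name!r}", lineno, col)
            edges[(name, target)] = sign
            roles.setdefault(name, "none")
            roles.setdefault(target, "none")
        else:
            attrs, rest = _parse_attrs(rest, lineno, col)
            if rest:
                raise DagSyntaxError(f"trailing text {rest!r} after node", lineno, col)
            role = "none"
            for attr in attrs:
                if attr not in ("exposure", "outcome"):
                    raise DagSyntaxError(f"unknown node attribute {attr!r}", lineno, col)
                role = attr
            if roles.get(name, "none") != "none" and role != "none" and roles[name] != role:
                raise DagSyntaxError(f"conflicting roles for node {name!r}", lineno, col)
            if role != "none" or name not in roles:
                roles[name] = role
    return CausalDAG(roles=roles, edges=edges)


def _format_name(name: str) -> str:
    if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", name):
        return name
    return f'"{name}"'


def write_dag(dag: CausalDAG) -> str:
    """Serialize so that ``parse_dag(write_dag(dag))`` is structurally identical."""
    lines = []
    for name in dag.nodes:
        role = dag.roles[name]
        suffix = f" [{role}]" if role != "none" else ""
        lines.append(f"{_format_name(name)}{suffix}")
    for edge in dag.signed_edges:
        attr = "" if edge.sign is None else f" [sign={'+' if edge.sign > 0 else '-'}]"
        lines.append(f"{_format_name(edge.source)} -> {_format_name(edge.target)}{attr}")
    return "\n".join(lines) + "\n"


def topological_order(dag: CausalDAG) -> list[str]:
    """A node ordering in which every edge points forward (lexicographic ties)."""
    return list(nx.lexicographical_topological_sort(dag.to_networkx()))
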