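"""Testable implications of a signed DAG.

Under the causal Markov assumption a DAG implies (i) a non-zero marginal
correlation for every pair of variables connected by at least one trek, with
an expected direction obtained by propagating edge signs along treks, and
(ii) a conditional independence ``X _||_ Y | Z`` for every set Z that
d-separates a non-adjacent pair.  Following the convention that every minimal
separating set yields its own testable statement, the implied test set lists
one conditional-independence statement per minimal separator of each
non-adjacent pair.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Literal, Optional

import networkx as nx

from .dag import CausalDAG, DagError

__all__ = [
    "IndependenceStatement",
    "MarginalExpectation",
    "ImpliedTestSet",
    "d_separated",
    "marginal_dependencies",
    "minimal_separators",
    "implied_conditional_independencies",
    "expected_sign",
    "expected_test_set",
]

Sign = Literal["positive", "negative", "ambiguous"]


def _canonical_pair(x: str, y: str) -> tuple[str, str]:
    return (x, y) if x <= y else (y, x)


@dataclass(frozen=True)
class IndependenceStatement:
    """``x _||_ y | conditioning_set``; unordered in (x, y)."""

    x: str
    y: str
    conditioning_set: FrozenSet[str]

    def __post_init__(self):
        if self.x == self.y:
            raise ValueError("independence statement needs two distinct variables")
        if self.x in self.conditioning_set or self.y in self.conditioning_set:
            raise ValueError("endpoints may not appear in the conditioning set")
        a, b = _canonical_pair(self.x, self.y)
        object.__setattr__(self, "x", a)
        object.__setattr__(self, "y", b)
        object.__setattr__(self, "conditioning_set", frozenset(self.conditioning_set))

    @property
    def variables(self) -> frozenset[str]:
        return frozenset({self.x, self.y}) | self.conditioning_set

    def sort_key(self):
        return (self.x, self.y, len(self.conditioning_set), tuple(sorted(self.conditioning_set)))

    def __str__(self) -> str:
        given = ", ".join(sorted(self.conditioning_set))
        return f"{self.x} _||_ {self.y} | {{{given}}}"


@dataclass(frozen=True)
class MarginalExpectation:
    """Unordered marginally dependent pair and its expected correlation sign."""

    x: str
    y: str
    expected_sign: Sign

    def __post_init__(self):
        if self.x == self.y:
            raise ValueError("marginal expectation needs two distinct variables")
        a, b = _canonical_pair(self.x, self.y)
        object.__setattr__(self, "x", a)
        object.__setattr__(self, "y", b)

    @property
    def variables(self) -> frozenset[str]:
        return frozenset({self.x, self.y})

    def sort_key(self):
        return (self.x, self.y)

    def __str__(self) -> str:
        return f"corr({self.x}, {self.y}) {self.expected_sign}"


@dataclass
class ImpliedTestSet:
    marginal: list[MarginalExpectation] = field(default_factory=list)
    conditional: list[IndependenceStatement] = field(default_factory=list)
    provenance: Optional[str] = None

    def restrict(self, measured: Iterable[str]) -> "ImpliedTestSet":
        """Keep only implications whose variables are all measured."""
        nodes = set(measured)
        return ImpliedTestSet(
            marginal=[m for m in self.marginal if m.variables <= nodes],
            conditional=[c for c in self.conditional if c.variables <= nodes],
            provenance=self.provenance,
        )

    def to_dict(self) -> dict:
        return {
            "marginal": [
                {"x": m.x, "y": m.y, "expected_sign": m.expected_sign} for m in self.marginal
            ],
            "conditional": [
                {"x": c.x, "y": c.y, "given": sorted(c.conditioning_set)}
                for c in self.conditional
            ],
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _check_nodes(dag: CausalDAG, *names: str) -> None:
    for name in names:
        if name not in dag.roles:
            raise DagError(f"unknown node {name!r}")


def d_separated(dag: CausalDAG, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """True iff ``z`` blocks every path between ``x`` and ``y``.

    A chain or fork node blocks when it is in ``z``; a collider blocks unless
    it, or one of its descendants, is in ``z``.
    """
    zset = frozenset(z)
    _check_nodes(dag, x, y, *zset)
    if x == y:
        raise DagError("d-separation query needs two distinct nodes")
    if x in zset or y in zset:
        raise DagError("query nodes may not be in the conditioning set")
    return nx.is_d_separator(dag.to_networkx(), {x}, {y}, zset)


def marginal_dependencies(dag: CausalDAG) -> list[tuple[str, str]]:
    """All unordered pairs not d-separated by the empty set, in canonical order."""
    g = dag.to_networkx()
    return sorted(
        (x, y)
        for x, y in itertools.combinations(sorted(dag.nodes), 2)
        if not nx.is_d_separator(g, {x}, {y}, set())
    )


def minimal_separators(
    dag: CausalDAG, x: str, y: str, max_sets: Optional[int] = None
) -> set[frozenset[str]]:
    """All minimal d-separating sets for a non-adjacent pair.

    Candidates are restricted to ancestors of {x, y} (sufficient for minimal
    separators in a DAG) and enumerated by increasing cardinality, so a set is
    minimal iff no previously found separator is a proper subset.  The search
    is exponential in the ancestor count; ``max_sets=1`` truncates to a single
    minimal set for large graphs.
    """
    _check_nodes(dag, x, y)
    if dag.adjacent(x, y):
        raise DagError(f"{x!r} and {y!r} are adjacent: no separating set exists")
    g = dag.to_networkx()
    candidates = sorted((nx.ancestors(g, x) | nx.ancestors(g, y)) - {x, y})
    if len(candidates) > 20:
        warnings.warn(
            f"enumerating minimal separators over {len(candidates)} candidate nodes; "
            "this is exponential — consider max_sets=1",
            RuntimeWarning,
            stacklevel=2,
        )
    found: set[frozenset[str]] = set()
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            zset = frozenset(combo)
            if any(prev < zset for prev in found):
                continue
            if nx.is_d_separator(g, {x}, {y}, set(zset)):
                found.add(zset)
                if max_sets is not None and len(found) >= max_sets:
                    return found
    return found


def implied_conditional_independencies(
    dag: CausalDAG, max_sets_per_pair: Optional[int] = None
) -> list[IndependenceStatement]:
    """One statement per minimal separating set of each non-adjacent pair."""
    statements = []
    g = dag.to_networkx()
    for x, y in itertools.combinations(sorted(dag.nodes), 2):
        if dag.adjacent(x, y):
            continue
        if not nx.is_d_separator(g, {x}, {y}, set()):
            seps = minimal_separators(dag, x, y, max_sets=max_sets_per_pair)
        else:
            seps = {frozenset()}
        statements.extend(IndependenceStatement(x, y, z) for z in seps)
    return sorted(set(statements), key=IndependenceStatement.sort_key)


def _treks(dag: CausalDAG, x: str, y: str) -> list[list[tuple[str, str]]]:
    """All simple collider-free paths between x and y, as lists of directed edges.

    These are the simple treks: a directed path either way, or two directed
    paths diverging from a common source.  Path-tracing over them determines
    the sign of the marginal association.
    """
    skeleton = nx.Graph()
    skeleton.add_nodes_from(dag.nodes)
    skeleton.add_edges_from(dag.edges)
    treks = []
    for path in nx.all_simple_paths(skeleton, x, y):
        edges = []
        ok = True
        for i in range(len(path) - 1):
            a, b = path[i], path[i + 1]
            edges.append((a, b) if dag.has_edge(a, b) else (b, a))
        for i in range(1, len(path) - 1):
            into_prev = edges[i - 1][1] == path[i]
            into_next = edges[i][1] == path[i]
            if into_prev and into_next:  # collider blocks a trek
                ok = False
                break
        if ok:
            treks.append(edges)
    return treks


def expected_sign(dag: CausalDAG, x: str, y: str) -> Sign:
    """Expected direction of the marginal correlation of a dependent pair.

    Each trek carries the product of its edge signs; if all treks agree the
    pair's expected direction is determined, otherwise (conflicting treks or
    an unknown edge sign on a trek) it is ``ambiguous``.
    """
    _check_nodes(dag, x, y)
    treks = _treks(dag, x, y)
    if not treks:
        raise DagError(f"{x!r} and {y!r} are not marginally dependent")
    signs = set()
    for trek in treks:
        product = 1
        for edge in trek:
            s = dag.edges[edge]
            if s is None:
                return "ambiguous"
            product *= s
        signs.add(product)
    if len(signs) > 1:
        return "ambiguous"
    return "positive" if signs.pop() > 0 else "negative"


def expected_test_set(
    dag: CausalDAG,
    measured: Optional[Iterable[str]] = None,
    max_sets_per_pair: Optional[int] = None,
    provenance: Optional[str] = None,
) -> ImpliedTestSet:
    """The DAG's full implied test set, optionally restricted to measured nodes."""
    marginal = [
        MarginalExpectation(x, y, expected_sign(dag, x, y))
        for x, y in marginal_dependencies(dag)
    ]
    conditional = implied_conditional_independencies(dag, max_sets_per_pair)
    out = ImpliedTestSet(marginal=marginal, conditional=conditional, provenance=provenance)
    if measured is not None:
        out = out.restrict(measured)
    return out


def test_set_provenance(dag_text: str, source: str = "<string>") -> str:
    digest = hashlib.sha256(dag_text.encode()).hexdigest()[:16]
    return f"{source}#sha256:{digest}"
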