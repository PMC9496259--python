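"""Independent brute-force oracles and random-graph generators for the tests.

These deliberately avoid the code paths they check: d-separation is decided
by enumerating every undirected simple path and applying the blocking rules
directly, and cycle detection by depth-first search over all simple cycles.
"""

from __future__ import annotations

import itertools

import numpy as np

from dagvalid import CausalDAG


def all_undirected_paths(edges: set[tuple[str, str]], x: str, y: str):
    """All simple paths between x and y in the skeleton (node sequences)."""
    adjacency: dict[str, set[str]] = {}
    for s, t in edges:
        adjacency.setdefault(s, set()).add(t)
        adjacency.setdefault(t, set()).add(s)
    paths = []

    def walk(node, path):
        if node == y:
            paths.append(list(path))
            return
        for nxt in adjacency.get(node, ()):
            if nxt not in path:
                path.append(nxt)
                walk(nxt, path)
                path.pop()

    walk(x, [x])
    return paths


def descendants_of(edges: set[tuple[str, str]], node: str) -> set[str]:
    out: set[str] = set()
    stack = [node]
    children: dict[str, set[str]] = {}
    for s, t in edges:
        children.setdefault(s, set()).add(t)
    while stack:
        for child in children.get(stack.pop(), ()):
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


def d_separated_bruteforce(dag: CausalDAG, x: str, y: str, z) -> bool:
    """Path-by-path blocking: chain/fork blocked when the mid-node is in z,
    collider blocked unless it or a descendant is in z."""
    zset = set(z)
    edges = set(dag.edges)
    for path in all_undirected_paths(edges, x, y):
        blocked = False
        for i in range(1, len(path) - 1):
            prev_into = (path[i - 1], path[i]) in edges
            next_into = (path[i + 1], path[i]) in edges
            if prev_into and next_into:  # collider
                if not (({path[i]} | descendants_of(edges, path[i])) & zset):
                    blocked = True
                    break
            elif path[i] in zset:
                blocked = True
                break
        if not blocked:
            return False
    return True


def has_cycle_bruteforce(nodes, edges) -> bool:
    """DFS enumeration of directed cycles, independent of networkx."""
    children: dict[str, set[str]] = {}
    for s, t in edges:
        children.setdefault(s, set()).add(t)

    def reaches(start, target, seen):
        if start == target:
            return True
        for nxt in children.get(start, ()):
            if nxt not in seen:
                seen.add(nxt)
                if reaches(nxt, target, seen):
                    return True
        return False

    return any(reaches(t, s, {t}) for s, t in edges)


def random_dag(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.4,
               signed: bool = True) -> CausalDAG:
    """Random DAG: edges oriented along a random node permutation."""
    names = [f"v{i}" for i in range(n_nodes)]
    order = list(rng.permutation(names))
    edges = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            sign = int(rng.choice([-1, 1])) if signed else None
            edges.append((order[i], order[j], sign))
    return CausalDAG.from_edges(edges, nodes=names)
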