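"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own code paths (and, where the
implementation delegates to a graph library, avoid that library's algorithm):
components via union-find / boolean reachability, betweenness via exhaustive
path enumeration, traversing paths via generic simple-path enumeration plus
membership filtering.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from regmet.graph import AnnotatedGraph, EdgeRecord, VertexRecord
from regmet.synthetic import toy8


@pytest.fixture
def toy():
    return toy8()


def make_plain_graph(n: int, edges: list[tuple[int, int]]) -> AnnotatedGraph:
    """Typed wrapper around an arbitrary digraph on vertices v0..v{n-1}
    (all compounds linked by complex-formation edges; topology-only tests)."""
    g = AnnotatedGraph()
    for i in range(n):
        g.add_vertex(VertexRecord(f"v{i:02d}", "compound", compartment="c"))
    for u, v in edges:
        g.add_edge(EdgeRecord(f"v{u:02d}", f"v{v:02d}", "complex-formation"))
    return g


def random_digraph(n: int, p: float, seed: int) -> AnnotatedGraph:
    rng = np.random.default_rng(seed)
    edges = [(u, v) for u in range(n) for v in range(n)
             if u != v and rng.random() < p]
    return make_plain_graph(n, edges)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def wcc_oracle(g: AnnotatedGraph) -> list[set[str]]:
    """Weak components by union-find."""
    parent = {v: v for v in g.nx.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in g.nx.edges(keys=False):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict[str, set[str]] = {}
    for v in parent:
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())


def scc_oracle(g: AnnotatedGraph) -> list[set[str]]:
    """Strong components from the boolean reachability matrix."""
    ids = sorted(g.nx.nodes)
    idx = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    reach = np.eye(n, dtype=bool)
    for u, v in g.nx.edges(keys=False):
        reach[idx[u], idx[v]] = True
    for k in range(n):
        reach |= reach[:, k : k + 1] & reach[k : k + 1, :]
    mutual = reach & reach.T
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        comp = {ids[j] for j in range(n) if mutual[i, j]}
        seen |= {idx[v] for v in comp}
        comps.append(comp)
    return comps


def _all_paths(adj: dict[str, set[str]], s: str, t: str) -> list[tuple[str, ...]]:
    """All simple directed paths s -> t (exhaustive DFS)."""
    out: list[tuple[str, ...]] = []
    stack = [(s, (s,))]
    while stack:
        v, path = stack.pop()
        if v == t:
            out.append(path)
            continue
        for w in adj[v]:
            if w not in path:
                stack.append((w, path + (w,)))
    return out


def betweenness_oracle(g: AnnotatedGraph, directed: bool = True) -> dict[str, float]:
    """Unnormalized betweenness by enumerating every shortest path."""
    nodes = sorted(g.nx.nodes)
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in g.nx.edges(keys=False):
        if u == v:
            continue
        adj[u].add(v)
        if not directed:
            adj[v].add(u)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        paths = _all_paths(adj, s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / sigma
    return bc


def traversing_paths_oracle(g: AnnotatedGraph, labels: dict[str, str], direction: str):
    """All paths [u, v_1..v_{k-1}, w] with u, w in the outer domains and a
    distinct all-interface interior, via generic simple-path enumeration."""
    src, dst = ("RD", "MD") if direction == "downwards" else ("MD", "RD")
    adj: dict[str, set[str]] = {v: set() for v in g.nx.nodes}
    for u, v in g.nx.edges(keys=False):
        adj[u].add(v)
    found = set()
    for s in [v for v, l in labels.items() if l == src]:
        for t in [v for v, l in labels.items() if l == dst]:
            for p in _all_paths(adj, s, t):
                if len(p) >= 3 and all(labels[x] == "PI" for x in p[1:-1]):
                    found.add(p)
    return found
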