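"""Domain-traversing paths, their statistics, and regulatory-metabolic loops.

A *traversing path* is a directed path [u, v_1, ..., v_{k-1}, w] whose
endpoints u and w lie in the two outer domains (regulatory and metabolic, or
vice versa) and whose interior vertices v_i are distinct members of the
protein interface.  "Downwards" runs RD -> MD, "upwards" MD -> RD.  A single
edge joining RD and MD is a *direct link*, tallied separately; the minimum
traversing-path length is therefore 2 edges.

Enumeration starts from the boundary edges into the interface and explores
interface successors depth-first, emitting a path at the first successor in
the opposite outer domain.  Successors are visited in sorted id order, so
paths stream out in lexicographic order of their vertex sequences.  Worst
case is exponential; a configurable cap raises :class:`PathExplosionError`
rather than exhausting memory.

A *feedback loop* pairs one upwards with one downwards path closed at both
ends by within-domain evidence: in RD a shared endpoint (the transcription
factor at the end of the upwards path regulates the gene starting the
downwards path) or a short RD-internal directed path; in MD a direct edge (or
short MD-internal path) from the downwards end to the upwards start.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

from .graph import AnnotatedGraph
from .partition import Partition

#: Default ceiling on the number of enumerated paths.
MAX_PATHS_DEFAULT = 2_000_000


class PathExplosionError(RuntimeError):
    """Raised when enumeration exceeds the configured path-count or depth cap."""


@dataclass(frozen=True)
class TraversingPath:
    """One domain-traversing path."""

    direction: str  # "downwards" (RD->MD) | "upwards" (MD->RD)
    vertices: tuple[str, ...]

    @property
    def length(self) -> int:
        """Edge count k."""
        return len(self.vertices) - 1

    @property
    def interior(self) -> tuple[str, ...]:
        return self.vertices[1:-1]

    @property
    def start(self) -> str:
        return self.vertices[0]

    @property
    def end(self) -> str:
        return self.vertices[-1]


def _domain_endpoints(direction: str) -> tuple[str, str]:
    if direction == "downwards":
        return "RD", "MD"
    if direction == "upwards":
        return "MD", "RD"
    raise ValueError("direction must be 'downwards' or 'upwards'")


def iter_traversing_paths(
    g: AnnotatedGraph,
    partition: Partition,
    direction: str,
    max_paths: int | None = MAX_PATHS_DEFAULT,
    max_depth: int | None = None,
) -> Iterator[TraversingPath]:
    """Stream all traversing paths in lexicographic vertex-sequence order.

    Requires a three-domain partition (an interface must exist as a label
    class).  ``max_depth`` bounds the edge count k; interior distinctness
    already bounds it by |PI| + 1.
    """
    if partition.n_domains != 3:
        raise ValueError("traversing paths require a three-domain partition")
    partition.validate_for(g)
    src_dom, dst_dom = _domain_endpoints(direction)
    labels = partition.labels
    gnx = g.nx
    adj: dict[str, list[str]] = {
        v: sorted({w for _, w in gnx.out_edges(v)}) for v in gnx.nodes
    }
    count = 0
    for u in sorted(v for v, lab in labels.items() if lab == src_dom):
        stack: list[str] = [u]
        on_path = {u}

        def dfs() -> Iterator[TraversingPath]:
            nonlocal count
            v = stack[-1]
            for w in adj[v]:
                lab = labels[w]
                if lab == dst_dom and len(stack) >= 2:
                    count += 1
                    if max_paths is not None and count > max_paths:
                        raise PathExplosionError(
                            f"more than {max_paths} traversing paths"
                        )
                    yield TraversingPath(direction, tuple(stack) + (w,))
                elif lab == "PI" and w not in on_path:
                    if max_depth is not None and len(stack) + 1 > max_depth:
                        raise PathExplosionError(f"path depth exceeds {max_depth}")
                    stack.append(w)
                    on_path.add(w)
                    yield from dfs()
                    stack.pop()
                    on_path.remove(w)

        yield from dfs()


def enumerate_traversing_paths(
    g: AnnotatedGraph,
    partition: Partition,
    direction: str,
    max_paths: int | None = MAX_PATHS_DEFAULT,
    max_depth: int | None = None,
) -> list[TraversingPath]:
    """Complete traversing-path enumeration (list form of
    :func:`iter_traversing_paths`)."""
    return list(iter_traversing_paths(g, partition, direction, max_paths, max_depth))


def count_direct_links(
    g: AnnotatedGraph, partition: Partition, from_domain: str, to_domain: str
) -> int:
    """Number of single directed edges from ``from_domain`` into
    ``to_domain`` (``D -> D`` counts the domain's internal directed edges)."""
    partition.validate_for(g)
    labels = partition.labels
    return sum(
        1
        for u, v in g.nx.edges(keys=False)
        if labels[u] == from_domain and labels[v] == to_domain
    )


@dataclass
class PathStats:
    """Aggregate statistics over one pool of traversing paths."""

    n_paths: int
    length_histogram: dict[int, int]
    #: fraction of paths whose interior contains the vertex / pair / triple
    vertex_participation: dict[str, float]
    pair_participation: dict[tuple[str, str], float]
    triple_participation: dict[tuple[str, str, str], float]
    distinct_interior_vertices: int

    def top(self, k: str = "triple", n: int = 5) -> list[tuple, float]:
        table = {
            "vertex": self.vertex_participation,
            "pair": self.pair_participation,
            "triple": self.triple_participation,
        }[k]
        return sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def path_statistics(paths: Iterable[TraversingPath]) -> PathStats:
    """Length histogram plus per-vertex, per-pair and per-triple interior
    participation fractions.  An empty pool yields all-zero statistics."""
    paths = list(paths)
    n = len(paths)
    hist: Counter = Counter(p.length for p in paths)
    vc: Counter = Counter()
    pc: Counter = Counter()
    tc: Counter = Counter()
    interior_union: set[str] = set()
    for p in paths:
        inner = sorted(set(p.interior))
        interior_union.update(inner)
        vc.update(inner)
        pc.update(combinations(inner, 2))
        tc.update(combinations(inner, 3))
    frac = (lambda c: {k: v / n for k, v in c.items()}) if n else (lambda c: {})
    return PathStats(
        n_paths=n,
        length_histogram=dict(sorted(hist.items())),
        vertex_participation=frac(vc),
        pair_participation=frac(pc),
        triple_participation=frac(tc),
        distinct_interior_vertices=len(interior_union),
    )


def scc_containment(paths: Iterable[TraversingPath], scc: set[str]) -> float:
    """Fraction of paths whose every vertex (endpoints included) lies in the
    given vertex set."""
    paths = list(paths)
    if not paths:
        return 0.0
    inside = sum(1 for p in paths if set(p.vertices) <= scc)
    return inside / len(paths)


@dataclass(frozen=True)
class FeedbackLoop:
    """An upwards and a downwards traversing path closed in both outer domains."""

    up: TraversingPath
    down: TraversingPath
    #: RD-internal vertex sequence from up.end to down.start (length 1 = shared endpoint)
    rd_closure: tuple[str, ...]
    #: MD-internal vertex sequence from down.end to up.start
    md_closure: tuple[str, ...]


def _bounded_paths_within(
    gnx, members: set[str], src: str, dst: str, max_len: int
) -> tuple[str, ...] | None:
    """Shortest directed path from src to dst of <= max_len edges staying
    inside ``members``; None if none exists.  max_len 0 demands src == dst."""
    if src == dst:
        return (src,)
    if max_len <= 0:
        return None
    dist = {src: (src,)}
    frontier = deque([src])
    depth = 0
    while frontier and depth < max_len:
        depth += 1
        for _ in range(len(frontier)):
            v = frontier.popleft()
            for _, w in gnx.out_edges(v):
                if w == dst:
                    return dist[v] + (w,)
                if w in members and w not in dist:
                    dist[w] = dist[v] + (w,)
                    frontier.append(w)
    return None


def find_feedback_loops(
    g: AnnotatedGraph,
    partition: Partition,
    up: Sequence[TraversingPath],
    down: Sequence[TraversingPath],
    rd_closure: int = 0,
    md_closure: int = 1,
    max_loops: int | None = MAX_PATHS_DEFAULT,
) -> list[FeedbackLoop]:
    """All (up, down) pairs closed in both outer domains.

    ``rd_closure`` / ``md_closure`` give the maximum closing-path length in
    edges within the respective domain: 0 means identity (shared endpoint;
    only meaningful in RD), 1 means a direct edge, L > 1 allows short
    within-domain cascades.  Closure evidence (the witnessing vertex
    sequences) is attached to each loop.
    """
    partition.validate_for(g)
    labels = partition.labels
    gnx = g.nx
    rd = {v for v, lab in labels.items() if lab == "RD"}
    md = {v for v, lab in labels.items() if lab == "MD"}
    loops: list[FeedbackLoop] = []
    for u_path in sorted(up, key=lambda p: p.vertices):
        for d_path in sorted(down, key=lambda p: p.vertices):
            rd_ev = _bounded_paths_within(gnx, rd, u_path.end, d_path.start, rd_closure)
            if rd_ev is None:
                continue
            md_ev = _bounded_paths_within(gnx, md, d_path.end, u_path.start, md_closure)
            if md_ev is None:
                continue
            loops.append(FeedbackLoop(up=u_path, down=d_path, rd_closure=rd_ev, md_closure=md_ev))
            if max_loops is not None and len(loops) > max_loops:
                raise PathExplosionError(f"more than {max_loops} feedback loops")
    return loops


# -- export -----------------------------------------------------------------


def paths_to_tsv(paths: Iterable[TraversingPath], path) -> None:
    """One path per row: direction, length, semicolon-joined vertex ids."""
    with open(path, "w") as fh:
        fh.write("direction\tlength\tvertices\n")
        for p in paths:
            fh.write(f"{p.direction}\t{p.length}\t{';'.join(p.vertices)}\n")
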