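"""Partition-aware and global network statistics.

Implements the inter-module edge fraction c_D, the Newman-style modularity of
a fixed partition, degree and betweenness centrality, the intra-domain degree
fraction (embeddedness, xi), hub detection, and the random-subset betweenness
null model used to calibrate the interface's centrality.

Modularity is evaluated on the undirected simple view of the network (each
directed edge contributes one undirected link; reciprocal and parallel pairs
collapse; self-links are excluded):

    M = sum_j [ L(D_j, D_j) / L_G - (deg(D_j) / (2 L_G))^2 ]

with L(D, D) the number of links inside domain D, L_G the total number of
links, and deg(D) the summed degree of D's vertices.  Degree-based measures
(DC, xi, hubs) count the directed multigraph: DC(v) = k_in + k_out.
Betweenness is the unnormalized Brandes count over ordered vertex pairs,
computed on the directed graph by default (the network is directed); an
undirected option is provided since the choice is a convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph import AnnotatedGraph
from .partition import Partition

#: Total degree above which (strictly) a vertex counts as a hub.
HUB_THRESHOLD = 50


@dataclass
class DomainMetric:
    """Connectivity summary of one domain under a partition."""

    domain: str
    internal_edges: int
    external_edges: int

    @property
    def c_d(self) -> float:
        """Inter-module edge fraction: external / (external + internal)."""
        tot = self.internal_edges + self.external_edges
        return self.external_edges / tot if tot else 0.0


def inter_module_edge_fraction(g: AnnotatedGraph, partition: Partition) -> dict[str, DomainMetric]:
    """Per-domain internal/external edge counts and c_D.

    Every directed edge is counted once; internal/external classification
    ignores direction (an edge is internal to D iff both endpoints carry
    label D, external to D iff exactly one does).
    """
    partition.validate_for(g)
    labels = partition.labels
    doms = sorted(set(labels.values()))
    internal = {d: 0 for d in doms}
    external = {d: 0 for d in doms}
    for u, v in g.nx.edges(keys=False):
        lu, lv = labels[u], labels[v]
        if lu == lv:
            internal[lu] += 1
        else:
            external[lu] += 1
            external[lv] += 1
    return {d: DomainMetric(d, internal[d], external[d]) for d in doms}


def modularity(g: AnnotatedGraph, partition: Partition) -> tuple[float, dict[str, float]]:
    """Partition modularity M and its per-domain summands.

    Raises ``ValueError`` on a graph whose undirected simple view has no
    links (the formula divides by L_G).
    """
    partition.validate_for(g)
    ug = g.undirected_simple()
    l_g = ug.number_of_edges()
    if l_g == 0:
        raise ValueError("modularity undefined: graph has no links")
    labels = partition.labels
    doms = sorted(set(labels.values()))
    intra = {d: 0 for d in doms}
    deg = {d: 0 for d in doms}
    for u, v in ug.edges():
        if labels[u] == labels[v]:
            intra[labels[u]] += 1
    for v, k in ug.degree():
        deg[labels[v]] += k
    terms = {d: intra[d] / l_g - (deg[d] / (2 * l_g)) ** 2 for d in doms}
    return sum(terms.values()), terms


def degree_centrality(g: AnnotatedGraph) -> pd.DataFrame:
    """Per-vertex in/out/total degree on the directed multigraph.

    The total over all vertices of DC equals 2|E|.
    """
    gnx = g.nx
    rows = [
        (v, gnx.in_degree(v), gnx.out_degree(v), gnx.in_degree(v) + gnx.out_degree(v))
        for v in sorted(gnx.nodes)
    ]
    return pd.DataFrame(rows, columns=["vertex", "k_in", "k_out", "DC"]).set_index("vertex")


def _domain_degree(g: AnnotatedGraph, vid: str, members: set[str]) -> int:
    """Multigraph degree of ``vid`` restricted to neighbors in ``members``
    (A_vw + A_wv summed over w in the domain)."""
    gnx = g.nx
    k = sum(1 for _, w in gnx.out_edges(vid) if w in members)
    k += sum(1 for u, _ in gnx.in_edges(vid) if u in members)
    return k


def embeddedness(
    g: AnnotatedGraph,
    partition: Partition,
    vid: str,
    domain: str | None = None,
) -> float | None:
    """Intra-domain degree fraction xi_D(v) = k_v^int / k_v.

    ``domain`` defaults to the vertex's own domain.  For an isolated vertex
    (DC = 0) the ratio is undefined and ``None`` is returned, never 0.
    """
    gnx = g.nx
    k = gnx.in_degree(vid) + gnx.out_degree(vid)
    if k == 0:
        return None
    dom = domain if domain is not None else partition.label(vid)
    members = {w for w, lab in partition.labels.items() if lab == dom}
    members.discard(vid)
    return _domain_degree(g, vid, members) / k


def embeddedness_table(g: AnnotatedGraph, partition: Partition) -> pd.DataFrame:
    """xi of every vertex toward every domain (columns ``xi_<D>``), plus the
    vertex's own-domain value in ``xi``.  Isolated vertices carry NaN."""
    doms = sorted(set(partition.labels.values()))
    members = {d: {v for v, lab in partition.labels.items() if lab == d} for d in doms}
    rows = []
    for vid in sorted(g.nx.nodes):
        k = g.nx.in_degree(vid) + g.nx.out_degree(vid)
        row: dict = {"vertex": vid, "domain": partition.label(vid)}
        for d in doms:
            mem = members[d] - {vid}
            row[f"xi_{d}"] = _domain_degree(g, vid, mem) / k if k else np.nan
        row["xi"] = row[f"xi_{partition.label(vid)}"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("vertex")


def betweenness(g: AnnotatedGraph, directed: bool = True) -> dict[str, float]:
    """Unnormalized betweenness BC(v) = sum_{s!=v!=t} sigma_st(v)/sigma_st.

    Brandes' algorithm on the simple (multi-edges collapsed) graph.  The sum
    runs over *ordered* vertex pairs in both modes (in the undirected view
    each unordered pair therefore contributes twice, giving k(k-1) for the
    centre of a k-star).  Pairs with no connecting path contribute 0.
    """
    if directed:
        return nx.betweenness_centrality(g.simple_digraph(), normalized=False)
    h = g.undirected_simple(self_loops=False)
    return {v: 2.0 * x for v, x in nx.betweenness_centrality(h, normalized=False).items()}


def find_hubs(g: AnnotatedGraph, threshold: int = HUB_THRESHOLD) -> set[str]:
    """Vertices whose total degree strictly exceeds ``threshold``."""
    gnx = g.nx
    return {v for v in gnx.nodes if gnx.in_degree(v) + gnx.out_degree(v) > threshold}


@dataclass
class NullDistribution:
    """Empirical distribution of mean betweenness over random vertex subsets."""

    means: np.ndarray
    subset_size: int

    def quantile_of(self, value: float) -> float:
        """Empirical quantile of ``value``: fraction of draws <= value."""
        if self.means.size == 0:
            raise ValueError("empty null distribution: no draws")
        return float(np.mean(self.means <= value))


def betweenness_null(
    g: AnnotatedGraph,
    subset_size: int,
    n_draws: int,
    seed: int,
    directed: bool = True,
    bc: dict[str, float] | None = None,
) -> NullDistribution:
    """Distribution of the mean BC of ``n_draws`` random vertex subsets drawn
    without replacement, for comparison with a domain's mean BC."""
    if subset_size > g.n_vertices:
        raise ValueError("subset_size exceeds the number of vertices")
    if bc is None:
        bc = betweenness(g, directed=directed)
    ids = sorted(bc)
    values = np.array([bc[v] for v in ids])
    rng = np.random.default_rng(seed)
    means = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(len(ids), size=subset_size, replace=False)
        means[i] = values[idx].mean()
    return NullDistribution(means=means, subset_size=subset_size)


def rank_report(
    g: AnnotatedGraph,
    partition: Partition,
    top_k: int,
    by: str = "BC",
    directed: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Top-k vertices by betweenness (``by="BC"``) or total degree
    (``by="DC"``), with domain labels and per-domain counts.

    Ties break deterministically by vertex id (lexicographic).
    """
    if by == "BC":
        scores = betweenness(g, directed=directed)
    elif by == "DC":
        gnx = g.nx
        scores = {v: gnx.in_degree(v) + gnx.out_degree(v) for v in gnx.nodes}
    else:
        raise ValueError("by must be 'BC' or 'DC'")
    order = sorted(scores, key=lambda v: (-scores[v], v))[:top_k]
    df = pd.DataFrame(
        {
            "rank": range(1, len(order) + 1),
            "vertex": order,
            "score": [scores[v] for v in order],
            "domain": [partition.label(v) for v in order],
        }
    ).set_index("rank")
    counts: dict[str, int] = {}
    for v in order:
        counts[partition.label(v)] = counts.get(partition.label(v), 0) + 1
    return df, counts


def vertex_metrics(
    g: AnnotatedGraph,
    partition: Partition,
    hub_threshold: int = HUB_THRESHOLD,
    directed: bool = True,
) -> pd.DataFrame:
    """Combined per-vertex metric report: degrees, embeddedness, betweenness
    and hub flag, with the vertex's domain label."""
    df = degree_centrality(g)
    emb = embeddedness_table(g, partition)
    bc = betweenness(g, directed=directed)
    df = df.join(emb)
    df["BC"] = pd.Series(bc)
    df["hub"] = df["DC"] > hub_threshold
    return df
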