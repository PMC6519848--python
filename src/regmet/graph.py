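"""Annotated-graph data model for the integrated regulatory–metabolic network.

The network is a directed multigraph with seven vertex types (genes, protein
monomers, three kinds of protein complexes, small compounds and biochemical
reactions) and seven edge types (two encoding associations, four
reaction/complex associations and regulation).  Vertices and edges carry the
attribute schema of :class:`VertexRecord` and :class:`EdgeRecord`; anything
else found in an input file is preserved verbatim as opaque metadata.

The on-disk interchange format is GraphML.  A second dialect, ``s1_xml``, is
the same XML graph container but with attribute keys named as in the deposited
annotation (e.g. ``affiliation`` / ``metabolic`` for the three- and two-domain
labels); a key-mapping table translates those onto the schema and is shipped
as an explicit, overridable constant rather than inferred ad hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

#: Closed set of vertex types.
VTYPES = frozenset(
    {
        "reaction",
        "compound",
        "gene",
        "protein-monomer",
        "protein-protein-complex",
        "protein-compound-complex",
        "protein-RNA-complex",
    }
)

#: Vertex types that represent proteins (monomers and complexes).
PROTEIN_VTYPES = frozenset(
    {
        "protein-monomer",
        "protein-protein-complex",
        "protein-compound-complex",
        "protein-RNA-complex",
    }
)

#: Closed set of edge types: two encoding associations, four
#: reaction/complex associations, and regulation.
ETYPES = frozenset(
    {
        "transcription-encoding",
        "translation-encoding",
        "educt",
        "product",
        "catalysis",
        "complex-formation",
        "regulation",
    }
)

#: Cellular compartments: cytosol, extracellular, periplasm, inner membrane,
#: outer membrane, membrane (unspecified).
COMPARTMENTS = frozenset({"c", "e", "p", "i", "o", "m"})

#: Edge types whose downstream semantics is Boolean AND (all partners needed).
_CONJUNCT_DEFAULT = frozenset({"educt", "complex-formation"})

_SCHEMA_NODE_KEYS = ("vtype", "compartment", "name", "covert_map", "affiliation3", "affiliation2")
_SCHEMA_EDGE_KEYS = ("etype", "stoichiometry", "regulation_mode", "logic", "reg_id", "reg_name")

#: Attribute-key mapping for the deposited annotation dialect.  Maps raw
#: attribute names onto the schema; keys absent from this table are kept as
#: opaque metadata.  Versioned config: edit/override via ``load_graph(...,
#: keymap=...)`` when a deposited file uses different spellings.
S1_KEYMAP: Mapping[str, str] = {
    "type": "vtype",
    "name": "name",
    "compartment": "compartment",
    "covert": "covert_map",
    "affiliation": "affiliation3",
    "metabolic": "affiliation2",
    "stoichiometry": "stoichiometry",
    "logic": "logic",
    "id": "reg_id",
}


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed as the stated dialect."""


class SchemaValidationError(ValueError):
    """Raised when a graph violates the vertex/edge schema.

    Carries the complete list of violations in :attr:`violations`.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        msg = "%d schema violation(s):\n  " % len(violations) + "\n  ".join(violations)
        super().__init__(msg)


@dataclass
class VertexRecord:
    """One network vertex: a gene, protein, compound or reaction."""

    id: str
    vtype: str
    compartment: str | None = None
    name: str | None = None
    covert_map: str | None = None
    affiliation3: str | None = None
    affiliation2: str | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class EdgeRecord:
    """One directed association between two vertices.

    ``stoichiometry`` is an integer, 0 meaning not applicable or ambiguous.
    For regulation edges it is mirrored in ``regulation_mode``: +1 activation,
    -1 inhibition, 0 combined.  ``logic`` marks non-regulation edges as
    ``conjunct`` (Boolean AND; reaction educts, complex formation) or
    ``disjunct`` (Boolean OR; products, isoenzyme catalysis, encoding).
    """

    source: str
    target: str
    etype: str
    stoichiometry: int = 0
    regulation_mode: int | None = None
    logic: str | None = None
    reg_id: str | None = None
    reg_name: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.etype == "regulation":
            if self.logic is None:
                self.logic = "n/a"
            if self.regulation_mode is None:
                self.regulation_mode = 0
        elif self.logic is None and self.etype in ETYPES:
            self.logic = "conjunct" if self.etype in _CONJUNCT_DEFAULT else "disjunct"


class AnnotatedGraph:
    """Directed typed multigraph over :class:`VertexRecord`/:class:`EdgeRecord`.

    Parallel edges between the same vertex pair are allowed when they differ
    in edge type (a transcription factor may both encode-relate to and
    regulate the same partner); identical ``(source, target, etype)`` triples
    are rejected.  The graph is always directed; undirected views needed by
    metrics are derived on the fly, never stored.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------

    def add_vertex(self, rec: VertexRecord, *, replace: bool = False) -> None:
        if not replace and rec.id in self._g:
            raise ValueError(f"duplicate vertex id {rec.id!r}")
        attrs = {k: getattr(rec, k) for k in _SCHEMA_NODE_KEYS if getattr(rec, k) is not None}
        self._g.add_node(rec.id, **attrs, **rec.meta)

    def add_edge(self, rec: EdgeRecord) -> None:
        if self._g.has_edge(rec.source, rec.target, key=rec.etype):
            raise ValueError(
                f"duplicate edge ({rec.source!r}, {rec.target!r}, {rec.etype!r})"
            )
        attrs = {k: getattr(rec, k) for k in _SCHEMA_EDGE_KEYS if getattr(rec, k) is not None}
        self._g.add_edge(rec.source, rec.target, key=rec.etype, **attrs, **rec.meta)

    # -- basic accessors ----------------------------------------------

    @property
    def nx(self) -> nx.MultiDiGraph:
        """The underlying networkx multigraph (treat as read-only)."""
        return self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __contains__(self, vid: str) -> bool:
        return vid in self._g

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def vertex_ids(self) -> list[str]:
        return sorted(self._g.nodes)

    def vertex(self, vid: str) -> VertexRecord:
        d = self._g.nodes[vid]
        return VertexRecord(
            id=vid,
            vtype=d.get("vtype"),
            compartment=d.get("compartment"),
            name=d.get("name"),
            covert_map=d.get("covert_map"),
            affiliation3=d.get("affiliation3"),
            affiliation2=d.get("affiliation2"),
            meta={k: v for k, v in d.items() if k not in _SCHEMA_NODE_KEYS},
        )

    def vtype(self, vid: str) -> str:
        return self._g.nodes[vid]["vtype"]

    @staticmethod
    def _edge_record(u: str, v: str, k: str, d: Mapping) -> EdgeRecord:
        return EdgeRecord(
            source=u,
            target=v,
            etype=d.get("etype", k),
            stoichiometry=d.get("stoichiometry", 0),
            regulation_mode=d.get("regulation_mode"),
            logic=d.get("logic"),
            reg_id=d.get("reg_id"),
            reg_name=d.get("reg_name"),
            meta={x: y for x, y in d.items() if x not in _SCHEMA_EDGE_KEYS},
        )

    def edge_records(self) -> Iterator[EdgeRecord]:
        for u, v, k, d in self._g.edges(keys=True, data=True):
            yield self._edge_record(u, v, k, d)

    def out_edges(self, vid: str) -> Iterator[EdgeRecord]:
        for u, v, k, d in self._g.out_edges(vid, keys=True, data=True):
            yield self._edge_record(u, v, k, d)

    def in_edges(self, vid: str) -> Iterator[EdgeRecord]:
        for u, v, k, d in self._g.in_edges(vid, keys=True, data=True):
            yield self._edge_record(u, v, k, d)

    def incident_etypes(self, vid: str) -> set[str]:
        out = {k for _, _, k in self._g.out_edges(vid, keys=True)}
        out |= {k for _, _, k in self._g.in_edges(vid, keys=True)}
        return out

    def set_vertex_attr(self, vid: str, key: str, value) -> None:
        self._g.nodes[vid][key] = value

    # -- derived graphs ------------------------------------------------

    def copy(self) -> "AnnotatedGraph":
        g = AnnotatedGraph()
        g._g = self._g.copy()
        return g

    def induced_subgraph(self, vids: Iterable[str]) -> "AnnotatedGraph":
        g = AnnotatedGraph()
        g._g = self._g.subgraph(vids).copy()
        return g

    def simple_digraph(self) -> nx.DiGraph:
        """Directed simple-graph view (parallel edges collapsed)."""
        return nx.DiGraph(self._g)

    def undirected_simple(self, *, self_loops: bool = False) -> nx.Graph:
        """Undirected simple-graph view.

        Each directed edge contributes one undirected link; reciprocal and
        parallel edges collapse to a single link.  Self-links are excluded
        unless requested.
        """
        g = nx.Graph()
        g.add_nodes_from(self._g.nodes)
        for u, v in self._g.edges(keys=False):
            if u == v and not self_loops:
                continue
            g.add_edge(u, v)
        return g

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        """Check the full schema; raise :class:`SchemaValidationError` listing
        every violation (never just the first)."""
        bad: list[str] = []
        for vid, d in self._g.nodes(data=True):
            vt = d.get("vtype")
            if vt not in VTYPES:
                bad.append(f"vertex {vid!r}: unknown vtype {vt!r}")
                continue
            comp = d.get("compartment")
            if vt in ("gene", "reaction"):
                if comp is not None:
                    bad.append(f"vertex {vid!r}: compartment on {vt} vertex")
            elif comp is not None and comp not in COMPARTMENTS:
                bad.append(f"vertex {vid!r}: unknown compartment {comp!r}")
        seen: set[tuple[str, str, str]] = set()
        for u, v, k, d in self._g.edges(keys=True, data=True):
            et = d.get("etype", k)
            if et not in ETYPES:
                bad.append(f"edge ({u!r},{v!r}): unknown etype {et!r}")
                continue
            for end in (u, v):
                if "vtype" not in self._g.nodes[end]:
                    bad.append(f"edge ({u!r},{v!r},{et!r}): dangling endpoint {end!r}")
            triple = (u, v, et)
            if triple in seen:
                bad.append(f"duplicate edge triple {triple!r}")
            seen.add(triple)
            mode = d.get("regulation_mode")
            if et == "regulation":
                if mode not in (-1, 0, 1):
                    bad.append(f"edge ({u!r},{v!r},regulation): regulation_mode {mode!r}")
            else:
                if mode is not None:
                    bad.append(f"edge ({u!r},{v!r},{et!r}): regulation_mode on non-regulation edge")
                if d.get("logic") not in ("conjunct", "disjunct"):
                    bad.append(f"edge ({u!r},{v!r},{et!r}): logic {d.get('logic')!r}")
        if bad:
            raise SchemaValidationError(bad)

    # -- equality (attribute-level) --------------------------------------

    def records_equal(self, other: "AnnotatedGraph") -> bool:
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        for vid in self._g.nodes:
            if self.vertex(vid) != other.vertex(vid):
                return False
        mine = {(e.source, e.target, e.etype): e for e in self.edge_records()}
        theirs = {(e.source, e.target, e.etype): e for e in other.edge_records()}
        return mine == theirs


# ---------------------------------------------------------------------------
# Construction helpers / IO
# ---------------------------------------------------------------------------


def build_graph(vertices: Iterable[VertexRecord], edges: Iterable[EdgeRecord]) -> AnnotatedGraph:
    """Assemble and validate an :class:`AnnotatedGraph` from record lists."""
    g = AnnotatedGraph()
    for v in vertices:
        g.add_vertex(v)
    for e in edges:
        g.add_edge(e)
    g.validate()
    return g


def save_graph(g: AnnotatedGraph, path) -> None:
    """Write GraphML.  All schema attributes and opaque metadata round-trip."""
    nx.write_graphml(g.nx, path, named_key_ids=True, edge_id_from_attribute="etype")


def load_graph(path, dialect: str = "graphml", keymap: Mapping[str, str] | None = None) -> AnnotatedGraph:
    """Read an annotated graph from an XML graph file.

    Parameters
    ----------
    path:
        File location.
    dialect:
        ``"graphml"`` for files written by :func:`save_graph` (attribute keys
        already match the schema) or ``"s1_xml"`` for the deposited annotation
        dialect, whose keys are translated through :data:`S1_KEYMAP`.
    keymap:
        Optional override of the attribute-key mapping table.

    Unknown attribute keys are preserved as opaque metadata.  Parse failures
    raise :class:`GraphFormatError`; schema violations raise
    :class:`SchemaValidationError` listing all of them.
    """
    if dialect not in ("graphml", "s1_xml"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if keymap is None:
        keymap = S1_KEYMAP if dialect == "s1_xml" else {}
    try:
        raw = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:  # the xml layer reports the offending element
        raise GraphFormatError(f"cannot parse {path!r} as {dialect}: {exc}") from exc
    if not raw.is_directed():
        raw = raw.to_directed()

    g = AnnotatedGraph()
    for vid, d in raw.nodes(data=True):
        mapped = {keymap.get(k, k): v for k, v in d.items()}
        rec = VertexRecord(
            id=str(vid),
            vtype=mapped.pop("vtype", None),
            compartment=mapped.pop("compartment", None),
            name=mapped.pop("name", None),
            covert_map=mapped.pop("covert_map", None),
            affiliation3=mapped.pop("affiliation3", None),
            affiliation2=mapped.pop("affiliation2", None),
            meta=mapped,
        )
        g.add_vertex(rec)
    for u, v, k, d in raw.edges(keys=True, data=True):
        mapped = {keymap.get(x, x): y for x, y in d.items()}
        mapped.pop("id", None)  # writer artifact
        et = mapped.pop("etype", k if k in ETYPES else None)
        stoich = mapped.pop("stoichiometry", 0)
        mode = mapped.pop("regulation_mode", None)
        if et == "regulation" and mode is None and isinstance(stoich, int):
            # deposited dialect: for regulation edges the stoichiometry slot
            # carries the mode (+1 activation, -1 inhibition, 0 combined)
            mode = stoich if stoich in (-1, 0, 1) else 0
        rec = EdgeRecord(
            source=str(u),
            target=str(v),
            etype=et,
            stoichiometry=int(stoich) if stoich is not None else 0,
            regulation_mode=mode,
            logic=mapped.pop("logic", None),
            reg_id=mapped.pop("reg_id", None),
            reg_name=mapped.pop("reg_name", None),
            meta=mapped,
        )
        g.add_edge(rec)
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Component decompositions
# ---------------------------------------------------------------------------


def largest_weakly_connected_component(g: AnnotatedGraph) -> AnnotatedGraph:
    """Induced subgraph on the largest weak component.

    Ties on component size break deterministically toward the component
    containing the lexicographically smallest vertex id.  The empty graph maps
    to an empty graph.
    """
    if g.n_vertices == 0:
        return AnnotatedGraph()
    comps = list(nx.weakly_connected_components(g.nx))
    best = max(comps, key=lambda c: (len(c), _neg_min_id(c)))
    return g.induced_subgraph(best)


def largest_strongly_connected_component(g: AnnotatedGraph) -> set[str]:
    """Vertex set of the largest strong component under edge direction.

    In a DAG every component is a singleton; ties break toward the component
    containing the smallest vertex id.
    """
    if g.n_vertices == 0:
        return set()
    comps = nx.strongly_connected_components(g.nx)
    best = max(comps, key=lambda c: (len(c), _neg_min_id(c)))
    return set(best)


class _neg_min_id:
    """Orders vertex-id sets so that a *smaller* minimum id compares larger
    (used as a deterministic max() tie-break)."""

    def __init__(self, comp):
        self.key = min(comp)

    def __lt__(self, other):
        return self.key > other.key

    def __eq__(self, other):
        return self.key == other.key
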