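"""Domain partitions of the integrated network.

Two families of vertex partitions are computed:

* **functional** — rule-based affiliation into metabolic domain (MD), protein
  interface (PI) and regulatory domain (RD), obtained as the fixed point of a
  synchronous neighbor-propagation procedure seeded from vertex composition
  and regulation involvement;
* **vertex-driven** — a pure vertex-type lookup (genes regulatory, proteins
  interface, reactions/compounds metabolic).

Both exist in a three-domain (MD—PI—RD) and a two-domain (MD—RD) variant.

Affiliation rules
-----------------
Seeds (round 0):

* *reaction*: all educt/product partners are compounds -> MD; all are
  proteins -> PI (interface-related, e.g. protein modification); mixed ->
  deferred; a reaction with no educt/product edges -> MD.
* *gene*: incident to any regulation edge (as target or source) -> RD;
  otherwise (not involved in any regulatory process) -> MD.
* *protein-compound complex* and *protein-RNA complex*: PI.  By analogy with
  the reaction seeding, a complex of mixed composition (protein plus
  metabolite or RNA) is a cross-system entity — the metabolic
  transcription-factor motif — and is interface by construction.
* *compound* with no adjacent reaction and no regulator -> MD (isolated
  metabolites are metabolic by type).
* *protein* (monomer or all-protein complex) with an empty influence set:
  RD if it is the source of a regulation edge (a pure regulator), else MD.

Propagation (synchronous rounds over the *influential* neighbor sets defined
in :data:`INFLUENCE_TABLE`): a deferred vertex adopts the unanimous label of
its influential set once all members are resolved; it resolves to PI as soon
as two distinct resolved labels appear among them (a bridging neighborhood
cannot become unanimous).  Vertices still deferred when a round changes
nothing sit on dependency cycles without outside information; they are
counted as *unresolved* and assigned to the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import AnnotatedGraph, PROTEIN_VTYPES

LABELS3 = ("MD", "PI", "RD")
LABELS2 = ("MD", "RD")

#: Declarative neighbor-scope table: which adjacent vertices *influence* a
#: deferred vertex's affiliation, as (edge type, direction) selectors where
#: direction is relative to the vertex ("in" = vertex is edge target).
#: Compounds listen to the reactions that produce/consume them and to their
#: regulators — not to complexes they are bound in (a metabolite stays
#: metabolic when it binds a transcription factor).  Proteins listen to their
#: encoding genes, the reactions and complexes they act in or are produced
#: by, and their regulators — not to their own components (the complex
#: informs its subunits, not vice versa).  Reactions (only consulted when
#: seeded deferred, i.e. mixed educt/product types) listen to their educts
#: and products.
INFLUENCE_TABLE: dict[str, tuple[tuple[str, str], ...]] = {
    "reaction": (("educt", "in"), ("product", "out")),
    "compound": (("educt", "out"), ("product", "in"), ("regulation", "in")),
    "protein": (
        ("transcription-encoding", "in"),
        ("translation-encoding", "in"),
        ("catalysis", "out"),
        ("complex-formation", "out"),
        ("educt", "out"),
        ("product", "in"),
        ("regulation", "in"),
    ),
}


class ConvergenceError(RuntimeError):
    """Raised if the affiliation propagation exceeds its round cap (|V| rounds;
    each vertex can be relabeled at most once, so this is a safety bound)."""


@dataclass
class Partition:
    """Total vertex -> domain labeling for a named scheme."""

    scheme: str  # "functional" | "vertex_driven"
    n_domains: int  # 2 | 3
    labels: dict[str, str]

    def label(self, vid: str) -> str:
        return self.labels[vid]

    def domains(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {
            lab: set() for lab in (LABELS3 if self.n_domains == 3 else LABELS2)
        }
        for vid, lab in self.labels.items():
            out.setdefault(lab, set()).add(vid)
        return out

    def validate_for(self, g: AnnotatedGraph) -> None:
        expected = set(LABELS3 if self.n_domains == 3 else LABELS2)
        if set(self.labels) != set(g.nx.nodes):
            raise ValueError("partition is not total on the graph's vertex set")
        stray = {lab for lab in self.labels.values()} - expected
        if stray:
            raise ValueError(f"labels {stray!r} not in scheme {expected!r}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for vid in sorted(self.labels):
                fh.write(f"{vid}\t{self.labels[vid]}\n")

    @classmethod
    def from_tsv(cls, path, scheme: str = "functional", n_domains: int = 3) -> "Partition":
        labels = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                vid, lab = line.split("\t")
                labels[vid] = lab
        return cls(scheme=scheme, n_domains=n_domains, labels=labels)


@dataclass
class AffiliationState:
    """Trace of the functional affiliation fixed point."""

    labels: dict[str, str]
    rounds: int = 0
    #: per-event trace: (round, vertex, rule fired, label)
    trace: list[tuple[int, str, str, str]] = field(default_factory=list)
    #: vertices never positively resolved (assigned PI at the fixed point)
    unresolved: frozenset[str] = frozenset()

    @property
    def n_unresolved(self) -> int:
        return len(self.unresolved)


def _influential(g: AnnotatedGraph, vid: str, vtype: str) -> set[str]:
    kind = "protein" if vtype in PROTEIN_VTYPES else vtype
    selectors = INFLUENCE_TABLE.get(kind, ())
    out: set[str] = set()
    gnx = g.nx
    for etype, direction in selectors:
        if direction == "out":
            for _, w, k in gnx.out_edges(vid, keys=True):
                if k == etype:
                    out.add(w)
        else:
            for w, _, k in gnx.in_edges(vid, keys=True):
                if k == etype:
                    out.add(w)
    out.discard(vid)
    return out


def _seed(g: AnnotatedGraph, vid: str) -> tuple[str | None, str]:
    """Return (label or None, rule name) for round-0 seeding."""
    gnx = g.nx
    vt = gnx.nodes[vid]["vtype"]
    if vt == "reaction":
        partners = [u for u, _, k in gnx.in_edges(vid, keys=True) if k == "educt"]
        partners += [w for _, w, k in gnx.out_edges(vid, keys=True) if k == "product"]
        if not partners:
            return "MD", "reaction-no-participants"
        types = {gnx.nodes[p]["vtype"] for p in partners}
        if types <= {"compound"}:
            return "MD", "reaction-all-compounds"
        if types <= PROTEIN_VTYPES:
            return "PI", "reaction-all-proteins"
        return None, "reaction-mixed"
    if vt == "gene":
        if "regulation" in g.incident_etypes(vid):
            return "RD", "gene-in-regulation"
        return "MD", "gene-no-regulation"
    if vt in ("protein-compound-complex", "protein-RNA-complex"):
        return "PI", "complex-mixed-composition"
    infl = _influential(g, vid, vt)
    if infl:
        return None, "deferred"
    if vt == "compound":
        return "MD", "compound-isolated"
    # protein with no influence set
    if any(k == "regulation" for _, _, k in gnx.out_edges(vid, keys=True)):
        return "RD", "protein-pure-regulator"
    return "MD", "protein-no-regulation"


def affiliate_functional(
    g: AnnotatedGraph,
    n_domains: int = 3,
    *,
    return_state: bool = False,
):
    """Functional domain partition (MD—PI—RD, or MD—RD for ``n_domains=2``).

    Deterministic and independent of vertex iteration order (synchronous
    rounds).  Always total: every vertex receives a label.
    """
    if n_domains not in (2, 3):
        raise ValueError("n_domains must be 2 or 3")
    labels: dict[str, str] = {}
    state = AffiliationState(labels=labels)
    deferred: list[str] = []
    infl_cache: dict[str, set[str]] = {}

    for vid in sorted(g.nx.nodes):
        lab, rule = _seed(g, vid)
        if lab is None:
            deferred.append(vid)
            vt = g.nx.nodes[vid]["vtype"]
            infl_cache[vid] = _influential(g, vid, vt)
        else:
            labels[vid] = lab
            state.trace.append((0, vid, rule, lab))

    cap = g.n_vertices + 1
    rnd = 0
    while deferred:
        rnd += 1
        if rnd > cap:
            raise ConvergenceError(f"affiliation did not converge within {cap} rounds")
        newly: list[tuple[str, str, str]] = []
        for vid in deferred:
            infl = infl_cache[vid]
            resolved = {labels[w] for w in infl if w in labels}
            if len(resolved) >= 2:
                newly.append((vid, "mixed-neighborhood", "PI"))
            elif len(resolved) == 1 and all(w in labels for w in infl):
                newly.append((vid, "unanimous-neighborhood", resolved.pop()))
        if not newly:
            break
        for vid, rule, lab in newly:
            labels[vid] = lab
            state.trace.append((rnd, vid, rule, lab))
        deferred = [v for v in deferred if v not in labels]
    state.rounds = rnd

    # fixed point reached with information-less cycles remaining: interface
    state.unresolved = frozenset(deferred)
    for vid in deferred:
        labels[vid] = "PI"
        state.trace.append((rnd, vid, "unresolved", "PI"))

    if n_domains == 2:
        labels = _merge_two_domain(g, labels)
    part = Partition(scheme="functional", n_domains=n_domains, labels=labels)
    return (part, state) if return_state else part


def _merge_two_domain(g: AnnotatedGraph, labels3: dict[str, str]) -> dict[str, str]:
    """Collapse PI onto MD/RD: each interface vertex falls to the side holding
    the majority of its non-regulation edges (edges to other PI vertices are
    uninformative); ties, including isolated cases, go to RD."""
    out: dict[str, str] = {}
    gnx = g.nx
    for vid, lab in labels3.items():
        if lab != "PI":
            out[vid] = lab
            continue
        votes = {"MD": 0, "RD": 0}
        for u, w, k in list(gnx.out_edges(vid, keys=True)) + list(gnx.in_edges(vid, keys=True)):
            if k == "regulation":
                continue
            other = w if u == vid else u
            if labels3[other] in votes:
                votes[labels3[other]] += 1
        out[vid] = "MD" if votes["MD"] > votes["RD"] else "RD"
    return out


def affiliate_vertex_driven(g: AnnotatedGraph, n_domains: int = 3) -> Partition:
    """Vertex-type partition: genes -> RD, proteins -> PI (3-domain) or RD
    (2-domain), reactions and compounds -> MD."""
    if n_domains not in (2, 3):
        raise ValueError("n_domains must be 2 or 3")
    labels: dict[str, str] = {}
    for vid in g.nx.nodes:
        vt = g.nx.nodes[vid]["vtype"]
        if vt == "gene":
            labels[vid] = "RD"
        elif vt in PROTEIN_VTYPES:
            labels[vid] = "PI" if n_domains == 3 else "RD"
        else:
            labels[vid] = "MD"
    return Partition(scheme="vertex_driven", n_domains=n_domains, labels=labels)


def count_unresolved(g: AnnotatedGraph) -> int:
    """Number of vertices still unresolved at the affiliation fixed point
    (assigned to the interface because they cannot be uniquely attributed)."""
    _, state = affiliate_functional(g, 3, return_state=True)
    return state.n_unresolved


def annotate_partition(g: AnnotatedGraph, partition: Partition) -> None:
    """Write a partition back onto the graph as vertex attributes
    (``affiliation3`` / ``affiliation2``)."""
    key = "affiliation3" if partition.n_domains == 3 else "affiliation2"
    for vid, lab in partition.labels.items():
        g.set_vertex_attr(vid, key, lab)
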