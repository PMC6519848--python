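"""Synthetic annotated networks with planted ground-truth domains.

The generator emulates the building blocks of an integrated
regulatory–metabolic system: metabolic genes encoding enzymes that catalyze
compound-transforming reactions; transcription-factor genes encoding
regulators, a fraction of which are *metabolic* regulators active only as
protein–compound complexes; enzymatic protein complexes; and a regulation
layer with heavy-tailed regulator out-degrees mimicking global regulators.
Every emitted edge respects the type grammar (educt/product edges touch
reactions, encoding runs gene -> protein, regulation originates from
proteins/complexes/genes), and each vertex carries a planted domain label
derived from its construction role, with genuinely mixed-wiring vertices
flagged as ambiguous rather than asserted.

The same networks can be serialized as miniature attribute-value flat files
(:func:`emit_flat_files`) so the database-reconstruction stage is testable
end to end without any external download.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

import networkx as nx

from .graph import AnnotatedGraph, EdgeRecord, VertexRecord
from .partition import Partition


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic network generator.

    Counts are vertex counts per type (protein monomers are implied 1:1 by
    genes).  ``regulation_density`` is the probability that a gene is a
    regulation target; ``metabolic_gene_fraction`` the share of genes
    encoding enzymes; ``metabolic_tf_fraction`` the share of transcription
    factors active only as protein-compound complexes;
    ``reversible_fraction`` the share of reactions tagged reversible (split
    into two vertices by the database-reconstruction stage).  Identical
    params + seed give identical graphs.
    """

    n_genes: int = 150
    n_compounds: int = 120
    n_reactions: int = 100
    n_protein_complexes: int = 20
    n_protein_rna_complexes: int = 1
    regulation_density: float = 0.35
    metabolic_gene_fraction: float = 0.7
    metabolic_tf_fraction: float = 0.3
    reversible_fraction: float = 0.2
    #: share of regulation events that are non-transcriptional (regulation of
    #: enzyme activity / reactions and metabolic-protein regulation of TF
    #: genes) rather than of transcription units; these create the direct
    #: regulatory-metabolic links of the integrated system
    nontranscriptional_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for f in ("n_genes", "n_compounds", "n_reactions", "n_protein_complexes",
                  "n_protein_rna_complexes"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for f in ("regulation_density", "metabolic_gene_fraction",
                  "metabolic_tf_fraction", "reversible_fraction",
                  "nontranscriptional_fraction"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1]")
        if self.n_reactions > 0 and self.n_compounds < 2:
            raise ValueError("reactions require at least 2 compounds")
        if self.n_protein_complexes > 0 and self.n_genes == 0:
            raise ValueError("protein complexes require protein monomers, hence genes")
        if self.n_protein_rna_complexes > 0 and self.n_genes < 2:
            raise ValueError("protein-RNA complexes require a gene and a monomer")


class SyntheticNetwork(NamedTuple):
    graph: AnnotatedGraph
    partition: Partition  # planted functional 3-domain ground truth
    ambiguous: frozenset  # vertices whose planted label is not asserted


PRESETS = {
    "toy": None,  # handled by toy8()
    "small": GeneratorParams(n_genes=40, n_compounds=30, n_reactions=25,
                             n_protein_complexes=5, n_protein_rna_complexes=0),
    "ecoli-like": GeneratorParams(),
}


def toy8() -> SyntheticNetwork:
    """The 8-vertex worked fixture.

    Two genes; an enzyme path (g1 -> p1 -> r1 transforming c1 into c2) and a
    metabolic-regulator path (c2 and p2 form complex pc1, which activates g1
    and inhibits g2).  Its functional three-domain fixed point is
    {RD: g1, g2; PI: p1, p2, pc1; MD: r1, c1, c2}.
    """
    vertices = [
        VertexRecord("g1", "gene"),
        VertexRecord("g2", "gene"),
        VertexRecord("p1", "protein-monomer", compartment="c"),
        VertexRecord("p2", "protein-monomer", compartment="c"),
        VertexRecord("pc1", "protein-compound-complex", compartment="c"),
        VertexRecord("r1", "reaction"),
        VertexRecord("c1", "compound", compartment="c"),
        VertexRecord("c2", "compound", compartment="c"),
    ]
    edges = [
        EdgeRecord("g1", "p1", "translation-encoding"),
        EdgeRecord("g2", "p2", "translation-encoding"),
        EdgeRecord("p1", "r1", "catalysis"),
        EdgeRecord("c1", "r1", "educt", stoichiometry=1),
        EdgeRecord("r1", "c2", "product", stoichiometry=1),
        EdgeRecord("c2", "pc1", "complex-formation", stoichiometry=1),
        EdgeRecord("p2", "pc1", "complex-formation", stoichiometry=1),
        EdgeRecord("pc1", "g1", "regulation", regulation_mode=1, reg_id="REG-1"),
        EdgeRecord("pc1", "g2", "regulation", regulation_mode=-1, reg_id="REG-2"),
    ]
    g = AnnotatedGraph()
    for v in vertices:
        g.add_vertex(v)
    for e in edges:
        g.add_edge(e)
    g.validate()
    labels = {"g1": "RD", "g2": "RD", "p1": "PI", "p2": "PI", "pc1": "PI",
              "r1": "MD", "c1": "MD", "c2": "MD"}
    return SyntheticNetwork(
        graph=g,
        partition=Partition(scheme="functional", n_domains=3, labels=labels),
        ambiguous=frozenset(),
    )


def generate_network(params: GeneratorParams) -> SyntheticNetwork:
    """Generate an annotated network with planted domain labels.

    Deterministic in ``params`` (including the seed).  The output passes
    schema validation, respects the edge-type grammar, and is weakly
    connected (minimal grammar-sound bridging edges are added if needed).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    g = AnnotatedGraph()
    planted: dict[str, str] = {}
    ambiguous: set[str] = set()

    no_regulation = params.regulation_density == 0.0

    genes = [f"G{i:04d}" for i in range(params.n_genes)]
    monomers = [f"P{i:04d}" for i in range(params.n_genes)]
    compounds = [f"C{i:04d}" for i in range(params.n_compounds)]
    reactions = [f"R{i:04d}" for i in range(params.n_reactions)]

    n_metab = int(round(params.metabolic_gene_fraction * params.n_genes))
    enzyme_idx = list(range(n_metab))
    tf_idx = list(range(n_metab, params.n_genes))
    if no_regulation:
        enzyme_idx, tf_idx = list(range(params.n_genes)), []

    for gid in genes:
        g.add_vertex(VertexRecord(gid, "gene"))
    for pid in monomers:
        g.add_vertex(VertexRecord(pid, "protein-monomer", compartment="c"))
    for cid in compounds:
        g.add_vertex(VertexRecord(cid, "compound", compartment="c"))
    for gid, pid in zip(genes, monomers):
        g.add_edge(EdgeRecord(gid, pid, "translation-encoding"))
    for cid in compounds:
        planted[cid] = "MD"

    # --- reactions: compound transformations catalyzed by enzymes ----------
    enzyme_pool = [monomers[i] for i in enzyme_idx]
    n_rev = int(round(params.reversible_fraction * params.n_reactions))
    for j, rid in enumerate(reactions):
        n_e = int(rng.integers(1, min(3, params.n_compounds - 1) + 1))
        educts = list(rng.choice(params.n_compounds, size=n_e, replace=False))
        remaining = [i for i in range(params.n_compounds) if i not in educts]
        n_p = int(rng.integers(1, min(2, len(remaining)) + 1))
        products = list(rng.choice(len(remaining), size=n_p, replace=False))
        products = [remaining[i] for i in products]
        rec = VertexRecord(rid, "reaction")
        if j < n_rev:
            rec.meta["reversible"] = True
        g.add_vertex(rec)
        planted[rid] = "MD"
        for ci in educts:
            g.add_edge(EdgeRecord(compounds[ci], rid, "educt",
                                  stoichiometry=int(rng.integers(1, 3))))
        for ci in products:
            g.add_edge(EdgeRecord(rid, compounds[ci], "product",
                                  stoichiometry=int(rng.integers(1, 3))))
        if enzyme_pool and rng.random() > 0.1:  # ~10% spontaneous
            enz = enzyme_pool[int(rng.integers(len(enzyme_pool)))]
            g.add_edge(EdgeRecord(enz, rid, "catalysis"))

    # --- enzymatic protein-protein complexes -------------------------------
    complexes: list[str] = []
    for i in range(params.n_protein_complexes):
        xid = f"CPLX{i:04d}"
        size = int(rng.integers(2, 4))
        comp = rng.choice(len(enzyme_pool), size=min(size, len(enzyme_pool)),
                          replace=False) if enzyme_pool else []
        g.add_vertex(VertexRecord(xid, "protein-protein-complex", compartment="c"))
        complexes.append(xid)
        for ci in comp:
            g.add_edge(EdgeRecord(enzyme_pool[int(ci)], xid, "complex-formation",
                                  stoichiometry=1))
        if params.n_reactions:
            rid = reactions[int(rng.integers(params.n_reactions))]
            if not g.nx.has_edge(xid, rid, key="catalysis"):
                g.add_edge(EdgeRecord(xid, rid, "catalysis"))

    # --- regulators ---------------------------------------------------------
    regulators: list[str] = []  # vertices that source regulation edges
    metabolic_tf_complexes: list[str] = []
    if not no_regulation:
        n_mtf = int(round(params.metabolic_tf_fraction * len(tf_idx)))
        mtf_idx = tf_idx[:n_mtf]
        plain_idx = tf_idx[n_mtf:]
        for i in plain_idx:
            regulators.append(monomers[i])
            planted[monomers[i]] = "RD"
        # reactions that can anchor a product-sensing feedback motif:
        # catalyzed by an enzyme monomer and emitting at least one product
        feedback_anchors = []
        for rid in reactions:
            enz = sorted(u for u, _, k in g.nx.in_edges(rid, keys=True)
                         if k == "catalysis"
                         and g.nx.nodes[u]["vtype"] == "protein-monomer")
            prods = sorted(w for _, w, k in g.nx.out_edges(rid, keys=True)
                           if k == "product")
            if enz and prods:
                feedback_anchors.append((rid, enz[0], prods[0]))
        pending_feedback: list[tuple[str, str]] = []  # (MTF, enzyme gene)
        for k, i in enumerate(mtf_idx):
            xid = f"MTF{k:04d}"
            if k % 2 == 0 and feedback_anchors:
                # product-sensing regulator: the effector is the product of a
                # reaction whose enzyme gene this TF will regulate (the
                # canonical metabolite -> TF -> enzyme-gene feedback motif)
                rid, enz, cid = feedback_anchors[int(rng.integers(len(feedback_anchors)))]
                gene_of_enz = genes[monomers.index(enz)]
                pending_feedback.append((xid, gene_of_enz))
            else:
                cid = compounds[int(rng.integers(params.n_compounds))]
            g.add_vertex(VertexRecord(xid, "protein-compound-complex", compartment="c"))
            g.add_edge(EdgeRecord(monomers[i], xid, "complex-formation", stoichiometry=1))
            g.add_edge(EdgeRecord(cid, xid, "complex-formation", stoichiometry=1))
            regulators.append(xid)
            metabolic_tf_complexes.append(xid)
            planted[xid] = "PI"
            planted[monomers[i]] = "PI"
        for k in range(params.n_protein_rna_complexes):
            xid = f"PRNA{k:04d}"
            gi = int(rng.integers(params.n_genes))
            pi = int(rng.integers(len(monomers)))
            g.add_vertex(VertexRecord(xid, "protein-RNA-complex", compartment="c"))
            g.add_edge(EdgeRecord(genes[gi], xid, "transcription-encoding"))
            if monomers[pi] not in g.nx or not g.nx.has_edge(monomers[pi], xid):
                g.add_edge(EdgeRecord(monomers[pi], xid, "complex-formation",
                                      stoichiometry=1))
            g.set_vertex_attr(xid, "name", f"sRNA-complex-{k}")
            regulators.append(xid)
            planted[xid] = "PI"
            # the sRNA gene and the partner monomer have mixed wiring; their
            # rule-based label depends on details the construction does not fix
            ambiguous.add(genes[gi])
            ambiguous.add(monomers[pi])

    # --- regulation edges: heavy-tailed regulator out-degree ----------------
    if regulators:
        weights = 1.0 / np.arange(1, len(regulators) + 1) ** 1.2  # zipf-ish
        weights /= weights.sum()
        targets = [i for i in range(params.n_genes)
                   if rng.random() < params.regulation_density]
        # every TF gene must itself be regulated, or its product's regulatory
        # role is invisible to wiring-based affiliation
        targets = sorted(set(targets) | set(tf_idx))
        for ti in targets:
            n_regs = 1 + (rng.random() < 0.15)
            for ridx in rng.choice(len(regulators), size=n_regs, replace=False,
                                   p=weights):
                reg = regulators[int(ridx)]
                if g.nx.has_edge(reg, genes[ti], key="regulation"):
                    continue
                mode = int(rng.choice([1, -1, 0], p=[0.55, 0.35, 0.10]))
                g.add_edge(EdgeRecord(reg, genes[ti], "regulation",
                                      regulation_mode=mode,
                                      reg_id=f"REG-{reg}-{genes[ti]}"))

        for xid, tgt_gene in pending_feedback:
            if not g.nx.has_edge(xid, tgt_gene, key="regulation"):
                g.add_edge(EdgeRecord(xid, tgt_gene, "regulation",
                                      regulation_mode=-1,
                                      reg_id=f"REG-{xid}-{tgt_gene}"))

        # non-transcriptional regulation: enzyme-activity / reaction
        # regulation (downward direct links) and metabolic-protein regulation
        # of TF genes (upward direct links)
        n_extra = int(round(params.nontranscriptional_fraction * len(targets)))
        wired_enzymes = [monomers[i] for i in enzyme_idx
                         if any(k in ("catalysis", "complex-formation")
                                for _, _, k in g.nx.out_edges(monomers[i], keys=True))]
        for j in range(n_extra):
            kind = j % 3
            ridx = int(rng.choice(len(regulators), p=weights))
            reg = regulators[ridx]
            mode = int(rng.choice([1, -1]))
            if kind == 0 and params.n_reactions:  # enzyme-activity: -> reaction
                tgt = reactions[int(rng.integers(params.n_reactions))]
            elif kind == 1 and wired_enzymes:  # -> enzyme protein
                tgt = wired_enzymes[int(rng.integers(len(wired_enzymes)))]
                ambiguous.add(tgt)  # its wiring now mixes a regulator in
            elif kind == 2 and wired_enzymes and tf_idx:
                # metabolic protein inhibiting/activating a TF gene
                reg = wired_enzymes[int(rng.integers(len(wired_enzymes)))]
                tgt = genes[tf_idx[int(rng.integers(len(tf_idx)))]]
            else:
                continue
            if reg != tgt and not g.nx.has_edge(reg, tgt, key="regulation"):
                g.add_edge(EdgeRecord(reg, tgt, "regulation",
                                      regulation_mode=mode,
                                      reg_id=f"REG-{reg}-{tgt}"))

    # --- planted labels for genes and remaining proteins --------------------
    regulated = {v for _, v, k in g.nx.edges(keys=True) if k == "regulation"}
    for i, gid in enumerate(genes):
        planted[gid] = "RD" if gid in regulated else "MD"
    for i in enzyme_idx:
        pid = monomers[i]
        wired = any(k in ("catalysis", "complex-formation")
                    for _, _, k in g.nx.out_edges(pid, keys=True))
        if genes[i] in regulated:
            planted[pid] = "PI" if wired else "RD"
            if not wired:
                # an enzyme by role but without metabolic wiring: its
                # rule-based label follows its regulated gene
                ambiguous.add(pid)
        else:
            planted[pid] = "MD"
    for i in tf_idx:
        planted.setdefault(monomers[i], "RD")
    for xid in complexes:
        # enzymatic complex: metabolic by wiring; its subunits sit between
        # their (possibly regulated) genes and the complex
        planted[xid] = "MD"
    for gid, pid in zip(genes, monomers):
        planted.setdefault(pid, "MD")

    # --- enforce weak connectivity with grammar-sound bridges ---------------
    comps = sorted(nx.weakly_connected_components(g.nx), key=len, reverse=True)
    if len(comps) > 1 and params.n_reactions:
        main_reaction = reactions[0]
        main = comps[0]
        for comp in comps[1:]:
            cands = sorted(v for v in comp if g.nx.nodes[v]["vtype"] == "compound")
            if cands:
                g.add_edge(EdgeRecord(cands[0], main_reaction, "educt", stoichiometry=1))
                continue
            prots = sorted(v for v in comp
                           if g.nx.nodes[v]["vtype"] == "protein-monomer")
            if prots:
                g.add_edge(EdgeRecord(prots[0], main_reaction, "catalysis"))
                ambiguous.add(prots[0])
                continue
            anyv = min(comp)
            ambiguous.add(anyv)
            if g.nx.nodes[anyv]["vtype"] == "gene":
                tgt = sorted(v for v in main if g.nx.nodes[v]["vtype"] == "gene")
                g.add_edge(EdgeRecord(anyv, tgt[0], "regulation", regulation_mode=0,
                                      reg_id=f"REG-BRIDGE-{anyv}"))

    g.validate()
    part = Partition(scheme="functional", n_domains=3, labels=dict(planted))
    for vid in g.nx.nodes:
        part.labels.setdefault(vid, "MD")
    return SyntheticNetwork(graph=g, partition=part, ambiguous=frozenset(ambiguous))


# ---------------------------------------------------------------------------
# Flat-file emission (miniature attribute-value fixture files)
# ---------------------------------------------------------------------------

FLAT_FILES = ("regulation.dat", "reactions.dat", "compounds.dat", "proteins.dat",
              "genes.dat", "rnas.dat", "classes.dat", "protcplxs.col")

_HEADER = "# synthetic attribute-value fixture file\n"


def emit_flat_files(g: AnnotatedGraph, directory) -> None:
    """Serialize an annotated graph as miniature database flat files.

    The files use the attribute-value dialect understood by the
    reconstruction stage (UNIQUE-ID records, ``//`` terminators, ``/``
    continuation lines, ``^`` sub-attributes); reconstruction of the emitted
    directory yields a graph isomorphic to the largest weakly connected
    component of ``g``.  An empty graph produces header-only files.
    """
    os.makedirs(directory, exist_ok=True)
    gnx = g.nx
    by_type: dict[str, list[str]] = {}
    for vid in sorted(gnx.nodes):
        by_type.setdefault(gnx.nodes[vid]["vtype"], []).append(vid)

    def a(fh, key, value, subattrs=()):
        fh.write(f"{key} - {value}\n")
        for sk, sv in subattrs:
            fh.write(f"^{sk} - {sv}\n")

    # genes.dat: regulated genes belong to a single-gene transcription unit
    regulated = sorted({v for _, v, k in gnx.edges(keys=True)
                        if k == "regulation" and gnx.nodes[v]["vtype"] == "gene"})
    with open(os.path.join(directory, "genes.dat"), "w") as fh:
        fh.write(_HEADER)
        for vid in by_type.get("gene", []):
            a(fh, "UNIQUE-ID", vid)
            name = gnx.nodes[vid].get("name")
            if name:
                a(fh, "COMMON-NAME", name)
            for _, w, k in gnx.out_edges(vid, keys=True):
                if k == "translation-encoding":
                    a(fh, "PRODUCT", w)
                elif k == "transcription-encoding":
                    a(fh, "PRODUCT", f"RNA-{vid}")
            if vid in regulated:
                a(fh, "COMPONENT-OF", f"TU-{vid}")
            fh.write("//\n")

    # rnas.dat: one RNA per gene that transcription-encodes a complex
    with open(os.path.join(directory, "rnas.dat"), "w") as fh:
        fh.write(_HEADER)
        for u, w, k in sorted(gnx.edges(keys=True)):
            if k == "transcription-encoding":
                a(fh, "UNIQUE-ID", f"RNA-{u}")
                a(fh, "GENE", u)
                fh.write("//\n")

    with open(os.path.join(directory, "compounds.dat"), "w") as fh:
        fh.write(_HEADER)
        for vid in by_type.get("compound", []):
            a(fh, "UNIQUE-ID", vid)
            name = gnx.nodes[vid].get("name")
            if name:
                a(fh, "COMMON-NAME", name)
            fh.write("//\n")

    prot_types = ("protein-monomer", "protein-protein-complex",
                  "protein-compound-complex", "protein-RNA-complex")
    with open(os.path.join(directory, "proteins.dat"), "w") as fh:
        fh.write(_HEADER)
        for vt in prot_types:
            for vid in by_type.get(vt, []):
                a(fh, "UNIQUE-ID", vid)
                comp = gnx.nodes[vid].get("compartment")
                if comp:
                    a(fh, "COMPARTMENT", comp)
                for u, _, k, d in gnx.in_edges(vid, keys=True, data=True):
                    if k == "complex-formation":
                        a(fh, "COMPONENTS", u,
                          [("COEFFICIENT", d.get("stoichiometry", 1) or 1)])
                    elif k == "translation-encoding":
                        a(fh, "GENE", u)
                    elif k == "transcription-encoding":
                        a(fh, "COMPONENTS", f"RNA-{u}", [("COEFFICIENT", 1)])
                fh.write("//\n")

    with open(os.path.join(directory, "reactions.dat"), "w") as fh:
        fh.write(_HEADER)
        for vid in by_type.get("reaction", []):
            a(fh, "UNIQUE-ID", vid)
            direction = ("REVERSIBLE" if gnx.nodes[vid].get("reversible")
                         else "LEFT-TO-RIGHT")
            a(fh, "REACTION-DIRECTION", direction)
            for u, _, k, d in sorted(gnx.in_edges(vid, keys=True, data=True)):
                if k == "educt":
                    subs = [("COEFFICIENT", d.get("stoichiometry", 1) or 1)]
                    c = gnx.nodes[u].get("compartment")
                    if c:
                        subs.append(("COMPARTMENT", c))
                    a(fh, "LEFT", u, subs)
                elif k == "catalysis":
                    a(fh, "ENZYMES", u)
            for _, w, k, d in sorted(gnx.out_edges(vid, keys=True, data=True)):
                if k == "product":
                    subs = [("COEFFICIENT", d.get("stoichiometry", 1) or 1)]
                    c = gnx.nodes[w].get("compartment")
                    if c:
                        subs.append(("COMPARTMENT", c))
                    a(fh, "RIGHT", w, subs)
            fh.write("//\n")

    with open(os.path.join(directory, "regulation.dat"), "w") as fh:
        fh.write(_HEADER)
        n = 0
        for u, w, k, d in sorted(gnx.edges(keys=True, data=True)):
            if k != "regulation":
                continue
            n += 1
            a(fh, "UNIQUE-ID", d.get("reg_id") or f"REG{n:05d}")
            a(fh, "REGULATOR", u)
            if gnx.nodes[w]["vtype"] == "gene":
                a(fh, "REGULATED-ENTITY", f"TU-{w}")
            else:
                a(fh, "REGULATED-ENTITY", w)
            mode = d.get("regulation_mode", 0)
            a(fh, "MODE", {1: "+", -1: "-", 0: "+/-"}[mode])
            fh.write("//\n")

    with open(os.path.join(directory, "classes.dat"), "w") as fh:
        fh.write(_HEADER)

    with open(os.path.join(directory, "protcplxs.col"), "w") as fh:
        fh.write("# synthetic tab-delimited complex table\n")
        fh.write("UNIQUE-ID\tNAME\tSUBUNIT-COMPOSITION\n")
        for vt in prot_types[1:]:
            for vid in by_type.get(vt, []):
                parts = sorted(u for u, _, k in gnx.in_edges(vid, keys=True)
                               if k == "complex-formation")
                fh.write(f"{vid}\t{gnx.nodes[vid].get('name') or vid}\t"
                         + "*1 ".join(parts) + ("*1" if parts else "") + "\n")
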