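"""Reduced-fidelity reconstruction from attribute-value database flat files.

Parses the BioCyc-style attribute-value dialect (``UNIQUE-ID`` keyed records,
``//`` terminators, ``/`` continuation lines, ``^`` sub-attribute
annotations), validates vertex candidates into the seven vertex types, and
assembles the annotated graph: regulation processes are multiplied over the
genes of the target transcription unit, regulating RNAs are translated into
their encoding genes, reversible reactions are split into two oppositely
oriented reaction vertices, and any process citing an unidentified
participant is dropped with a report entry.

Fixture-dialect conventions (this parser is exercised on miniature synthetic
flat files, not on a licensed database download):

* transcription-unit membership is read from the genes' ``COMPONENT-OF``
  attribute (a TU exists iff some gene lists it);
* enzymes are attached through a simplified ``ENZYMES`` attribute on
  reaction records;
* double annotations (two accessions for one entity) are declared with a
  ``CANONICAL-FORM`` attribute on the alias record — a synthetic stand-in
  for the database's alias mechanism;
* generic class terms are records in ``classes.dat``; their members are the
  records whose ``TYPES`` attribute names the class.

Anything else in the input is carried along as opaque record attributes.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from .graph import (
    AnnotatedGraph,
    EdgeRecord,
    VertexRecord,
    largest_weakly_connected_component,
)

log = logging.getLogger(__name__)

DAT_FILES = (
    "regulation.dat",
    "reactions.dat",
    "compounds.dat",
    "proteins.dat",
    "genes.dat",
    "rnas.dat",
    "classes.dat",
)
COL_FILES = ("protcplxs.col",)

#: Compartments retained for reactions (cytosol, periplasm, inner membrane).
REACTION_COMPARTMENTS = frozenset({"c", "p", "i"})


class FlatFileError(ValueError):
    """Malformed attribute-value record (strict mode)."""


@dataclass
class AttrValue:
    value: str
    annotations: dict[str, str] = field(default_factory=dict)


#: One record: accession -> attribute multimap (attr key -> list of values).
Record = dict[str, list[AttrValue]]


@dataclass
class RawRecordSet:
    """Parsed per-file keyed record lists."""

    files: dict[str, dict[str, Record]] = field(default_factory=dict)
    #: rows of tab-delimited .col files, keyed by file name
    tables: dict[str, list[dict[str, str]]] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def records(self, fname: str) -> dict[str, Record]:
        return self.files.get(fname, {})

    def get1(self, fname: str, acc: str, attr: str) -> str | None:
        rec = self.records(fname).get(acc)
        if not rec or attr not in rec or not rec[attr]:
            return None
        return rec[attr][0].value

    def getall(self, fname: str, acc: str, attr: str) -> list[AttrValue]:
        rec = self.records(fname).get(acc)
        return list(rec.get(attr, ())) if rec else []


def _parse_dat(path: str, strict: bool, skipped: list[str]) -> dict[str, Record]:
    """Parse one attribute-value file.

    Comment lines start with ``#``; ``ATTR - VALUE`` lines open attribute
    occurrences; ``/``-prefixed lines continue the previous value;
    ``^SUB - VALUE`` lines annotate the previous attribute occurrence;
    ``//`` closes a record.  A record must open with ``UNIQUE-ID``.
    """
    records: dict[str, Record] = {}
    current: Record = {}
    acc: str | None = None
    last: AttrValue | None = None

    def close(lineno: int):
        nonlocal current, acc, last
        if current:
            if acc is None:
                msg = f"{os.path.basename(path)}:{lineno}: record without UNIQUE-ID"
                if strict:
                    raise FlatFileError(msg)
                skipped.append(msg)
                log.warning("%s (skipped)", msg)
            else:
                records[acc] = current
        current, acc, last = {}, None, None

    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line == "//":
                close(lineno)
                continue
            if line.startswith("^"):
                body = line[1:]
                if " - " in body and last is not None:
                    k, v = body.split(" - ", 1)
                    last.annotations[k] = v
                continue
            if line.startswith("/"):
                if last is not None:
                    last.value = f"{last.value} {line[1:].strip()}"
                continue
            if " - " not in line:
                msg = f"{os.path.basename(path)}:{lineno}: malformed line {line!r}"
                if strict:
                    raise FlatFileError(msg)
                skipped.append(msg)
                continue
            key, value = line.split(" - ", 1)
            last = AttrValue(value)
            current.setdefault(key, []).append(last)
            if key == "UNIQUE-ID":
                if acc is not None:
                    msg = f"{os.path.basename(path)}:{lineno}: duplicate UNIQUE-ID in record"
                    if strict:
                        raise FlatFileError(msg)
                    skipped.append(msg)
                acc = value.strip()
        close(lineno)
    return records


def _parse_col(path: str) -> list[dict[str, str]]:
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                continue
            rows.append(dict(zip(header, cells)))
    return rows


def parse_flat_files(directory, strict: bool = False) -> RawRecordSet:
    """Parse the eight named flat files of ``directory``.

    Missing files are allowed (empty record lists) unless ``strict`` is set.
    Malformed records raise :class:`FlatFileError` with a line number when
    strict, and are skipped and logged otherwise.  Parsing is idempotent.
    """
    raw = RawRecordSet()
    for fname in DAT_FILES:
        path = os.path.join(directory, fname)
        if not os.path.exists(path):
            if strict:
                raise FlatFileError(f"missing flat file {fname!r} in {directory!r}")
            raw.files[fname] = {}
            continue
        raw.files[fname] = _parse_dat(path, strict, raw.skipped)
    for fname in COL_FILES:
        path = os.path.join(directory, fname)
        raw.tables[fname] = _parse_col(path) if os.path.exists(path) else []
    return raw


# ---------------------------------------------------------------------------
# Candidate validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """What the validation stage accepted, substituted and dropped."""

    accepted: dict[str, int] = field(default_factory=dict)  # vtype -> count
    aliases: dict[str, str] = field(default_factory=dict)  # alias -> canonical
    class_members: dict[str, list[str]] = field(default_factory=dict)
    defaulted_compartments: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (acc, reason)
    dropped_processes: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


def build_candidate_vertices(raw: RawRecordSet) -> tuple[dict[str, VertexRecord], ValidationReport]:
    """Classify database records into the seven vertex types.

    Protein records are subclassified by composition: no components ->
    monomer; all-protein components -> protein-protein complex; any compound
    component -> protein-compound complex; any RNA component -> protein-RNA
    complex.  Alias records (``CANONICAL-FORM``) become log entries, not
    vertices; class terms never become vertices — their members (records
    whose ``TYPES`` names the class) stand in for them.
    """
    report = ValidationReport()
    vertices: dict[str, VertexRecord] = {}

    classes = set(raw.records("classes.dat"))
    for fname in ("compounds.dat", "proteins.dat"):
        for acc in raw.records(fname):
            for tv in raw.getall(fname, acc, "TYPES"):
                if tv.value in classes:
                    report.class_members.setdefault(tv.value, []).append(acc)

    def alias_of(fname: str, acc: str) -> str | None:
        return raw.get1(fname, acc, "CANONICAL-FORM")

    compound_ids = set(raw.records("compounds.dat"))
    rna_ids = set(raw.records("rnas.dat"))
    protein_ids = set(raw.records("proteins.dat"))

    for acc in sorted(raw.records("compounds.dat")):
        canon = alias_of("compounds.dat", acc)
        if canon:
            report.aliases[acc] = canon
            continue
        rec = VertexRecord(acc, "compound", compartment="c",
                           name=raw.get1("compounds.dat", acc, "COMMON-NAME"))
        vertices[acc] = rec

    for acc in sorted(raw.records("genes.dat")):
        vertices[acc] = VertexRecord(
            acc, "gene", name=raw.get1("genes.dat", acc, "COMMON-NAME"))

    for acc in sorted(raw.records("proteins.dat")):
        canon = alias_of("proteins.dat", acc)
        if canon:
            report.aliases[acc] = canon
            continue
        comps = [c.value for c in raw.getall("proteins.dat", acc, "COMPONENTS")]
        if not comps:
            vtype = "protein-monomer"
        elif any(c in rna_ids for c in comps):
            vtype = "protein-RNA-complex"
        elif any(c in compound_ids for c in comps):
            vtype = "protein-compound-complex"
        elif all(c in protein_ids for c in comps):
            vtype = "protein-protein-complex"
        else:
            report.rejected.append((acc, "components match no vertex type"))
            continue
        comp = raw.get1("proteins.dat", acc, "COMPARTMENT")
        if comp is None:
            comp = "c"
            report.defaulted_compartments.append(acc)
        vertices[acc] = VertexRecord(acc, vtype, compartment=comp,
                                     name=raw.get1("proteins.dat", acc, "COMMON-NAME"))

    for acc in sorted(raw.records("reactions.dat")):
        vertices[acc] = VertexRecord(acc, "reaction",
                                     name=raw.get1("reactions.dat", acc, "EC-NUMBER"))

    for rec in vertices.values():
        report.accepted[rec.vtype] = report.accepted.get(rec.vtype, 0) + 1
    return vertices, report


# ---------------------------------------------------------------------------
# Edge construction
# ---------------------------------------------------------------------------


def _resolve(
    acc: str,
    raw: RawRecordSet,
    vertices: dict[str, VertexRecord],
    report: ValidationReport,
) -> list[str] | None:
    """Map a cited accession to concrete vertex ids.

    Applies alias decoding, RNA-to-encoding-gene translation and generic-term
    substitution.  Returns None when the accession cannot be identified.
    """
    acc = report.aliases.get(acc, acc)
    if acc in vertices:
        return [acc]
    if acc in raw.records("rnas.dat"):
        gene = raw.get1("rnas.dat", acc, "GENE")
        if gene and gene in vertices:
            return [gene]
        return None
    if acc in report.class_members:
        out: list[str] = []
        for m in report.class_members[acc]:
            sub = _resolve(m, raw, vertices, report)
            if sub:
                out.extend(sub)
        return out or None
    return None


def _add_edge(edges: dict[tuple[str, str, str], EdgeRecord], rec: EdgeRecord) -> None:
    """Deduplicate on the (source, target, etype) triple; colliding
    regulation edges merge their modes (disagreement -> combined, 0)."""
    key = (rec.source, rec.target, rec.etype)
    old = edges.get(key)
    if old is None:
        edges[key] = rec
    elif rec.etype == "regulation" and old.regulation_mode != rec.regulation_mode:
        old.regulation_mode = 0


def build_edges(
    raw: RawRecordSet,
    vertices: dict[str, VertexRecord],
    report: ValidationReport | None = None,
) -> tuple[list[EdgeRecord], ValidationReport]:
    """Build the validated edge list (and any split reaction vertices).

    Reversible reactions are split into ``ACC`` and ``ACC__REV`` with swapped
    educt/product edges (the ``__REV`` vertex is added to ``vertices``).
    Regulation of a transcription unit is multiplied over its member genes;
    a TU without genes drops the process.  Reactions citing compartments
    outside cytosol/periplasm/inner membrane are dropped, as is any process
    with an unidentified participant.
    """
    if report is None:
        report = ValidationReport()
    edges: dict[tuple[str, str, str], EdgeRecord] = {}

    # transcription units, from the genes' COMPONENT-OF attributes
    tu_genes: dict[str, list[str]] = {}
    for acc in raw.records("genes.dat"):
        for tv in raw.getall("genes.dat", acc, "COMPONENT-OF"):
            tu_genes.setdefault(tv.value, []).append(acc)

    # --- encoding edges ----------------------------------------------------
    for acc in sorted(raw.records("genes.dat")):
        if acc not in vertices:
            continue
        for pv in raw.getall("genes.dat", acc, "PRODUCT"):
            prod = pv.value
            if prod in vertices and vertices[prod].vtype.startswith("protein"):
                _add_edge(edges, EdgeRecord(acc, prod, "translation-encoding"))
            # RNA products contribute transcription-encoding edges into the
            # complexes that contain them (below), not vertices of their own

    # --- protein composition ----------------------------------------------
    for acc in sorted(raw.records("proteins.dat")):
        if acc not in vertices:
            continue
        ok = True
        staged: list[EdgeRecord] = []
        for cv in raw.getall("proteins.dat", acc, "COMPONENTS"):
            coeff = int(cv.annotations.get("COEFFICIENT", 1))
            if cv.value in raw.records("rnas.dat"):
                gene = raw.get1("rnas.dat", cv.value, "GENE")
                if gene and gene in vertices:
                    staged.append(EdgeRecord(gene, acc, "transcription-encoding"))
                else:
                    ok = False
                continue
            resolved = _resolve(cv.value, raw, vertices, report)
            if not resolved:
                ok = False
                continue
            for comp in resolved:
                staged.append(EdgeRecord(comp, acc, "complex-formation",
                                         stoichiometry=coeff))
        gene = raw.get1("proteins.dat", acc, "GENE")
        if gene:
            if gene in vertices:
                staged.append(EdgeRecord(gene, acc, "translation-encoding"))
            else:
                ok = False
        if ok:
            for e in staged:
                _add_edge(edges, e)
        else:
            report.dropped_processes.append((acc, "unidentified component"))

    # --- reactions ---------------------------------------------------------
    for acc in sorted(raw.records("reactions.dat")):
        if acc not in vertices:
            continue
        direction = (raw.get1("reactions.dat", acc, "REACTION-DIRECTION")
                     or "LEFT-TO-RIGHT")
        lefts = raw.getall("reactions.dat", acc, "LEFT")
        rights = raw.getall("reactions.dat", acc, "RIGHT")
        if "RIGHT-TO-LEFT" in direction:
            lefts, rights = rights, lefts
        comps = {av.annotations.get("COMPARTMENT", "c") for av in lefts + rights}
        if not comps <= REACTION_COMPARTMENTS:
            report.dropped_processes.append(
                (acc, f"compartments {sorted(comps - REACTION_COMPARTMENTS)} not retained"))
            del vertices[acc]
            continue
        participants: list[tuple[list[str], int, bool]] = []  # (ids, stoich, is_educt)
        ok = True
        for av, is_educt in [(x, True) for x in lefts] + [(x, False) for x in rights]:
            resolved = _resolve(av.value, raw, vertices, report)
            if not resolved:
                ok = False
                break
            coeff = int(av.annotations.get("COEFFICIENT", 0) or 0)
            participants.append((resolved, coeff, is_educt))
        enzymes: list[str] = []
        if ok:
            for ev in raw.getall("reactions.dat", acc, "ENZYMES"):
                resolved = _resolve(ev.value, raw, vertices, report)
                if not resolved:
                    ok = False
                    break
                enzymes.extend(resolved)
        if not ok:
            report.dropped_processes.append((acc, "unidentified participant"))
            del vertices[acc]
            continue
        targets = [acc]
        if "REVERSIBLE" in direction:
            rev = acc + "__REV"
            vertices[rev] = VertexRecord(rev, "reaction",
                                         name=vertices[acc].name,
                                         meta={"reverse_of": acc})
            targets.append(rev)
        for i, rid in enumerate(targets):
            swap = i == 1
            for ids, coeff, is_educt in participants:
                educt = is_educt != swap
                for pid in ids:
                    if educt:
                        _add_edge(edges, EdgeRecord(pid, rid, "educt",
                                                    stoichiometry=coeff))
                    else:
                        _add_edge(edges, EdgeRecord(rid, pid, "product",
                                                    stoichiometry=coeff))
            for enz in enzymes:
                _add_edge(edges, EdgeRecord(enz, rid, "catalysis"))

    # --- regulation --------------------------------------------------------
    for acc in sorted(raw.records("regulation.dat")):
        regulator = raw.get1("regulation.dat", acc, "REGULATOR")
        entity = raw.get1("regulation.dat", acc, "REGULATED-ENTITY")
        mode_s = raw.get1("regulation.dat", acc, "MODE") or ""
        mode = {"+": 1, "-": -1}.get(mode_s.strip(), 0)
        name = raw.get1("regulation.dat", acc, "MECHANISM")
        if regulator is None or entity is None:
            report.dropped_processes.append((acc, "incomplete regulation record"))
            continue
        sources = _resolve(regulator, raw, vertices, report)
        if not sources:
            report.dropped_processes.append((acc, f"unidentified regulator {regulator!r}"))
            continue
        if entity in tu_genes:
            targets = [gid for gid in tu_genes[entity] if gid in vertices]
            if not targets:
                report.dropped_processes.append(
                    (acc, f"transcription unit {entity!r} has no genes"))
                continue
        else:
            targets = _resolve(entity, raw, vertices, report)
            if not targets:
                report.dropped_processes.append(
                    (acc, f"unidentified regulated entity {entity!r}"))
                continue
        for src in sources:
            for tgt in targets:
                _add_edge(edges, EdgeRecord(src, tgt, "regulation",
                                            regulation_mode=mode,
                                            reg_id=acc, reg_name=name))

    return list(edges.values()), report


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionResult:
    full: AnnotatedGraph
    wcc: AnnotatedGraph
    report: ValidationReport


def assemble_network(
    vertices: dict[str, VertexRecord],
    edges: list[EdgeRecord],
    report: ValidationReport | None = None,
) -> ReconstructionResult:
    """Build the validated graph and extract its largest weak component."""
    g = AnnotatedGraph()
    for rec in vertices.values():
        g.add_vertex(rec)
    for e in edges:
        g.add_edge(e)
    g.validate()
    return ReconstructionResult(
        full=g,
        wcc=largest_weakly_connected_component(g),
        report=report or ValidationReport(),
    )


def reconstruct(directory, strict: bool = False) -> ReconstructionResult:
    """End-to-end reconstruction: parse, validate, wire, assemble."""
    raw = parse_flat_files(directory, strict=strict)
    vertices, report = build_candidate_vertices(raw)
    edges, report = build_edges(raw, vertices, report)
    return assemble_network(vertices, edges, report)
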