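"""Attribute-value flat-file parsing and graph reconstruction."""

import os

import pytest

from regmet.ecocyc import (
    FlatFileError,
    assemble_network,
    build_candidate_vertices,
    build_edges,
    parse_flat_files,
    reconstruct,
)


def write(dirpath, name, text):
    with open(os.path.join(dirpath, name), "w") as fh:
        fh.write(text)


@pytest.fixture
def fixture_dir(tmp_path):
    """A small consistent flat-file set: one reversible reaction A <-> B
    catalyzed by an enzyme, one 3-gene transcription unit regulated by a
    metabolic TF complex, one class term with two member compounds, and one
    alias record."""
    write(tmp_path, "compounds.dat", "\n".join([
        "# header comment",
        "UNIQUE-ID - CPD-A", "COMMON-NAME - alanine", "//",
        "UNIQUE-ID - CPD-B", "//",
        "UNIQUE-ID - CPD-EFF", "//",
        "UNIQUE-ID - CPD-M1", "TYPES - DIPEPTIDES", "//",
        "UNIQUE-ID - CPD-M2", "TYPES - DIPEPTIDES", "//",
        "UNIQUE-ID - CPD-ALIAS", "CANONICAL-FORM - CPD-B", "//",
    ]) + "\n")
    write(tmp_path, "classes.dat", "UNIQUE-ID - DIPEPTIDES\n//\n")
    write(tmp_path, "genes.dat", "\n".join([
        "UNIQUE-ID - GENE-E", "PRODUCT - PROT-E", "//",
        "UNIQUE-ID - GENE-1", "PRODUCT - PROT-1", "COMPONENT-OF - TU-OP", "//",
        "UNIQUE-ID - GENE-2", "PRODUCT - PROT-2", "COMPONENT-OF - TU-OP", "//",
        "UNIQUE-ID - GENE-3", "PRODUCT - PROT-3", "COMPONENT-OF - TU-OP", "//",
        "UNIQUE-ID - GENE-T", "PRODUCT - PROT-T", "//",
    ]) + "\n")
    write(tmp_path, "rnas.dat", "")
    write(tmp_path, "proteins.dat", "\n".join([
        "UNIQUE-ID - PROT-E", "GENE - GENE-E", "//",
        "UNIQUE-ID - PROT-1", "GENE - GENE-1", "//",
        "UNIQUE-ID - PROT-2", "GENE - GENE-2", "//",
        "UNIQUE-ID - PROT-3", "GENE - GENE-3", "//",
        "UNIQUE-ID - PROT-T", "GENE - GENE-T", "//",
        "UNIQUE-ID - CPLX-TF",
        "COMPONENTS - PROT-T", "^COEFFICIENT - 2",
        "COMPONENTS - CPD-EFF", "^COEFFICIENT - 1",
        "//",
    ]) + "\n")
    write(tmp_path, "reactions.dat", "\n".join([
        "UNIQUE-ID - RXN-1",
        "REACTION-DIRECTION - REVERSIBLE",
        "LEFT - CPD-A", "^COEFFICIENT - 1",
        "RIGHT - CPD-ALIAS", "^COEFFICIENT - 2",
        "ENZYMES - PROT-E",
        "//",
    ]) + "\n")
    write(tmp_path, "regulation.dat", "\n".join([
        "UNIQUE-ID - REG-OP",
        "REGULATOR - CPLX-TF",
        "REGULATED-ENTITY - TU-OP",
        "MODE - +",
        "//",
    ]) + "\n")
    write(tmp_path, "protcplxs.col",
          "UNIQUE-ID\tNAME\tSUBUNIT-COMPOSITION\nCPLX-TF\ttf\tPROT-T*2\n")
    return tmp_path


class TestParser:
    def test_record_counts(self, fixture_dir):
        raw = parse_flat_files(fixture_dir)
        assert len(raw.records("reactions.dat")) == 1
        assert len(raw.records("genes.dat")) == 5
        assert len(raw.records("compounds.dat")) == 6

    def test_comment_only_file_yields_no_records(self, tmp_path):
        write(tmp_path, "reactions.dat", "# only a comment\n# another\n")
        raw = parse_flat_files(tmp_path)
        assert raw.records("reactions.dat") == {}

    def test_continuation_line_concatenates(self, tmp_path):
        write(tmp_path, "regulation.dat", "\n".join([
            "UNIQUE-ID - REG-X",
            "COMMENT - binding of the effector",
            "/to the amino-terminal domain",
            "//",
        ]) + "\n")
        raw = parse_flat_files(tmp_path)
        assert raw.get1("regulation.dat", "REG-X", "COMMENT") == \
            "binding of the effector to the amino-terminal domain"

    def test_sub_attribute_annotations(self, fixture_dir):
        raw = parse_flat_files(fixture_dir)
        right = raw.getall("reactions.dat", "RXN-1", "RIGHT")
        assert right[0].annotations["COEFFICIENT"] == "2"

    def test_strict_mode_raises_with_line_number(self, tmp_path):
        from regmet.ecocyc import DAT_FILES

        for name in DAT_FILES:
            write(tmp_path, name, "")
        write(tmp_path, "genes.dat", "COMMON-NAME - orphan attribute\n//\n")
        with pytest.raises(FlatFileError, match=r"genes.dat:2"):
            parse_flat_files(tmp_path, strict=True)

    def test_lenient_mode_skips_and_logs(self, tmp_path):
        write(tmp_path, "genes.dat",
              "COMMON-NAME - orphan\n//\nUNIQUE-ID - GENE-OK\n//\n")
        raw = parse_flat_files(tmp_path)
        assert list(raw.records("genes.dat")) == ["GENE-OK"]
        assert any("genes.dat" in s for s in raw.skipped)

    def test_missing_files_allowed_when_lenient(self, tmp_path):
        raw = parse_flat_files(tmp_path)
        assert raw.records("reactions.dat") == {}
        with pytest.raises(FlatFileError, match="missing flat file"):
            parse_flat_files(tmp_path, strict=True)

    def test_parsing_is_idempotent(self, fixture_dir):
        a = parse_flat_files(fixture_dir)
        b = parse_flat_files(fixture_dir)
        assert a.files == b.files and a.tables == b.tables


class TestCandidates:
    def test_protein_with_compound_ligand_is_protein_compound_complex(self, fixture_dir):
        raw = parse_flat_files(fixture_dir)
        vertices, _ = build_candidate_vertices(raw)
        assert vertices["CPLX-TF"].vtype == "protein-compound-complex"

    def test_monomer_and_gene_classification(self, fixture_dir):
        raw = parse_flat_files(fixture_dir)
        vertices, report = build_candidate_vertices(raw)
        assert vertices["PROT-E"].vtype == "protein-monomer"
        assert vertices["GENE-1"].vtype == "gene"
        assert report.accepted["gene"] == 5

    def test_class_term_substituted_by_members(self, fixture_dir):
        raw = parse_flat_files(fixture_dir)
        vertices, report = build_candidate_vertices(raw)
        assert "DIPEPTIDES" not in vertices
        assert set(report.class_members["DIPEPTIDES"]) == {"CPD-M1", "CPD-M2"}
        assert {"CPD-M1", "CPD-M2"} <= set(vertices)

    def test_alias_resolved_to_canonical(self, fixture_dir):
        raw = parse_flat_files(fixture_dir)
        vertices, report = build_candidate_vertices(raw)
        assert "CPD-ALIAS" not in vertices
        assert report.aliases["CPD-ALIAS"] == "CPD-B"


class TestEdges:
    def _build(self, d):
        raw = parse_flat_files(d)
        vertices, report = build_candidate_vertices(raw)
        return raw, vertices, build_edges(raw, vertices, report)

    def test_reversible_reaction_split(self, fixture_dir):
        raw, vertices, (edges, _) = self._build(fixture_dir)
        rxns = [v for v, rec in vertices.items() if rec.vtype == "reaction"]
        assert sorted(rxns) == ["RXN-1", "RXN-1__REV"]
        ep = [(e.source, e.target, e.etype) for e in edges
              if e.etype in ("educt", "product")]
        assert ("CPD-A", "RXN-1", "educt") in ep
        assert ("RXN-1", "CPD-B", "product") in ep  # alias decoded
        assert ("CPD-B", "RXN-1__REV", "educt") in ep
        assert ("RXN-1__REV", "CPD-A", "product") in ep
        assert len(ep) == 4

    def test_split_preserves_stoichiometry_under_swap(self, fixture_dir):
        _, _, (edges, _) = self._build(fixture_dir)
        fwd = {(e.source, e.target): e.stoichiometry for e in edges
               if "RXN-1" in (e.source, e.target) and "__REV" not in e.source + e.target
               and e.etype in ("educt", "product")}
        rev = {(e.source, e.target): e.stoichiometry for e in edges
               if "__REV" in e.source + e.target and e.etype in ("educt", "product")}
        assert fwd[("CPD-A", "RXN-1")] == rev[("RXN-1__REV", "CPD-A")] == 1
        assert fwd[("RXN-1", "CPD-B")] == rev[("CPD-B", "RXN-1__REV")] == 2

    def test_regulation_multiplied_per_operon_gene(self, fixture_dir):
        _, _, (edges, _) = self._build(fixture_dir)
        regs = [(e.source, e.target) for e in edges if e.etype == "regulation"]
        assert sorted(regs) == [("CPLX-TF", "GENE-1"), ("CPLX-TF", "GENE-2"),
                                ("CPLX-TF", "GENE-3")]
        modes = {e.regulation_mode for e in edges if e.etype == "regulation"}
        assert modes == {1}

    def test_enzyme_catalysis_on_both_split_directions(self, fixture_dir):
        _, _, (edges, _) = self._build(fixture_dir)
        cats = sorted((e.source, e.target) for e in edges if e.etype == "catalysis")
        assert cats == [("PROT-E", "RXN-1"), ("PROT-E", "RXN-1__REV")]

    def test_unidentified_participant_drops_whole_process(self, tmp_path):
        write(tmp_path, "compounds.dat", "UNIQUE-ID - CPD-A\n//\n")
        write(tmp_path, "reactions.dat", "\n".join([
            "UNIQUE-ID - RXN-BAD", "LEFT - CPD-A", "RIGHT - CPD-UNKNOWN", "//",
        ]) + "\n")
        res = reconstruct(tmp_path)
        assert all(res.full.vtype(v) != "reaction" for v in res.full.nx.nodes)
        assert any(pid == "RXN-BAD" for pid, _ in res.report.dropped_processes)

    def test_transcription_unit_without_genes_dropped(self, tmp_path):
        write(tmp_path, "proteins.dat", "UNIQUE-ID - PROT-X\n//\n")
        write(tmp_path, "regulation.dat", "\n".join([
            "UNIQUE-ID - REG-BAD", "REGULATOR - PROT-X",
            "REGULATED-ENTITY - TU-EMPTY", "MODE - -", "//",
        ]) + "\n")
        res = reconstruct(tmp_path)
        assert res.full.n_edges == 0
        assert any("REG-BAD" == pid for pid, _ in res.report.dropped_processes)

    def test_foreign_compartment_reaction_dropped(self, tmp_path):
        write(tmp_path, "compounds.dat",
              "UNIQUE-ID - CPD-A\n//\nUNIQUE-ID - CPD-B\n//\n")
        write(tmp_path, "reactions.dat", "\n".join([
            "UNIQUE-ID - RXN-EX", "LEFT - CPD-A", "^COMPARTMENT - e",
            "RIGHT - CPD-B", "//",
        ]) + "\n")
        res = reconstruct(tmp_path)
        assert any(pid == "RXN-EX" for pid, _ in res.report.dropped_processes)

    def test_rna_regulator_translated_to_encoding_gene(self, tmp_path):
        write(tmp_path, "genes.dat", "\n".join([
            "UNIQUE-ID - GENE-S", "PRODUCT - RNA-S", "//",
            "UNIQUE-ID - GENE-T", "COMPONENT-OF - TU-T", "//",
        ]) + "\n")
        write(tmp_path, "rnas.dat", "UNIQUE-ID - RNA-S\nGENE - GENE-S\n//\n")
        write(tmp_path, "regulation.dat", "\n".join([
            "UNIQUE-ID - REG-S", "REGULATOR - RNA-S",
            "REGULATED-ENTITY - TU-T", "MODE - -", "//",
        ]) + "\n")
        res = reconstruct(tmp_path)
        regs = [(e.source, e.target, e.regulation_mode)
                for e in res.full.edge_records() if e.etype == "regulation"]
        assert regs == [("GENE-S", "GENE-T", -1)]


class TestAssembly:
    def test_wcc_extracted_from_two_components(self, fixture_dir, tmp_path):
        res = reconstruct(fixture_dir)
        # the operon block (TF complex + effector + 3 genes + products) and
        # the reaction block are wired into one component via nothing -- they
        # are separate, so the larger one is returned
        assert res.wcc.n_vertices < res.full.n_vertices

    def test_full_graph_validates(self, fixture_dir):
        res = reconstruct(fixture_dir)
        res.full.validate()
        res.wcc.validate()

    def test_empty_inputs_empty_graph(self, tmp_path):
        res = reconstruct(tmp_path)
        assert res.full.n_vertices == 0 and res.wcc.n_vertices == 0

    def test_forced_component_sizes(self, tmp_path):
        # 7-vertex TU-regulation block vs 3-vertex reaction block
        write(tmp_path, "compounds.dat",
              "UNIQUE-ID - CPD-A\n//\nUNIQUE-ID - CPD-B\n//\n")
        write(tmp_path, "reactions.dat",
              "UNIQUE-ID - RXN-1\nLEFT - CPD-A\nRIGHT - CPD-B\n//\n")
        write(tmp_path, "genes.dat", "\n".join([
            "UNIQUE-ID - G1", "PRODUCT - P1", "COMPONENT-OF - TU-X", "//",
            "UNIQUE-ID - G2", "PRODUCT - P2", "COMPONENT-OF - TU-X", "//",
            "UNIQUE-ID - G3", "PRODUCT - P3", "COMPONENT-OF - TU-X", "//",
        ]) + "\n")
        write(tmp_path, "proteins.dat", "\n".join([
            "UNIQUE-ID - P1", "GENE - G1", "//",
            "UNIQUE-ID - P2", "GENE - G2", "//",
            "UNIQUE-ID - P3", "GENE - G3", "//",
            "UNIQUE-ID - PTF", "//",
        ]) + "\n")
        write(tmp_path, "regulation.dat", "\n".join([
            "UNIQUE-ID - REG-1", "REGULATOR - PTF",
            "REGULATED-ENTITY - TU-X", "MODE - +", "//",
        ]) + "\n")
        res = reconstruct(tmp_path)
        assert res.full.n_vertices == 10
        assert res.wcc.n_vertices == 7
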