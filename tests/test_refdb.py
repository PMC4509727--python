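"""Lineage normalization, taxonomy trees, and the two database dialects."""

import itertools

import pytest

from pollenpipe.refdb import (
    RANKS,
    Lineage,
    ReferenceDB,
    TaxTree,
    assign_lineages,
    coverage_report,
    parse_rdp_taxonomy,
    read_utax_fasta,
    write_rdp_training,
    write_utax_fasta,
)

from conftest import make_lineage


@pytest.fixture
def toy_tree():
    # root(1) -> kingdom(2) -> phylum(3) -> class(4) -> order(5) -> family(6)
    #   -> genus(7) -> species(8); a second species(9); a subfamily node (10)
    nodes = {
        1: ("root", 1, "no rank", 0),
        2: ("Plantae", 1, "kingdom", 1),
        3: ("Tracheophyta", 2, "phylum", 2),
        4: ("Magnoliopsida", 3, "class", 3),
        5: ("Brassicales", 4, "order", 4),
        6: ("Brassicaceae", 5, "family", 5),
        10: ("Brassicoideae", 6, "subfamily", 6),
        7: ("Brassica", 10, "genus", 7),
        8: ("Brassica napus", 7, "species", 8),
        9: ("Brassica rapa", 7, "species", 8),
    }
    return TaxTree(nodes)


class TestLineage:
    def test_full_path_fully_named(self, toy_tree):
        lin = toy_tree.lineage_of(8)
        assert lin.names == (
            "Plantae", "Tracheophyta", "Magnoliopsida", "Brassicales",
            "Brassicaceae", "Brassica", "Brassica napus",
        )

    def test_family_level_attachment_gets_placeholders(self, toy_tree):
        lin = toy_tree.lineage_of(6)
        assert lin["genus"] == "unclassified_Brassicaceae"
        assert lin["species"] == "unclassified_Brassicaceae"

    def test_intermediate_rank_skipped(self, toy_tree):
        # the subfamily node is not one of the seven ranks
        lin = toy_tree.lineage_of(7)
        assert lin["family"] == "Brassicaceae"
        assert lin["genus"] == "Brassica"

    def test_normalization_idempotent(self):
        lin = Lineage.from_partial(["K", "P", None, "O", None, None, None])
        again = Lineage.from_partial(list(lin.names))
        assert again.names == lin.names
        assert lin["class"] == "unclassified_P"
        assert lin["species"] == "unclassified_O"

    def test_kingdom_must_be_named(self):
        with pytest.raises(ValueError, match="kingdom"):
            Lineage.from_partial([None, "P", "C", "O", "F", "G", "S"])

    def test_deepest_named(self):
        lin = Lineage.from_partial(["K", "P", "C", "O", "F", None, None])
        assert lin.deepest_named == ("family", "F")


class TestTaxTree:
    def test_depth_invariant_enforced(self):
        with pytest.raises(ValueError, match="depth"):
            TaxTree({1: ("root", 1, "no rank", 0), 2: ("x", 1, "kingdom", 5)})

    def test_cycle_detected_in_tsv(self, tmp_path):
        p = tmp_path / "nodes.tsv"
        p.write_text("taxon_id\tname\tparent_id\trank\n1\ta\t2\tkingdom\n2\tb\t1\tphylum\n")
        with pytest.raises(ValueError, match="cycle"):
            TaxTree.from_tsv(p)

    def test_tsv_roundtrip(self, tmp_path, toy_tree):
        p = tmp_path / "nodes.tsv"
        lines = ["taxon_id\tname\tparent_id\trank"]
        for nid, (name, parent, rank, _d) in toy_tree.nodes.items():
            lines.append(f"{nid}\t{name}\t{parent}\t{rank}")
        p.write_text("\n".join(lines) + "\n")
        tree = TaxTree.from_tsv(p)
        assert tree.lineage_of(8).names == toy_tree.lineage_of(8).names


class TestAssignLineages:
    def test_mapped_and_dropped(self, toy_tree):
        seqs = {"s1": "ACGT", "s2": "ACGT", "s3": "ACGT"}
        id2tax = {"s1": 8, "s2": 9}  # s3 unmapped
        db, dropped = assign_lineages(seqs, id2tax, toy_tree)
        assert len(db) == 2
        assert dropped == 1
        assert db.records[0][2]["species"] == "Brassica napus"

    def test_taxid_missing_from_tree_also_dropped(self, toy_tree):
        db, dropped = assign_lineages({"s1": "ACGT"}, {"s1": 999}, toy_tree)
        assert len(db) == 0 and dropped == 1


class TestUtaxDialect:
    def test_roundtrip_identity(self, tmp_path, toy_db):
        p = tmp_path / "db.fasta"
        write_utax_fasta(toy_db, p)
        back = read_utax_fasta(p)
        assert [(i, s, l.names) for i, s, l in back.records] == [
            (i, s, l.names) for i, s, l in toy_db.records
        ]

    def test_header_format(self, tmp_path):
        db = ReferenceDB([("id1", "ACGT", make_lineage())])
        p = tmp_path / "db.fasta"
        write_utax_fasta(db, p)
        header = p.read_text().splitlines()[0]
        assert header == ">id1;tax=d:Plantae,p:Tracheophyta,c:Magnoliopsida,o:o1,f:f1,g:g1,s:s1;"

    def test_delimiters_sanitized(self, tmp_path):
        lin = Lineage.from_partial(["K", "P", "C", "O", "F", "G", "Abies alba, hybrid"])
        db = ReferenceDB([("id1", "ACGT", lin)])
        p = tmp_path / "db.fasta"
        write_utax_fasta(db, p)
        back = read_utax_fasta(p)
        assert back.records[0][2]["species"] == "Abies alba_ hybrid"

    def test_empty_db_roundtrip(self, tmp_path):
        p = tmp_path / "empty.fasta"
        write_utax_fasta(ReferenceDB([]), p)
        assert len(read_utax_fasta(p)) == 0

    def test_malformed_header_reports_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">id1 no tax annotation\nACGT\n")
        with pytest.raises(ValueError, match=":1:"):
            read_utax_fasta(p)


class TestRdpDialect:
    def test_two_species_one_genus_node_counts(self, tmp_path):
        db = ReferenceDB(
            [
                ("a", "ACGT", make_lineage(species="s1")),
                ("b", "ACGT", make_lineage(species="s2")),
            ]
        )
        tax_path, fasta_path = write_rdp_training(db, tmp_path)
        lines = tax_path.read_text().strip().splitlines()
        genus_nodes = [l for l in lines if l.endswith("*genus")]
        species_nodes = [l for l in lines if l.endswith("*species")]
        assert len(genus_nodes) == 1
        assert len(species_nodes) == 2
        assert fasta_path.read_text().count(">") == 2

    def test_single_record_has_8_nodes(self, tmp_path):
        db = ReferenceDB([("a", "ACGT", make_lineage())])
        tax_path, _ = write_rdp_training(db, tmp_path)
        assert len(tax_path.read_text().strip().splitlines()) == 8

    def test_training_fasta_header_layout(self, tmp_path):
        db = ReferenceDB([("a", "ACGT", make_lineage())])
        _, fasta_path = write_rdp_training(db, tmp_path)
        header = fasta_path.read_text().splitlines()[0]
        assert header == ">a\tRoot;Plantae;Tracheophyta;Magnoliopsida;o1;f1;g1;s1"

    def test_taxonomy_parses_back_to_valid_tree(self, tmp_path, toy_db):
        tax_path, _ = write_rdp_training(toy_db, tmp_path)
        tree = parse_rdp_taxonomy(tax_path)  # TaxTree invariants checked on build
        assert tree.nodes[tree.root][0] == "Root"

    def test_node_count_equals_distinct_prefixes_plus_root(self, tmp_path, sim_db):
        tax_path, _ = write_rdp_training(sim_db, tmp_path)
        n_nodes = len(tax_path.read_text().strip().splitlines())
        prefixes = {
            tuple(lin.names[:d])
            for _, _, lin in sim_db.records
            for d in range(1, len(RANKS) + 1)
        }
        assert n_nodes == len(prefixes) + 1


class TestCoverage:
    def test_full_and_partial(self, toy_db):
        assert coverage_report(toy_db, ["s1", "s3"]) == 1.0
        assert coverage_report(toy_db, ["s1", "s2", "nope", "missing"]) == 0.5

    def test_case_insensitive(self, toy_db):
        assert coverage_report(toy_db, ["S1"]) == 1.0

    def test_genus_covered_via_any_species(self, toy_db):
        # toy db holds species of genera g1 and g2
        assert coverage_report(toy_db, ["g1", "g2", "g3"], rank="genus") == pytest.approx(2 / 3)

    def test_empty_checklist_rejected(self, toy_db):
        with pytest.raises(ValueError, match="empty"):
            coverage_report(toy_db, [])
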