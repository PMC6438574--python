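"""Readers/writers: gene2pubmed filtering, gene lists, GMT, regulation tables."""

import io

import pytest

from netpharm.signature_io import (
    AnnotationCollection,
    Context,
    Direction,
    GeneId,
    GeneSignature,
    ParseError,
    parse_gene2pubmed,
    read_gene_list,
    read_gmt,
    read_regulation_table,
    write_gene_list,
    write_gmt,
    write_regulation_table,
)

from conftest import gset

G2P_FIXTURE = [
    "#tax_id\tGeneID\tPubMed_ID",
    "9606\t100\t1",
    "9606\t200\t2",
    "10090\t300\t1",
    "9606\t100\t2",
    "9606\t400\t3",
]


class TestGeneId:
    def test_equality_and_hash_ignore_symbol(self):
        assert GeneId(7, "A") == GeneId(7, "B")
        assert len({GeneId(7, "A"), GeneId(7)}) == 1

    def test_rejects_nonpositive_entrez(self):
        with pytest.raises(ValueError):
            GeneId(0)

    def test_signature_provenance_must_be_subset(self):
        with pytest.raises(ValueError):
            GeneSignature("x", genes=gset(1), provenance={GeneId(2): {5}})


class TestParseGene2Pubmed:
    def test_manual_enumeration_of_fixture(self):
        # tax 9606 & pmid 1 passes only the line (9606, 100, 1)
        out = parse_gene2pubmed(G2P_FIXTURE, pmid_filter={1}, tax_filter=9606)
        assert out.genes == gset(100)
        assert out.provenance[GeneId(100)] == {1}

    def test_gene_on_two_passing_lines_collects_both_pmids(self):
        out = parse_gene2pubmed(G2P_FIXTURE, pmid_filter={1, 2}, tax_filter=9606)
        assert out.genes == gset(100, 200)
        assert out.provenance[GeneId(100)] == {1, 2}

    def test_taxon_absent_from_stream_gives_empty_signature(self):
        out = parse_gene2pubmed(G2P_FIXTURE[:4], pmid_filter={1}, tax_filter=7227)
        assert out.genes == set()

    def test_invariant_under_line_permutation(self):
        fwd = parse_gene2pubmed(G2P_FIXTURE, pmid_filter={1, 2, 3})
        rev = parse_gene2pubmed(list(reversed(G2P_FIXTURE)), pmid_filter={1, 2, 3})
        assert fwd.genes == rev.genes and fwd.provenance == rev.provenance

    def test_pmid_union_equals_union_of_filtered_signatures(self):
        both = parse_gene2pubmed(G2P_FIXTURE, pmid_filter={1, 3})
        one = parse_gene2pubmed(G2P_FIXTURE, pmid_filter={1})
        three = parse_gene2pubmed(G2P_FIXTURE, pmid_filter={3})
        assert both.genes == one.genes | three.genes

    def test_empty_pmid_filter_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="pmid_filter"):
            parse_gene2pubmed(G2P_FIXTURE, pmid_filter=set())

    def test_malformed_line_reports_line_number(self):
        bad = ["9606\t100\t1", "9606\tnot_a_gene\t2"]
        with pytest.raises(ParseError, match="line 2"):
            parse_gene2pubmed(bad, pmid_filter={1, 2})


class TestGeneList:
    def test_round_trip_identity(self):
        s = GeneSignature("x", genes={GeneId(1234, "MMP9"), GeneId(7), GeneId(99)})
        buf = io.StringIO()
        write_gene_list(s, buf)
        buf.seek(0)
        back = read_gene_list(buf, label="x")
        assert back.genes == s.genes
        assert {g.symbol for g in back.genes} == {g.symbol for g in s.genes}

    def test_symbol_column_parsed(self):
        out = read_gene_list(["1234\tMMP9"])
        (g,) = out.genes
        assert g == GeneId(1234) and g.symbol == "MMP9"

    def test_duplicates_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            out = read_gene_list(["5", "5", "6"])
        assert out.genes == gset(5, 6)

    def test_empty_file_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = read_gene_list([])
        assert out.genes == set()


class TestGMT:
    def test_shared_gene_union_and_default_reference_total(self):
        gmt = ["pwA\tdesc\t1\t2\t3", "pwB\tdesc\t3\t4"]
        coll = read_gmt(gmt)
        assert set(coll.categories) == {"pwA", "pwB"}
        assert coll.annotated_genes() == gset(1, 2, 3, 4)
        assert coll.reference_total == 4

    def test_reference_total_override(self):
        coll = read_gmt(["pwA\td\t1\t2"], reference_total=100)
        assert coll.reference_total == 100

    def test_override_below_union_rejected(self):
        with pytest.raises(ValueError):
            read_gmt(["pwA\td\t1\t2\t3"], reference_total=2)

    def test_duplicate_category_name_is_error(self):
        with pytest.raises(ParseError, match="duplicate"):
            read_gmt(["pwA\td\t1", "pwA\td\t2"])

    def test_line_without_genes_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="no genes"):
            coll = read_gmt(["empty\tdesc", "pwA\td\t1"])
        assert set(coll.categories) == {"pwA"}

    def test_round_trip(self):
        coll = AnnotationCollection({"a": gset(1, 2), "b": gset(2, 3)})
        buf = io.StringIO()
        write_gmt(coll, buf)
        buf.seek(0)
        back = read_gmt(buf)
        assert back.categories == coll.categories
        assert back.reference_total == coll.reference_total


class TestRegulationTable:
    def test_conflicting_rows_consolidate_to_mixed(self):
        rows = ["1\tdisease\tup\t10", "1\tdisease\tdown\t11"]
        (rec,) = read_regulation_table(rows)
        assert rec.direction is Direction.MIXED
        assert rec.sources == {10, 11}

    def test_single_row_kept_as_given(self):
        (rec,) = read_regulation_table(["2\tdrug\tdown\t"])
        assert rec.gene == GeneId(2)
        assert rec.context is Context.DRUG
        assert rec.direction is Direction.DOWN

    def test_duplicate_row_collapses(self):
        rows = [
            "gene\tcontext\tdirection\tsources",
            "1\tdisease\tup\t1",
            "1\tdisease\tup\t2",
            "2\tdrug\tdown\t",
            "3\tdisease\tdown\t",
        ]
        recs = read_regulation_table(rows)
        assert len(recs) == 3

    def test_direction_tokens_case_insensitive(self):
        (rec,) = read_regulation_table(["1\tdisease\tUP\t"])
        assert rec.direction is Direction.UP

    def test_unknown_direction_token_named_in_error(self):
        with pytest.raises(ParseError, match="sideways"):
            read_regulation_table(["1\tdisease\tsideways\t"])

    def test_round_trip(self):
        recs = read_regulation_table(
            ["1\tdisease\tup\t5,6", "1\tdrug\tdown\t7", "2\tdisease\tmixed\t"]
        )
        buf = io.StringIO()
        write_regulation_table(recs, buf)
        buf.seek(0)
        assert read_regulation_table(buf) == recs
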