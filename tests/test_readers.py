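"""Source-format readers: Wikidata dump, OTT taxonomy, GloBI TSV, TSV round-trip."""

import io

import pytest

from taxograph import (
    ExternalId,
    LookupTable,
    extract_wikidata_taxa,
    parse_curie,
    read_globi_taxon_graph,
    read_lookup_table,
    read_ott_taxonomy,
    write_lookup_table,
)

from conftest import make_table, wd_entity


class TestWikidataExtraction:
    def test_single_taxon_with_one_link(self):
        lines = [wd_entity("Q140", name="Panthera leo", ids={"P815": ["183803"]})]
        table, stats = extract_wikidata_taxa(lines)
        assert table.rows == [
            (ExternalId("WD", "Q140"), "Panthera leo", ExternalId("ITIS", "183803"))
        ]
        assert stats.taxa_extracted == 1 and stats.entities_scanned == 1

    def test_multi_scheme_taxon_emits_one_row_per_claim(self):
        lines = [
            wd_entity(
                "Q7247420",
                name="Procladius",
                ids={"P850": ["156905"], "P846": ["1449280"], "P685": ["191633"]},
            )
        ]
        table, _ = extract_wikidata_taxa(lines)
        assert table.ids_of(ExternalId("WD", "Q7247420")) == {
            ExternalId("WORMS", "156905"),
            ExternalId("GBIF", "1449280"),
            ExternalId("NCBI", "191633"),
        }

    def test_non_taxon_entities_are_filtered(self):
        lines = [
            wd_entity("Q42", taxon=False, name=None, ids={"P685": ["9606"]}),
            wd_entity("Q140", name="Panthera leo", ids={"P815": ["183803"]}),
        ]
        table, stats = extract_wikidata_taxa(lines)
        assert len(table) == 1
        assert stats.entities_scanned == 2 and stats.taxa_extracted == 1

    def test_zero_link_taxa_count_in_histogram_but_emit_no_rows(self):
        lines = [wd_entity("Q1", name="Linkless taxon"), wd_entity("Q2", ids={"P685": ["1"]})]
        table, stats = extract_wikidata_taxa(lines)
        assert len(table) == 1
        assert stats.links_per_taxon_histogram == {0: 1, 1: 1}

    def test_histogram_conservation(self):
        lines = [
            wd_entity("Q1", ids={"P685": ["1"], "P846": ["2"]}),
            wd_entity("Q2", ids={"P685": ["3"]}),
            wd_entity("Q3"),
        ]
        table, stats = extract_wikidata_taxa(lines)
        assert sum(stats.links_per_taxon_histogram.values()) == stats.taxa_extracted == 3
        assert sum(k * n for k, n in stats.links_per_taxon_histogram.items()) == len(table) == 3
        assert stats.conserved()

    def test_malformed_lines_are_counted_not_fatal(self):
        lines = [
            "{ not json",
            wd_entity("Q140", ids={"P815": ["183803"]}),
            '{"truncated": ',
        ]
        table, stats = extract_wikidata_taxa(lines)
        assert len(table) == 1
        assert stats.malformed_lines == 2

    def test_json_array_wrapping_and_trailing_commas_tolerated(self):
        lines = ["[", wd_entity("Q1", ids={"P685": ["1"]}) + ",", wd_entity("Q2") + ",", "]"]
        table, stats = extract_wikidata_taxa(lines)
        assert stats.entities_scanned == 2 and len(table) == 1

    def test_deprecated_rank_claims_are_skipped(self):
        lines = [wd_entity("Q1", ids={"P685": ["1"]}, deprecated={"P685": ["999"]})]
        table, _ = extract_wikidata_taxa(lines)
        assert table.external_ids() == {ExternalId("NCBI", "1")}

    def test_streaming_from_generator_is_single_pass(self):
        """A one-shot generator suffices: the extractor never rewinds or buffers."""

        def stream():
            for i in range(50):
                yield wd_entity(f"Q{i}", ids={"P685": [str(i)]})

        table, stats = extract_wikidata_taxa(stream())
        assert stats.taxa_extracted == 50 and len(table) == 50

    def test_property_map_override(self):
        lines = [wd_entity("Q1", ids={"P9999": ["77"]})]
        _, stats_default = extract_wikidata_taxa(lines)
        table, _ = extract_wikidata_taxa(
            lines, property_map={"external_ids": {"P9999": "GBIF"}}
        )
        assert stats_default.rows_emitted == 0
        assert table.external_ids() == {ExternalId("GBIF", "77")}


OTT_HEADER = "uid\t|\tparent_uid\t|\tname\t|\trank\t|\tsourceinfo\t|\tuniqname\t|\tflags\t|"


def _ott_file(tmp_path, lines):
    path = tmp_path / "taxonomy.tsv"
    path.write_text("\n".join([OTT_HEADER, *lines]) + "\n", encoding="utf-8")
    return path


class TestOttReader:
    def test_one_row_per_sourceinfo_entry(self, tmp_path):
        path = _ott_file(
            tmp_path,
            ["1087695\t|\t1\t|\tProcladius\t|\tgenus\t|\tncbi:191633,worms:156905,gbif:1449280\t|\t\t|\t\t|"],
        )
        table, stats = read_ott_taxonomy(path)
        assert table.ids_of(ExternalId("OTT", "1087695")) == {
            ExternalId("NCBI", "191633"),
            ExternalId("WORMS", "156905"),
            ExternalId("GBIF", "1449280"),
        }
        assert table.name_of(ExternalId("OTT", "1087695")) == "Procladius"
        assert stats.records_scanned == 3 and stats.rows_emitted == 3

    def test_empty_sourceinfo_emits_nothing(self, tmp_path):
        path = _ott_file(tmp_path, ["7\t|\t\t|\tEmptyus\t|\tspecies\t|\t\t|\t\t|\t\t|"])
        table, stats = read_ott_taxonomy(path)
        assert len(table) == 0 and stats.records_scanned == 0

    def test_non_target_schemes_counted_but_excluded(self, tmp_path):
        path = _ott_file(
            tmp_path, ["5\t|\t\t|\tMicrobius\t|\tspecies\t|\tsilva:AB123,ncbi:77,irmng:10\t|\t\t|\t\t|"]
        )
        table, stats = read_ott_taxonomy(path)
        assert table.external_ids() == {ExternalId("NCBI", "77")}
        assert stats.per_scheme_link_counts["SILVA"] == 1
        assert stats.skipped_by_reason["non-target-scheme"] == 2
        assert stats.conserved()

        table_all, _ = read_ott_taxonomy(path, include_all_schemes=True)
        assert ExternalId("SILVA", "AB123") in table_all.external_ids()

    def test_directory_argument_resolves_taxonomy_tsv(self, tmp_path):
        _ott_file(tmp_path, ["1\t|\t\t|\tX\t|\tspecies\t|\tncbi:1\t|\t\t|\t\t|"])
        table, _ = read_ott_taxonomy(tmp_path)
        assert len(table) == 1

    def test_wrong_delimiter_is_a_format_error(self, tmp_path):
        path = tmp_path / "taxonomy.tsv"
        path.write_text("uid\tparent_uid\tname\tsourceinfo\n1\t\tX\tncbi:1\n")
        with pytest.raises(ValueError, match="tab-pipe-tab"):
            read_ott_taxonomy(path)

    def test_unparsable_sourceinfo_entry_skipped_and_counted(self, tmp_path):
        path = _ott_file(tmp_path, ["9\t|\t\t|\tY\t|\tspecies\t|\tncbi:8,junkentry\t|\t\t|\t\t|"])
        table, stats = read_ott_taxonomy(path)
        assert len(table) == 1
        assert stats.skipped_by_reason["unparsable-sourceinfo"] == 1
        assert stats.conserved()


GLOBI_HEADER = "providedTaxonId\tprovidedTaxonName\tresolvedTaxonId\tresolvedTaxonName"


def _globi_stream(records):
    return io.StringIO("\n".join([GLOBI_HEADER, *records]) + "\n")


class TestGlobiReader:
    def test_null_provided_id_synthesizes_globi_key(self):
        table, _ = read_globi_taxon_graph(
            _globi_stream(["\tProcladius sp1 M_PL_014\tNCBI:1981571\tProcladius"])
        )
        assert table.rows == [
            (
                ExternalId("GLOBI", "null@Procladius sp1 M_PL_014"),
                "Procladius sp1 M_PL_014",
                ExternalId("NCBI", "1981571"),
            )
        ]

    def test_provided_curie_kept_as_taxon_key(self):
        table, _ = read_globi_taxon_graph(
            _globi_stream(["EOL:1049789\tPluvialis obscura\tGBIF:2481943\tPluvialis obscura"])
        )
        assert table.taxa() == {ExternalId("EOL", "1049789")}

    def test_header_only_file_yields_empty_table(self):
        table, stats = read_globi_taxon_graph(_globi_stream([]))
        assert len(table) == 0 and stats.records_scanned == 0

    def test_unparsable_resolved_ids_skipped_with_count(self):
        # 10 records, 3 with unparsable resolved IDs -> 7 rows + skip count 3
        records = [f"\tTaxon {i}\tNCBI:{100 + i}\tTaxon {i}" for i in range(7)]
        records += [
            "\tBad one\tno-scheme-here\tBad one",
            "\tBad two\t\tBad two",
            "\tBad three\t:777\tBad three",
        ]
        table, stats = read_globi_taxon_graph(_globi_stream(records))
        assert stats.records_scanned == 10
        assert len(table) == stats.rows_emitted == 7
        assert stats.records_skipped == 3
        assert stats.conserved()

    def test_missing_required_column_named_in_error(self):
        stream = io.StringIO("providedTaxonId\tprovidedTaxonName\tresolvedTaxonName\nx\ty\tz\n")
        with pytest.raises(ValueError, match="resolvedTaxonId"):
            read_globi_taxon_graph(stream)

    def test_duplicate_records_deduplicated(self):
        record = "\tSenecio pectinatus\tGBIF:8317096\tSenecio pectinatus"
        table, stats = read_globi_taxon_graph(_globi_stream([record, record]))
        assert len(table) == 1 and stats.duplicate_rows == 1
        assert stats.conserved()


class TestLookupTableIO:
    def test_write_read_round_trip_identity(self, tmp_path):
        table = make_table(
            "WD",
            [
                ("WD:Q140", "Panthera leo", "ITIS:183803"),
                ("WD:Q7247420", "Procladius", "NCBI:191633"),
                ("WD:Q7247420", "Procladius", "WORMS:156905"),
            ],
        )
        path = tmp_path / "wd.tsv"
        assert write_lookup_table(table, path) == 3
        again = read_lookup_table(path)
        assert again == table and again.resource == "WD"

    def test_byte_stable_output_across_runs(self):
        table = make_table(
            "OTT", [("OTT:2", None, "NCBI:5"), ("OTT:1", "A", "GBIF:9"), ("OTT:1", "A", "NCBI:3")]
        )
        a, b = io.StringIO(), io.StringIO()
        write_lookup_table(table, a)
        write_lookup_table(table, b)
        assert a.getvalue() == b.getvalue()
        assert a.getvalue().splitlines()[0] == "taxonId\ttaxonName\texternalId"
        # sorted by (taxonId, externalId)
        data = [line.split("\t") for line in a.getvalue().splitlines()[1:]]
        assert data == sorted(data, key=lambda r: (r[0], r[2]))

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        assert write_lookup_table(LookupTable("WD"), path) == 0
        assert path.read_text() == "taxonId\ttaxonName\texternalId\n"
        assert len(read_lookup_table(path, resource="WD")) == 0

    def test_table_invariants_enforced_on_add(self):
        table = LookupTable("WD")
        with pytest.raises(ValueError):
            table.add(parse_curie("OTT:1"), parse_curie("NCBI:1"))  # foreign taxon scheme
        with pytest.raises(ValueError):
            table.add(parse_curie("WD:Q1"), parse_curie("WD:Q2"))  # self-referential external

    def test_globi_table_allows_foreign_provided_keys(self):
        table = LookupTable("GLOBI")
        assert table.add(parse_curie("EOL:1049789"), parse_curie("GBIF:2481943"))
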