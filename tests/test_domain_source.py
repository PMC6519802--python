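"""Protein record retrieval (replayed transport), fixture files, gene catalog."""

import json

import pytest

from lollipop.domain_source import (
    DomainFeature,
    FormatError,
    GeneCatalog,
    LookupError_,
    ProteinRecord,
    RecordValidationError,
    TransportError,
    fetch_protein_record,
    list_gene_catalog,
    load_gene_catalog,
    load_protein_record,
    resolve_accession,
    save_protein_record,
)

# Hand-written replay payloads mimicking the shape of UniProt REST responses
# (synthetic: never captured from the live service).
SEARCH_PAYLOAD = {
    "results": [
        {"primaryAccession": "P04637", "genes": [{"geneName": {"value": "TP53"}}]},
    ]
}

ENTRY_PAYLOAD = {
    "primaryAccession": "P04637",
    "organism": {"taxonId": 9606},
    "genes": [{"geneName": {"value": "TP53"}}],
    "sequence": {"length": 393},
    "features": [
        {"type": "Domain", "description": "P53_TAD",
         "location": {"start": {"value": 6}, "end": {"value": 29}}},
        {"type": "Domain", "description": "P53",
         "location": {"start": {"value": 95}, "end": {"value": 288}}},
        {"type": "Domain", "description": "P53_tetramer",
         "location": {"start": {"value": 318}, "end": {"value": 358}}},
        {"type": "Region", "description": "Disordered",
         "location": {"start": {"value": 1}, "end": {"value": 60}}},
    ],
}


def replay(payload):
    return lambda url: json.dumps(payload).encode()


class TestResolveAccession:
    def test_reviewed_match(self):
        acc = resolve_accession("TP53", 9606, transport=replay(SEARCH_PAYLOAD))
        assert acc == "P04637"

    def test_tie_break_smallest_accession(self):
        payload = {"results": [
            {"primaryAccession": "Q99999"}, {"primaryAccession": "P12345"},
        ]}
        assert resolve_accession("X", transport=replay(payload)) == "P12345"

    def test_unknown_symbol(self):
        with pytest.raises(LookupError_, match="NOT_A_GENE"):
            resolve_accession("NOT_A_GENE", transport=replay({"results": []}))

    def test_network_down_is_transport_error(self):
        def down(url):
            raise TransportError("connection refused")
        with pytest.raises(TransportError):
            resolve_accession("TP53", transport=down)


class TestFetch:
    def test_entry_parsed_domains_only(self):
        rec = fetch_protein_record("P04637", transport=replay(ENTRY_PAYLOAD))
        assert rec.accession == "P04637"
        assert rec.length == 393
        assert [d.name for d in rec.domains] == ["P53_TAD", "P53", "P53_tetramer"]
        assert all(1 <= d.start <= d.end <= rec.length for d in rec.domains)

    def test_region_class_opt_in(self):
        rec = fetch_protein_record(
            "P04637", feature_classes=("Domain", "Region"),
            transport=replay(ENTRY_PAYLOAD),
        )
        assert len(rec.domains) == 4

    def test_zero_domains_is_valid(self):
        payload = dict(ENTRY_PAYLOAD, features=[])
        rec = fetch_protein_record("P04637", transport=replay(payload))
        assert rec.domains == ()

    def test_truncated_body_is_format_error(self):
        with pytest.raises(FormatError):
            fetch_protein_record("P04637", transport=lambda url: b'{"primaryAcc')

    def test_cache_write_through_equals_fetched(self, tmp_path):
        rec = fetch_protein_record(
            "P04637", transport=replay(ENTRY_PAYLOAD), cache_dir=tmp_path
        )
        cached = load_protein_record(tmp_path / "P04637.domains.txt")
        assert cached.retrieved_at == "fixture"
        assert (cached.accession, cached.gene_symbol, cached.organism_id,
                cached.length, cached.domains) == (
            rec.accession, rec.gene_symbol, rec.organism_id, rec.length, rec.domains)


class TestFixtureFiles:
    def test_bundled_tp53_fixture(self, tp53_record):
        assert tp53_record.gene_symbol == "TP53"
        assert len(tp53_record.domains) == 3
        assert {d.name for d in tp53_record.domains} == {"P53_TAD", "P53", "P53_tetramer"}

    def test_round_trip(self, tmp_path):
        rec = ProteinRecord("A00001", "GENE1", 9606, 100,
                            (DomainFeature(5, 50, "D one"),))
        path = tmp_path / "rec.txt"
        save_protein_record(rec, path)
        assert load_protein_record(path) == rec

    def test_start_after_end_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "accession\tX\ngene_symbol\tG\norganism_id\t9606\nlength\t100\n"
            "domain\tD\t50\t5\n"
        )
        with pytest.raises(RecordValidationError, match="start <= end"):
            load_protein_record(path)

    def test_domain_beyond_length_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "accession\tX\ngene_symbol\tG\norganism_id\t9606\nlength\t100\n"
            "domain\tD\t90\t150\n"
        )
        with pytest.raises(RecordValidationError, match="length"):
            load_protein_record(path)

    def test_missing_field_named(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("accession\tX\ngene_symbol\tG\nlength\t100\n")
        with pytest.raises(FormatError, match="organism_id"):
            load_protein_record(path)

    def test_domains_sorted_by_start(self, tmp_path):
        rec = ProteinRecord("A1", "G", 9606, 200,
                            (DomainFeature(100, 150, "B"), DomainFeature(1, 50, "A")))
        assert [d.name for d in rec.domains] == ["A", "B"]


class TestGeneCatalog:
    def test_bundled_catalog_has_409_unique_symbols(self):
        catalog = list_gene_catalog()
        assert len(catalog) == 409
        assert len({s.upper() for s in catalog.symbols}) == 409
        assert "TP53" in catalog

    def test_user_catalog(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("BRCA1\nBRCA2\n")
        assert len(load_gene_catalog(path)) == 2

    def test_duplicates_folded(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("TP53\ntp53\nEGFR\n")
        assert len(load_gene_catalog(path)) == 2

    def test_extension_file(self, tmp_path):
        path = tmp_path / "extra.txt"
        path.write_text("MYNEWGENE1\nMYNEWGENE2\n")
        extended = list_gene_catalog(extra_path=path)
        assert len(extended) == 411
        assert "MYNEWGENE1" in extended
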