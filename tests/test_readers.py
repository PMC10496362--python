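"""Parsers for the three source XML dialects."""

from __future__ import annotations

import io
import tracemalloc

import pytest

from protsyn.fixtures import FixtureSpec, generate
from protsyn.readers import (
    ParseError,
    Source,
    SourceRecord,
    XRef,
    extract_tag_value,
    parse_biogrid,
    parse_ncbigene,
    parse_uniprot,
)

from conftest import parse_corpus

UNIPROT_ZNT10 = b"""<?xml version="1.0" encoding="UTF-8"?>
<uniprot xmlns="http://uniprot.org/uniprot">
  <entry>
    <accession>P0A0002</accession>
    <protein>
      <recommendedName><fullName>Zinc transporter 10</fullName></recommendedName>
    </protein>
    <gene>
      <name type="primary">SLC30A10</name>
      <name type="synonym">ZNT10</name>
      <name type="synonym">ZNT8</name>
    </gene>
    <organism>
      <name type="scientific">Homo sapiens</name>
      <dbReference type="NCBI Taxonomy" id="9606"/>
    </organism>
    <dbReference type="GeneID" id="102"/>
    <sequence length="485">MGRYSG</sequence>
  </entry>
</uniprot>
"""

BIOGRID_PPP2R3B = b"""<?xml version="1.0" encoding="UTF-8"?>
<entrySet xmlns="net:sf:psidev:mi" level="2" version="5">
  <entry><interactorList>
    <interactor id="2001">
      <names>
        <shortLabel>PPP2R3 L</shortLabel>
        <alias type="synonym">PR48</alias>
        <alias type="synonym">NYREN8</alias>
        <alias type="synonym">PPP2R3LY</alias>
        <alias type="synonym">LL0YNC03-56G10.1</alias>
      </names>
      <xref>
        <primaryRef db="BIOGRID" id="2001"/>
        <secondaryRef db="uniprot/swiss-prot" id="P0A0001"/>
      </xref>
      <organism ncbiTaxId="9606"><names><shortLabel>Homo sapiens</shortLabel></names></organism>
    </interactor>
  </interactorList></entry>
</entrySet>
"""

NCBIGENE_PPP2R3B = b"""<?xml version="1.0" encoding="UTF-8"?>
<Entrezgene-Set>
  <Entrezgene>
    <GeneID>101</GeneID>
    <Symbol>PPP2R3 L</Symbol>
    <Synonyms>PR48; NYREN8; PPP2R3LY; PR70</Synonyms>
    <TaxID>9606</TaxID>
    <dbXrefs><dbXref db="UniProt" id="P0A0001"/></dbXrefs>
  </Entrezgene>
</Entrezgene-Set>
"""


class TestParseUniprot:
    def test_znt10_entry_has_four_names(self):
        """All four name-bearing values of the entry land in the synonym list."""
        (record,) = parse_uniprot(io.BytesIO(UNIPROT_ZNT10))
        assert record.source is Source.UNIPROT
        assert record.native_id == "P0A0002"
        assert record.primary_name == "Zinc transporter 10"
        assert set(record.synonyms) == {"Zinc transporter 10", "SLC30A10", "ZNT10", "ZNT8"}
        assert len(record.synonyms) == 4
        assert record.tax_id == 9606
        assert XRef("GeneID", "102") in record.xrefs

    def test_empty_stream_yields_no_records(self):
        assert list(parse_uniprot(io.BytesIO(b"<uniprot/>"))) == []

    def test_entry_without_accession_is_skipped(self, caplog):
        xml = b"<uniprot><entry><protein/></entry><entry><accession>A1</accession></entry></uniprot>"
        with caplog.at_level("ERROR"):
            records = list(parse_uniprot(io.BytesIO(xml)))
        assert [r.native_id for r in records] == ["A1"]
        assert any("accession" in m for m in caplog.messages)

    def test_malformed_xml_raises_parse_error(self):
        with pytest.raises(ParseError):
            list(parse_uniprot(io.BytesIO(b"<uniprot><entry>")))


class TestParseBiogrid:
    def test_ppp2r3b_interactor_has_five_names(self):
        """shortLabel plus the four aliases give five synonym strings."""
        (record,) = parse_biogrid(io.BytesIO(BIOGRID_PPP2R3B))
        assert record.primary_name == "PPP2R3 L"
        assert set(record.synonyms) == {
            "PPP2R3 L",
            "PR48",
            "NYREN8",
            "PPP2R3LY",
            "LL0YNC03-56G10.1",
        }
        assert record.tax_id == 9606
        assert XRef("uniprot/swiss-prot", "P0A0001") in record.xrefs

    def test_interactor_without_aliases_keeps_short_label_only(self):
        xml = b"""<entrySet><entry><interactorList>
            <interactor id="7"><names><shortLabel>ABC1</shortLabel></names>
            <organism ncbiTaxId="9606"/></interactor>
        </interactorList></entry></entrySet>"""
        (record,) = parse_biogrid(io.BytesIO(xml))
        assert record.synonyms == ("ABC1",)

    def test_missing_taxid_kept_with_warning(self, caplog):
        xml = b"""<entrySet><entry><interactorList>
            <interactor id="8"><names><shortLabel>NoTax</shortLabel></names></interactor>
        </interactorList></entry></entrySet>"""
        with caplog.at_level("WARNING"):
            (record,) = parse_biogrid(io.BytesIO(xml))
        assert record.tax_id is None
        assert any("ncbiTaxId" in m for m in caplog.messages)


class TestParseNcbigene:
    def test_ppp2r3b_gene_has_five_names(self):
        """The Symbol joins the four split synonyms."""
        (record,) = parse_ncbigene(io.BytesIO(NCBIGENE_PPP2R3B))
        assert record.native_id == "101"
        assert record.primary_name == "PPP2R3 L"
        assert set(record.synonyms) == {"PPP2R3 L", "PR48", "NYREN8", "PPP2R3LY", "PR70"}
        assert record.tax_id == 9606

    def test_empty_synonyms_field(self):
        xml = b"""<Entrezgene-Set><Entrezgene>
            <GeneID>5</GeneID><Symbol>X1</Symbol><Synonyms></Synonyms><TaxID>9606</TaxID>
        </Entrezgene></Entrezgene-Set>"""
        (record,) = parse_ncbigene(io.BytesIO(xml))
        assert record.synonyms == ("X1",)

    def test_gene_without_geneid_is_skipped(self, caplog):
        xml = b"""<Entrezgene-Set><Entrezgene><Symbol>X</Symbol></Entrezgene>
            <Entrezgene><GeneID>9</GeneID><Symbol>Y</Symbol></Entrezgene></Entrezgene-Set>"""
        with caplog.at_level("ERROR"):
            records = list(parse_ncbigene(io.BytesIO(xml)))
        assert [r.native_id for r in records] == ["9"]


@pytest.mark.parametrize("seed", range(5))
def test_fixture_round_trip_field_for_field(tmp_path, seed):
    """Parsing a generated corpus reproduces the generator's records exactly."""
    truth = generate(FixtureSpec(seed=seed), tmp_path)
    parsed = parse_corpus(tmp_path)
    for source in Source:
        assert parsed[source] == truth.records[source]


def test_parsed_records_respect_type_invariants(tmp_path):
    generate(FixtureSpec(seed=11), tmp_path)
    for records in parse_corpus(tmp_path).values():
        for record in records:
            assert record.native_id.strip()
            assert all(s.strip() for s in record.synonyms)
            assert record.tax_id is None or record.tax_id > 0


def test_streaming_memory_is_bounded_per_record(tmp_path):
    """Parsing 10⁴ records allocates far less than the document size."""
    n = 10_000
    path = tmp_path / "big.xml"
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("<Entrezgene-Set>")
        for i in range(n):
            handle.write(
                f"<Entrezgene><GeneID>{i}</GeneID><Symbol>G{i}</Symbol>"
                f"<Synonyms>A{i}; B{i}; C{i}</Synonyms><TaxID>9606</TaxID></Entrezgene>"
            )
        handle.write("</Entrezgene-Set>")

    tracemalloc.start()
    count = sum(1 for _ in parse_ncbigene(path))
    _current, peak = tracemalloc.get_traced_memory()
    tracemalloc.stop()
    assert count == n
    assert peak < 8 * 1024 * 1024  # well below the ~1 MB/record worst case of full-DOM parsing


class TestExtractTagValue:
    def test_taxonomy_fragment_with_spaced_tags(self):
        """The printed one-line taxonomy fragment yields its numeric value."""
        assert extract_tag_value("<TaxID > 8355 </TaxID >", "TaxID") == "8355"

    def test_absent_tag_yields_empty_string(self):
        assert extract_tag_value("<Symbol>ABC</Symbol>", "TaxID") == ""

    def test_internal_whitespace_is_stripped(self):
        assert extract_tag_value("<name>  spaced out  </name>", "name") == "spaced out"

    @pytest.mark.parametrize("fragment", ["<TaxID>8355", "8355</TaxID>", "</TaxID>8355<TaxID>"])
    def test_unbalanced_tag_raises(self, fragment):
        with pytest.raises(ParseError):
            extract_tag_value(fragment, "TaxID")


def test_source_record_invariants_enforced():
    with pytest.raises(ValueError):
        SourceRecord(source=Source.UNIPROT, native_id="")
    with pytest.raises(ValueError):
        SourceRecord(source=Source.UNIPROT, native_id="A", synonyms=("ok", "  "))
    with pytest.raises(ValueError):
        SourceRecord(source=Source.UNIPROT, native_id="A", tax_id=0)
    with pytest.raises(ValueError):
        XRef("", "x")
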