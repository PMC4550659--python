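"""DataCite crosswalk, retrieval URLs, search grammar and response parsing."""

from __future__ import annotations

import pytest
from lxml import etree

from molcurate.datacite import (
    DATACITE_NS,
    DataCiteRecord,
    RelatedIdentifier,
    SearchQuery,
    Term,
    build_locatt_url,
    build_media_url,
    build_search_query,
    crosswalk,
    parse_search_response,
    register_media,
    related_identifier_element,
    serialize_search_response,
    to_datacite_xml,
)
from molcurate.errors import CMLValidationError, SearchPayloadError
from molcurate.packaging_mets import BundleFile, EntryBundle, EntryMetadata

METS_URL = "https://spectradspace.lib.imperial.ac.uk:8443/metadata/handle/10042/159060/mets.xml"
ORE_URL = "https://spectradspace.lib.imperial.ac.uk:8443/metadata/handle/10042/159060/ore.xml"


def _bundle(metadata: EntryMetadata | None = None) -> EntryBundle:
    return EntryBundle(
        handle="10042/159060",
        doi="10.14469/ch/159060",
        metadata=metadata or EntryMetadata(name="NSC138467"),
        files=(BundleFile.from_payload("PM7.xml", b"<cml/>", sequence=1),),
    )


class TestCrosswalk:
    def test_manifest_urls_become_hasmetadata_related_identifiers(self):
        record = crosswalk(EntryMetadata(name="NSC138467"), _bundle(), (METS_URL, ORE_URL))
        mets = [r for r in record.related_identifiers if r.metadata_scheme == "METS"]
        assert len(mets) == 1
        assert mets[0].relation_type == "HasMetadata"
        assert mets[0].id_type == "URL"
        assert mets[0].scheme_uri == "http://www.loc.gov/METS/"
        assert mets[0].value == METS_URL
        assert any(r.metadata_scheme == "OAI-ORE" for r in record.related_identifiers)

    def test_chemical_identifiers_become_alternate_identifiers(self):
        md = EntryMetadata(
            name="NSC5396",
            nsc_id=5396,
            cas_id="50-00-0",
            inchi="InChI=1S/H2O/h1H2",
            inchikey="XLYOFNOQVPJJNP-UHFFFAOYSA-N",
            smiles="O",
        )
        record = crosswalk(md, _bundle(md), (METS_URL, ORE_URL))
        schemes = {s for s, _ in record.alternate_identifiers}
        assert schemes == {"InChI", "InChIKey", "CAS", "NCI", "SMILES"}

    def test_orcids_become_name_identifiers(self):
        md = EntryMetadata(
            name="x", contributors=(("H. S. Rzepa", "0000-0002-8635-8390"),)
        )
        xml = to_datacite_xml(crosswalk(md, _bundle(md), (METS_URL, ORE_URL)))
        doc = etree.fromstring(xml.encode())
        ni = doc.find(f".//{{{DATACITE_NS}}}nameIdentifier")
        assert ni is not None
        assert ni.get("nameIdentifierScheme") == "ORCID"
        assert ni.text == "0000-0002-8635-8390"

    def test_minimal_metadata_yields_schema_valid_record(self):
        record = crosswalk(EntryMetadata(name="bare"), _bundle(), (METS_URL, ORE_URL))
        xml = to_datacite_xml(record)  # raises on schema violation
        doc = etree.fromstring(xml.encode())
        assert doc.find(f"{{{DATACITE_NS}}}identifier").text == "10.14469/ch/159060"

    def test_hasmetadata_requires_scheme(self):
        with pytest.raises(CMLValidationError):
            RelatedIdentifier(value=METS_URL)  # no scheme/schemeURI


def test_printed_hasmetadata_element_byte_exact():
    rel = RelatedIdentifier(
        value=METS_URL, metadata_scheme="METS", scheme_uri="http://www.loc.gov/METS/"
    )
    expected = (
        '<relatedIdentifier relatedIdentifierType="URL" relationType="HasMetadata" '
        'relatedMetadataScheme="METS" schemeURI="http://www.loc.gov/METS/">'
        + METS_URL
        + "</relatedIdentifier>"
    )
    assert related_identifier_element(rel) == expected


class TestRetrievalUrls:
    def test_locatt_url_exact_form(self):
        assert (
            build_locatt_url("10042/31117", "chemical/x-cml")
            == "http://doi.org/10042/31117?locatt=mimetype:chemical/x-cml"
        )

    def test_locatt_alternate_resolver(self):
        url = build_locatt_url("10042/31117", "chemical/x-cml", resolver="http://hdl.handle.net/")
        assert url.startswith("http://hdl.handle.net/10042/31117")

    def test_media_url_exact_form(self):
        assert (
            build_media_url("10.14469/ch/153690", "chemical/x-cml")
            == "http://data.datacite.org/chemical/x-cml/10.14469/ch/153690"
        )

    @pytest.mark.parametrize("builder", [build_locatt_url, build_media_url])
    def test_empty_identifier_rejected(self, builder):
        with pytest.raises(CMLValidationError):
            builder("", "chemical/x-cml")


class TestSearchQuery:
    def test_inchikey_exact_lookup(self):
        q = SearchQuery(terms=(Term("InChIKey", "LQPOSWKBQVCBKS-PGMHMLKASA-N", op="="),))
        assert (
            build_search_query(q)
            == "http://search.datacite.org/ui?q=InChIKey=LQPOSWKBQVCBKS-PGMHMLKASA-N"
        )

    def test_prefix_and_wildcard_api_query(self):
        q = SearchQuery(
            terms=(Term("prefix", "10.14469"), Term("alternateIdentifier", "NCI:", wildcard=True)),
            output_format="xml",
            row_limit=3,
        )
        url = build_search_query(q)
        assert "prefix:10.14469" in url
        assert r"alternateIdentifier:NCI\:*" in url
        assert "fl=doi,title,relatedIdentifier" in url
        assert url.endswith("&wt=xml&rows=3")

    def test_orcid_wildcard_plus_prefix(self):
        q = SearchQuery(terms=(Term("ORCID", "", wildcard=True), Term("prefix", "10.14469")))
        assert build_search_query(q).endswith("?q=ORCID:*+prefix:10.14469")

    def test_doi_slashes_escaped(self):
        q = SearchQuery(terms=(Term("doi", "10.14469/CH/", wildcard=True),))
        assert build_search_query(q).endswith(r"?q=doi:10.14469\/CH\/*")

    def test_empty_terms_rejected(self):
        with pytest.raises(CMLValidationError):
            SearchQuery(terms=())


PRINTED_CSV = (
    "doi,title,relatedIdentifier\n"
    '10.14469/CH/123315,NSC5396,"HasMetadata:URL:https://spectradspace.lib.imperial.ac.uk:8443'
    "/metadata/handle/10042/130536/mets.xml, HasMetadata:URL:https://spectradspace.lib.imperial"
    '.ac.uk:8443/metadata/handle/10042/130536/ore.xml, IsPartOf:Handle:10042/31117"\n'
)


class TestParseSearchResponse:
    def test_printed_csv_record(self):
        hits = parse_search_response(PRINTED_CSV)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.doi == "10.14469/CH/123315"
        assert hit.title == "NSC5396"
        urls = hit.has_metadata_urls()
        assert len(urls) == 2
        assert urls[0].endswith("/metadata/handle/10042/130536/mets.xml")
        assert ("IsPartOf", "Handle", "10042/31117") in hit.related

    def test_empty_payload(self):
        assert parse_search_response("") == []

    def test_row_without_related_identifiers(self):
        hits = parse_search_response("doi,title,relatedIdentifier\n10.1/x,thing,\n")
        assert hits[0].related == ()

    def test_malformed_header_rejected(self):
        with pytest.raises(SearchPayloadError):
            parse_search_response("nope,nope\n1,2\n")

    @pytest.mark.parametrize("fmt", ["csv", "xml"])
    def test_serialize_parse_round_trip(self, fmt):
        hits = parse_search_response(PRINTED_CSV)
        again = parse_search_response(serialize_search_response(hits, fmt))
        assert again == hits


def test_register_media_idempotent():
    record = DataCiteRecord(
        doi="10.14469/ch/1",
        creators=(("(:unav)", None),),
        title="x",
        publisher="p",
        publication_year="2015",
    )
    url = build_media_url("10.14469/ch/1", "chemical/x-cml")
    once = register_media(record, "chemical/x-cml", url)
    twice = register_media(once, "chemical/x-cml", url)
    assert once.media == (("chemical/x-cml", url),)
    assert twice is once
    other = register_media(once, "chemical/x-mopac-input", url)
    assert len(other.media) == 2
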