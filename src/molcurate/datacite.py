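"""Crosswalk of entry metadata to DataCite records, plus retrieval URLs and
fielded search queries.

The curated repository exposes its per-molecule metadata to the DataCite
registry.  Three extensions make the records machine-actionable:

* the METS and OAI-ORE manifest locations travel as ``relatedIdentifier``
  elements with the ``HasMetadata`` relation type (introduced in version
  3.0 of the DataCite metadata schema, which is why the writer targets
  kernel-3);
* every chemical identifier (InChI, InChIKey, CAS, NCI, SMILES) becomes an
  ``alternateIdentifier``, so entries are discoverable by fielded search;
* contributor ORCID iDs become ``nameIdentifier`` elements.

Two resolver URL forms retrieve a data file knowing only a persistent
identifier and a media type: the handle 10320/loc form
(``<resolver>/<handle>?locatt=mimetype:<mime>``) and the DataCite content
resolver form (``<content-resolver>/<mime>/<doi>``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Sequence

from lxml import etree

from .cml_records import _load_schema
from .errors import CMLValidationError, SearchPayloadError
from .packaging_mets import EntryBundle, EntryMetadata

DATACITE_NS = "http://datacite.org/schema/kernel-3"
HANDLE_RESOLVER = "http://doi.org/"
ALT_HANDLE_RESOLVER = "http://hdl.handle.net/"
CONTENT_RESOLVER = "http://data.datacite.org/"
SEARCH_BASE = "http://search.datacite.org"
METS_SCHEME_URI = "http://www.loc.gov/METS/"
ORE_SCHEME_URI = "http://www.openarchives.org/ore/terms/"
ORCID_SCHEME_URI = "http://orcid.org/"

ALTERNATE_ID_SCHEMES = ("InChI", "InChIKey", "CAS", "NCI", "SMILES")


@dataclass(frozen=True)
class RelatedIdentifier:
    value: str
    id_type: str = "URL"
    relation_type: str = "HasMetadata"
    metadata_scheme: str | None = None
    scheme_uri: str | None = None

    def __post_init__(self) -> None:
        if self.relation_type == "HasMetadata" and not (
            self.metadata_scheme and self.scheme_uri
        ):
            raise CMLValidationError(
                "HasMetadata related identifiers must carry a metadata scheme and scheme URI"
            )


@dataclass(frozen=True)
class DataCiteRecord:
    doi: str
    creators: tuple[tuple[str, str | None], ...]  # (name, ORCID or None)
    title: str
    publisher: str
    publication_year: str
    alternate_identifiers: tuple[tuple[str, str], ...] = ()  # (scheme, value)
    related_identifiers: tuple[RelatedIdentifier, ...] = ()
    media: tuple[tuple[str, str], ...] = ()  # (media type, URL)

    def __post_init__(self) -> None:
        if not self.creators:
            raise CMLValidationError("a DataCite record needs at least one creator")
        for scheme, _ in self.alternate_identifiers:
            if scheme not in ALTERNATE_ID_SCHEMES:
                raise CMLValidationError(f"unknown alternate identifier scheme {scheme!r}")


def crosswalk(
    metadata: EntryMetadata,
    bundle: EntryBundle,
    manifest_urls: tuple[str, str],
    publisher: str = "Imperial College London",
    publication_year: str = "2015",
) -> DataCiteRecord:
    """Map one entry's metadata to a DataCite kernel-3 record.

    ``manifest_urls`` is the (METS URL, ORE URL) pair; both appear as
    HasMetadata related identifiers.  Entries without named contributors get
    the standard unavailable-value code as creator so the record stays
    schema-valid.
    """
    mets_url, ore_url = manifest_urls
    creators = tuple((name, orcid) for name, orcid in metadata.contributors) or (
        ("(:unav)", None),
    )
    alternates: list[tuple[str, str]] = []
    if metadata.inchi:
        alternates.append(("InChI", metadata.inchi))
    if metadata.inchikey:
        alternates.append(("InChIKey", metadata.inchikey))
    if metadata.cas_id:
        alternates.append(("CAS", metadata.cas_id))
    if metadata.nsc_id is not None:
        alternates.append(("NCI", str(metadata.nsc_id)))
    if metadata.smiles:
        alternates.append(("SMILES", metadata.smiles))
    related = [
        RelatedIdentifier(
            value=mets_url,
            metadata_scheme="METS",
            scheme_uri=METS_SCHEME_URI,
        ),
        RelatedIdentifier(
            value=ore_url,
            metadata_scheme="OAI-ORE",
            scheme_uri=ORE_SCHEME_URI,
        ),
        RelatedIdentifier(
            value=bundle.handle,
            id_type="Handle",
            relation_type="IsPartOf",
        ),
    ]
    return DataCiteRecord(
        doi=bundle.doi,
        creators=creators,
        title=metadata.name,
        publisher=publisher,
        publication_year=publication_year,
        alternate_identifiers=tuple(alternates),
        related_identifiers=tuple(related),
    )


def register_media(record: DataCiteRecord, mime: str, url: str) -> DataCiteRecord:
    """Add a (media type, URL) pair, as the DataCite Media API would record it.

    Idempotent: registering an identical pair returns the record unchanged.
    """
    pair = (mime, url)
    if pair in record.media:
        return record
    return replace(record, media=record.media + (pair,))


# ---------------------------------------------------------------------------
# XML serialization


def related_identifier_element(rel: RelatedIdentifier) -> str:
    """Serialize one relatedIdentifier element exactly as registered."""
    el = etree.Element("relatedIdentifier")
    el.set("relatedIdentifierType", rel.id_type)
    el.set("relationType", rel.relation_type)
    if rel.metadata_scheme:
        el.set("relatedMetadataScheme", rel.metadata_scheme)
    if rel.scheme_uri:
        el.set("schemeURI", rel.scheme_uri)
    el.text = rel.value
    return etree.tostring(el, encoding="unicode")


def to_datacite_xml(record: DataCiteRecord, validate: bool = True) -> str:
    """DataCite kernel-3 XML for a record, validated against the bundled
    schema profile."""
    q = lambda tag: f"{{{DATACITE_NS}}}{tag}"  # noqa: E731
    root = etree.Element(q("resource"), nsmap={None: DATACITE_NS})
    ident = etree.SubElement(root, q("identifier"))
    ident.set("identifierType", "DOI")
    ident.text = record.doi
    creators = etree.SubElement(root, q("creators"))
    for name, orcid in record.creators:
        cr = etree.SubElement(creators, q("creator"))
        etree.SubElement(cr, q("creatorName")).text = name
        if orcid:
            ni = etree.SubElement(cr, q("nameIdentifier"))
            ni.set("schemeURI", ORCID_SCHEME_URI)
            ni.set("nameIdentifierScheme", "ORCID")
            ni.text = orcid
    titles = etree.SubElement(root, q("titles"))
    etree.SubElement(titles, q("title")).text = record.title
    etree.SubElement(root, q("publisher")).text = record.publisher
    etree.SubElement(root, q("publicationYear")).text = record.publication_year
    if record.alternate_identifiers:
        alts = etree.SubElement(root, q("alternateIdentifiers"))
        for scheme, value in record.alternate_identifiers:
            alt = etree.SubElement(alts, q("alternateIdentifier"))
            alt.set("alternateIdentifierType", scheme)
            alt.text = value
    if record.related_identifiers:
        rels = etree.SubElement(root, q("relatedIdentifiers"))
        for rel in record.related_identifiers:
            el = etree.SubElement(rels, q("relatedIdentifier"))
            el.set("relatedIdentifierType", rel.id_type)
            el.set("relationType", rel.relation_type)
            if rel.metadata_scheme:
                el.set("relatedMetadataScheme", rel.metadata_scheme)
            if rel.scheme_uri:
                el.set("schemeURI", rel.scheme_uri)
            el.text = rel.value
    text = etree.tostring(root, pretty_print=True, encoding="unicode")
    if validate:
        xsd = _load_schema("datacite-v3")
        doc = etree.fromstring(text.encode())
        if not xsd.validate(doc):
            entry = xsd.error_log[0]
            raise CMLValidationError(
                f"generated DataCite record fails schema validation at "
                f"{entry.path or entry.line}: {entry.message}"
            )
    return text


# ---------------------------------------------------------------------------
# machine-actionable retrieval URLs


def build_locatt_url(handle: str, mime: str, resolver: str = HANDLE_RESOLVER) -> str:
    """Handle 10320/loc retrieval URL: ``<resolver><handle>?locatt=mimetype:<mime>``."""
    if not handle or "/" not in handle:
        raise CMLValidationError(f"malformed handle {handle!r}")
    return f"{resolver}{handle}?locatt=mimetype:{mime}"


def build_media_url(doi: str, mime: str, resolver: str = CONTENT_RESOLVER) -> str:
    """DataCite content-resolver URL: ``<content-resolver><mime>/<doi>``."""
    if not doi or "/" not in doi:
        raise CMLValidationError(f"malformed DOI {doi!r}")
    return f"{resolver}{mime}/{doi}"


# ---------------------------------------------------------------------------
# fielded search


@dataclass(frozen=True)
class Term:
    """One ``field:value`` search term; ``wildcard`` appends ``*``."""

    field: str
    value: str
    wildcard: bool = False
    op: str = ":"  # the UI also accepts '=' for exact identifier match


@dataclass(frozen=True)
class SearchQuery:
    terms: tuple[Term, ...]
    output_format: str = "ui"  # ui | xml | csv | json
    row_limit: int | None = None
    fields: tuple[str, ...] = ("doi", "title", "relatedIdentifier")

    def __post_init__(self) -> None:
        if not self.terms:
            raise CMLValidationError("a search query needs at least one term")
        if self.output_format not in ("ui", "xml", "csv", "json"):
            raise CMLValidationError(f"unknown output format {self.output_format!r}")


def _escape_value(value: str) -> str:
    """Backslash-escape ':' and '/' inside field values; '*' is never escaped."""
    return value.replace(":", r"\:").replace("/", r"\/")


def build_search_query(query: SearchQuery, base: str = SEARCH_BASE) -> str:
    """Serialize to the search API grammar: '+'-joined ``field:value`` terms,
    with ``fl``/``wt``/``rows`` parameters appended for the API formats."""
    parts = []
    for t in query.terms:
        value = _escape_value(t.value)
        if t.wildcard:
            value += "*"
        parts.append(f"{t.field}{t.op}{value}")
    q = "+".join(parts)
    if query.output_format == "ui":
        return f"{base}/ui?q={q}"
    url = f"{base}/api?&q={q}&fl={','.join(query.fields)}&wt={query.output_format}"
    if query.row_limit is not None:
        url += f"&rows={query.row_limit}"
    return url


@dataclass(frozen=True)
class SearchHit:
    """One search result row: DOI, title, and its related identifiers as
    (relationType, identifierType, value) triples."""

    doi: str
    title: str
    related: tuple[tuple[str, str, str], ...] = ()

    def has_metadata_urls(self) -> tuple[str, ...]:
        """The HasMetadata child URLs — the entry's METS/ORE manifest locations."""
        return tuple(v for rel, _t, v in self.related if rel == "HasMetadata")


def _split_related(cell: str) -> tuple[tuple[str, str, str], ...]:
    out = []
    for token in (t.strip() for t in cell.split(", ")):
        if not token:
            continue
        pieces = token.split(":", 2)
        if len(pieces) != 3:
            raise SearchPayloadError(f"unparseable related identifier {token!r}")
        out.append((pieces[0], pieces[1], pieces[2]))
    return tuple(out)


def parse_search_response(payload: str) -> list[SearchHit]:
    """Parse a search-API response (csv or xml form) into hits.

    The csv form carries a ``doi,title,relatedIdentifier`` header and packs
    all related identifiers of a row into one quoted cell; splitting the
    HasMetadata children out is what enables programmatic re-curation from
    the manifests alone.
    """
    payload = payload.strip()
    if not payload:
        return []
    if payload.startswith("<"):
        return _parse_search_xml(payload)
    reader = csv.reader(io.StringIO(payload))
    rows = list(reader)
    header = rows[0]
    if [h.strip() for h in header[:2]] != ["doi", "title"]:
        raise SearchPayloadError(f"unexpected csv header {header!r}")
    hits: list[SearchHit] = []
    for idx, row in enumerate(rows[1:], start=1):
        if not row:
            continue
        if len(row) < 2:
            raise SearchPayloadError(f"csv record {idx}: expected at least doi,title")
        related = _split_related(row[2]) if len(row) > 2 and row[2] else ()
        hits.append(SearchHit(doi=row[0].strip(), title=row[1].strip(), related=related))
    return hits


def _parse_search_xml(payload: str) -> list[SearchHit]:
    try:
        root = etree.fromstring(payload.encode())
    except etree.XMLSyntaxError as exc:
        raise SearchPayloadError(f"malformed xml payload: {exc}") from exc
    hits: list[SearchHit] = []
    for idx, doc in enumerate(root.iter("doc")):
        fields = {el.get("name"): el for el in doc if el.get("name")}
        if "doi" not in fields or "title" not in fields:
            raise SearchPayloadError(f"xml record {idx}: missing doi/title")
        related: list[tuple[str, str, str]] = []
        arr = fields.get("relatedIdentifier")
        if arr is not None:
            for s in arr.iter("str"):
                if s.text:
                    related.extend(_split_related(s.text))
        hits.append(
            SearchHit(
                doi=fields["doi"].text or "",
                title=fields["title"].text or "",
                related=tuple(related),
            )
        )
    return hits


def serialize_search_response(hits: Sequence[SearchHit], fmt: str = "csv") -> str:
    """Emit hits in the search API's csv or xml form (round-trip companion,
    also used by the recording mock transport)."""
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["doi", "title", "relatedIdentifier"])
        for h in hits:
            cell = ", ".join(f"{r}:{t}:{v}" for r, t, v in h.related)
            writer.writerow([h.doi, h.title, cell])
        return buf.getvalue()
    if fmt == "xml":
        root = etree.Element("response")
        result = etree.SubElement(root, "result")
        result.set("numFound", str(len(hits)))
        for h in hits:
            doc = etree.SubElement(result, "doc")
            d = etree.SubElement(doc, "str")
            d.set("name", "doi")
            d.text = h.doi
            t = etree.SubElement(doc, "str")
            t.set("name", "title")
            t.text = h.title
            arr = etree.SubElement(doc, "arr")
            arr.set("name", "relatedIdentifier")
            for r, ty, v in h.related:
                etree.SubElement(arr, "str").text = f"{r}:{ty}:{v}"
        return etree.tostring(root, pretty_print=True, encoding="unicode")
    raise CMLValidationError(f"unknown serialization format {fmt!r}")
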