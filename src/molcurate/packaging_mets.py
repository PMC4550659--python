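"""Per-entry deposition bundles: checksummed files, METS manifest, ORE map, SWORD archive.

Each curated molecule is packaged individually: the data files (the two
unaltered source CML documents, the conflated three-geometry CML, and the
optimizer input/output for the re-computation) are described in a METS
manifest whose ``fileSec`` records size, MD5 checksum and chemical media
type per file, an OAI-ORE resource map lists the retrieval URL of every
file, and the whole set is zipped into a SWORD-ready archive suitable for
a METSDSpaceSIP-packaged deposit into any compliant repository.

MD5 is retained deliberately — it is what the target repository profile
records — and ``CHECKSUMTYPE`` is always written so a future curation can
migrate digests knowingly.
"""

from __future__ import annotations

import hashlib
import io
import re
import warnings
import zipfile
from dataclasses import dataclass, field
from typing import Sequence

from lxml import etree

from .cml_records import _load_schema  # shared XSD cache
from .errors import CMLValidationError, ConfigurationError

METS_NS = "http://www.loc.gov/METS/"
XLINK_NS = "http://www.w3.org/1999/xlink"
DIM_NS = "http://www.dspace.org/xmlns/dspace/dim"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
ORE_NS = "http://www.openarchives.org/ore/terms/"

SWORD_PACKAGING = "http://purl.org/net/sword-types/METSDSpaceSIP"
DEFAULT_REPOSITORY_BASE = "https://spectradspace.lib.imperial.ac.uk:8443"

#: Registered media types by file extension; structure XML is chemical/x-cml.
MEDIA_TYPES = {
    ".cml": "chemical/x-cml",
    ".xml": "chemical/x-cml",
    ".mop": "chemical/x-mopac-input",
    ".dat": "chemical/x-mopac-input",
    ".out": "chemical/x-mopac-output",
    ".arc": "chemical/x-mopac-archive",
    ".xyz": "chemical/x-xyz",
}
FALLBACK_MEDIA_TYPE = "application/octet-stream"

_HANDLE_RE = re.compile(r"^\d[\d.]*/\S+$")
_DOI_RE = re.compile(r"^10\.\d{4,9}/\S+$")
_ORCID_RE = re.compile(r"^(\d{4})-(\d{4})-(\d{4})-(\d{3}[\dX])$")


class UnknownMediaTypeWarning(UserWarning):
    """A filename fell outside the registered media-type table."""


def checksum_file(payload: bytes) -> tuple[int, str]:
    """Size in bytes and lowercase-hex MD5 digest of a payload."""
    return len(payload), hashlib.md5(payload).hexdigest()


def assign_mime(filename: str) -> str:
    """Media type for a bundle filename, from the registered table.

    Unknown extensions degrade gracefully to application/octet-stream with
    an :class:`UnknownMediaTypeWarning`.
    """
    dot = filename.rfind(".")
    ext = filename[dot:].lower() if dot >= 0 else ""
    mime = MEDIA_TYPES.get(ext)
    if mime is None:
        warnings.warn(
            f"no registered media type for {filename!r}; using {FALLBACK_MEDIA_TYPE}",
            UnknownMediaTypeWarning,
            stacklevel=2,
        )
        return FALLBACK_MEDIA_TYPE
    return mime


def orcid_is_valid(orcid: str) -> bool:
    """Syntactic + ISO 7064 11-2 checksum validation of an ORCID iD."""
    m = _ORCID_RE.match(orcid)
    if not m:
        return False
    digits = orcid.replace("-", "")
    total = 0
    for ch in digits[:-1]:
        total = (total + int(ch)) * 2
    check = (12 - total % 11) % 11
    expected = "X" if check == 10 else str(check)
    return digits[-1] == expected


@dataclass(frozen=True)
class BundleFile:
    """One data file of a deposition bundle, with its manifest attributes."""

    filename: str
    payload: bytes
    mime: str
    size: int
    md5: str
    sequence: int

    def __post_init__(self) -> None:
        size, md5 = checksum_file(self.payload)
        if size != self.size or md5 != self.md5:
            raise CMLValidationError(f"{self.filename}: size/checksum do not match payload")

    @classmethod
    def from_payload(cls, filename: str, payload: bytes, sequence: int) -> "BundleFile":
        size, md5 = checksum_file(payload)
        return cls(
            filename=filename,
            payload=payload,
            mime=assign_mime(filename),
            size=size,
            md5=md5,
            sequence=sequence,
        )


@dataclass(frozen=True)
class EntryMetadata:
    """Descriptive metadata of one entry, exactly the deposited field list:
    chemical identifiers, accessions and name, the back-link to the origin
    entry, the article DOI, contributor ORCIDs and the license URL."""

    name: str
    nsc_id: int | None = None
    cas_id: str | None = None
    inchi: str | None = None
    inchikey: str | None = None
    smiles: str | None = None
    back_link: str | None = None
    article_doi: str | None = None
    contributors: tuple[tuple[str, str], ...] = ()  # (display name, ORCID iD)
    license_url: str | None = None

    def __post_init__(self) -> None:
        for name, orcid in self.contributors:
            if not orcid_is_valid(orcid):
                raise CMLValidationError(f"contributor {name!r}: invalid ORCID iD {orcid!r}")

    @property
    def orcids(self) -> tuple[str, ...]:
        return tuple(orcid for _, orcid in self.contributors)


@dataclass(frozen=True)
class EntryBundle:
    """Repository-ready package for one molecule: identifiers, metadata, files."""

    handle: str  # e.g. 10042/159060
    doi: str  # e.g. 10.14469/ch/159060
    metadata: EntryMetadata
    files: tuple[BundleFile, ...]

    def __post_init__(self) -> None:
        if not _HANDLE_RE.match(self.handle):
            raise CMLValidationError(f"syntactically invalid handle {self.handle!r}")
        if not _DOI_RE.match(self.doi):
            raise CMLValidationError(f"syntactically invalid DOI {self.doi!r}")
        seqs = [f.sequence for f in self.files]
        if len(set(seqs)) != len(seqs):
            raise CMLValidationError("bundle file sequence ordinals must be unique")


def bitstream_path(handle: str, filename: str, sequence: int) -> str:
    """Site-relative retrieval path of one bitstream."""
    return f"/bitstream/handle/{handle}/{filename}?sequence={sequence}"


def manifest_url(handle: str, which: str, base: str = DEFAULT_REPOSITORY_BASE) -> str:
    """Absolute URL of the METS or ORE manifest generated for an entry."""
    if which not in ("mets", "ore"):
        raise ConfigurationError("which must be 'mets' or 'ore'")
    return f"{base}/metadata/handle/{handle}/{which}.xml"


def _dim_field(parent, element: str, value: str, qualifier: str | None = None, authority: str | None = None):
    el = etree.SubElement(parent, f"{{{DIM_NS}}}field")
    el.set("mdschema", "dc")
    el.set("element", element)
    if qualifier:
        el.set("qualifier", qualifier)
    if authority:
        el.set("authority", authority)
    el.text = value
    return el


def build_mets(bundle: EntryBundle, validate: bool = True) -> str:
    """The METS manifest: descriptive metadata plus one ``mets:file`` per
    bundle file carrying CHECKSUMTYPE/CHECKSUM/MIMETYPE/SIZE and an FLocat
    whose href follows the repository bitstream path pattern."""
    if not bundle.files:
        raise CMLValidationError("cannot build a METS manifest for an empty file list")
    nsmap = {"mets": METS_NS, "xlink": XLINK_NS, "dim": DIM_NS}
    root = etree.Element(f"{{{METS_NS}}}mets", nsmap=nsmap)
    root.set("OBJID", f"hdl:{bundle.handle}")
    root.set("PROFILE", "DSpace METS SIP Profile 1.0")

    dmd = etree.SubElement(root, f"{{{METS_NS}}}dmdSec")
    dmd.set("ID", "dmd_1")
    wrap = etree.SubElement(dmd, f"{{{METS_NS}}}mdWrap")
    wrap.set("MDTYPE", "OTHER")
    wrap.set("OTHERMDTYPE", "DIM")
    xml_data = etree.SubElement(wrap, f"{{{METS_NS}}}xmlData")
    dim = etree.SubElement(xml_data, f"{{{DIM_NS}}}dim")

    md = bundle.metadata
    _dim_field(dim, "title", md.name)
    if md.nsc_id is not None:
        _dim_field(dim, "identifier", f"NCI:{md.nsc_id}", qualifier="other")
    if md.cas_id:
        _dim_field(dim, "identifier", f"CAS:{md.cas_id}", qualifier="other")
    for qual, value in (("inchi", md.inchi), ("inchikey", md.inchikey), ("smiles", md.smiles)):
        if value:
            _dim_field(dim, "identifier", value, qualifier=qual)
    _dim_field(dim, "identifier", f"doi:{bundle.doi}", qualifier="uri")
    if md.back_link:
        _dim_field(dim, "relation", md.back_link, qualifier="isreplacedby")
    if md.article_doi:
        _dim_field(dim, "relation", md.article_doi, qualifier="isreferencedby")
    for cname, orcid in md.contributors:
        _dim_field(dim, "contributor", cname, qualifier="author", authority=f"orcid:{orcid}")
    if md.license_url:
        _dim_field(dim, "rights", md.license_url, qualifier="uri")

    file_sec = etree.SubElement(root, f"{{{METS_NS}}}fileSec")
    grp = etree.SubElement(file_sec, f"{{{METS_NS}}}fileGrp")
    grp.set("USE", "CONTENT")
    for bf in bundle.files:
        fel = etree.SubElement(grp, f"{{{METS_NS}}}file")
        fel.set("CHECKSUMTYPE", "MD5")
        fel.set("GROUPID", f"group_file_{bf.sequence}")
        fel.set("ID", f"file_{bf.sequence}")
        fel.set("MIMETYPE", bf.mime)
        fel.set("SIZE", str(bf.size))
        fel.set("CHECKSUM", bf.md5)
        loc = etree.SubElement(fel, f"{{{METS_NS}}}FLocat")
        loc.set("LOCTYPE", "URL")
        loc.set(f"{{{XLINK_NS}}}title", bf.filename)
        loc.set(f"{{{XLINK_NS}}}type", "locator")
        loc.set(f"{{{XLINK_NS}}}href", bitstream_path(bundle.handle, bf.filename, bf.sequence))

    smap = etree.SubElement(root, f"{{{METS_NS}}}structMap")
    div = etree.SubElement(smap, f"{{{METS_NS}}}div")
    div.set("DMDID", "dmd_1")
    for bf in bundle.files:
        fptr = etree.SubElement(div, f"{{{METS_NS}}}fptr")
        fptr.set("FILEID", f"file_{bf.sequence}")

    text = etree.tostring(root, pretty_print=True, encoding="unicode")
    if validate:
        xsd = _load_schema("mets")
        doc = etree.fromstring(text.encode())
        if not xsd.validate(doc):
            entry = xsd.error_log[0]
            raise CMLValidationError(
                f"generated METS fails profile validation at {entry.path or entry.line}: "
                f"{entry.message}"
            )
    return text


def build_ore_map(bundle: EntryBundle, base: str = DEFAULT_REPOSITORY_BASE) -> str:
    """OAI-ORE resource map (RDF/XML): one aggregation whose aggregated
    resources are the absolute retrieval URLs of every bundle file —
    the same URL set the METS FLocat entries describe."""
    if not bundle.files:
        raise CMLValidationError("cannot build a resource map for an empty file list")
    nsmap = {"rdf": RDF_NS, "ore": ORE_NS}
    root = etree.Element(f"{{{RDF_NS}}}RDF", nsmap=nsmap)
    map_url = manifest_url(bundle.handle, "ore", base)
    desc = etree.SubElement(root, f"{{{RDF_NS}}}Description")
    desc.set(f"{{{RDF_NS}}}about", f"{map_url}#aggregation")
    typ = etree.SubElement(desc, f"{{{RDF_NS}}}type")
    typ.set(f"{{{RDF_NS}}}resource", f"{ORE_NS}Aggregation")
    for bf in bundle.files:
        agg = etree.SubElement(desc, f"{{{ORE_NS}}}aggregates")
        agg.set(
            f"{{{RDF_NS}}}resource",
            base + bitstream_path(bundle.handle, bf.filename, bf.sequence),
        )
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def build_sword_bundle(bundle: EntryBundle, base: str = DEFAULT_REPOSITORY_BASE) -> bytes:
    """Compressed SWORD bundle: mets.xml plus every payload file.

    Unpacking and re-checksumming reproduces every manifest digest; the
    archive is suitable for a METSDSpaceSIP-packaged deposit.
    """
    mets_text = build_mets(bundle)
    buf = io.BytesIO()
    stamp = (2015, 8, 27, 0, 0, 0)  # fixed so identical bundles are byte-identical
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(zipfile.ZipInfo("mets.xml", date_time=stamp), mets_text)
        for bf in bundle.files:
            zf.writestr(zipfile.ZipInfo(bf.filename, date_time=stamp), bf.payload)
    return buf.getvalue()


@dataclass(frozen=True)
class DepositAction:
    """One SWORD deposit request, fully described but not executed."""

    url: str
    headers: tuple[tuple[str, str], ...]
    archive_name: str = "mets.zip"

    def header_dict(self) -> dict[str, str]:
        return dict(self.headers)


def sword_deposit_action(
    collection_handle: str,
    base: str = DEFAULT_REPOSITORY_BASE,
    no_op: bool = True,
) -> DepositAction:
    """Shape of the SWORD v1 deposit request for a bundle archive.

    Dry-run by default (``X-No-Op: true``); nothing here touches the
    network — executing the request is the caller's decision.
    """
    if not _HANDLE_RE.match(collection_handle):
        raise CMLValidationError(f"syntactically invalid handle {collection_handle!r}")
    return DepositAction(
        url=f"{base}/sword/deposit/{collection_handle}",
        headers=(
            ("Content-Disposition", "filename=mets.zip"),
            ("Content-Type", "application/zip"),
            ("X-Packaging", SWORD_PACKAGING),
            ("X-No-Op", "true" if no_op else "false"),
            ("X-Verbose", "true"),
        ),
    )
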