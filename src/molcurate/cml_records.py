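"""Reading, validating and writing the two CML dialects of the corpus.

The collection being curated stores every molecule twice: an *original*
document whose net charge lives in a legacy ``identifier`` element
(``<charge>+1</charge>`` next to an early-InChI ``<basic>`` string), and a
*post-optimization* document that declares the charge as a ``formalCharge``
attribute on the ``molecule`` element.  Both dialects are captured
independently and an undeclared charge is recorded as :data:`None` — absence
is a distinct state, never silently read as zero.  That distinction is the
module-level guard against the implicit-default failure mode that motivates
the whole curation workflow.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
from lxml import etree

from .errors import CMLParseError, CMLValidationError, ConfigurationError, GeometryError
from .formula import formula_counts, hill_formula, is_element

CML_NS = "http://www.xml-cml.org/schema"
_NSMAP = {None: CML_NS}

PROVENANCES = ("NCI", "PM5", "PM7")

#: Elements that, alone, typically constitute a removed counter-ion component.
COUNTER_ION_ELEMENTS = frozenset(
    {"Li", "Na", "K", "Rb", "Cs", "Mg", "Ca", "Sr", "Ba", "F", "Cl", "Br", "I"}
)


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, optional Cartesian position (Å), optional mass number."""

    element: str
    position: tuple[float, float, float] | None = None
    isotope: int | None = None

    def __post_init__(self) -> None:
        if not is_element(self.element):
            raise CMLValidationError(f"unknown element symbol {self.element!r}")
        if self.position is not None:
            if len(self.position) != 3 or not all(math.isfinite(c) for c in self.position):
                raise GeometryError(
                    f"atom {self.element}: position must be three finite coordinates"
                )


@dataclass(frozen=True)
class MoleculeRecord:
    """One version of one molecule, as read from a single CML document.

    ``formal_charge_attr`` and ``legacy_charge`` are each ``None`` when the
    corresponding dialect did not declare a charge; ``None`` ≠ 0.
    """

    atoms: tuple[Atom, ...]
    provenance: str = "NCI"
    nsc_id: int | None = None
    cas_id: str | None = None
    name: str | None = None
    bonds: tuple[tuple[int, int, str], ...] = ()
    formal_charge_attr: int | None = None
    legacy_charge: int | None = None
    legacy_basic: str | None = None
    smiles: str | None = None
    inchi: str | None = None
    inchikey: str | None = None

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise CMLValidationError(
                f"provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )
        n = len(self.atoms)
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise CMLValidationError(f"bond ({i},{j}) references atom out of range (n={n})")

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.element for a in self.atoms)

    def formula(self) -> dict[str, int]:
        return formula_counts(self.elements)

    def has_positions(self) -> bool:
        return bool(self.atoms) and all(a.position is not None for a in self.atoms)


@dataclass(frozen=True)
class CorpusReport:
    """Bookkeeping for a deduplication / filtering pass over a corpus."""

    total_read: int
    unique_kept: int
    duplicates_removed: int
    excluded_no_annotation: int = 0

    def __post_init__(self) -> None:
        if self.total_read != (
            self.unique_kept + self.duplicates_removed + self.excluded_no_annotation
        ):
            raise CMLValidationError("corpus report counts are inconsistent")


@dataclass(frozen=True)
class Violation:
    """One schema/profile violation: where and what."""

    path: str
    message: str


@dataclass(frozen=True)
class CMLProfile:
    """Schema descriptor: which XSD profile to apply, plus corpus profile rules."""

    name: str = "cml24"
    require_bond_array: bool = False


CML24 = CMLProfile()
CML24_WITH_BONDS = CMLProfile(require_bond_array=True)


@dataclass(frozen=True)
class ComponentRemoval:
    """Summary of atoms dropped by :func:`select_largest_component`."""

    formula: str  # Hill formula of all removed atoms; "" when nothing removed
    n_atoms_removed: int
    tie_break: bool = False  # equal-size components; lowest-index one retained
    charge_suspect: bool = False  # counter-ion removed but no nonzero charge declared


# ---------------------------------------------------------------------------
# parsing


def _q(tag: str) -> str:
    return f"{{{CML_NS}}}{tag}"


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _find(parent: etree._Element, tag: str) -> etree._Element | None:
    """Find a direct child by local name, namespace-agnostic (legacy documents
    in the original collection predate consistent namespacing)."""
    for child in parent:
        if isinstance(child.tag, str) and etree.QName(child).localname == tag:
            return child
    return None


def _findall(parent: etree._Element, tag: str) -> list[etree._Element]:
    return [
        c
        for c in parent
        if isinstance(c.tag, str) and etree.QName(c).localname == tag
    ]


def _parse_charge_text(text: str | None, where: str) -> int:
    if text is None:
        raise CMLParseError(f"empty charge value in {where}")
    text = text.strip()
    try:
        return int(text)
    except ValueError as exc:
        raise CMLParseError(f"cannot parse charge {text!r} in {where}") from exc


def _molecule_element(root: etree._Element) -> etree._Element:
    if _local(root) == "molecule":
        return root
    if _local(root) == "cml":
        mols = _findall(root, "molecule")
        if len(mols) == 1:
            return mols[0]
        raise CMLParseError(
            f"expected exactly one molecule element, found {len(mols)} "
            "(use parse_conflated_cml for multi-geometry documents)"
        )
    raise CMLParseError(f"unexpected root element {_local(root)!r}")


def _parse_molecule(mol: etree._Element) -> MoleculeRecord:
    nsc_id: int | None = None
    mol_id = mol.get("id")
    if mol_id and mol_id.upper().startswith("NSC"):
        try:
            nsc_id = int(mol_id[3:])
        except ValueError:
            nsc_id = None

    formal_charge_attr: int | None = None
    if mol.get("formalCharge") is not None:
        formal_charge_attr = _parse_charge_text(mol.get("formalCharge"), "formalCharge attribute")

    atoms: list[Atom] = []
    atom_ids: dict[str, int] = {}
    atom_array = _find(mol, "atomArray")
    if atom_array is not None:
        for el in _findall(atom_array, "atom"):
            sym = el.get("elementType")
            if sym is None:
                raise CMLParseError(f"atom {el.get('id')!r} lacks elementType")
            if not is_element(sym):
                raise CMLValidationError(
                    f"atom {el.get('id') or len(atoms)}: unknown element symbol {sym!r}"
                )
            pos = None
            if el.get("x3") is not None:
                try:
                    pos = (float(el.get("x3")), float(el.get("y3")), float(el.get("z3")))
                except (TypeError, ValueError) as exc:
                    raise CMLParseError(
                        f"atom {el.get('id')!r}: bad coordinates"
                    ) from exc
            iso = el.get("isotopeNumber")
            atoms.append(Atom(sym, pos, int(iso) if iso is not None else None))
            if el.get("id"):
                atom_ids[el.get("id")] = len(atoms) - 1

    bonds: list[tuple[int, int, str]] = []
    bond_array = _find(mol, "bondArray")
    if bond_array is not None:
        for el in _findall(bond_array, "bond"):
            refs = (el.get("atomRefs2") or "").split()
            if len(refs) != 2:
                raise CMLParseError(f"bond with bad atomRefs2 {el.get('atomRefs2')!r}")
            try:
                i, j = atom_ids[refs[0]], atom_ids[refs[1]]
            except KeyError as exc:
                raise CMLParseError(f"bond references unknown atom id {exc.args[0]!r}") from exc
            bonds.append((i, j, el.get("order") or "1"))

    legacy_charge: int | None = None
    legacy_basic: str | None = None
    ident = _find(mol, "identifier")
    if ident is not None:
        basic = _find(ident, "basic")
        if basic is not None and basic.text:
            legacy_basic = basic.text.strip()
        charge = _find(ident, "charge")
        if charge is not None:
            legacy_charge = _parse_charge_text(charge.text, "identifier/charge")

    meta: dict[str, str] = {}
    meta_list = _find(mol, "metadataList")
    if meta_list is not None:
        for el in _findall(meta_list, "metadata"):
            if el.get("name") and el.get("content") is not None:
                meta[el.get("name")] = el.get("content")

    return MoleculeRecord(
        atoms=tuple(atoms),
        provenance=mol.get("provenance") or "NCI",
        nsc_id=nsc_id,
        cas_id=meta.get("mc:cas"),
        name=mol.get("name"),
        bonds=tuple(bonds),
        formal_charge_attr=formal_charge_attr,
        legacy_charge=legacy_charge,
        legacy_basic=legacy_basic,
        smiles=meta.get("mc:smiles"),
        inchi=meta.get("mc:inchi"),
        inchikey=meta.get("mc:inchikey"),
    )


def _parse_xml(document: str | bytes) -> etree._Element:
    if isinstance(document, str):
        document = document.encode()
    try:
        return etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise CMLParseError(f"malformed XML: {exc}") from exc


def parse_cml(document: str | bytes) -> MoleculeRecord:
    """Parse a single-molecule CML document (either dialect) into a record.

    Both charge declarations are captured independently; a missing dialect is
    recorded as ``None``, never coerced to 0.  Atom order follows document
    order.
    """
    return _parse_molecule(_molecule_element(_parse_xml(document)))


def parse_conflated_cml(document: str | bytes) -> list[MoleculeRecord]:
    """Parse a conflated multi-geometry document into its provenance-tagged records."""
    root = _parse_xml(document)
    if _local(root) == "molecule":
        return [_parse_molecule(root)]
    if _local(root) != "cml":
        raise CMLParseError(f"unexpected root element {_local(root)!r}")
    mols = _findall(root, "molecule")
    if not mols:
        raise CMLParseError("conflated document contains no molecule elements")
    return [_parse_molecule(m) for m in mols]


# ---------------------------------------------------------------------------
# writing


def _fmt(x: float) -> str:
    return repr(float(x))


def _write_molecule(record: MoleculeRecord) -> etree._Element:
    mol = etree.Element(_q("molecule"), nsmap=_NSMAP)
    if record.nsc_id is not None:
        mol.set("id", f"NSC{record.nsc_id}")
    if record.name is not None:
        mol.set("name", record.name)
    if record.formal_charge_attr is not None:
        mol.set("formalCharge", str(record.formal_charge_attr))
    mol.set("provenance", record.provenance)

    if record.legacy_basic is not None or record.legacy_charge is not None:
        ident = etree.SubElement(mol, _q("identifier"))
        ident.set("version", "0.932Beta")
        ident.set("tautomeric", "0")
        if record.legacy_basic is not None:
            etree.SubElement(ident, _q("basic")).text = record.legacy_basic
        if record.legacy_charge is not None:
            etree.SubElement(ident, _q("charge")).text = f"{record.legacy_charge:+d}"

    arr = etree.SubElement(mol, _q("atomArray"))
    for idx, atom in enumerate(record.atoms):
        el = etree.SubElement(arr, _q("atom"))
        el.set("id", f"a{idx + 1}")
        el.set("elementType", atom.element)
        if atom.position is not None:
            el.set("x3", _fmt(atom.position[0]))
            el.set("y3", _fmt(atom.position[1]))
            el.set("z3", _fmt(atom.position[2]))
        if atom.isotope is not None:
            el.set("isotopeNumber", str(atom.isotope))

    if record.bonds:
        barr = etree.SubElement(mol, _q("bondArray"))
        for i, j, order in record.bonds:
            b = etree.SubElement(barr, _q("bond"))
            b.set("atomRefs2", f"a{i + 1} a{j + 1}")
            b.set("order", order)

    meta_pairs = [
        ("mc:cas", record.cas_id),
        ("mc:smiles", record.smiles),
        ("mc:inchi", record.inchi),
        ("mc:inchikey", record.inchikey),
    ]
    meta_pairs = [(k, v) for k, v in meta_pairs if v is not None]
    if meta_pairs:
        ml = etree.SubElement(mol, _q("metadataList"))
        for k, v in meta_pairs:
            m = etree.SubElement(ml, _q("metadata"))
            m.set("name", k)
            m.set("content", v)
    return mol


def write_cml(
    record: MoleculeRecord | Sequence[MoleculeRecord],
    profile: str = "legacy",
) -> str:
    """Serialize one record ("legacy" profile) or several provenance-tagged
    versions of the same molecule into a single conflated document.

    The output round-trips through :func:`parse_cml` /
    :func:`parse_conflated_cml` to equivalent records.
    """
    if profile not in ("legacy", "conflated"):
        raise ValueError(f"unknown profile {profile!r}")
    if profile == "legacy":
        if not isinstance(record, MoleculeRecord):
            raise TypeError("legacy profile writes a single MoleculeRecord")
        if not record.atoms:
            raise CMLValidationError("refusing to write a molecule with 0 atoms")
        root = _write_molecule(record)
    else:
        records = [record] if isinstance(record, MoleculeRecord) else list(record)
        if not records:
            raise CMLValidationError("conflated profile needs at least one record")
        for r in records:
            if not r.atoms:
                raise CMLValidationError("refusing to write a molecule with 0 atoms")
            if not r.has_positions():
                missing = [i for i, a in enumerate(r.atoms) if a.position is None]
                raise GeometryError(
                    f"conflated profile requires coordinates for all atoms; "
                    f"{r.provenance} record lacks positions for atoms {missing}"
                )
        root = etree.Element(_q("cml"), nsmap=_NSMAP)
        for r in records:
            root.append(_write_molecule(r))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# schema validation

_SCHEMA_CACHE: dict[str, etree.XMLSchema] = {}


def _load_schema(name: str) -> etree.XMLSchema:
    if name not in _SCHEMA_CACHE:
        try:
            res = importlib.resources.files("molcurate.schemas").joinpath(f"{name}-subset.xsd")
            with importlib.resources.as_file(res) as path:
                _SCHEMA_CACHE[name] = etree.XMLSchema(etree.parse(str(path)))
        except (FileNotFoundError, etree.XMLSchemaParseError, OSError) as exc:
            raise ConfigurationError(f"schema profile {name!r} unavailable: {exc}") from exc
    return _SCHEMA_CACHE[name]


def validate_cml(document: str | bytes, schema: CMLProfile = CML24) -> list[Violation]:
    """Validate a document against the declared CML 2.4 subset profile.

    Returns an empty list iff the document conforms.  Malformed XML raises
    :class:`CMLParseError` — a document that cannot be parsed has no violation
    list.
    """
    root = _parse_xml(document)
    xsd = _load_schema(schema.name)
    violations: list[Violation] = []
    if not xsd.validate(root):
        for entry in xsd.error_log:
            path = entry.path or f"line {entry.line}"
            violations.append(Violation(path=path, message=entry.message))
    if schema.require_bond_array:
        mols = [root] if _local(root) == "molecule" else _findall(root, "molecule")
        for mol in mols:
            if _find(mol, "bondArray") is None:
                violations.append(
                    Violation(
                        path=etree.ElementTree(root).getpath(mol),
                        message="profile requires a bondArray element; none present",
                    )
                )
    return violations


# ---------------------------------------------------------------------------
# corpus operations


def deduplicate(records: Sequence[MoleculeRecord]) -> tuple[list[MoleculeRecord], CorpusReport]:
    """Keep one record per NSC accession — the first encountered, in input order."""
    seen: set[int] = set()
    unique: list[MoleculeRecord] = []
    removed = 0
    for pos, rec in enumerate(records):
        if rec.nsc_id is None:
            raise CMLValidationError(f"record at position {pos} lacks an NSC accession")
        if rec.nsc_id in seen:
            removed += 1
        else:
            seen.add(rec.nsc_id)
            unique.append(rec)
    report = CorpusReport(
        total_read=len(records),
        unique_kept=len(unique),
        duplicates_removed=removed,
        excluded_no_annotation=0,
    )
    return unique, report


def filter_annotated(
    pairs: Sequence[tuple[MoleculeRecord, MoleculeRecord | None]],
) -> tuple[list[tuple[MoleculeRecord, MoleculeRecord]], int]:
    """Drop entries with no computed annotation, mirroring the original
    corpus policy of not recovering entries that never had a calculation."""
    kept = [(a, b) for a, b in pairs if b is not None]
    return kept, len(pairs) - len(kept)


def select_largest_component(
    record: MoleculeRecord, connectivity: "ConnectivityGraph"
) -> tuple[MoleculeRecord, ComponentRemoval]:
    """Retain the largest connected component (counter-ion stripping).

    Ties are broken deterministically in favour of the component containing
    the lowest original atom index, and flagged.  The declared whole-record
    charge is carried over unchanged; when the removed atoms look like a bare
    counter-ion yet no nonzero charge is declared, the result is flagged
    ``charge_suspect``.
    """
    from .connectivity_inchi import ConnectivityGraph  # cycle guard

    if not isinstance(connectivity, ConnectivityGraph):
        raise TypeError("connectivity must be a ConnectivityGraph")
    if connectivity.n_atoms != len(record.atoms):
        raise CMLValidationError("connectivity graph does not cover the record's atoms")
    if connectivity.n_atoms == 0:
        raise GeometryError("empty connectivity graph")

    g = nx.Graph()
    g.add_nodes_from(range(connectivity.n_atoms))
    g.add_edges_from(connectivity.edges)
    components = [sorted(c) for c in nx.connected_components(g)]
    max_size = max(len(c) for c in components)
    largest = [c for c in components if len(c) == max_size]
    largest.sort(key=lambda c: c[0])
    retained = largest[0]
    tie = len(largest) > 1

    keep = set(retained)
    if len(keep) == len(record.atoms):
        return record, ComponentRemoval(formula="", n_atoms_removed=0, tie_break=tie)

    index_map = {old: new for new, old in enumerate(retained)}
    new_atoms = tuple(record.atoms[i] for i in retained)
    new_bonds = tuple(
        (index_map[i], index_map[j], order)
        for i, j, order in record.bonds
        if i in keep and j in keep
    )
    removed_elements = [record.atoms[i].element for i in range(len(record.atoms)) if i not in keep]
    declared = record.formal_charge_attr if record.formal_charge_attr is not None else record.legacy_charge
    suspect = (
        all(el in COUNTER_ION_ELEMENTS for el in removed_elements)
        and (declared is None or declared == 0)
    )
    summary = ComponentRemoval(
        formula=hill_formula(formula_counts(removed_elements)),
        n_atoms_removed=len(removed_elements),
        tie_break=tie,
        charge_suspect=suspect,
    )
    return replace(record, atoms=new_atoms, bonds=new_bonds), summary
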