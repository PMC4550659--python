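"""Structure normalization, distance-based bond perception and InChI layers.

The normalization protocol deliberately throws away any connection table a
source document may carry: every structure version is reduced to bare
Cartesian coordinates (XMol XYZ), connectivity is re-perceived from a single
covalent-radius rule, and the InChI is generated from that one normalized
path.  Identifiers from different structure versions are then comparable,
because any disagreement must come from the geometry itself rather than
from whichever program once wrote the bonds.

Bond perception: atoms *i*, *j* are bonded iff

    floor < d(i, j) <= r(el_i) + r(el_j) + tolerance

with single-bond covalent radii from a versioned data file, a default
tolerance of 0.40 Å, and a 0.40 Å lower floor below which a pair is treated
as a geometry error (corrupt coordinates), not a bond.  There is no formal
standard for these thresholds, so they are explicit configuration here.

InChI canonicalization itself is delegated to the IUPAC reference library
via RDKit; re-implementing it is a non-goal.
"""

from __future__ import annotations

import importlib.resources
import json
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdDetermineBonds

from .cml_records import Atom, MoleculeRecord
from .errors import ConfigurationError, GeometryError, InChIError

# the reference library reports benign normalization notes (proton moves,
# stereo perception) through the RDKit warning log; keep corpus runs quiet
RDLogger.DisableLog("rdApp.warning")

DEFAULT_TOLERANCE = 0.40  # Å added to the radius sum
DISTANCE_FLOOR = 0.40  # Å; closer pairs indicate corrupt coordinates

#: Comparison labels in canonical layer order (stereo is two labels because
#: double-bond and tetrahedral mismatches are tallied separately).
LAYER_LABELS = (
    "formula",
    "connectivity",
    "hydrogen",
    "charge",
    "protonation",
    "double_bond",
    "tetrahedral",
    "isotope",
)


@lru_cache(maxsize=1)
def default_radii() -> dict[str, float]:
    """Covalent radius table (Å) shipped with the package."""
    res = importlib.resources.files("molcurate.data").joinpath("covalent_radii.json")
    with res.open() as fh:
        return dict(json.load(fh)["radii"])


def load_radii(path: str) -> dict[str, float]:
    """Load a user-supplied radius table: JSON with a top-level "radii" map
    (or a bare element → Å map)."""
    try:
        with open(path) as fh:
            data = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot load radius table {path!r}: {exc}") from exc
    return dict(data.get("radii", data))


@dataclass(frozen=True)
class ConnectivityGraph:
    """Undirected bond graph over atom indices."""

    n_atoms: int
    edges: frozenset[tuple[int, int]]  # each pair stored as (min, max)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise GeometryError(f"self-edge on atom {i}")
            if not (0 <= i < j < self.n_atoms):
                raise GeometryError(f"edge ({i},{j}) out of range for {self.n_atoms} atoms")

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)


def _positions(atoms: Sequence[Atom]) -> np.ndarray:
    missing = [i for i, a in enumerate(atoms) if a.position is None]
    if missing:
        raise GeometryError(f"atoms {missing} lack positions")
    return np.asarray([a.position for a in atoms], dtype=float)


def perceive_connectivity(
    atoms: Sequence[Atom],
    radii: Mapping[str, float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    distance_floor: float = DISTANCE_FLOOR,
) -> ConnectivityGraph:
    """Perceive bonds from interatomic distances and covalent radii."""
    if tolerance < 0:
        raise ConfigurationError("tolerance must be non-negative")
    radii = default_radii() if radii is None else radii
    symbols = [a.element for a in atoms]
    for el in set(symbols):
        if el not in radii:
            raise ConfigurationError(f"no covalent radius configured for element {el!r}")
    pos = _positions(atoms)
    n = len(atoms)
    edges: set[tuple[int, int]] = set()
    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        rsum = np.asarray([radii[s] for s in symbols])
        cutoff = rsum[:, None] + rsum[None, :] + tolerance
        for i in range(n):
            for j in range(i + 1, n):
                d = dist[i, j]
                if d <= distance_floor:
                    raise GeometryError(
                        f"atoms {i} ({symbols[i]}) and {j} ({symbols[j]}) are "
                        f"{d:.3f} Å apart — below the {distance_floor} Å floor"
                    )
                if d <= cutoff[i, j]:
                    edges.add((i, j))
    return ConnectivityGraph(n_atoms=n, edges=frozenset(edges))


# ---------------------------------------------------------------------------
# XMol XYZ


def write_xyz(symbols: Sequence[str], coords: np.ndarray, comment: str = "") -> str:
    coords = np.asarray(coords, dtype=float)
    lines = [str(len(symbols)), comment.replace("\n", " ")]
    for s, (x, y, z) in zip(symbols, coords):
        lines.append(f"{s} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(lines) + "\n"


def read_xyz(text: str) -> tuple[list[str], np.ndarray, str]:
    """Parse XMol XYZ: count line, comment line, then `element x y z` rows (Å)."""
    lines = text.splitlines()
    if not lines:
        raise GeometryError("empty XYZ document")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise GeometryError("XYZ first line must be the atom count") from exc
    if len(lines) < n + 2:
        raise GeometryError(f"XYZ declares {n} atoms but has {max(len(lines) - 2, 0)} rows")
    comment = lines[1] if len(lines) > 1 else ""
    symbols: list[str] = []
    coords = np.empty((n, 3), dtype=float)
    for k in range(n):
        parts = lines[2 + k].split()
        if len(parts) < 4:
            raise GeometryError(f"XYZ row {k + 3} is not `element x y z`")
        symbols.append(parts[0])
        coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
    return symbols, coords, comment


def canonical_order(record: MoleculeRecord) -> list[int]:
    """Deterministic atom order for normalized output: element alphabetical,
    then original index.  Cosmetic for the InChI (whose own canonicalization
    is order-invariant) but gives reproducible diffs."""
    return sorted(range(len(record.atoms)), key=lambda i: (record.atoms[i].element, i))


def to_canonical_xyz(record: MoleculeRecord) -> str:
    """Reduce a record to bare Cartesian coordinates (XMol XYZ).

    Any bond/connection data in the source is discarded — this is the
    normalization step that makes identifiers from different structure
    versions comparable.
    """
    if not record.atoms:
        raise GeometryError("record has no atoms")
    order = canonical_order(record)
    pos = _positions(record.atoms)
    symbols = [record.atoms[i].element for i in order]
    comment = f"NSC{record.nsc_id} {record.provenance}" if record.nsc_id else record.provenance
    return write_xyz(symbols, pos[order], comment)


def canonical_isotopes(record: MoleculeRecord) -> dict[int, int]:
    """Mass-number labels re-indexed to the canonical XYZ atom order.

    XMol XYZ cannot carry isotope labels, so a record's declared mass
    numbers travel alongside the coordinates when the InChI is generated.
    """
    order = canonical_order(record)
    return {
        new: record.atoms[old].isotope
        for new, old in enumerate(order)
        if record.atoms[old].isotope is not None
    }


# ---------------------------------------------------------------------------
# InChI generation


def _mol_from_xyz(
    symbols: Sequence[str],
    coords: np.ndarray,
    charge: int,
    isotopes: Mapping[int, int] | None,
    radii: Mapping[str, float] | None,
    tolerance: float,
) -> Chem.Mol:
    atoms = [Atom(s, tuple(map(float, c))) for s, c in zip(symbols, coords)]
    graph = perceive_connectivity(atoms, radii=radii, tolerance=tolerance)
    rw = Chem.RWMol()
    for s in symbols:
        a = Chem.Atom(s)
        a.SetNoImplicit(True)  # every hydrogen in this corpus is explicit
        rw.AddAtom(a)
    conf = Chem.Conformer(len(symbols))
    for i, c in enumerate(coords):
        conf.SetAtomPosition(i, tuple(map(float, c)))
    rw.AddConformer(conf)
    for i, j in sorted(graph.edges):
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    if isotopes:
        for i, mass in isotopes.items():
            rw.GetAtomWithIdx(int(i)).SetIsotope(int(mass))
    try:
        rdDetermineBonds.DetermineBondOrders(rw, charge=charge)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        Chem.AssignStereochemistryFrom3D(mol)
    except Exception as exc:
        raise InChIError(f"bond-order/stereo perception failed: {exc}") from exc
    return mol


def generate_inchi(
    xyz: str,
    charge: int = 0,
    isotopes: Mapping[int, int] | None = None,
    radii: Mapping[str, float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[str, str]:
    """Standard InChI and InChIKey for a normalized XYZ geometry.

    Connectivity comes from :func:`perceive_connectivity`; bond orders,
    stereo perception and the canonical identifier itself come from the
    reference InChI library (via RDKit).  Deterministic for identical input.
    """
    symbols, coords, _ = read_xyz(xyz)
    if not symbols:
        raise GeometryError("XYZ contains no atoms")
    mol = _mol_from_xyz(symbols, coords, charge, isotopes, radii, tolerance)
    inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
    if not inchi:
        raise InChIError("reference InChI implementation returned no identifier")
    key = Chem.InchiToInchiKey(inchi)
    if not key:
        raise InChIError(f"could not derive InChIKey for {inchi!r}")
    return inchi, key


def generate_inchi_for_record(
    record: MoleculeRecord,
    charge: int = 0,
    radii: Mapping[str, float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[str, str]:
    """Record → canonical XYZ → InChI, carrying isotope labels across."""
    return generate_inchi(
        to_canonical_xyz(record),
        charge=charge,
        isotopes=canonical_isotopes(record),
        radii=radii,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# layer dissection

_PREFIX_RE = re.compile(r"^InChI=(\d[A-Z]?)/(.*)$", re.S)

# segment prefixes of the standard identifier, in the order they may appear
_KNOWN_PREFIXES = set("chqpbtmsi")


@dataclass(frozen=True)
class InChILayers:
    """An InChI dissected into its delimiter-prefixed layers.

    ``segments`` preserves the exact non-formula segments in source order so
    that :meth:`serialize` reproduces the input string byte for byte.  The
    named accessors expose the comparison layers; ``tetrahedral`` includes
    the m/s sublayers and everything from ``/i`` onward counts as isotope.
    """

    version_prefix: str
    formula: str
    segments: tuple[tuple[str, str], ...]

    def serialize(self) -> str:
        tail = "".join(f"/{p}{v}" for p, v in self.segments)
        return f"InChI={self.version_prefix}/{self.formula}{tail}"

    def _labelled(self) -> dict[str, str]:
        out: dict[str, str] = {"formula": self.formula}
        label_of = {
            "c": "connectivity",
            "h": "hydrogen",
            "q": "charge",
            "p": "protonation",
            "b": "double_bond",
            "t": "tetrahedral",
        }
        in_isotope = False
        for prefix, value in self.segments:
            if prefix == "i":
                in_isotope = True
            if in_isotope:
                label = "isotope"
            elif prefix in ("m", "s"):
                label = "tetrahedral" if any(p == "t" for p, _ in self.segments) else "double_bond"
            else:
                label = label_of[prefix]
            piece = f"{prefix}{value}" if label in out or prefix in ("m", "s", "i") else value
            if label in out:
                out[label] = f"{out[label]}/{piece}"
            else:
                out[label] = value if prefix not in ("m", "s") else piece
        return out

    def layer(self, label: str) -> str | None:
        """The layer string for a comparison label, or None when absent."""
        if label not in LAYER_LABELS:
            raise KeyError(f"unknown layer label {label!r}")
        return self._labelled().get(label)

    @property
    def connectivity(self) -> str | None:
        return self.layer("connectivity")

    @property
    def hydrogen(self) -> str | None:
        return self.layer("hydrogen")

    @property
    def charge(self) -> str | None:
        return self.layer("charge")

    @property
    def protonation(self) -> str | None:
        return self.layer("protonation")

    @property
    def double_bond(self) -> str | None:
        return self.layer("double_bond")

    @property
    def tetrahedral(self) -> str | None:
        return self.layer("tetrahedral")

    @property
    def isotope(self) -> str | None:
        return self.layer("isotope")


def parse_layers(inchi: str) -> InChILayers:
    """Dissect an InChI string into its component layers.

    Only the standard identifier is supported; fixed-H (``/f``) and
    reconnected (``/r``) blocks are out of scope and rejected.
    """
    m = _PREFIX_RE.match(inchi.strip())
    if not m:
        raise InChIError(f"unrecognized InChI version prefix in {inchi!r}")
    version, body = m.group(1), m.group(2)
    chunks = body.split("/")
    formula = chunks[0]
    segments: list[tuple[str, str]] = []
    for chunk in chunks[1:]:
        if not chunk:
            raise InChIError(f"empty layer segment in {inchi!r}")
        prefix = chunk[0]
        if prefix in ("f", "r"):
            raise InChIError(f"non-standard /{prefix} block in {inchi!r} is unsupported")
        if prefix not in _KNOWN_PREFIXES:
            raise InChIError(f"unknown layer prefix {prefix!r} in {inchi!r}")
        segments.append((prefix, chunk[1:]))
    return InChILayers(version_prefix=version, formula=formula, segments=tuple(segments))


def serialize_layers(layers: InChILayers) -> str:
    return layers.serialize()
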