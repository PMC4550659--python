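"""Fully explicit semi-empirical QM input decks, and optimizer output parsing.

The deck builder enforces two guards learned the hard way from legacy
conversions: the keyword line always carries an explicit ``CHARGE=<n>``
token (including ``CHARGE=0`` — the optimizer would otherwise silently
assume zero), and always carries exactly one spin token (``SINGLET`` or
``DOUBLET``) computed from the electron count, which acts as a checksum:
the optimizer aborts if the declared spin conflicts with any declared or
defaulted charge.  The placeholder line a naive format conversion leaves
behind ("PUT KEYWORDS HERE") can never be produced.

Geometry defaults to internal coordinates (Z-matrix).  Reference-atom
selection is not critical for the optimized result; nearest-neighbour
references are used for numerical stability.
"""

from __future__ import annotations

import enum
import re
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cml_records import Atom, MoleculeRecord
from .charge_semantics import (
    ChargeAssignment,
    Multiplicity,
    electron_count,
    spin_state,
)
from .errors import ConfigurationError, GeometryError, MopacParseError
from .formula import formula_counts

PLACEHOLDER_KEYWORDS = "PUT KEYWORDS HERE"

_COINCIDENT_TOL = 1e-6  # Å
_COLLINEAR_SIN = 1e-6


@dataclass(frozen=True)
class ZMatrixRow:
    """One internal-coordinate row: distance to r1, angle w.r.t. r2, dihedral w.r.t. r3.

    Reference indices are 0-based positions of previously defined rows; the
    first row has none, the second only r1, the third r1 and r2.
    """

    element: str
    distance: float | None = None  # Å
    angle: float | None = None  # degrees, in [0, 180]
    dihedral: float | None = None  # degrees
    r1: int | None = None
    r2: int | None = None
    r3: int | None = None


@dataclass(frozen=True)
class MopacInput:
    keywords: tuple[str, ...]
    title: str
    comment: str
    zmatrix: tuple[ZMatrixRow, ...] | None = None
    cartesian: tuple[Atom, ...] | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        line = " ".join(self.keywords)
        if PLACEHOLDER_KEYWORDS in line.upper():
            raise ConfigurationError("keyword line must never be the placeholder text")
        if not any(k.startswith("CHARGE=") for k in self.keywords):
            raise ConfigurationError("keyword line must declare CHARGE= explicitly")
        spins = [k for k in self.keywords if k in ("SINGLET", "DOUBLET")]
        if len(spins) != 1:
            raise ConfigurationError("keyword line must carry exactly one spin token")
        if (self.zmatrix is None) == (self.cartesian is None):
            raise ConfigurationError("exactly one of zmatrix/cartesian geometry required")


class Termination(enum.Enum):
    NORMAL = "normal"
    ERROR = "error"


# ---------------------------------------------------------------------------
# geometry: cartesian <-> internal


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length vector in internal-coordinate frame")
    return v / n


def _angle_deg(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    u, v = _unit(p - a), _unit(b - a)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def _dihedral_deg(p0, p1, p2, p3) -> float:
    """Torsion angle of the chain p0-p1-p2-p3, signed, in degrees."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def cartesian_to_internal(atoms: Sequence[Atom]) -> list[ZMatrixRow]:
    """Convert Cartesian atoms to a Z-matrix with nearest-neighbour references.

    For each row, r1 is the nearest previously defined atom, r2 the nearest
    other, and r3 the nearest that keeps the (r1, r2, r3) triple
    non-collinear (falling back to the least collinear candidate).
    Reconstructing Cartesians from the result reproduces all pairwise
    distances to well under 1e-4 Å; global orientation is unconstrained.
    """
    if not atoms:
        raise GeometryError("need at least one atom")
    pos = np.asarray([a.position for a in atoms], dtype=float)
    if any(a.position is None for a in atoms):
        raise GeometryError("all atoms need positions")
    n = len(atoms)
    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        close = np.argwhere((dist < _COINCIDENT_TOL) & ~np.eye(n, dtype=bool))
        if close.size:
            i, j = close[0]
            raise GeometryError(f"atoms {i} and {j} are coincident")
    rows: list[ZMatrixRow] = []
    for i, atom in enumerate(atoms):
        if i == 0:
            rows.append(ZMatrixRow(atom.element))
            continue
        prev = list(range(i))
        prev.sort(key=lambda j: dist[i, j])
        r1 = prev[0]
        if i == 1:
            rows.append(ZMatrixRow(atom.element, distance=float(dist[i, r1]), r1=r1))
            continue
        r2 = next(j for j in prev if j != r1)
        angle = _angle_deg(pos[i], pos[r1], pos[r2])
        if i == 2:
            rows.append(
                ZMatrixRow(atom.element, float(dist[i, r1]), angle, r1=r1, r2=r2)
            )
            continue
        best, best_sin = None, -1.0
        for j in prev:
            if j in (r1, r2):
                continue
            s = np.linalg.norm(
                np.cross(_unit(pos[r2] - pos[r1]), pos[j] - pos[r2])
            ) / max(np.linalg.norm(pos[j] - pos[r2]), _COINCIDENT_TOL)
            if s > _COLLINEAR_SIN:
                best = j
                break  # prev is distance-sorted: first non-collinear = nearest
            if s > best_sin:
                best, best_sin = j, s
        if best is None:
            raise GeometryError(f"no dihedral reference available for atom {i}")
        if best_sin >= 0 and best_sin <= _COLLINEAR_SIN and best is not None:
            # only collinear candidates exist
            s_check = np.linalg.norm(
                np.cross(_unit(pos[r2] - pos[r1]), pos[best] - pos[r2])
            ) / max(np.linalg.norm(pos[best] - pos[r2]), _COINCIDENT_TOL)
            if s_check <= _COLLINEAR_SIN:
                raise GeometryError(
                    f"atom {i}: all reference triples are collinear; "
                    "linear chains need a dummy atom, which is out of scope"
                )
        r3 = best
        rows.append(
            ZMatrixRow(
                atom.element,
                float(dist[i, r1]),
                angle,
                _dihedral_deg(pos[i], pos[r1], pos[r2], pos[r3]),
                r1=r1,
                r2=r2,
                r3=r3,
            )
        )
    return rows


def internal_to_cartesian(rows: Sequence[ZMatrixRow]) -> list[Atom]:
    """Rebuild Cartesian coordinates from a Z-matrix (NeRF placement).

    The absolute orientation is arbitrary; pairwise distances are what the
    round trip preserves.
    """
    if not rows:
        raise GeometryError("empty Z-matrix")
    pos = np.zeros((len(rows), 3))
    for i, row in enumerate(rows):
        if i == 0:
            continue
        a = pos[row.r1]
        if i == 1:
            pos[i] = a + np.array([row.distance, 0.0, 0.0])
            continue
        b = pos[row.r2]
        theta = np.radians(row.angle)
        if i == 2:
            u = _unit(b - a)
            w = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(w) < _COLLINEAR_SIN:
                w = np.array([0.0, 1.0, 0.0])
            w = _unit(w)
            pos[i] = a + row.distance * (np.cos(theta) * u + np.sin(theta) * w)
            continue
        c = pos[row.r3]
        phi = np.radians(row.dihedral)
        # place X with |X-a|=d, angle(X,a,b)=theta, dihedral(X,a,b,c)=phi
        ab = _unit(b - a)
        ncr = np.cross(b - c, -ab)
        nrm = np.linalg.norm(ncr)
        if nrm < _COLLINEAR_SIN:
            raise GeometryError(f"row {i}: collinear reference frame")
        ncr = ncr / nrm
        m = np.cross(ncr, ab)
        d2 = row.distance * np.array(
            [np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
        )
        pos[i] = a + d2[0] * ab + d2[1] * m + d2[2] * ncr
    return [Atom(r.element, tuple(map(float, pos[i]))) for i, r in enumerate(rows)]


# ---------------------------------------------------------------------------
# deck building / formatting


def build_input(
    record: MoleculeRecord,
    charge: ChargeAssignment,
    method: str = "PM7",
    coords_mode: str = "internal",
) -> MopacInput:
    """Build a fully explicit input deck for one molecule record.

    The CHARGE token always equals the reconciled charge and the spin token
    always equals the multiplicity computed from the electron count at that
    charge, so every deck satisfies the spin checksum by construction.
    An implausible charge does not abort deck generation; it is carried as a
    warning so corpus curation can proceed and report.
    """
    if coords_mode not in ("internal", "cartesian"):
        raise ConfigurationError(f"unknown coords_mode {coords_mode!r}")
    if not record.has_positions():
        missing = [i for i, a in enumerate(record.atoms) if a.position is None]
        raise GeometryError(f"record lacks coordinates for atoms {missing}")
    mult = spin_state(electron_count(record.formula(), charge.value)).multiplicity
    keywords = (method, f"CHARGE={charge.value}", mult.value)
    warnings: tuple[str, ...] = ()
    if not charge.plausible:
        warnings = (f"declared charge {charge.value:+d} exceeds |q|<=3 plausibility bound",)
    if charge.conflict:
        warnings = warnings + ("charge dialects disagreed; formalCharge attribute used",)
    title = record.name or (f"NSC{record.nsc_id}" if record.nsc_id else "molecule")
    comment = f"geometry provenance: {record.provenance}"
    if coords_mode == "internal":
        return MopacInput(
            keywords=keywords,
            title=title,
            comment=comment,
            zmatrix=tuple(cartesian_to_internal(record.atoms)),
            warnings=warnings,
        )
    return MopacInput(
        keywords=keywords,
        title=title,
        comment=comment,
        cartesian=tuple(record.atoms),
        warnings=warnings,
    )


def format_input(deck: MopacInput) -> str:
    """Serialize a deck: keyword line, two comment lines, geometry block.

    Distances carry 4 decimals and angles 2 — matching the round-trip
    tolerances (1e-4 Å, 1e-2°).  Identical decks serialize byte-identically.
    """
    lines = [" ".join(deck.keywords), deck.title, deck.comment]
    if deck.zmatrix is not None:
        for row in deck.zmatrix:
            d = 0.0 if row.distance is None else row.distance
            a = 0.0 if row.angle is None else row.angle
            t = 0.0 if row.dihedral is None else row.dihedral
            fd = 0 if row.distance is None else 1
            fa = 0 if row.angle is None else 1
            ft = 0 if row.dihedral is None else 1
            refs = tuple(0 if r is None else r + 1 for r in (row.r1, row.r2, row.r3))
            lines.append(
                f"{row.element:<2s} {d:10.4f} {fd} {a:10.2f} {fa} {t:10.2f} {ft} "
                f"{refs[0]:4d} {refs[1]:4d} {refs[2]:4d}"
            )
    else:
        for atom in deck.cartesian:
            x, y, z = atom.position
            lines.append(f"{atom.element:<2s} {x:12.4f} 1 {y:12.4f} 1 {z:12.4f} 1")
    return "\n".join(lines) + "\n"


def parse_input(text: str) -> MopacInput:
    """Parse a deck produced by :func:`format_input` (round-trip companion)."""
    lines = text.splitlines()
    if len(lines) < 4:
        raise MopacParseError("deck too short: keyword line, two comments, geometry expected")
    keywords = tuple(lines[0].split())
    title, comment = lines[1], lines[2]
    zrows: list[ZMatrixRow] = []
    crows: list[Atom] = []
    for ln in lines[3:]:
        parts = ln.split()
        if not parts:
            continue
        if len(parts) == 10:
            el = parts[0]
            d, fd, a, fa, t, ft = (
                float(parts[1]), int(parts[2]), float(parts[3]),
                int(parts[4]), float(parts[5]), int(parts[6]),
            )
            r1, r2, r3 = (int(p) for p in parts[7:10])
            zrows.append(
                ZMatrixRow(
                    el,
                    distance=d if fd or r1 else None,
                    angle=a if fa or r2 else None,
                    dihedral=t if ft or r3 else None,
                    r1=r1 - 1 if r1 else None,
                    r2=r2 - 1 if r2 else None,
                    r3=r3 - 1 if r3 else None,
                )
            )
        elif len(parts) == 7:
            crows.append(Atom(parts[0], (float(parts[1]), float(parts[3]), float(parts[5]))))
        else:
            raise MopacParseError(f"unrecognized geometry row: {ln!r}")
    return MopacInput(
        keywords=keywords,
        title=title,
        comment=comment,
        zmatrix=tuple(zrows) if zrows else None,
        cartesian=tuple(crows) if crows else None,
    )


# ---------------------------------------------------------------------------
# output parsing and the external optimizer stage

_COORD_HEADER = re.compile(r"^\s*CARTESIAN COORDINATES\s*$")
_COORD_ROW = re.compile(
    r"^\s*\d+\s+([A-Z][a-z]?)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$"
)
_PROP_RES = {
    "final_heat_of_formation_kcal_mol": re.compile(
        r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+\.\d+)\s*KCAL/MOL"
    ),
    "total_energy_ev": re.compile(r"TOTAL ENERGY\s*=\s*(-?\d+\.\d+)\s*EV"),
    "dipole_debye": re.compile(r"DIPOLE\s*=\s*(-?\d+\.\d+)\s*DEBYE"),
}
_NORMAL_MARK = "== MOPAC DONE =="
_ERROR_MARKS = ("CALCULATION IS TERMINATED", "ERROR", "UNABLE TO ACHIEVE")


def parse_output(text: str) -> tuple[tuple[Atom, ...], dict[str, float], Termination]:
    """Extract the final geometry (Cartesian Å), computed properties and the
    termination status from optimizer output or archive text.

    The last CARTESIAN COORDINATES block wins (optimizers print several).
    Error termination needs no geometry; text with neither a geometry block
    nor a termination marker is a parse error.
    """
    lines = text.splitlines()
    blocks: list[list[Atom]] = []
    i = 0
    while i < len(lines):
        if _COORD_HEADER.match(lines[i]):
            block: list[Atom] = []
            j = i + 1
            started = False
            while j < len(lines):
                m = _COORD_ROW.match(lines[j])
                if m:
                    started = True
                    block.append(
                        Atom(m.group(1), (float(m.group(2)), float(m.group(3)), float(m.group(4))))
                    )
                elif started:
                    break
                elif lines[j].strip() and "ATOM" not in lines[j].upper():
                    break
                j += 1
            if block:
                blocks.append(block)
            i = j
        else:
            i += 1

    status: Termination | None = None
    if any(_NORMAL_MARK in ln for ln in lines):
        status = Termination.NORMAL
    elif any(any(mark in ln for mark in _ERROR_MARKS) for ln in lines):
        status = Termination.ERROR

    if status is None:
        context = lines[-1] if lines else "<empty>"
        raise MopacParseError(
            f"no termination marker found; output looks truncated (last line: {context!r})"
        )
    if status is Termination.NORMAL and not blocks:
        raise MopacParseError("normal termination but no CARTESIAN COORDINATES block")

    props: dict[str, float] = {}
    for key, rx in _PROP_RES.items():
        for ln in lines:
            m = rx.search(ln)
            if m:
                props[key] = float(m.group(1))
    final = tuple(blocks[-1]) if blocks else ()
    return final, props, status


def mock_optimizer_output(deck: MopacInput, heat_kcal_mol: float = 0.0) -> str:
    """Canned optimizer output for a deck: identity 'optimization'.

    Lets the whole pipeline run without the licensed external optimizer;
    the output dialect is exactly what :func:`parse_output` consumes.
    """
    atoms = (
        list(deck.cartesian)
        if deck.cartesian is not None
        else internal_to_cartesian(deck.zmatrix)
    )
    lines = [
        " *** MOCK SEMI-EMPIRICAL OPTIMIZER ***",
        f" KEYWORDS: {' '.join(deck.keywords)}",
        "",
        "          CARTESIAN COORDINATES",
        "",
        "    NO.       ATOM         X         Y         Z",
    ]
    for k, atom in enumerate(atoms, start=1):
        x, y, z = atom.position
        lines.append(f"    {k:3d}       {atom.element:<2s}   {x:12.6f} {y:12.6f} {z:12.6f}")
    lines += [
        "",
        f"          FINAL HEAT OF FORMATION = {heat_kcal_mol:12.5f} KCAL/MOL",
        "",
        f" {_NORMAL_MARK}",
    ]
    return "\n".join(lines) + "\n"


def run_optimizer(
    deck: MopacInput,
    command: str,
    timeout: float = 300.0,
    entry_name: str = "entry",
) -> str:
    """Run the pluggable external optimizer and capture its output text.

    ``command`` is a shell-free template such as ``"mopac {input}"``; the
    deck is written to a temporary file substituted for ``{input}``.  The
    sentinel command ``"mock"`` short-circuits to the built-in mock.  The
    captured text is returned verbatim — interpretation belongs to
    :func:`parse_output`.
    """
    if command == "mock":
        return mock_optimizer_output(deck)
    if "{input}" not in command:
        raise ConfigurationError("optimizer command template must contain {input}")
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / f"{entry_name}.mop"
        path.write_text(format_input(deck))
        argv = [
            a.replace("{input}", str(path)) for a in shlex.split(command)
        ]
        try:
            proc = subprocess.run(
                argv, capture_output=True, text=True, timeout=timeout
            )
        except FileNotFoundError as exc:
            raise ConfigurationError(f"optimizer executable not found: {argv[0]!r}") from exc
        except subprocess.TimeoutExpired as exc:
            raise MopacParseError(
                f"optimizer timed out after {timeout}s on entry {entry_name!r}"
            ) from exc
        out_file = path.with_suffix(".out")
        if out_file.exists():
            return out_file.read_text()
        return proc.stdout + proc.stderr
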