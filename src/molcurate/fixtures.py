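"""Synthetic corpora with recorded ground truth.

Every pipeline stage is testable without downloading anything: this module
generates per-entry CML document sets shaped like the curated collection —
a legacy-dialect original, a computed-annotation document and a third,
re-optimized geometry — and records exactly what it injected: duplicates,
entries without a computed annotation, the five charge-dialect cases,
counter-ion components, implausible charges, and per-layer InChI
mismatches between designated provenance versions.

Mismatch injections are deterministic structure edits whose layer
signatures were verified against the package's own normalization path and
frozen here (a test re-derives them):

=============  =======================================================  ====================
layer request  mechanism                                                divergent layers
=============  =======================================================  ====================
hydrogen       cyclohexane → cyclohexene (same skeleton, 2 H fewer)     formula, hydrogen
connectivity   cyclohexene → methylenecyclopentane (same formula)       connectivity, hydrogen
charge         allyl anion → allyl cation (declared charge −1 → +1)     charge
double_bond    trans-2-butene → cis-2-butene                            double_bond
tetrahedral    geometric mirror of L-alanine                            tetrahedral
isotope        a ¹³C mass label on one carbon                           isotope
=============  =======================================================  ====================

Multi-layer signatures are deliberate: one mismatched pair may diverge in
several layers at once, so the per-layer tallies of a corpus may sum to
more than its mismatched-pair count.  Geometric realism is bounded: benign
perturbations emulate a re-optimization's small coordinate shifts, not any
quantum-chemical physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .cml_records import Atom, MoleculeRecord, write_cml
from .connectivity_inchi import perceive_connectivity
from .errors import GeometryError, InfeasibleSpecError
from .formula import formula_counts, hill_formula


@dataclass(frozen=True)
class BaseMolecule:
    name: str
    smiles: str
    charge: int = 0  # net charge of the whole SMILES (fragment charge for salts)


#: General pool for unremarkable corpus entries.
REGULAR_POOL: tuple[BaseMolecule, ...] = (
    BaseMolecule("methane", "C"),
    BaseMolecule("ethanol", "CCO"),
    BaseMolecule("acetone", "CC(C)=O"),
    BaseMolecule("benzene", "c1ccccc1"),
    BaseMolecule("toluene", "Cc1ccccc1"),
    BaseMolecule("pyridine", "c1ccncc1"),
    BaseMolecule("phenol", "Oc1ccccc1"),
    BaseMolecule("aniline", "Nc1ccccc1"),
    BaseMolecule("acetic acid", "CC(O)=O"),
    BaseMolecule("glycine", "NCC(O)=O"),
    BaseMolecule("urea", "NC(N)=O"),
    BaseMolecule("furan", "c1ccoc1"),
    BaseMolecule("thiophene", "c1ccsc1"),
    BaseMolecule("dimethyl sulfide", "CSC"),
    BaseMolecule("naphthalene", "c1ccc2ccccc2c1"),
    BaseMolecule("cyclopentanone", "O=C1CCCC1"),
    BaseMolecule("isopropanol", "CC(C)O"),
    BaseMolecule("diethyl ether", "CCOCC"),
    BaseMolecule("tetramethylammonium", "C[N+](C)(C)C", charge=1),
    BaseMolecule("ammonium", "[NH4+]", charge=1),
    BaseMolecule("acetate", "CC(=O)[O-]", charge=-1),
)

#: Salts for multi-component entries: (salt SMILES, retained-fragment charge,
#: counter-ion Hill formula).
SALT_POOL: tuple[tuple[BaseMolecule, str], ...] = (
    (BaseMolecule("sodium acetate", "CC(=O)[O-].[Na+]", charge=-1), "Na"),
    (BaseMolecule("sodium phenoxide", "[O-]c1ccccc1.[Na+]", charge=-1), "Na"),
)

#: Injection-designated structures per requested layer, with the frozen
#: divergent-layer signature of the PM7-vs-NCI pair.
_INJECTIONS: dict[str, dict] = {
    "hydrogen": {
        "base": BaseMolecule("cyclohexane", "C1CCCCC1"),
        "variant": BaseMolecule("cyclohexene", "C1=CCCCC1"),
        "signature": frozenset({"formula", "hydrogen"}),
    },
    "connectivity": {
        "base": BaseMolecule("cyclohexene", "C1=CCCCC1"),
        "variant": BaseMolecule("methylenecyclopentane", "C=C1CCCC1"),
        "signature": frozenset({"connectivity", "hydrogen"}),
    },
    "charge": {
        "base": BaseMolecule("allyl anion", "C=C[CH2-]", charge=-1),
        "variant": None,  # same geometry, declared charge flipped to +1
        "signature": frozenset({"charge"}),
    },
    "double_bond": {
        "base": BaseMolecule("trans-2-butene", "C/C=C/C"),
        "variant": BaseMolecule("cis-2-butene", "C/C=C\\C"),
        "signature": frozenset({"double_bond"}),
    },
    "tetrahedral": {
        "base": BaseMolecule("L-alanine", "C[C@@H](N)C(=O)O"),
        "variant": None,  # geometric mirror
        "signature": frozenset({"tetrahedral"}),
    },
    "isotope": {
        "base": BaseMolecule("ethanol", "CCO"),
        "variant": None,  # 13C label on the first carbon
        "signature": frozenset({"isotope"}),
    },
}

INJECTION_LAYERS = tuple(sorted(_INJECTIONS))


def injection_signature(layer: str) -> frozenset[str]:
    """The divergent-layer set an injection of *layer* produces (PM7 vs NCI)."""
    return _INJECTIONS[layer]["signature"]


DIALECT_CASES = ("legacy_only", "attribute_only", "both_agree", "both_conflict", "absent")

_DEFAULT_DIALECT_MIX = {
    # the real corpus declared the charge in both documents for nearly every
    # entry; minority cases keep the reconciliation logic exercised
    "both_agree": 0.70,
    "attribute_only": 0.10,
    "legacy_only": 0.10,
    "absent": 0.05,
    "both_conflict": 0.05,
}


@dataclass(frozen=True)
class InjectionSpec:
    """What a synthetic corpus should contain.

    Default proportions emulate the curated collection: ~0.5 % duplicate
    accessions, ~9.4 % of entries without a computed annotation, a charge
    distribution dominated by neutral species with rare implausible
    declarations, and a small share of multi-component salt entries.
    """

    n_entries: int
    seed: int
    fraction_duplicates: float = 0.005
    fraction_unannotated: float = 0.094
    per_layer_mismatch_counts: Mapping[str, int] = dc_field(default_factory=dict)
    charge_dialect_mix: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(_DEFAULT_DIALECT_MIX)
    )
    fraction_multicomponent: float = 0.05
    fraction_implausible_charge: float = 0.01
    n_pm5_divergent: int = 0  # PM5 differs from NCI = PM7
    n_nci_divergent: int = 0  # NCI differs from PM5 = PM7
    n_all_differ: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_duplicates",
            "fraction_unannotated",
            "fraction_multicomponent",
            "fraction_implausible_charge",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InfeasibleSpecError(f"{name} must be in [0, 1], got {v}")
        for layer in self.per_layer_mismatch_counts:
            if layer not in _INJECTIONS:
                raise InfeasibleSpecError(
                    f"unknown injection layer {layer!r}; choose from {INJECTION_LAYERS}"
                )
        bad = set(self.charge_dialect_mix) - set(DIALECT_CASES)
        if bad:
            raise InfeasibleSpecError(f"unknown charge dialect cases {sorted(bad)}")


# ---------------------------------------------------------------------------
# geometry helpers


@lru_cache(maxsize=256)
def _embedded(smiles: str, seed: int) -> tuple[tuple[str, ...], tuple[tuple[float, float, float], ...]]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GeometryError(f"cannot parse SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        raise GeometryError(f"3-D embedding failed for {smiles!r}")
    conf = mol.GetConformer()
    symbols = tuple(a.GetSymbol() for a in mol.GetAtoms())
    coords = tuple(
        (conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z)
        for i in range(mol.GetNumAtoms())
    )
    return symbols, coords


def _atoms_of(base: BaseMolecule, seed: int) -> tuple[Atom, ...]:
    symbols, coords = _embedded(base.smiles, seed)
    return tuple(Atom(s, c) for s, c in zip(symbols, coords))


def perturb_geometry(
    atoms: Sequence[Atom],
    mode: str = "benign",
    magnitude: float = 0.02,
    seed: int = 0,
) -> tuple[Atom, ...]:
    """Deterministically perturb a geometry.

    benign
        Random per-atom displacements of at most *magnitude* Å that leave
        the perceived connectivity unchanged — a stand-in for the small
        coordinate shifts of a re-optimization.
    bond_breaking
        Moves the most borderline bonded pair apart along its axis by
        *magnitude* Å in total, pushing it across the perception threshold.
    stereo_flip
        Mirrors the whole geometry (x → −x), inverting every tetrahedral
        stereocenter while preserving all distances and connectivity.
    """
    if magnitude < 0:
        raise GeometryError("magnitude must be non-negative")
    pos = np.asarray([a.position for a in atoms], dtype=float)
    rng = np.random.default_rng(seed)

    if mode == "benign":
        if magnitude == 0:
            return tuple(atoms)
        before = perceive_connectivity(atoms)
        for shrink in (1.0, 0.5, 0.25, 0.1):
            vecs = rng.normal(size=pos.shape)
            vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
            vecs *= rng.uniform(0, magnitude * shrink, size=(len(atoms), 1))
            new = tuple(
                Atom(a.element, tuple(map(float, p)), a.isotope)
                for a, p in zip(atoms, pos + vecs)
            )
            if perceive_connectivity(new).edges == before.edges:
                return new
        raise GeometryError("benign perturbation could not preserve connectivity")

    if mode == "bond_breaking":
        graph = perceive_connectivity(atoms)
        if not graph.edges:
            raise GeometryError("no bonded pair to break")
        from .connectivity_inchi import default_radii

        radii = default_radii()

        def slack(edge: tuple[int, int]) -> float:
            i, j = edge
            d = float(np.linalg.norm(pos[i] - pos[j]))
            thr = radii[atoms[i].element] + radii[atoms[j].element] + 0.40
            return thr - d

        edge = min(graph.edges, key=slack)
        if slack(edge) >= magnitude:
            raise GeometryError(
                f"no bonded pair within {magnitude} Å of the perception threshold"
            )
        i, j = edge
        axis = pos[j] - pos[i]
        axis /= np.linalg.norm(axis)
        pos[i] -= axis * magnitude / 2
        pos[j] += axis * magnitude / 2
        return tuple(
            Atom(a.element, tuple(map(float, p)), a.isotope) for a, p in zip(atoms, pos)
        )

    if mode == "stereo_flip":
        if not _has_stereocenter(atoms):
            raise GeometryError("no tetrahedral stereocenter to flip")
        pos[:, 0] *= -1
        return tuple(
            Atom(a.element, tuple(map(float, p)), a.isotope) for a, p in zip(atoms, pos)
        )

    raise GeometryError(f"unknown perturbation mode {mode!r}")


def _has_stereocenter(atoms: Sequence[Atom]) -> bool:
    from rdkit.Chem import rdDetermineBonds

    graph = perceive_connectivity(atoms)
    rw = Chem.RWMol()
    for a in atoms:
        at = Chem.Atom(a.element)
        at.SetNoImplicit(True)
        rw.AddAtom(at)
    conf = Chem.Conformer(len(atoms))
    for i, a in enumerate(atoms):
        conf.SetAtomPosition(i, a.position)
    rw.AddConformer(conf)
    for i, j in sorted(graph.edges):
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    try:
        rdDetermineBonds.DetermineBondOrders(rw, charge=0)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        Chem.AssignStereochemistryFrom3D(mol)
    except Exception:
        return False
    return any(
        a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED for a in mol.GetAtoms()
    )


def _mirror(atoms: Sequence[Atom]) -> tuple[Atom, ...]:
    return tuple(
        Atom(a.element, (-a.position[0], a.position[1], a.position[2]), a.isotope)
        for a in atoms
    )


# ---------------------------------------------------------------------------
# corpus generation


@dataclass(frozen=True)
class CorpusEntry:
    """One entry occurrence: its directory name and document texts."""

    seq: int
    nsc_id: int
    dirname: str
    files: Mapping[str, str]  # filename -> document text


@dataclass(frozen=True)
class Corpus:
    entries: tuple[CorpusEntry, ...]
    ground_truth: Mapping

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for entry in self.entries:
            d = out / entry.dirname
            d.mkdir(exist_ok=True)
            for filename, text in entry.files.items():
                (d / filename).write_text(text)
        (out / "ground_truth.json").write_text(json.dumps(self.ground_truth, indent=2))
        return out


def _role_plan(spec: InjectionSpec) -> tuple[int, list[tuple[str, str | None]]]:
    """Number of duplicate occurrences and the per-unique-entry role list."""
    n = spec.n_entries
    n_dup = round(spec.fraction_duplicates * n)
    m = n - n_dup  # unique entries
    n_unann = round(spec.fraction_unannotated * m)
    n_multi = round(spec.fraction_multicomponent * m)
    n_implaus = round(spec.fraction_implausible_charge * m)
    injections = [
        (layer, count)
        for layer, count in sorted(spec.per_layer_mismatch_counts.items())
        if count
    ]
    n_inj = sum(c for _, c in injections)
    special = (
        n_unann
        + n_inj
        + spec.n_pm5_divergent
        + spec.n_nci_divergent
        + spec.n_all_differ
        + n_multi
        + n_implaus
    )
    if m <= 0 or special > m:
        raise InfeasibleSpecError(
            f"spec asks for {special} special entries plus {n_dup} duplicates "
            f"but only {m} unique slots exist"
        )
    roles: list[tuple[str, str | None]] = []
    roles += [("unannotated", None)] * n_unann
    for layer, count in injections:
        roles += [("inject_pm7", layer)] * count
    roles += [("inject_pm5", None)] * spec.n_pm5_divergent
    roles += [("inject_nci", None)] * spec.n_nci_divergent
    roles += [("inject_all", None)] * spec.n_all_differ
    roles += [("multicomponent", None)] * n_multi
    roles += [("implausible", None)] * n_implaus
    roles += [("regular", None)] * (m - len(roles))
    return n_dup, roles


def _dialect_case(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    cases = [c for c in DIALECT_CASES if mix.get(c, 0) > 0]
    weights = np.array([mix[c] for c in cases], dtype=float)
    weights /= weights.sum()
    return str(rng.choice(cases, p=weights))


def _entry_files(
    nsc: int,
    base: BaseMolecule,
    nci_atoms: Sequence[Atom],
    pm5_atoms: Sequence[Atom] | None,
    pm7_atoms: Sequence[Atom] | None,
    nci_charge: int | None,
    pm5_attr_charge: int | None,
    pm7_attr_charge: int | None,
    nci_bonds: tuple[tuple[int, int, str], ...] = (),
) -> dict[str, str]:
    files: dict[str, str] = {}
    nci = MoleculeRecord(
        atoms=tuple(nci_atoms),
        provenance="NCI",
        nsc_id=nsc,
        name=base.name,
        bonds=nci_bonds,
        legacy_basic=hill_formula(formula_counts(a.element for a in nci_atoms)),
        legacy_charge=nci_charge,
    )
    files[f"nsc{nsc}_original.cml"] = write_cml(nci)
    if pm5_atoms is not None:
        pm5 = MoleculeRecord(
            atoms=tuple(pm5_atoms),
            provenance="PM5",
            nsc_id=nsc,
            name=base.name,
            formal_charge_attr=pm5_attr_charge,
        )
        files[f"nsc{nsc}_post-mopac.cml"] = write_cml(pm5)
    if pm7_atoms is not None:
        pm7 = MoleculeRecord(
            atoms=tuple(pm7_atoms),
            provenance="PM7",
            nsc_id=nsc,
            name=base.name,
            formal_charge_attr=pm7_attr_charge,
        )
        files["PM7.xml"] = write_cml(pm7)
    return files


def generate_corpus(spec: InjectionSpec) -> Corpus:
    """Generate a corpus and its ground truth.  Same spec (same seed) →
    identical output, byte for byte."""
    n_dup, roles = _role_plan(spec)
    rng = np.random.default_rng(spec.seed)

    entries: list[CorpusEntry] = []
    truth_entries: dict[str, dict] = {}
    duplicates: list[int] = []
    layer_hist: dict[str, int] = {}
    categories = {
        "ALL_MATCH": 0,
        "PM5_PM7_NOT_NCI": 0,
        "PM7_NCI_NOT_PM5": 0,
        "PM5_NCI_NOT_PM7": 0,
        "ALL_DIFFER": 0,
    }

    def bump(labels: Sequence[str]) -> None:
        for lab in labels:
            layer_hist[lab] = layer_hist.get(lab, 0) + 1

    regular_idx = 0
    salt_idx = 0
    for k, (role, layer) in enumerate(roles):
        nsc = 100001 + k
        embed_seed = int(rng.integers(1, 2**31 - 1))
        jitter_seed = int(rng.integers(1, 2**31 - 1))
        truth: dict = {"role": role}
        annotated = role != "unannotated"

        if role == "inject_pm7":
            inj = _INJECTIONS[layer]
            base = inj["base"]
            nci_atoms = _atoms_of(base, embed_seed)
            pm5_atoms = perturb_geometry(nci_atoms, "benign", 0.02, jitter_seed)
            declared = base.charge
            pm7_charge = declared
            if layer == "charge":
                pm7_atoms = perturb_geometry(nci_atoms, "benign", 0.02, jitter_seed + 1)
                pm7_charge = +1  # anion re-declared as the cation
            elif layer == "tetrahedral":
                pm7_atoms = _mirror(perturb_geometry(nci_atoms, "benign", 0.02, jitter_seed + 1))
            elif layer == "isotope":
                pm7_atoms = perturb_geometry(nci_atoms, "benign", 0.02, jitter_seed + 1)
                first_c = next(i for i, a in enumerate(pm7_atoms) if a.element == "C")
                pm7_atoms = tuple(
                    Atom(a.element, a.position, 13 if i == first_c else a.isotope)
                    for i, a in enumerate(pm7_atoms)
                )
            else:  # variant swap
                pm7_atoms = _atoms_of(inj["variant"], embed_seed)
            files = _entry_files(
                nsc, base, nci_atoms, pm5_atoms, pm7_atoms,
                nci_charge=declared, pm5_attr_charge=declared, pm7_attr_charge=pm7_charge,
            )
            categories["PM5_NCI_NOT_PM7"] += 1
            bump(sorted(inj["signature"]))
            truth.update(
                injected_layer=layer,
                expected_divergent_pm7_nci=sorted(inj["signature"]),
                expected_charge=declared,
                dialect_case="both_agree",
            )

        elif role in ("inject_pm5", "inject_nci", "inject_all"):
            if role == "inject_nci":
                # NCI differs from PM5 = PM7 by the hydrogen-type edit
                inj = _INJECTIONS["hydrogen"]
                nci_atoms = _atoms_of(inj["variant"], embed_seed)  # cyclohexene
                pm_atoms = _atoms_of(inj["base"], embed_seed)  # cyclohexane
                base = inj["base"]
                files = _entry_files(
                    nsc, base, nci_atoms,
                    perturb_geometry(pm_atoms, "benign", 0.02, jitter_seed),
                    perturb_geometry(pm_atoms, "benign", 0.02, jitter_seed + 1),
                    nci_charge=0, pm5_attr_charge=0, pm7_attr_charge=0,
                )
                categories["PM5_PM7_NOT_NCI"] += 1
                bump(sorted(inj["signature"]))
                truth.update(
                    expected_divergent_pm7_nci=sorted(inj["signature"]),
                    expected_charge=0, dialect_case="both_agree",
                )
            else:
                # isotope labels distinguish versions without touching geometry
                base = BaseMolecule("ethanol", "CCO")
                nci_atoms = _atoms_of(base, embed_seed)
                pm5_atoms = perturb_geometry(nci_atoms, "benign", 0.02, jitter_seed)
                pm7_atoms = perturb_geometry(nci_atoms, "benign", 0.02, jitter_seed + 1)
                first_c = next(i for i, a in enumerate(nci_atoms) if a.element == "C")

                def _label(atoms: Sequence[Atom], mass: int) -> tuple[Atom, ...]:
                    return tuple(
                        Atom(a.element, a.position, mass if i == first_c else a.isotope)
                        for i, a in enumerate(atoms)
                    )

                if role == "inject_pm5":
                    pm5_atoms = _label(pm5_atoms, 13)
                    categories["PM7_NCI_NOT_PM5"] += 1
                    truth.update(expected_divergent_pm7_nci=[])
                else:  # inject_all: PM5 and PM7 get different labels
                    pm5_atoms = _label(pm5_atoms, 13)
                    pm7_atoms = _label(pm7_atoms, 14)
                    categories["ALL_DIFFER"] += 1
                    bump(["isotope"])
                    truth.update(expected_divergent_pm7_nci=["isotope"])
                files = _entry_files(
                    nsc, base, nci_atoms, pm5_atoms, pm7_atoms,
                    nci_charge=0, pm5_attr_charge=0, pm7_attr_charge=0,
                )
                truth.update(expected_charge=0, dialect_case="both_agree")

        elif role == "multicomponent":
            salt, counter_formula = SALT_POOL[salt_idx % len(SALT_POOL)]
            salt_idx += 1
            salt_atoms = _atoms_of(salt, embed_seed)
            # retained fragment = everything except the single counter-ion atom;
            # park the counter-ion well outside bonding range so the embedded
            # ion pair is unambiguously two components
            frag = tuple(a for a in salt_atoms if a.element != counter_formula)
            frag_pos = np.asarray([a.position for a in frag])
            centroid = frag_pos.mean(axis=0)
            radius = float(np.linalg.norm(frag_pos - centroid, axis=1).max())
            offset = centroid + np.array([radius + 6.0, 0.0, 0.0])
            salt_atoms = tuple(
                Atom(a.element, tuple(map(float, offset)), a.isotope)
                if a.element == counter_formula
                else a
                for a in salt_atoms
            )
            pm5_atoms = perturb_geometry(frag, "benign", 0.02, jitter_seed)
            pm7_atoms = perturb_geometry(frag, "benign", 0.02, jitter_seed + 1)
            files = _entry_files(
                nsc, salt, salt_atoms, pm5_atoms, pm7_atoms,
                nci_charge=salt.charge, pm5_attr_charge=salt.charge,
                pm7_attr_charge=salt.charge,
            )
            categories["ALL_MATCH"] += 1
            truth.update(
                multicomponent=True,
                removed_formula=counter_formula,
                expected_charge=salt.charge,
                dialect_case="both_agree",
                expected_divergent_pm7_nci=[],
            )

        elif role == "implausible":
            base = BaseMolecule("benzene", "c1ccccc1")
            nci_atoms = _atoms_of(base, embed_seed)
            pm5_atoms = perturb_geometry(nci_atoms, "benign", 0.02, jitter_seed)
            pm7_atoms = perturb_geometry(nci_atoms, "benign", 0.02, jitter_seed + 1)
            files = _entry_files(
                nsc, base, nci_atoms, pm5_atoms, pm7_atoms,
                nci_charge=None, pm5_attr_charge=4, pm7_attr_charge=4,
            )
            categories["ALL_MATCH"] += 1
            truth.update(
                implausible_charge=True,
                expected_charge=4,
                dialect_case="attribute_only",
                expected_divergent_pm7_nci=[],
            )

        else:  # regular or unannotated
            base = REGULAR_POOL[regular_idx % len(REGULAR_POOL)]
            regular_idx += 1
            nci_atoms = _atoms_of(base, embed_seed)
            if base.charge != 0:
                case = "both_agree"  # a charged species must declare its charge
            else:
                case = _dialect_case(rng, spec.charge_dialect_mix)
            nci_charge = base.charge if case in ("legacy_only", "both_agree", "both_conflict") else None
            pm5_attr = base.charge if case in ("attribute_only", "both_agree", "both_conflict") else None
            # an unannotated entry never reaches reconciliation, so its
            # dialect case carries no conflict in the ground truth
            conflict = case == "both_conflict" and annotated
            if case == "both_conflict":
                nci_charge = base.charge + 1  # stale legacy declaration
            if annotated:
                pm5_atoms = perturb_geometry(nci_atoms, "benign", 0.02, jitter_seed)
                pm7_atoms = perturb_geometry(nci_atoms, "benign", 0.02, jitter_seed + 1)
                categories["ALL_MATCH"] += 1
            else:
                pm5_atoms = pm7_atoms = None
            files = _entry_files(
                nsc, base, nci_atoms, pm5_atoms, pm7_atoms,
                nci_charge=nci_charge, pm5_attr_charge=pm5_attr,
                pm7_attr_charge=base.charge if annotated else None,
            )
            truth.update(
                expected_charge=base.charge,
                dialect_case=case if annotated else "unannotated",
                conflict=conflict,
            )
            if annotated:
                truth.update(expected_divergent_pm7_nci=[])

        seq = len(entries)
        entries.append(
            CorpusEntry(seq=seq, nsc_id=nsc, dirname=f"{seq:05d}_NSC{nsc}", files=files)
        )
        truth_entries[str(nsc)] = truth

    # duplicate occurrences: re-emit annotated entries under a new sequence
    annotated_pool = [
        e for e in entries if truth_entries[str(e.nsc_id)]["role"] not in ("unannotated",)
    ]
    for d in range(n_dup):
        src = annotated_pool[int(rng.integers(0, len(annotated_pool)))]
        seq = len(entries)
        entries.append(
            CorpusEntry(seq=seq, nsc_id=src.nsc_id, dirname=f"{seq:05d}_NSC{src.nsc_id}",
                        files=dict(src.files))
        )
        duplicates.append(src.nsc_id)

    n_unann = sum(1 for t in truth_entries.values() if t["role"] == "unannotated")
    ground_truth = {
        "spec": {
            "n_entries": spec.n_entries,
            "seed": spec.seed,
            "per_layer_mismatch_counts": dict(spec.per_layer_mismatch_counts),
        },
        "total_occurrences": len(entries),
        "unique_entries": len(truth_entries),
        "duplicates_removed": n_dup,
        "duplicate_nscs": sorted(duplicates),
        "unannotated_excluded": n_unann,
        "expected_category_counts": categories,
        "expected_layer_histogram_pm7_nci": dict(sorted(layer_hist.items())),
        "entries": truth_entries,
    }
    return Corpus(entries=tuple(entries), ground_truth=ground_truth)
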