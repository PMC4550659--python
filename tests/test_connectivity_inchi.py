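"""Bond perception, XYZ normalization, InChI generation and layer dissection."""

from __future__ import annotations

import shutil
import subprocess

import numpy as np
import pytest

from molcurate.cml_records import Atom, MoleculeRecord
from molcurate.connectivity_inchi import (
    DEFAULT_TOLERANCE,
    InChILayers,
    canonical_order,
    default_radii,
    generate_inchi,
    parse_layers,
    perceive_connectivity,
    read_xyz,
    serialize_layers,
    to_canonical_xyz,
    write_xyz,
)
from molcurate.errors import ConfigurationError, GeometryError, InChIError

WATER_XYZ = (
    "3\nwater\n"
    "O 0.000000 0.000000 0.000000\n"
    "H 0.957200 0.000000 0.000000\n"
    "H -0.239987 0.926627 0.000000\n"
)
METHANE_XYZ = (
    "5\nmethane\n"
    "C 0.000000 0.000000 0.000000\n"
    "H 0.629118 0.629118 0.629118\n"
    "H -0.629118 -0.629118 0.629118\n"
    "H -0.629118 0.629118 -0.629118\n"
    "H 0.629118 -0.629118 -0.629118\n"
)


def _rigid_motion(atoms, seed=5):
    rng = np.random.default_rng(seed)
    # random rotation via QR, plus a translation
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-10, 10, size=3)
    pos = np.array([a.position for a in atoms])
    moved = pos @ q.T + t
    return [Atom(a.element, tuple(p)) for a, p in zip(atoms, moved)]


class TestPerceiveConnectivity:
    def test_h2_within_radius_sum_plus_tolerance(self):
        # r(H)+r(H)+tol = 0.31+0.31+0.40 = 1.02 Å, so 0.74 Å is a bond
        atoms = [Atom("H", (0, 0, 0)), Atom("H", (0.74, 0, 0))]
        assert perceive_connectivity(atoms).edges == frozenset({(0, 1)})
        far = [Atom("H", (0, 0, 0)), Atom("H", (1.03, 0, 0))]
        assert perceive_connectivity(far).edges == frozenset()

    def test_distant_pair_never_bonded(self):
        atoms = [Atom("C", (0, 0, 0)), Atom("C", (5.0, 0, 0))]
        assert perceive_connectivity(atoms).edges == frozenset()

    def test_invariant_under_rigid_motion(self, water_record):
        g0 = perceive_connectivity(water_record.atoms)
        g1 = perceive_connectivity(_rigid_motion(water_record.atoms))
        assert g0.edges == g1.edges

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(7)
        atoms = [Atom("C", tuple(p)) for p in rng.uniform(-3, 3, size=(10, 3))]
        previous = frozenset()
        for tol in (0.0, 0.2, 0.4, 0.8, 1.5):
            edges = perceive_connectivity(atoms, tolerance=tol).edges
            assert previous <= edges
            previous = edges

    def test_missing_radius_names_element(self):
        atoms = [Atom("C", (0, 0, 0)), Atom("O", (1.2, 0, 0))]
        with pytest.raises(ConfigurationError, match="'O'"):
            perceive_connectivity(atoms, radii={"C": 0.76})

    def test_sub_floor_distance_is_geometry_error(self):
        atoms = [Atom("C", (0, 0, 0)), Atom("H", (0.2, 0, 0))]
        with pytest.raises(GeometryError, match="floor"):
            perceive_connectivity(atoms)

    def test_default_radius_table_loaded(self):
        radii = default_radii()
        assert radii["H"] == 0.31 and radii["C"] == 0.76


class TestCanonicalXYZ:
    def test_bond_data_discarded(self, water_record):
        from dataclasses import replace

        rec = replace(water_record, bonds=((0, 1, "1"), (0, 2, "1")))
        xyz = to_canonical_xyz(rec)
        assert "bond" not in xyz.lower()
        symbols, coords, _ = read_xyz(xyz)
        assert symbols == ["H", "H", "O"]  # element-alphabetical order

    def test_xyz_round_trip_six_decimals(self):
        symbols, coords, comment = read_xyz(WATER_XYZ)
        again = write_xyz(symbols, coords, comment)
        s2, c2, _ = read_xyz(again)
        assert s2 == symbols
        assert np.abs(c2 - coords).max() < 1e-6

    def test_zero_atoms_rejected(self):
        rec = MoleculeRecord(atoms=(), nsc_id=1)
        with pytest.raises(GeometryError):
            to_canonical_xyz(rec)

    def test_canonical_order_stable_within_element(self, water_record):
        assert canonical_order(water_record) == [1, 2, 0]


class TestGenerateInChI:
    @pytest.mark.parametrize(
        "xyz,expected",
        [(WATER_XYZ, "InChI=1S/H2O/h1H2"), (METHANE_XYZ, "InChI=1S/CH4/h1H4")],
        ids=["water", "methane"],
    )
    def test_reference_values(self, xyz, expected):
        inchi, key = generate_inchi(xyz)
        assert inchi == expected
        assert len(key) == 27 and key[14] == "-"

    @pytest.mark.skipif(shutil.which("obabel") is None, reason="obabel not on PATH")
    @pytest.mark.parametrize("xyz", [WATER_XYZ, METHANE_XYZ], ids=["water", "methane"])
    def test_agrees_with_independent_openbabel_oracle(self, xyz, tmp_path):
        path = tmp_path / "in.xyz"
        path.write_text(xyz)
        out = subprocess.run(
            ["obabel", str(path), "-oinchi"], capture_output=True, text=True, check=True
        )
        oracle = out.stdout.strip().splitlines()[0]
        assert generate_inchi(xyz)[0] == oracle

    def test_deterministic(self):
        assert generate_inchi(WATER_XYZ) == generate_inchi(WATER_XYZ)

    def test_invariant_to_atom_order(self):
        shuffled = (
            "3\nwater shuffled\n"
            "H 0.957200 0.000000 0.000000\n"
            "O 0.000000 0.000000 0.000000\n"
            "H -0.239987 0.926627 0.000000\n"
        )
        assert generate_inchi(shuffled) == generate_inchi(WATER_XYZ)

    def test_charge_reaches_q_layer(self):
        # allyl geometry is valid as both the anion and the cation
        from molcurate.fixtures import _atoms_of, BaseMolecule

        atoms = _atoms_of(BaseMolecule("allyl", "C=C[CH2-]", charge=-1), seed=7)
        xyz = write_xyz([a.element for a in atoms], np.array([a.position for a in atoms]))
        minus, _ = generate_inchi(xyz, charge=-1)
        plus, _ = generate_inchi(xyz, charge=+1)
        assert parse_layers(minus).charge == "-1"
        assert parse_layers(plus).charge == "+1"

    def test_isotope_labels_travel_with_coordinates(self):
        inchi, _ = generate_inchi(METHANE_XYZ, isotopes={0: 13})
        assert parse_layers(inchi).isotope is not None

    def test_empty_xyz_rejected(self):
        with pytest.raises(GeometryError):
            generate_inchi("0\nempty\n")


# layer strings derived from the reference implementation during development
TMA_INCHI = "InChI=1S/C4H12N/c1-5(2,3)4/h1-4H3/q+1"
ALANINE_INCHI = "InChI=1S/C3H7NO2/c1-2(4)3(5)6/h2H,4H2,1H3,(H,5,6)/t2-/m1/s1"
BUTENE_INCHI = "InChI=1S/C4H8/c1-3-4-2/h3-4H,1-2H3/b4-3+"


class TestParseLayers:
    def test_water_layers(self):
        layers = parse_layers("InChI=1S/H2O/h1H2")
        assert layers.formula == "H2O"
        assert layers.hydrogen == "1H2"
        for label in ("connectivity", "charge", "double_bond", "tetrahedral", "isotope"):
            assert layers.layer(label) is None

    def test_charge_layer_present(self):
        layers = parse_layers(TMA_INCHI)
        assert layers.charge == "+1"
        assert layers.connectivity == "1-5(2,3)4"

    def test_tetrahedral_includes_m_s_sublayers(self):
        layers = parse_layers(ALANINE_INCHI)
        assert layers.tetrahedral == "2-/m1/s1"

    def test_double_bond_layer(self):
        assert parse_layers(BUTENE_INCHI).double_bond == "4-3+"

    def test_round_trip_on_many_strings(self):
        # grammar-valid layer combinations over several formulas; ≥200 strings
        bodies = ["H2O", "CH4", "C6H10", "C4H12N", "C3H7NO2", "2CH3S", "C2H4O2", "C13H21N2O"]
        tails = [
            "", "/c1-2", "/h1H2", "/c1-2/h1H2", "/q+1", "/q-2", "/p-1",
            "/b4-3+", "/t2-/m1/s1", "/i1+1", "/c1-2/h1H2/q+1/b4-3-/t2-/m0/s1/i1+2",
            "/h1H2/i1D", "/c1-3-4-2/h3-4H,1-2H3/b4-3+;", "/c1-2/h1H;2H/q+1;-1",
        ]
        strings = [f"InChI=1S/{b}{t}" for b in bodies for t in tails]
        strings += [s.replace("1S/", "1/") for s in strings[:100]]
        assert len(strings) >= 200
        for s in strings:
            assert serialize_layers(parse_layers(s)) == s

    @pytest.mark.parametrize("bad", ["NotAnInChI", "InChI=1S/H2O/f", "InChI=1S/H2O/x9"])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(InChIError):
            parse_layers(bad)
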