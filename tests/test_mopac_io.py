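"""Input decks, Z-matrix round trips and optimizer output parsing."""

from __future__ import annotations

import math

import numpy as np
import pytest

from molcurate.charge_semantics import ChargeAssignment, ChargeSource, reconcile_charge
from molcurate.cml_records import Atom, MoleculeRecord
from molcurate.charge_semantics import Multiplicity, electron_count, spin_state, validate_spin_consistency
from molcurate.errors import ConfigurationError, GeometryError, MopacParseError
from molcurate.mopac_io import (
    MopacInput,
    Termination,
    build_input,
    cartesian_to_internal,
    format_input,
    internal_to_cartesian,
    mock_optimizer_output,
    parse_input,
    parse_output,
    run_optimizer,
)


def _pairwise(coords: np.ndarray) -> np.ndarray:
    return np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)


class TestZMatrix:
    def test_diatomic_distance(self):
        rows = cartesian_to_internal([Atom("H", (0, 0, 0)), Atom("H", (0.74, 0, 0))])
        assert rows[1].distance == pytest.approx(0.74)

    def test_water_angle_reproduced(self):
        # build a geometry with O-H 0.96 Å and H-O-H 104.5°, then convert
        theta = math.radians(104.5)
        atoms = [
            Atom("O", (0, 0, 0)),
            Atom("H", (0.96, 0, 0)),
            Atom("H", (0.96 * math.cos(theta), 0.96 * math.sin(theta), 0)),
        ]
        rows = cartesian_to_internal(atoms)
        assert rows[2].distance == pytest.approx(0.96, abs=1e-6)
        assert rows[2].angle == pytest.approx(104.5, abs=1e-6)

    def test_round_trip_preserves_pairwise_distances(self):
        rng = np.random.default_rng(20240815)
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(5, 16))
            pos = rng.uniform(-4, 4, size=(n, 3))
            atoms = [Atom("C", tuple(p)) for p in pos]
            back = internal_to_cartesian(cartesian_to_internal(atoms))
            q = np.array([a.position for a in back])
            worst = max(worst, float(np.abs(_pairwise(pos) - _pairwise(q)).max()))
        assert worst < 1e-4

    def test_coincident_atoms_rejected(self):
        with pytest.raises(GeometryError, match="coincident"):
            cartesian_to_internal([Atom("C", (0, 0, 0)), Atom("C", (0, 0, 0))])

    def test_reference_indices_precede_row(self):
        rng = np.random.default_rng(3)
        atoms = [Atom("C", tuple(p)) for p in rng.uniform(-2, 2, size=(8, 3))]
        for i, row in enumerate(cartesian_to_internal(atoms)):
            for r in (row.r1, row.r2, row.r3):
                assert r is None or r < i


def _neutral_record(elements=("O", "H", "H")) -> MoleculeRecord:
    theta = math.radians(104.5)
    pos = [(0, 0, 0), (0.96, 0, 0), (0.96 * math.cos(theta), 0.96 * math.sin(theta), 0)]
    return MoleculeRecord(
        atoms=tuple(Atom(e, p) for e, p in zip(elements, pos)),
        nsc_id=5,
        name="species",
    )


class TestBuildInput:
    def test_charged_record_declares_charge(self):
        rec = MoleculeRecord(
            atoms=(Atom("N", (0, 0, 0)), Atom("H", (1, 0, 0)), Atom("H", (0, 1, 0)),
                   Atom("H", (0, 0, 1)), Atom("H", (-0.6, -0.6, -0.6))),
            nsc_id=3, formal_charge_attr=1,
        )
        deck = build_input(rec, reconcile_charge(rec))
        assert "CHARGE=1" in deck.keywords

    def test_neutral_record_still_explicit(self):
        rec = _neutral_record()
        deck = build_input(rec, reconcile_charge(rec))
        assert "CHARGE=0" in deck.keywords
        assert "SINGLET" in deck.keywords

    def test_odd_electron_neutral_species_is_doublet(self):
        rec = MoleculeRecord(
            atoms=(Atom("N", (0, 0, 0)), Atom("O", (1.15, 0, 0))), nsc_id=4
        )
        deck = build_input(rec, reconcile_charge(rec))
        assert "DOUBLET" in deck.keywords

    def test_placeholder_never_appears(self):
        rec = _neutral_record()
        text = format_input(build_input(rec, reconcile_charge(rec)))
        assert "PUT KEYWORDS HERE" not in text

    def test_placeholder_keywords_rejected_at_construction(self):
        with pytest.raises(ConfigurationError):
            MopacInput(keywords=("PUT", "KEYWORDS", "HERE"), title="", comment="",
                       cartesian=(Atom("C", (0, 0, 0)),))

    def test_implausible_charge_proceeds_with_warning(self):
        rec = _neutral_record()
        charge = ChargeAssignment(4, ChargeSource.FORMAL_ATTR, plausible=False)
        deck = build_input(rec, charge)
        assert "CHARGE=4" in deck.keywords
        assert any("plausibility" in w for w in deck.warnings)

    def test_missing_coordinates_rejected(self):
        rec = MoleculeRecord(atoms=(Atom("C"),), nsc_id=1)
        with pytest.raises(GeometryError):
            build_input(rec, reconcile_charge(rec))

    def test_deterministic_byte_identical(self):
        rec = _neutral_record()
        charge = reconcile_charge(rec)
        assert format_input(build_input(rec, charge)) == format_input(build_input(rec, charge))

    def test_spin_checksum_holds_by_construction(self):
        for attr in (None, 1, -1, 2):
            rec = MoleculeRecord(
                atoms=_neutral_record().atoms, nsc_id=1, formal_charge_attr=attr
            )
            charge = reconcile_charge(rec)
            deck = build_input(rec, charge)
            declared = Multiplicity.SINGLET if "SINGLET" in deck.keywords else Multiplicity.DOUBLET
            assert validate_spin_consistency(declared, charge, rec.formula()).ok

    @pytest.mark.parametrize("mode", ["internal", "cartesian"])
    def test_deck_text_round_trip_within_tolerance(self, mode):
        rec = _neutral_record()
        deck = build_input(rec, reconcile_charge(rec), coords_mode=mode)
        back = parse_input(format_input(deck))
        assert back.keywords == deck.keywords
        if mode == "internal":
            for a, b in zip(back.zmatrix, deck.zmatrix):
                assert a.element == b.element
                if b.distance is not None:
                    assert a.distance == pytest.approx(b.distance, abs=1e-4)
                if b.angle is not None:
                    assert a.angle == pytest.approx(b.angle, abs=1e-2)
        else:
            for a, b in zip(back.cartesian, deck.cartesian):
                assert a.position == pytest.approx(b.position, abs=1e-4)


class TestParseOutput:
    def test_mock_output_round_trips_geometry(self):
        rec = _neutral_record()
        deck = build_input(rec, reconcile_charge(rec), coords_mode="cartesian")
        atoms, props, status = parse_output(mock_optimizer_output(deck, heat_kcal_mol=-57.8))
        assert status is Termination.NORMAL
        assert [a.element for a in atoms] == ["O", "H", "H"]
        assert props["final_heat_of_formation_kcal_mol"] == pytest.approx(-57.8)
        got = np.array([a.position for a in atoms])
        want = np.array([a.position for a in rec.atoms])
        assert np.abs(got - want).max() < 1e-5

    def test_error_termination_needs_no_geometry(self):
        text = " SOMETHING WENT WRONG\n CALCULATION IS TERMINATED\n"
        atoms, _props, status = parse_output(text)
        assert status is Termination.ERROR
        assert atoms == ()

    def test_truncated_output_is_a_parse_error(self):
        with pytest.raises(MopacParseError, match="truncated"):
            parse_output("          CARTESIAN COORDINATES\n     1  C  0.0 0.0 0.0\n")


class TestRunOptimizer:
    def test_mock_command_returns_parseable_text(self):
        rec = _neutral_record()
        deck = build_input(rec, reconcile_charge(rec))
        text = run_optimizer(deck, "mock")
        _atoms, _props, status = parse_output(text)
        assert status is Termination.NORMAL

    def test_missing_executable_is_configuration_error(self):
        rec = _neutral_record()
        deck = build_input(rec, reconcile_charge(rec))
        with pytest.raises(ConfigurationError):
            run_optimizer(deck, "definitely-not-a-real-optimizer {input}")

    def test_template_without_placeholder_rejected(self):
        rec = _neutral_record()
        deck = build_input(rec, reconcile_charge(rec))
        with pytest.raises(ConfigurationError):
            run_optimizer(deck, "mopac")
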