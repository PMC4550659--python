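"""CML parsing, validation, writing and corpus operations."""

from __future__ import annotations

import pytest

from molcurate.cml_records import (
    CML24,
    Atom,
    CMLProfile,
    CorpusReport,
    MoleculeRecord,
    deduplicate,
    filter_annotated,
    parse_cml,
    parse_conflated_cml,
    select_largest_component,
    validate_cml,
    write_cml,
)
from molcurate.connectivity_inchi import perceive_connectivity
from molcurate.errors import CMLParseError, CMLValidationError, GeometryError
from conftest import ATTRIBUTE_DIALECT_DOC, LEGACY_DIALECT_DOC


class TestParseDialects:
    def test_attribute_dialect(self):
        rec = parse_cml(ATTRIBUTE_DIALECT_DOC)
        assert rec.formal_charge_attr == 1
        assert rec.legacy_charge is None
        assert rec.nsc_id == 138467
        assert rec.name == "mol1"

    def test_legacy_dialect(self):
        rec = parse_cml(LEGACY_DIALECT_DOC)
        assert rec.legacy_charge == 1
        assert rec.formal_charge_attr is None
        assert rec.legacy_basic.startswith("C13H21N2O")

    def test_neither_dialect_is_absent_not_zero(self):
        doc = (
            '<molecule xmlns="http://www.xml-cml.org/schema" id="NSC7">'
            '<atomArray><atom id="a1" elementType="C"/></atomArray></molecule>'
        )
        rec = parse_cml(doc)
        assert rec.formal_charge_attr is None
        assert rec.legacy_charge is None

    def test_atom_order_and_coordinates(self, water_record):
        rec = parse_cml(write_cml(water_record))
        assert rec.elements == ("O", "H", "H")
        assert rec.atoms[1].position == pytest.approx((0.9572, 0.0, 0.0))

    def test_malformed_xml_raises(self):
        with pytest.raises(CMLParseError):
            parse_cml("this is not xml <<<")

    def test_unknown_element_named_in_error(self):
        doc = (
            '<molecule xmlns="http://www.xml-cml.org/schema">'
            '<atomArray><atom id="a1" elementType="Xx"/></atomArray></molecule>'
        )
        with pytest.raises(CMLValidationError, match="Xx"):
            parse_cml(doc)


_ROUND_TRIP_RECORDS = [
    MoleculeRecord(
        atoms=(Atom("C", (0.1, -0.25, 3.5)), Atom("O", (1.3, 0.0, 0.0), isotope=18)),
        bonds=((0, 1, "2"),),
        provenance="PM5",
        nsc_id=42,
        cas_id="50-00-0",
        name="formaldehyde-ish",
        formal_charge_attr=0,
        smiles="C=O",
        inchi="InChI=1S/CH2O/c1-2/h1H2",
        inchikey="WSFSSNUMVMOOMR-UHFFFAOYSA-N",
    ),
    MoleculeRecord(
        atoms=(Atom("N", (0.0, 0.0, 0.0)),),
        provenance="NCI",
        nsc_id=7,
        legacy_charge=1,
        legacy_basic="N",
    ),
    MoleculeRecord(
        atoms=(Atom("H", None), Atom("H", (0.74, 0.0, 0.0))),
        provenance="PM7",
        nsc_id=9,
        name="partial positions",
    ),
]


@pytest.mark.parametrize("record", _ROUND_TRIP_RECORDS, ids=["full", "legacy", "sparse"])
def test_write_parse_round_trip_exact(record):
    assert parse_cml(write_cml(record)) == record


class TestConflated:
    def test_three_provenances_one_document(self, water_record):
        from dataclasses import replace

        records = [
            water_record,
            replace(water_record, provenance="PM5"),
            replace(water_record, provenance="PM7"),
        ]
        doc = write_cml(records, profile="conflated")
        back = parse_conflated_cml(doc)
        assert [r.provenance for r in back] == ["NCI", "PM5", "PM7"]
        assert all(r.atoms == water_record.atoms for r in back)

    def test_zero_atoms_rejected(self):
        rec = MoleculeRecord(atoms=(), nsc_id=1)
        with pytest.raises(CMLValidationError):
            write_cml(rec)

    def test_missing_coordinates_rejected_listing_atoms(self):
        rec = MoleculeRecord(atoms=(Atom("C"), Atom("H", (1.0, 0, 0))), nsc_id=1)
        with pytest.raises(GeometryError, match=r"\[0\]"):
            write_cml([rec], profile="conflated")


class TestValidate:
    def test_valid_document_has_no_violations(self, water_record):
        assert validate_cml(write_cml(water_record)) == []

    def test_missing_bond_array_violation_names_element(self, water_record):
        violations = validate_cml(
            write_cml(water_record), CMLProfile(require_bond_array=True)
        )
        assert len(violations) == 1
        assert "bondArray" in violations[0].message

    def test_schema_invalid_attribute_reported(self):
        doc = (
            '<molecule xmlns="http://www.xml-cml.org/schema" formalCharge="one">'
            '<atomArray><atom id="a1" elementType="C"/></atomArray></molecule>'
        )
        # bad formalCharge is caught by the parser before the schema sees it
        with pytest.raises(CMLParseError):
            parse_cml(doc)
        violations = validate_cml(doc.replace('formalCharge="one"', 'bogus="1"'))
        assert violations and any("bogus" in v.message for v in violations)

    def test_non_xml_is_a_parse_error_not_violations(self):
        with pytest.raises(CMLParseError):
            validate_cml("not xml at all")


def _rec(nsc: int) -> MoleculeRecord:
    return MoleculeRecord(atoms=(Atom("C", (0.0, 0.0, 0.0)),), nsc_id=nsc)


class TestDeduplicate:
    def test_first_occurrence_kept(self):
        a, b, a2 = _rec(1), _rec(2), _rec(1)
        unique, report = deduplicate([a, b, a2])
        assert unique == [a, b]
        assert report == CorpusReport(3, 2, 1, 0)

    def test_empty_corpus(self):
        unique, report = deduplicate([])
        assert unique == [] and report == CorpusReport(0, 0, 0, 0)

    def test_injected_duplicates_match_set_oracle(self):
        # 100 records, 7 of which repeat an earlier accession
        records = [_rec(i) for i in range(93)] + [_rec(i * 13 % 93) for i in range(7)]
        unique, report = deduplicate(records)
        assert report.unique_kept == len({r.nsc_id for r in records}) == 93
        assert report.duplicates_removed == 7

    def test_idempotent(self):
        records = [_rec(1), _rec(2), _rec(1), _rec(3)]
        unique, _ = deduplicate(records)
        again, report2 = deduplicate(unique)
        assert again == unique
        assert report2.duplicates_removed == 0

    def test_missing_accession_identifies_position(self):
        records = [_rec(1), MoleculeRecord(atoms=(Atom("C", (0, 0, 0)),))]
        with pytest.raises(CMLValidationError, match="position 1"):
            deduplicate(records)


class TestFilterAnnotated:
    @pytest.mark.parametrize(
        "present,expected_kept,expected_excluded",
        [([True, True, False, True, False], 3, 2), ([True] * 4, 4, 0), ([False] * 3, 0, 3)],
    )
    def test_exclusion_counts(self, present, expected_kept, expected_excluded):
        pairs = [(_rec(i), _rec(i) if p else None) for i, p in enumerate(present)]
        kept, excluded = filter_annotated(pairs)
        assert len(kept) == expected_kept
        assert excluded == expected_excluded
        assert all(b is not None for _, b in kept)


class TestSelectLargestComponent:
    def test_counter_ion_removed(self, salt_record):
        graph = perceive_connectivity(salt_record.atoms)
        core, removal = select_largest_component(salt_record, graph)
        assert len(core.atoms) == 7
        assert removal.formula == "Na"
        assert not removal.charge_suspect  # -1 declared on the fragment
        assert core.legacy_charge == -1

    def test_counter_ion_without_declared_charge_is_suspect(self, salt_record):
        from dataclasses import replace

        rec = replace(salt_record, legacy_charge=None)
        graph = perceive_connectivity(rec.atoms)
        _, removal = select_largest_component(rec, graph)
        assert removal.charge_suspect

    def test_single_component_identity(self, water_record):
        graph = perceive_connectivity(water_record.atoms)
        core, removal = select_largest_component(water_record, graph)
        assert core == water_record
        assert removal.formula == "" and removal.n_atoms_removed == 0

    def test_equal_size_tie_breaks_to_lowest_index_and_flags(self):
        rec = MoleculeRecord(
            atoms=(Atom("O", (0, 0, 0)), Atom("N", (9, 9, 9))), nsc_id=1
        )
        graph = perceive_connectivity(rec.atoms)
        core, removal = select_largest_component(rec, graph)
        assert core.elements == ("O",)
        assert removal.tie_break

    def test_never_increases_atoms_and_preserves_order(self, salt_record):
        graph = perceive_connectivity(salt_record.atoms)
        core, _ = select_largest_component(salt_record, graph)
        assert len(core.atoms) <= len(salt_record.atoms)
        kept = [a for a in salt_record.atoms if a.element != "Na"]
        assert list(core.atoms) == kept

    def test_empty_graph_rejected(self):
        from molcurate.connectivity_inchi import ConnectivityGraph

        rec = MoleculeRecord(atoms=(), nsc_id=1)
        with pytest.raises(GeometryError):
            select_largest_component(rec, ConnectivityGraph(0, frozenset()))


def test_corpus_report_arithmetic_enforced():
    with pytest.raises(CMLValidationError):
        CorpusReport(total_read=10, unique_kept=5, duplicates_removed=2, excluded_no_annotation=1)
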