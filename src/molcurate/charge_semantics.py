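"""Charge reconciliation and spin-multiplicity semantics.

A semi-empirical optimizer treats an undeclared net charge as zero and then
derives the spin multiplicity implicitly from the electron count — so a +1
species whose charge is silently dropped runs as a neutral odd-electron
doublet without any error.  This module makes every one of those implicit
steps explicit: the two CML charge dialects are reconciled with a stated
precedence, charges outside |q| ≤ 3 are flagged as implausible (manual
inspection of the corpus showed such declarations to be curation errors),
and the singlet/doublet assignment is computed from the electron count so it
can serve as a checksum against the declared state.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from .cml_records import MoleculeRecord
from .errors import CMLValidationError
from .formula import atomic_number

#: Declared charges with |q| above this are flagged implausible.
PLAUSIBLE_ABS_CHARGE = 3


class ChargeSource(enum.Enum):
    FORMAL_ATTR = "FORMAL_ATTR"
    LEGACY_IDENTIFIER = "LEGACY_IDENTIFIER"
    DEFAULT_ZERO = "DEFAULT_ZERO"


class Multiplicity(enum.Enum):
    SINGLET = "SINGLET"
    DOUBLET = "DOUBLET"


@dataclass(frozen=True)
class ChargeAssignment:
    """Reconciled net charge with provenance and plausibility flags."""

    value: int
    source: ChargeSource
    conflict: bool = False  # both dialects present and unequal
    plausible: bool = True  # |value| <= PLAUSIBLE_ABS_CHARGE

    def __post_init__(self) -> None:
        if self.source is ChargeSource.DEFAULT_ZERO and self.value != 0:
            raise CMLValidationError("DEFAULT_ZERO charge must be 0")


@dataclass(frozen=True)
class SpinState:
    electron_count: int
    multiplicity: Multiplicity

    def __post_init__(self) -> None:
        expected = Multiplicity.SINGLET if self.electron_count % 2 == 0 else Multiplicity.DOUBLET
        if self.multiplicity is not expected:
            raise CMLValidationError(
                f"multiplicity {self.multiplicity.value} inconsistent with "
                f"{self.electron_count} electrons"
            )


@dataclass(frozen=True)
class SpinConsistency:
    """Result of checking a declared multiplicity against the computed one."""

    ok: bool
    declared: Multiplicity
    computed: Multiplicity
    charge_used: int

    def message(self) -> str:
        if self.ok:
            return "declared multiplicity consistent with electron count"
        return (
            f"declared {self.declared.value} but electron count at charge "
            f"{self.charge_used:+d} implies {self.computed.value}"
        )


def reconcile_charge(
    record: MoleculeRecord, plausible_abs: int = PLAUSIBLE_ABS_CHARGE
) -> ChargeAssignment:
    """Reconcile the two dialect declarations into one net charge.

    Precedence: ``formalCharge`` attribute over the legacy ``identifier``
    child over an explicit default of zero.  Disagreeing dialects yield a
    conflict flag (value from the attribute) rather than an error — corpus
    curation annotates and proceeds.
    """
    attr, legacy = record.formal_charge_attr, record.legacy_charge
    if attr is not None:
        value, source = attr, ChargeSource.FORMAL_ATTR
        conflict = legacy is not None and legacy != attr
    elif legacy is not None:
        value, source, conflict = legacy, ChargeSource.LEGACY_IDENTIFIER, False
    else:
        value, source, conflict = 0, ChargeSource.DEFAULT_ZERO, False
    return ChargeAssignment(
        value=value,
        source=source,
        conflict=conflict,
        plausible=abs(value) <= plausible_abs,
    )


def electron_count(formula: Mapping[str, int], charge: int = 0) -> int:
    """Total electron count of a species: Σ Z·n over the formula, minus the net charge."""
    total = sum(atomic_number(el) * n for el, n in formula.items())
    count = total - charge
    if count < 0:
        raise CMLValidationError(
            f"impossible species: {total} electrons from nuclei, net charge {charge:+d}"
        )
    return count


def spin_state(electrons: int) -> SpinState:
    """Even electron count → singlet; odd → doublet.

    Higher multiplicities are out of scope for this closed-shell organic
    corpus and are never produced.
    """
    if electrons < 0:
        raise CMLValidationError("electron count must be non-negative")
    mult = Multiplicity.SINGLET if electrons % 2 == 0 else Multiplicity.DOUBLET
    return SpinState(electron_count=electrons, multiplicity=mult)


def validate_spin_consistency(
    declared: Multiplicity,
    charge: ChargeAssignment,
    formula: Mapping[str, int],
) -> SpinConsistency:
    """Checksum: does the declared multiplicity match the one implied by the
    formula and the reconciled charge?  Inconsistency is a value, not an
    exception — exactly how a declared SINGLET keyword traps a silently
    dropped charge in the optimizer itself."""
    computed = spin_state(electron_count(formula, charge.value)).multiplicity
    return SpinConsistency(
        ok=(declared is computed),
        declared=declared,
        computed=computed,
        charge_used=charge.value,
    )


def charge_histogram(assignments: list[ChargeAssignment]) -> dict[int, int]:
    """Formal-charge distribution over a corpus, net charge → count."""
    return dict(sorted(Counter(a.value for a in assignments).items()))
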