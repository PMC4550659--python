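"""Molecular formula helpers (Hill order, parsing, element lookups)."""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable, Mapping

from rdkit import Chem

from .errors import CMLValidationError

_PT = Chem.GetPeriodicTable()

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def is_element(symbol: str) -> bool:
    """True iff *symbol* is a periodic-table element symbol."""
    try:
        return _PT.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


def atomic_number(symbol: str) -> int:
    try:
        z = _PT.GetAtomicNumber(symbol)
    except Exception:
        z = 0
    if z <= 0:
        raise CMLValidationError(f"unknown element symbol {symbol!r}")
    return z


def hill_formula(counts: Mapping[str, int]) -> str:
    """Hill-order formula string: C first, H second, remaining alphabetical.

    Without carbon, all elements (H included) are alphabetical.
    """
    counts = {el: n for el, n in counts.items() if n}
    parts: list[str] = []

    def emit(el: str) -> None:
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")

    if "C" in counts:
        emit("C")
        if "H" in counts:
            emit("H")
        for el in sorted(counts):
            if el not in ("C", "H"):
                emit(el)
    else:
        for el in sorted(counts):
            emit(el)
    return "".join(parts)


def formula_counts(elements: Iterable[str]) -> dict[str, int]:
    """Element → count map from an iterable of element symbols."""
    return dict(Counter(elements))


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a plain Hill-style formula (no parentheses) into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise CMLValidationError(f"cannot parse formula {formula!r} at {pos}")
        el, num = m.group(1), m.group(2)
        if not is_element(el):
            raise CMLValidationError(f"unknown element symbol {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise CMLValidationError(f"cannot parse formula {formula!r}")
    return counts
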