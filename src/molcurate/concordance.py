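"""Triplet concordance: comparing the three InChI strings of each molecule.

Every curated molecule has three structure versions — the original database
geometry (NCI), the first-generation semi-empirical optimization (PM5) and
the re-optimization (PM7).  After normalization each yields one InChI, and
the equality pattern of the three strings falls into exactly one of five
categories.  Whole-string equality decides the category; a second,
diagnostic pass attributes each unequal pair to the InChI layers that
differ.  One mismatched pair can diverge in several layers at once, so the
per-layer tallies may legitimately sum to more than the number of
mismatched pairs.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .connectivity_inchi import LAYER_LABELS, InChILayers, parse_layers
from .errors import CMLValidationError


class ConcordanceCategory(enum.Enum):
    ALL_MATCH = "NCI = PM5 = PM7"
    PM5_PM7_NOT_NCI = "(PM5 = PM7) != NCI"
    PM7_NCI_NOT_PM5 = "(PM7 = NCI) != PM5"
    PM5_NCI_NOT_PM7 = "(PM5 = NCI) != PM7"
    ALL_DIFFER = "PM7 != PM5 != NCI"


#: The three comparable provenance pairs, in canonical order.
PAIRS = (("NCI", "PM5"), ("NCI", "PM7"), ("PM5", "PM7"))


def classify_triplet(inchi_nci: str, inchi_pm5: str, inchi_pm7: str) -> ConcordanceCategory:
    """Exactly one of the five categories, by exact string equality."""
    for name, value in (("NCI", inchi_nci), ("PM5", inchi_pm5), ("PM7", inchi_pm7)):
        if not value:
            raise CMLValidationError(f"empty InChI for provenance {name}")
    eq_55_77 = inchi_pm5 == inchi_pm7
    eq_nci_5 = inchi_nci == inchi_pm5
    eq_nci_7 = inchi_nci == inchi_pm7
    if eq_55_77 and eq_nci_5:
        return ConcordanceCategory.ALL_MATCH
    if eq_55_77:
        return ConcordanceCategory.PM5_PM7_NOT_NCI
    if eq_nci_7:
        return ConcordanceCategory.PM7_NCI_NOT_PM5
    if eq_nci_5:
        return ConcordanceCategory.PM5_NCI_NOT_PM7
    return ConcordanceCategory.ALL_DIFFER


def divergent_layers(a: InChILayers, b: InChILayers) -> set[str]:
    """All layer labels whose strings differ between two dissected InChIs.

    Absence is a comparable state: a present-but-different layer and a
    missing layer both count as divergent.  Every differing layer is
    reported, not just the first.
    """
    out: set[str] = set()
    if a.version_prefix != b.version_prefix:
        out.add("formula")  # version mismatch surfaces at the head of the string
    for label in LAYER_LABELS:
        if a.layer(label) != b.layer(label):
            out.add(label)
    return out


@dataclass(frozen=True)
class TripletResult:
    """Concordance outcome for one molecule's NCI/PM5/PM7 InChI triplet."""

    nsc_id: int
    category: ConcordanceCategory
    divergent: Mapping[tuple[str, str], frozenset[str]]  # unequal pair -> layer labels

    def __post_init__(self) -> None:
        if (self.category is ConcordanceCategory.ALL_MATCH) != (len(self.divergent) == 0):
            raise CMLValidationError(
                "divergent-layer map must be empty exactly for ALL_MATCH triplets"
            )


def analyze_triplet(
    nsc_id: int, inchi_nci: str, inchi_pm5: str, inchi_pm7: str
) -> TripletResult:
    """Classify a triplet and attribute every unequal pair to its layers."""
    category = classify_triplet(inchi_nci, inchi_pm5, inchi_pm7)
    by_prov = {"NCI": inchi_nci, "PM5": inchi_pm5, "PM7": inchi_pm7}
    divergent: dict[tuple[str, str], frozenset[str]] = {}
    if category is not ConcordanceCategory.ALL_MATCH:
        parsed = {p: parse_layers(s) for p, s in by_prov.items()}
        for pa, pb in PAIRS:
            if by_prov[pa] != by_prov[pb]:
                divergent[(pa, pb)] = frozenset(divergent_layers(parsed[pa], parsed[pb]))
    return TripletResult(nsc_id=nsc_id, category=category, divergent=divergent)


@dataclass(frozen=True)
class ConcordanceTable:
    """Category counts plus the per-layer mismatch distribution of one pair."""

    counts: Mapping[ConcordanceCategory, int]
    layer_distribution: Mapping[str, int]
    pair: tuple[str, str]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def mismatched_for_pair(self) -> int:
        """Number of triplets in which the table's pair differs."""
        a, b = self.pair
        out = self.counts.get(ConcordanceCategory.ALL_DIFFER, 0)
        for cat, both in (
            (ConcordanceCategory.PM5_PM7_NOT_NCI, {"PM5", "PM7"}),
            (ConcordanceCategory.PM7_NCI_NOT_PM5, {"PM7", "NCI"}),
            (ConcordanceCategory.PM5_NCI_NOT_PM7, {"PM5", "NCI"}),
        ):
            if {a, b} != both:  # the pair equal in this category ≠ our pair ⇒ ours differs
                out += self.counts.get(cat, 0)
        return out


def tabulate(
    results: Sequence[TripletResult], pair: tuple[str, str] = ("PM7", "NCI")
) -> ConcordanceTable:
    """Aggregate triplet results into category counts and, for the requested
    pair (default PM7 vs NCI), a per-layer histogram over the triplets in
    which that pair differs."""
    key = tuple(sorted(pair))
    if key not in {tuple(sorted(p)) for p in PAIRS}:
        raise CMLValidationError(f"unknown provenance pair {pair!r}")
    counts = Counter(r.category for r in results)
    layers: Counter[str] = Counter()
    for r in results:
        labels = r.divergent.get(key)  # PAIRS keys are already sorted tuples
        if labels:
            layers.update(labels)
    return ConcordanceTable(
        counts={cat: counts.get(cat, 0) for cat in ConcordanceCategory},
        layer_distribution={lab: layers[lab] for lab in LAYER_LABELS if layers[lab]},
        pair=(key[0], key[1]),
    )


def all_match_fraction(counts: Mapping[ConcordanceCategory, int]) -> float:
    """Fraction of triplets whose three identifiers all agree."""
    total = sum(counts.values())
    if total == 0:
        raise CMLValidationError("no triplets to summarize")
    return counts.get(ConcordanceCategory.ALL_MATCH, 0) / total


def pm7_vs_nci_mismatches(counts: Mapping[ConcordanceCategory, int]) -> int:
    """Triplets whose PM7 and NCI identifiers differ: the sum of the three
    categories in which that pair is unequal."""
    return (
        counts.get(ConcordanceCategory.PM5_PM7_NOT_NCI, 0)
        + counts.get(ConcordanceCategory.PM5_NCI_NOT_PM7, 0)
        + counts.get(ConcordanceCategory.ALL_DIFFER, 0)
    )


# ---------------------------------------------------------------------------
# simple delimited I/O


def read_triplets_tsv(text: str) -> list[tuple[int, str, str, str]]:
    """Parse `nsc_id<TAB>inchi_nci<TAB>inchi_pm5<TAB>inchi_pm7` rows
    (header row optional, `#` comments ignored)."""
    rows: list[tuple[int, str, str, str]] = []
    for k, ln in enumerate(text.splitlines()):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 4:
            raise CMLValidationError(f"triplet line {k + 1}: expected 4 tab-separated fields")
        if k == 0 and not parts[0].isdigit():
            continue  # header
        rows.append((int(parts[0]), parts[1], parts[2], parts[3]))
    return rows


def table_as_dict(table: ConcordanceTable) -> dict:
    """JSON-ready view of a concordance table."""
    return {
        "pair": list(table.pair),
        "counts": {cat.name: n for cat, n in table.counts.items()},
        "total": table.total,
        "layer_distribution": dict(table.layer_distribution),
    }
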