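"""Shared fixtures: printed-dialect documents, small records, and one
session-scoped synthetic corpus processed by the full pipeline."""

from __future__ import annotations

import math

import pytest

from molcurate.cml_records import Atom, MoleculeRecord
from molcurate.fixtures import InjectionSpec, generate_corpus
from molcurate.pipeline import RunConfig, run_pipeline

# The two charge dialects as they appear in the source collection: the
# legacy identifier element with a charge child, and the formalCharge
# attribute on the molecule element.
LEGACY_DIALECT_DOC = """\
<molecule xmlns="http://www.xml-cml.org/schema" id="NSC138467">
  <identifier version="0.932Beta" tautomeric="0">
    <basic>C13H21N2O,1H3-12H(2H3)15(13H(3H3)4H3)11(16)10-7H-6H-8H-14(5H3)9H-10</basic>
    <charge>+1</charge>
  </identifier>
  <atomArray>
    <atom id="a1" elementType="C" x3="0.0" y3="0.0" z3="0.0"/>
  </atomArray>
</molecule>
"""

ATTRIBUTE_DIALECT_DOC = """\
<molecule xmlns="http://www.xml-cml.org/schema" id="NSC138467" formalCharge="1" name="mol1">
  <atomArray>
    <atom id="a1" elementType="C" x3="0.0" y3="0.0" z3="0.0"/>
  </atomArray>
</molecule>
"""


@pytest.fixture
def water_record() -> MoleculeRecord:
    theta = math.radians(104.52)
    return MoleculeRecord(
        atoms=(
            Atom("O", (0.0, 0.0, 0.0)),
            Atom("H", (0.9572, 0.0, 0.0)),
            Atom("H", (0.9572 * math.cos(theta), 0.9572 * math.sin(theta), 0.0)),
        ),
        provenance="NCI",
        nsc_id=1,
        name="water",
    )


@pytest.fixture
def salt_record() -> MoleculeRecord:
    """Acetate fragment (7 atoms) plus a distant sodium counter-ion."""
    return MoleculeRecord(
        atoms=(
            Atom("C", (0.0, 0.0, 0.0)),
            Atom("C", (1.50, 0.0, 0.0)),
            Atom("O", (2.12, 1.05, 0.0)),
            Atom("O", (2.10, -1.10, 0.0)),
            Atom("H", (-0.40, 0.50, 0.87)),
            Atom("H", (-0.40, 0.50, -0.87)),
            Atom("H", (-0.40, -1.01, 0.0)),
            Atom("Na", (8.0, 0.0, 0.0)),
        ),
        provenance="NCI",
        nsc_id=2,
        name="sodium acetate",
        legacy_charge=-1,
    )


#: Conditions of the reference synthetic corpus: duplicate and unannotated
#: shares matching the source collection, all five charge-dialect cases, a
#: stated per-layer injection plan, counter-ion entries and implausible
#: charges.  The same spec (at n=200) backs the acceptance run.
def corpus_spec(n_entries: int, seed: int) -> InjectionSpec:
    return InjectionSpec(
        n_entries=n_entries,
        seed=seed,
        fraction_duplicates=0.035,
        fraction_unannotated=0.094,
        per_layer_mismatch_counts={
            "hydrogen": 4,
            "connectivity": 3,
            "charge": 2,
            "double_bond": 3,
            "tetrahedral": 3,
            "isotope": 2,
        },
        n_pm5_divergent=2,
        n_nci_divergent=3,
        n_all_differ=2,
        fraction_multicomponent=0.05,
        fraction_implausible_charge=0.01,
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run over a seeded n=200 corpus, shared by the
    end-to-end tests: (ground truth, run report, corpus dir, output dir)."""
    corpus = generate_corpus(corpus_spec(n_entries=200, seed=1))
    root = tmp_path_factory.mktemp("corpus200")
    corpus_dir = root / "corpus"
    out_dir = root / "out"
    corpus.write(corpus_dir)
    report = run_pipeline(RunConfig(input_dir=str(corpus_dir), output_dir=str(out_dir)))
    return corpus.ground_truth, report, corpus_dir, out_dir
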