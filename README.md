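# molcurate

Standards-based curation tooling for collections of computed molecular
structures — the kind of decade-old repository holding a hundred thousand
semi-empirically optimized geometries in two generations of Chemical Markup
Language (CML), which must be re-validated, re-computed and re-deposited
without losing a single declared charge along the way.

`molcurate` implements one full curation cycle:

1. **CML records** — parse and validate both historical dialects (the legacy
   `identifier` element with a `<charge>` child, and the `formalCharge`
   attribute on `molecule`), deduplicate a corpus by NSC accession, and
   exclude entries that never had a computed annotation.
2. **Charge/spin semantics** — reconcile the two charge declarations with
   explicit precedence, flag implausible net charges (|q| > 3), and compute
   the spin multiplicity (singlet for an even electron count, doublet for
   odd) so it can act as a checksum against silently dropped charges.
3. **MOPAC-style input decks** — fully explicit keyword lines
   (`CHARGE=<n>` always written, even `CHARGE=0`, plus exactly one spin
   token), geometries in internal coordinates (Z-matrix with
   nearest-neighbour references) or Cartesians, and output parsing for the
   final geometry. The external optimizer is a pluggable command; a mock is
   built in.
4. **Connectivity & InChI** — normalize every structure version to bare
   Cartesian XYZ (discarding any inherited bond data), re-perceive bonds
   with one covalent-radius rule (`d ≤ r(A)+r(B)+0.40 Å`), and generate
   standard InChI/InChIKey via the IUPAC reference implementation (through
   RDKit). InChIs are dissected into layers: formula, connectivity (`/c`),
   hydrogen (`/h`), charge (`/q`, `/p`), stereo (`/b`, `/t` with `m`/`s`),
   isotope (`/i`).
5. **Concordance** — classify each NCI/PM5/PM7 identifier triplet into the
   five equality categories and attribute every mismatched pair to *all* the
   layers in which it differs (one mismatch may diverge in several layers).
6. **Packaging & metadata** — per-molecule METS manifests (MD5, size, and
   chemical media type per file), OAI-ORE resource maps, SWORD
   (METSDSpaceSIP) bundles, and a DataCite kernel-3 crosswalk with
   `HasMetadata` related identifiers, chemical alternate identifiers and
   ORCID name identifiers, plus the two machine-actionable retrieval URL
   forms (`?locatt=mimetype:` and the content-resolver path).
7. **Fixtures & pipeline** — a seeded synthetic-corpus generator with
   recorded ground truth (duplicates, missing annotations, charge-dialect
   cases, counter-ion components, per-layer InChI mismatches), and a
   pipeline that runs the whole chain with per-entry fault isolation.

## Worked example

Parse the attribute-dialect record of an ammonium cation, reconcile its
charge and build an optimizer input deck:

```python
from molcurate import parse_cml, reconcile_charge, build_input
from molcurate.mopac_io import format_input

record = parse_cml(open("nsc138467_post-mopac.cml").read())
charge = reconcile_charge(record)
print(charge.value, charge.source.value, charge.conflict)
# 1 FORMAL_ATTR False
print(format_input(build_input(record, charge)))
```

```
PM7 CHARGE=1 SINGLET
mol1
geometry provenance: NCI
N      0.0000 0       0.00 0       0.00 0    0    0    0
H      1.0200 1       0.00 0       0.00 0    1    0    0
H      1.0218 1     110.03 1       0.00 0    1    2    0
H      1.0207 1     108.93 1     -59.28 1    1    3    2
H      1.0207 1     108.82 1      61.37 1    1    4    3
```

The keyword line is fully explicit: `CHARGE=1` because the record declares
+1, and `SINGLET` because NH₄⁺ has 10 electrons — if the charge had been
silently dropped, the optimizer's own electron count would contradict the
declared singlet and abort instead of quietly computing the wrong species.

Normalize a geometry to XYZ and compare identifiers layer by layer:

```python
from molcurate import generate_inchi, parse_layers

inchi, key = generate_inchi(open("water.xyz").read())
# ('InChI=1S/H2O/h1H2', 'XLYOFNOQVPJJNP-UHFFFAOYSA-N')

layers = parse_layers("InChI=1S/C4H12N/c1-5(2,3)4/h1-4H3/q+1")
layers.formula, layers.connectivity, layers.charge
# ('C4H12N', '1-5(2,3)4', '+1')
```

A shell interface wraps the same functions:

```sh
molcurate validate entry.cml --schema cml24
molcurate fixtures --n-entries 50 --seed 7 -o corpus/
molcurate run --input corpus/ --output out/
molcurate query --field alternateIdentifier --value 'NCI:' --wildcard --prefix 10.14469
```

`molcurate run` prints a corpus summary: entries read, duplicates removed,
entries excluded for missing annotations, the charge histogram with
conflict/implausibility flags, the five-category concordance table with its
per-layer mismatch histogram, and the number of bundles packaged.

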