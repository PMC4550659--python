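# Methods

## The curation model

`molcurate` models one incremental curation cycle over a repository of
computed molecular structures. Each molecule exists in three versions: the
original database geometry (provenance tag `NCI`), a first-generation
semi-empirical optimization (`PM5`), and a re-optimization with the current
method (`PM7`). The cycle is retrieval bookkeeping (deduplication by NSC
accession, exclusion of entries that never had a calculation), technical
validation (schema conformance, charge/spin reconciliation, regeneration of
explicit optimizer inputs), identifier concordance across the three
versions, and re-deposition (METS/ORE/SWORD packaging with
DataCite-crosswalked metadata).

The central design commitment is the elimination of *implicit semantics*:
any value a downstream program would silently default — the net charge, the
spin state, the bond connectivity — is computed and written explicitly, and
absence is modelled as a distinct state (`None`), never as zero.

## Charge and spin

Two historical charge dialects coexist: a legacy `identifier` element with
a `<charge>` child, and a `formalCharge` attribute on `molecule`.
Reconciliation precedence is attribute > legacy > explicit default zero;
disagreement sets a `conflict` flag and keeps the attribute value, because
corpus curation annotates and proceeds rather than aborting. Declared
charges with |q| > 3 are flagged implausible (corpus inspection showed such
declarations to be curation errors, typically misread metal centres); the
bound is configurable with 3 as default. The spin multiplicity is derived
from the electron count (Σ atomic number − net charge): even → `SINGLET`,
odd → `DOUBLET`. Higher multiplicities are out of scope — the corpus is
closed-shell organic molecules — and the derived spin token doubles as a
checksum: a deck declaring `SINGLET` for a species whose
electron count at the declared charge is odd is an inconsistency the
optimizer itself would also trap.

## Input decks and internal coordinates

Every generated deck carries the method token, `CHARGE=<n>` (always,
including `CHARGE=0`) and exactly one spin token; the placeholder keyword
line a naive format conversion can leave behind is rejected at
construction. Geometry defaults to a Z-matrix. Reference selection per row:
r1 = nearest previously defined atom, r2 = nearest other, r3 = nearest that
keeps (r1, r2, r3) non-collinear, falling back to the least collinear
candidate — nearest-neighbour references are numerically stable, and the
choice does not affect the optimized result. Reconstruction uses standard
NeRF placement; the conversion round trip preserves pairwise distances to
~1e−13 Å (the contract is < 1e−4 Å, matching the deck's number format:
distances to 4 decimals, angles to 2). Fully collinear ≥4-atom chains would
need dummy atoms and are rejected; none occur in the fixture library.
The external optimizer is a command template; the built-in mock returns the
input geometry unchanged with a normal-termination marker, so the whole
pipeline runs without licensed software.

## Bond perception and InChI generation

All structure versions are reduced to bare Cartesian XYZ — inherited
connection tables are deliberately discarded — so that identifiers from
different versions are normalized against a single connectivity algorithm.
Bonds: `floor < d(i,j) ≤ r(el_i) + r(el_j) + tolerance`, with single-bond
covalent radii (Cordero et al. 2008) shipped as a versioned JSON data file,
tolerance 0.40 Å, and a 0.40 Å lower floor below which a pair is treated as
corrupt coordinates. There is no formal standard for these thresholds;
they are explicit, documented configuration, and bit-identical replication
of any particular legacy converter's edge cases is not claimed.

Bond orders and stereo are perceived from the distance-derived graph and
the 3-D coordinates, and the canonical identifier is produced by the IUPAC
reference InChI library, both via RDKit; re-implementing InChI is a
non-goal. Two pieces of information the XYZ dialect cannot carry travel
alongside the coordinates: the declared net charge and per-atom mass
numbers. The perception step assumes closed-shell species (a declared
charge inconsistent with a closed-shell electron count fails identifier
generation and is reported per entry); for identifier purposes an
implausible declared charge falls back to neutral, with the flag retained.
Canonical atom order for XYZ output is element-alphabetical then original
index — cosmetic, since InChI canonicalization is order-invariant (tested),
but it gives deterministic diffs.

## Layer dissection and concordance

An InChI is dissected into delimiter-prefixed segments preserved verbatim,
so `serialize(parse(s)) == s` byte for byte. Comparison labels: formula,
connectivity (`c`), hydrogen (`h`), charge (`q`), protonation (`p`),
double_bond (`b`), tetrahedral (`t` with its `m`/`s` sublayers), isotope
(`i` and everything after it). Stereo is two labels because double-bond and
tetrahedral mismatches are tallied separately.

Triplet classification uses whole-string equality, yielding exactly one of
five categories (all match; PM5=PM7≠NCI; PM7=NCI≠PM5; PM5=NCI≠PM7; all
differ) — layer attribution is a separate diagnostic pass, not
layer-by-layer equality with reassembly. Every unequal pair is attributed
to *all* layers in which it differs, with an absent layer a comparable
state. This all-layers reading is the only arithmetically consistent one:
per-layer tallies may legitimately sum to more than the number of
mismatched pairs (a hydrogen-count change, for instance, moves both the
formula and the hydrogen layer). The default histogram pair is PM7 vs NCI.

## Packaging and metadata profiles

Bundle files carry size, lowercase-hex MD5 and a media type from a
registered table (`chemical/x-cml` for structure XML, MOPAC input/output
types, `application/octet-stream` fallback with a warning). MD5 is retained
deliberately for fidelity to the target repository profile; `CHECKSUMTYPE`
is always recorded so a future curation can migrate digests. METS, DIM,
xlink, CML 2.4 and DataCite kernel-3 are validated against subset XSD
profiles authored in this package (`src/molcurate/schemas/`): they cover
exactly the elements the toolkit emits, which keeps validation offline and
the profiles reviewable; they are not the full official schemas. The
DataCite writer targets kernel-3 because the `HasMetadata` relation type —
the mechanism that makes the METS/ORE manifest locations machine-
discoverable — first appears in schema 3.0. Handle and DOI syntax is
validated; resolution is never attempted at build time, and the SWORD
deposit adapter is dry-run by default (`X-No-Op: true`), describing the
request (including the `X-Packaging: …/METSDSpaceSIP` header) without
touching the network.

## The synthetic corpus

The fixtures module generates per-entry document sets shaped like the real
collection: a legacy-dialect original, an attribute-dialect computed
annotation, and a third re-optimized geometry. Default proportions emulate
the collection's reported composition: ~0.5 % duplicate accessions, ~9.4 %
of entries without a computed annotation, a charge distribution dominated
by neutral species, rare implausible declarations (~1 %), and a small share
of two-component salt entries (5 %, counter-ion parked outside bonding
range). Charged species always declare their charge in at least one dialect
(a charged geometry with no declaration could not be processed by anything
downstream). Geometries come from seeded RDKit ETKDG embedding of a
built-in table of small organic structures; re-optimization is emulated by
benign random displacements (≤ 0.02 Å, connectivity-preserving).

Per-layer mismatch injections are deterministic structure edits with
frozen, test-verified layer signatures: hydrogen → cyclohexane/cyclohexene
swap ({formula, hydrogen}; the two share a `c` layer), connectivity →
cyclohexene/methylenecyclopentane swap ({connectivity, hydrogen}), charge →
allyl anion re-declared as the cation ({charge}; both are even-electron, a
one-electron flip on a fixed closed-shell geometry is impossible),
double_bond → trans/cis-2-butene swap, tetrahedral → geometric mirror of
L-alanine, isotope → a ¹³C mass label. The generator records the intended
category and layer set per entry; the pipeline must recover every tally
exactly.

What the generator does **not** emulate: the real NCI structure
distribution, any quantum-chemical physics of re-optimization, borderline
bond-distance drift (the connectivity injection is a constitutional-isomer
stand-in), radicals, or metal complexes. Passing the recovery tests
demonstrates that the bookkeeping, normalization and comparison machinery
is exact on known inputs — not that the covalent-radius rule reproduces any
particular legacy converter on real borderline geometries.

## Problem sizes and numerics

The test suite and the acceptance script use a 200-entry corpus (seeded; 7
duplicates, 18 unannotated, 17 PM7-side injections plus 7 other-category
injections at the stated counts), 50 random 5–15-atom geometries for the
Z-matrix round trip, and ≥ 200 strings for the layer-grammar identity —
sizes chosen so the full chain (three InChI generations per entry, METS/
ORE/DataCite per entry) completes in seconds while every injected condition
appears several times. Tolerances: 1e−4 Å / 1e−2° for deck round trips
(set by the deck number format), 1e−6 Å coincidence threshold, sine < 1e−6
collinearity threshold.

## Known limitations

- Identifier generation requires closed-shell species; odd-electron
  molecules are supported in the charge/spin/deck path only.
- Schema validation targets the authored subset profiles, not the full
  official XSDs; documents using elements outside the profiles are not
  covered.
- Legacy CML parsing is namespace-agnostic for reading but the writer
  always emits the CML namespace.
- The SWORD/DataCite network adapters are request builders; live deposit
  and DOI minting are out of scope.
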