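"""End-to-end curation run: ingest → validate → charge → optimize → normalize
→ InChI → concordance → package → crosswalk.

The run is corpus-shaped: one bad record never aborts the whole corpus —
per-entry failures are isolated and recorded in the run report, which
mirrors the curation bookkeeping (retrieval counts, charge distribution
and flags, the five-category concordance table with its per-layer
histogram, and the package manifest list).

Input layout: one directory per entry occurrence containing
``nsc<ID>_original.cml`` (original structure, legacy charge dialect),
optionally ``nsc<ID>_post-mopac.cml`` (computed annotation, attribute
dialect) and ``PM7.xml`` (re-optimized structure).  Entries without a
computed annotation are excluded, as in the original collection.  When
``PM7.xml`` is absent the configured optimizer (default: the built-in
mock) supplies the re-optimized geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from . import charge_semantics as cs
from . import cml_records as cml
from . import concordance as conc
from . import connectivity_inchi as ci
from . import datacite as dc
from . import mopac_io as mop
from . import packaging_mets as pm
from .errors import ConfigurationError, MolcurateError

CC0_URL = "https://creativecommons.org/publicdomain/zero/1.0/"


@dataclass(frozen=True)
class RunConfig:
    input_dir: str
    output_dir: str
    schema_profile: str = "cml24"
    radius_table: str | None = None
    tolerance: float = ci.DEFAULT_TOLERANCE
    optimizer_command: str = "mock"
    handle_prefix: str = "10042"
    doi_prefix: str = "10.14469"
    doi_suffix_template: str = "ch/{n}"
    repository_base: str = pm.DEFAULT_REPOSITORY_BASE
    publisher: str = "Imperial College London"
    publication_year: str = "2015"
    contributors: tuple[tuple[str, str], ...] = ()
    license_url: str = CC0_URL
    write_bundles: bool = True
    seed: int = 0  # only the fixtures module consumes randomness


@dataclass
class EntryStatus:
    seq: int
    dirname: str
    nsc_id: int | None
    status: str  # ok | duplicate | excluded_no_annotation | error
    message: str = ""
    category: str | None = None

    def as_dict(self) -> dict:
        return {
            "seq": self.seq,
            "dirname": self.dirname,
            "nsc_id": self.nsc_id,
            "status": self.status,
            "message": self.message,
            "category": self.category,
        }


@dataclass
class RunReport:
    corpus: cml.CorpusReport
    charge_histogram: dict[int, int]
    n_conflicts: int
    n_implausible: int
    concordance: dict
    entry_statuses: list[EntryStatus]
    deck_stats: dict
    bundles: list[dict]
    violations: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "corpus": {
                "total_read": self.corpus.total_read,
                "unique_kept": self.corpus.unique_kept,
                "duplicates_removed": self.corpus.duplicates_removed,
                "excluded_no_annotation": self.corpus.excluded_no_annotation,
            },
            "charge_histogram": {str(k): v for k, v in self.charge_histogram.items()},
            "n_conflicts": self.n_conflicts,
            "n_implausible": self.n_implausible,
            "concordance": self.concordance,
            "deck_stats": self.deck_stats,
            "bundles": self.bundles,
            "violations": self.violations,
            "entry_statuses": [s.as_dict() for s in self.entry_statuses],
        }

    def summary(self) -> str:
        c = self.corpus
        lines = [
            f"entries read:        {c.total_read}",
            f"unique kept:         {c.unique_kept}",
            f"duplicates removed:  {c.duplicates_removed}",
            f"excluded (no calc):  {c.excluded_no_annotation}",
            f"charge conflicts:    {self.n_conflicts}",
            f"implausible charges: {self.n_implausible}",
            "concordance: "
            + ", ".join(f"{k}={v}" for k, v in self.concordance["counts"].items()),
            "layer histogram (PM7 vs NCI): "
            + (
                ", ".join(f"{k}={v}" for k, v in self.concordance["layer_distribution"].items())
                or "(empty)"
            ),
            f"decks generated:     {self.deck_stats['n_decks']} "
            f"(explicit CHARGE+spin: {self.deck_stats['n_explicit']})",
            f"bundles packaged:    {len(self.bundles)}",
        ]
        return "\n".join(lines) + "\n"


def _scan_entry_dir(path: Path) -> dict[str, Path]:
    docs: dict[str, Path] = {}
    for f in sorted(path.iterdir()):
        if f.name.endswith("_original.cml"):
            docs["NCI"] = f
        elif f.name.endswith("_post-mopac.cml"):
            docs["PM5"] = f
        elif f.name == "PM7.xml":
            docs["PM7"] = f
    return docs


def _charge_for_record(rec: cml.MoleculeRecord, entry_charge: int) -> int:
    # only the formal attribute can override the entry-level reconciliation;
    # a record's legacy declaration already lost any conflict during
    # reconciliation and must not resurface here
    own = rec.formal_charge_attr
    return own if own is not None else entry_charge


def run_pipeline(config: RunConfig) -> RunReport:
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise ConfigurationError(f"input directory {config.input_dir!r} does not exist")
    entry_dirs = sorted(d for d in input_dir.iterdir() if d.is_dir())
    if not entry_dirs:
        raise ConfigurationError(f"input directory {config.input_dir!r} contains no entries")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    radii = ci.load_radii(config.radius_table) if config.radius_table else None
    profile = cml.CMLProfile(name=config.schema_profile)

    statuses: list[EntryStatus] = []
    parsed: list[tuple[int, Path, dict[str, Path], cml.MoleculeRecord]] = []
    for seq, d in enumerate(entry_dirs):
        docs = _scan_entry_dir(d)
        if "NCI" not in docs:
            statuses.append(EntryStatus(seq, d.name, None, "error", "no original CML document"))
            continue
        try:
            nci = cml.parse_cml(docs["NCI"].read_text())
        except MolcurateError as exc:
            statuses.append(EntryStatus(seq, d.name, None, "error", f"parse: {exc}"))
            continue
        parsed.append((seq, d, docs, nci))

    # deduplicate on the original records, first occurrence kept
    seen: set[int] = set()
    kept: list[tuple[int, Path, dict[str, Path], cml.MoleculeRecord]] = []
    n_dup = 0
    for seq, d, docs, nci in parsed:
        if nci.nsc_id is None:
            statuses.append(EntryStatus(seq, d.name, None, "error", "record lacks NSC accession"))
            continue
        if nci.nsc_id in seen:
            n_dup += 1
            statuses.append(EntryStatus(seq, d.name, nci.nsc_id, "duplicate"))
            continue
        seen.add(nci.nsc_id)
        kept.append((seq, d, docs, nci))

    # exclude entries with no computed annotation
    annotated: list[tuple[int, Path, dict[str, Path], cml.MoleculeRecord, cml.MoleculeRecord]] = []
    n_excluded = 0
    for seq, d, docs, nci in kept:
        if "PM5" not in docs:
            n_excluded += 1
            statuses.append(EntryStatus(seq, d.name, nci.nsc_id, "excluded_no_annotation"))
            continue
        try:
            pm5 = cml.parse_cml(docs["PM5"].read_text())
        except MolcurateError as exc:
            statuses.append(EntryStatus(seq, d.name, nci.nsc_id, "error", f"parse: {exc}"))
            continue
        annotated.append((seq, d, docs, nci, pm5))

    charge_assignments: list[cs.ChargeAssignment] = []
    triplets: list[conc.TripletResult] = []
    violations: dict[str, int] = {}
    deck_stats = {"n_decks": 0, "n_explicit": 0, "n_placeholder": 0, "n_doublet": 0}
    bundles_out: list[dict] = []

    for seq, d, docs, nci, pm5 in annotated:
        try:
            # schema validation is annotate-and-continue
            n_viol = 0
            for prov in ("NCI", "PM5", "PM7"):
                if prov in docs:
                    n_viol += len(cml.validate_cml(docs[prov].read_text(), profile))
            if n_viol:
                violations[d.name] = n_viol

            # reconcile the two dialects: attribute (computed doc) over legacy
            merged = replace(pm5, legacy_charge=nci.legacy_charge)
            charge = cs.reconcile_charge(merged)
            charge_assignments.append(charge)

            # strip counter-ion components from the original structure
            graph = ci.perceive_connectivity(nci.atoms, radii=radii, tolerance=config.tolerance)
            nci_core, _removal = cml.select_largest_component(nci, graph)

            # explicit input deck; the mock (or configured) optimizer supplies
            # the re-optimized geometry when no PM7 document is present
            deck = mop.build_input(pm5, charge, method="PM7", coords_mode="internal")
            deck_text = mop.format_input(deck)
            deck_stats["n_decks"] += 1
            line = " ".join(deck.keywords)
            if any(k.startswith("CHARGE=") for k in deck.keywords) and any(
                k in ("SINGLET", "DOUBLET") for k in deck.keywords
            ):
                deck_stats["n_explicit"] += 1
            if mop.PLACEHOLDER_KEYWORDS in line.upper():
                deck_stats["n_placeholder"] += 1
            if "DOUBLET" in deck.keywords:
                deck_stats["n_doublet"] += 1

            out_text = mop.run_optimizer(deck, config.optimizer_command, entry_name=d.name)
            if "PM7" in docs:
                pm7 = cml.parse_cml(docs["PM7"].read_text())
            else:
                atoms, _props, term = mop.parse_output(out_text)
                if term is not mop.Termination.NORMAL:
                    raise MolcurateError("optimizer reported error termination")
                pm7 = cml.MoleculeRecord(
                    atoms=atoms,
                    provenance="PM7",
                    nsc_id=nci.nsc_id,
                    name=nci.name,
                    formal_charge_attr=charge.value,
                )

            # one normalization path for all three versions; an implausible
            # declared charge falls back to neutral for identifier purposes
            inchis: dict[str, str] = {}
            keys: dict[str, str] = {}
            for prov, rec in (("NCI", nci_core), ("PM5", pm5), ("PM7", pm7)):
                q = _charge_for_record(rec, charge.value)
                if abs(q) > cs.PLAUSIBLE_ABS_CHARGE:
                    q = 0
                inchis[prov], keys[prov] = ci.generate_inchi_for_record(
                    rec, charge=q, radii=radii, tolerance=config.tolerance
                )
            result = conc.analyze_triplet(nci.nsc_id, inchis["NCI"], inchis["PM5"], inchis["PM7"])
            triplets.append(result)

            # package the entry
            n = 150000 + seq
            handle = f"{config.handle_prefix}/{n}"
            doi = f"{config.doi_prefix}/{config.doi_suffix_template.format(n=n)}"
            metadata = pm.EntryMetadata(
                name=nci.name or f"NSC{nci.nsc_id}",
                nsc_id=nci.nsc_id,
                cas_id=nci.cas_id,
                inchi=inchis["PM7"],
                inchikey=keys["PM7"],
                smiles=nci.smiles,
                article_doi="https://doi.org/10.1039/b411033a",
                contributors=config.contributors,
                license_url=config.license_url,
            )
            conflated = cml.write_cml([nci, pm5, pm7], profile="conflated")
            payloads = [
                (f"nsc{nci.nsc_id}_original.cml", docs["NCI"].read_text().encode()),
                (f"nsc{nci.nsc_id}_post-mopac.cml", docs["PM5"].read_text().encode()),
                (f"nsc{nci.nsc_id}_conflated.cml", conflated.encode()),
                ("PM7.xml", cml.write_cml(pm7).encode()),
                (f"nsc{nci.nsc_id}.mop", deck_text.encode()),
                (f"nsc{nci.nsc_id}.out", out_text.encode()),
            ]
            files = tuple(
                pm.BundleFile.from_payload(name, payload, sequence=k + 1)
                for k, (name, payload) in enumerate(payloads)
            )
            bundle = pm.EntryBundle(handle=handle, doi=doi, metadata=metadata, files=files)
            mets_text = pm.build_mets(bundle)
            ore_text = pm.build_ore_map(bundle, base=config.repository_base)
            record = dc.crosswalk(
                metadata,
                bundle,
                (
                    pm.manifest_url(handle, "mets", config.repository_base),
                    pm.manifest_url(handle, "ore", config.repository_base),
                ),
                publisher=config.publisher,
                publication_year=config.publication_year,
            )
            record = dc.register_media(
                record, "chemical/x-cml", dc.build_media_url(doi, "chemical/x-cml")
            )
            datacite_xml = dc.to_datacite_xml(record)

            if config.write_bundles:
                bdir = out_dir / "bundles" / d.name
                bdir.mkdir(parents=True, exist_ok=True)
                for name, payload in payloads:
                    (bdir / name).write_bytes(payload)
                (bdir / "mets.xml").write_text(mets_text)
                (bdir / "ore.xml").write_text(ore_text)
                (bdir / "datacite.xml").write_text(datacite_xml)

            bundles_out.append(
                {"dirname": d.name, "handle": handle, "doi": doi, "n_files": len(files)}
            )
            statuses.append(
                EntryStatus(seq, d.name, nci.nsc_id, "ok", category=result.category.name)
            )
        except MolcurateError as exc:
            statuses.append(EntryStatus(seq, d.name, nci.nsc_id, "error", str(exc)))

    table = conc.tabulate(triplets, pair=("PM7", "NCI"))
    # entries whose documents failed to parse count toward unique_kept (they
    # were read once and are neither duplicates nor unannotated); their
    # failure is visible in the per-entry statuses
    report = RunReport(
        corpus=cml.CorpusReport(
            total_read=len(entry_dirs),
            unique_kept=len(entry_dirs) - n_dup - n_excluded,
            duplicates_removed=n_dup,
            excluded_no_annotation=n_excluded,
        ),
        charge_histogram=cs.charge_histogram(charge_assignments),
        n_conflicts=sum(1 for a in charge_assignments if a.conflict),
        n_implausible=sum(1 for a in charge_assignments if not a.plausible),
        concordance=conc.table_as_dict(table),
        entry_statuses=sorted(statuses, key=lambda s: s.seq),
        deck_stats=deck_stats,
        bundles=bundles_out,
        violations=violations,
    )
    (out_dir / "report.json").write_text(json.dumps(report.as_dict(), indent=2))
    (out_dir / "summary.txt").write_text(report.summary())
    return report


def recuration_export(
    bundles: Sequence[pm.EntryBundle],
    collection_handle: str = "10042/31118",
    base: str = pm.DEFAULT_REPOSITORY_BASE,
    no_op: bool = True,
) -> list[dict]:
    """Manifest of the programmatic re-curation recipe, one action per entry:
    the METS/ORE manifest retrieval URLs plus the shape of the SWORD deposit
    request (METSDSpaceSIP packaging header).  Dry-run by default — nothing
    here touches the network."""
    actions: list[dict] = []
    for bundle in bundles:
        deposit = pm.sword_deposit_action(collection_handle, base=base, no_op=no_op)
        actions.append(
            {
                "handle": bundle.handle,
                "doi": bundle.doi,
                "mets_url": pm.manifest_url(bundle.handle, "mets", base),
                "ore_url": pm.manifest_url(bundle.handle, "ore", base),
                "deposit": {"url": deposit.url, "headers": deposit.header_dict()},
            }
        )
    return actions
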