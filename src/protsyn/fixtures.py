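"""Seeded synthetic fixtures in all three source XML dialects.

The generator emits small, mutually cross-referencing files — UniProtKB
entry XML, PSI-MI 2.5 interactor XML and Entrezgene XML — together with
machine-readable ground truth, so every pipeline stage is testable with
no download.  It emulates the structure of real synonym data at desk
scale: per-entity synonym lists that overlap partially across sources,
case variation between databases, identifier cross-references into
UniProt, records without any link, and planted cross-species name
collisions (the same name reused by entities of different species, the
situation the taxonomy-consistency filter exists to catch).

The emitted XML uses the minimal element subset the readers interpret;
this is the supported dialect subset, documented here.  Species ids are
drawn from a small fixed pool including 9606, extended with synthetic
ids ≥ 10⁶ to avoid accidental real-taxon semantics.  The same seed
yields byte-identical files.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

from lxml import etree

from .alignment import CrossRefLink, LinkKind, normalize_name
from .readers import Source, SourceRecord, TaggedValue, XRef

__all__ = ["FixtureSpec", "GroundTruth", "generate", "table1_fixture", "write_xml_files"]

_REAL_SPECIES = (9606, 10090, 7227, 10116, 4932)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture.

    Defaults describe a small but structurally complete corpus: a handful
    of entities over three species, half the synonyms shared across
    sources, a quarter of the entities unlinked, and two planted
    cross-species collisions.
    """

    n_entities: int = 8
    n_species: int = 3
    synonyms_per_entity: tuple[int, int] = (2, 5)
    overlap_fraction: float = 0.5
    cross_species_collision_count: int = 2
    unlinked_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entities < 0:
            raise ValueError("n_entities must be non-negative")
        if self.n_entities > 0 and self.n_species < 1:
            raise ValueError("n_species must be at least 1 when entities are generated")
        lo, hi = self.synonyms_per_entity
        if lo < 0 or hi < lo:
            raise ValueError("synonyms_per_entity must be a non-decreasing non-negative range")
        for name in ("overlap_fraction", "unlinked_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cross_species_collision_count < 0:
            raise ValueError("cross_species_collision_count must be non-negative")
        if self.cross_species_collision_count > 0 and (self.n_entities < 2 or self.n_species < 2):
            raise ValueError("cross-species collisions need at least 2 entities and 2 species")


def _species_pool(n: int) -> list[int]:
    pool = list(_REAL_SPECIES[:n])
    while len(pool) < n:
        pool.append(1_000_001 + len(pool) - len(_REAL_SPECIES))
    return pool


def _record_dict(record: SourceRecord) -> dict:
    return {
        "source": record.source.value,
        "native_id": record.native_id,
        "primary_name": record.primary_name,
        "alt_names": list(record.alt_names),
        "synonyms": list(record.synonyms),
        "tax_id": record.tax_id,
        "xrefs": [[x.target_db, x.target_id] for x in record.xrefs],
    }


@dataclass
class GroundTruth:
    """What the generator actually wrote, in pipeline-checkable form."""

    records: dict[Source, list[SourceRecord]]
    links: list[CrossRefLink]
    n_mappings_kept: int
    n_mappings_ignored: int
    entities: list[dict]  # hub_accession, primary_name, tax_id, synonyms_normalized, gene_ids, unlinked
    stats: dict

    def record_dicts(self) -> dict[str, list[dict]]:
        return {s.value: [_record_dict(r) for r in recs] for s, recs in self.records.items()}

    def to_dict(self) -> dict:
        return {
            "records": self.record_dicts(),
            "links": [
                {
                    "from_source": l.from_source.value,
                    "from_id": l.from_id,
                    "hub_accession": l.hub_accession,
                    "link_kind": l.link_kind.value,
                }
                for l in self.links
            ],
            "n_mappings_kept": self.n_mappings_kept,
            "n_mappings_ignored": self.n_mappings_ignored,
            "entities": self.entities,
            "stats": self.stats,
        }

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# record builders (assemble SourceRecord exactly as the readers would)


def _dedup(values: Sequence[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for v in values:
        if v and v not in seen:
            seen[v] = None
    return tuple(seen)


def build_uniprot_record(
    accession: str,
    tax_id: int | None,
    recommended_name: str | None = None,
    primary_gene_name: str | None = None,
    gene_synonyms: Sequence[str] = (),
    alt_names: Sequence[str] = (),
    gene_id: str | None = None,
) -> SourceRecord:
    tagged: list[TaggedValue] = []
    if recommended_name:
        tagged.append(TaggedValue("recommendedName", recommended_name))
    for name in alt_names:
        tagged.append(TaggedValue("alternativeName", name))
    if primary_gene_name:
        tagged.append(TaggedValue("PrimaryName", primary_gene_name))
    for name in gene_synonyms:
        tagged.append(TaggedValue("synonymName", name))
    names = [tv.value for tv in tagged]
    if tax_id is not None:
        tagged.append(TaggedValue("NCBI TaxonomyId", str(tax_id)))
    xrefs = (XRef("GeneID", gene_id),) if gene_id else ()
    return SourceRecord(
        source=Source.UNIPROT,
        native_id=accession,
        primary_name=recommended_name,
        alt_names=tuple(alt_names),
        synonyms=_dedup(names),
        tax_id=tax_id,
        xrefs=xrefs,
        tagged_values=tuple(tagged),
    )


def build_biogrid_record(
    interactor_id: str,
    tax_id: int | None,
    short_label: str | None,
    aliases: Sequence[str] = (),
    uniprot_accession: str | None = None,
) -> SourceRecord:
    tagged: list[TaggedValue] = []
    if short_label:
        tagged.append(TaggedValue("shortLabel", short_label))
    for alias in aliases:
        tagged.append(TaggedValue("alias", alias))
    if tax_id is not None:
        tagged.append(TaggedValue("ncbiTaxId", str(tax_id)))
    xrefs: list[XRef] = [XRef("BIOGRID", interactor_id)]
    if uniprot_accession:
        xrefs.append(XRef("uniprot/swiss-prot", uniprot_accession))
    return SourceRecord(
        source=Source.BIOGRID,
        native_id=interactor_id,
        primary_name=short_label,
        alt_names=(),
        synonyms=_dedup([short_label or "", *aliases]),
        tax_id=tax_id,
        xrefs=tuple(xrefs),
        tagged_values=tuple(tagged),
    )


def build_ncbigene_record(
    gene_id: str,
    tax_id: int | None,
    symbol: str | None,
    synonyms: Sequence[str] = (),
    uniprot_accession: str | None = None,
) -> SourceRecord:
    tagged: list[TaggedValue] = []
    if symbol:
        tagged.append(TaggedValue("Symbol", symbol))
    for s in synonyms:
        tagged.append(TaggedValue("Synonym", s))
    if tax_id is not None:
        tagged.append(TaggedValue("taxId", str(tax_id)))
    xrefs = (XRef("UniProt", uniprot_accession),) if uniprot_accession else ()
    return SourceRecord(
        source=Source.NCBIGENE,
        native_id=gene_id,
        primary_name=symbol,
        alt_names=(),
        synonyms=_dedup([symbol or "", *synonyms]),
        tax_id=tax_id,
        xrefs=tuple(xrefs),
        tagged_values=tuple(tagged),
    )


# ---------------------------------------------------------------------------
# XML writers (minimal dialect subset)


def _uniprot_xml(records: Sequence[SourceRecord]) -> bytes:
    root = etree.Element("uniprot")
    for record in records:
        entry = etree.SubElement(root, "entry")
        etree.SubElement(entry, "accession").text = record.native_id
        protein = etree.SubElement(entry, "protein")
        gene_names: list[tuple[str, str]] = []
        for tv in record.tagged_values:
            if tv.tag == "recommendedName":
                rec = etree.SubElement(protein, "recommendedName")
                etree.SubElement(rec, "fullName").text = tv.value
            elif tv.tag == "alternativeName":
                alt = etree.SubElement(protein, "alternativeName")
                etree.SubElement(alt, "fullName").text = tv.value
            elif tv.tag == "PrimaryName":
                gene_names.append(("primary", tv.value))
            elif tv.tag == "synonymName":
                gene_names.append(("synonym", tv.value))
        if gene_names:
            gene = etree.SubElement(entry, "gene")
            for kind, value in gene_names:
                name = etree.SubElement(gene, "name", type=kind)
                name.text = value
        if record.tax_id is not None:
            organism = etree.SubElement(entry, "organism")
            etree.SubElement(
                organism, "dbReference", type="NCBI Taxonomy", id=str(record.tax_id)
            )
        for xref in record.xrefs:
            etree.SubElement(entry, "dbReference", type=xref.target_db, id=xref.target_id)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _biogrid_xml(records: Sequence[SourceRecord]) -> bytes:
    root = etree.Element("entrySet", level="2", version="5")
    entry = etree.SubElement(root, "entry")
    interactor_list = etree.SubElement(entry, "interactorList")
    for record in records:
        interactor = etree.SubElement(interactor_list, "interactor", id=record.native_id)
        names = etree.SubElement(interactor, "names")
        for tv in record.tagged_values:
            if tv.tag == "shortLabel":
                etree.SubElement(names, "shortLabel").text = tv.value
            elif tv.tag == "alias":
                etree.SubElement(names, "alias", type="synonym").text = tv.value
        if record.xrefs:
            xref = etree.SubElement(interactor, "xref")
            for i, ref in enumerate(record.xrefs):
                kind = "primaryRef" if i == 0 else "secondaryRef"
                etree.SubElement(xref, kind, db=ref.target_db, id=ref.target_id)
        if record.tax_id is not None:
            etree.SubElement(interactor, "organism", ncbiTaxId=str(record.tax_id))
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _ncbigene_xml(records: Sequence[SourceRecord]) -> bytes:
    root = etree.Element("Entrezgene-Set")
    for record in records:
        gene = etree.SubElement(root, "Entrezgene")
        etree.SubElement(gene, "GeneID").text = record.native_id
        raw_synonyms: list[str] = []
        for tv in record.tagged_values:
            if tv.tag == "Symbol":
                etree.SubElement(gene, "Symbol").text = tv.value
            elif tv.tag == "Synonym":
                raw_synonyms.append(tv.value)
        etree.SubElement(gene, "Synonyms").text = "; ".join(raw_synonyms)
        if record.tax_id is not None:
            etree.SubElement(gene, "TaxID").text = str(record.tax_id)
        if record.xrefs:
            dbxrefs = etree.SubElement(gene, "dbXrefs")
            for ref in record.xrefs:
                etree.SubElement(dbxrefs, "dbXref", db=ref.target_db, id=ref.target_id)
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def write_xml_files(
    records: Mapping[Source, Sequence[SourceRecord]], out_dir: Union[str, Path]
) -> dict[Source, Path]:
    """Write one XML file per dialect; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        Source.UNIPROT: out_dir / "uniprot.xml",
        Source.BIOGRID: out_dir / "biogrid.xml",
        Source.NCBIGENE: out_dir / "ncbigene.xml",
    }
    paths[Source.UNIPROT].write_bytes(_uniprot_xml(records.get(Source.UNIPROT, ())))
    paths[Source.BIOGRID].write_bytes(_biogrid_xml(records.get(Source.BIOGRID, ())))
    paths[Source.NCBIGENE].write_bytes(_ncbigene_xml(records.get(Source.NCBIGENE, ())))
    return paths


# ---------------------------------------------------------------------------
# ground-truth bookkeeping (brute-force, independent of the pipeline)


def _brute_force_mapping_counts(
    records: Mapping[Source, Sequence[SourceRecord]],
) -> tuple[int, int]:
    """Nested-loop enumeration of candidate name mappings and their fate."""
    all_records = [r for source in records for r in records[source]]
    kept = ignored = 0
    for i, a in enumerate(all_records):
        names_a = {normalize_name(s) for s in a.synonyms}
        for b in all_records[i + 1 :]:
            if a.source is b.source:
                continue
            shared = names_a & {normalize_name(s) for s in b.synonyms}
            for _name in shared:
                if a.tax_id is not None and b.tax_id is not None and a.tax_id == b.tax_id:
                    kept += 1
                else:
                    ignored += 1
    return kept, ignored


def _ground_truth(
    records: dict[Source, list[SourceRecord]],
    links: list[CrossRefLink],
    entity_groups: list[dict],
) -> GroundTruth:
    kept, ignored = _brute_force_mapping_counts(records)
    entities = sorted(entity_groups, key=lambda e: e["hub_accession"])
    stats = {
        "n_entities": len(entities),
        "n_species": len({e["tax_id"] for e in entities if e["tax_id"] is not None}),
        "n_terms": sum(len(e["synonyms_normalized"]) for e in entities),
        "n_mappings_kept": kept,
        "n_mappings_ignored": ignored,
    }
    return GroundTruth(records, links, kept, ignored, entities, stats)


def _entity_dict(
    hub: str,
    primary_name: str | None,
    tax_id: int | None,
    member_records: Sequence[SourceRecord],
    gene_ids: Sequence[str],
    unlinked: bool,
) -> dict:
    normalized = sorted(
        {normalize_name(s) for record in member_records for s in record.synonyms}
    )
    return {
        "hub_accession": hub,
        "primary_name": primary_name,
        "tax_id": tax_id,
        "synonyms_normalized": normalized,
        "gene_ids": sorted(set(gene_ids)),
        "unlinked": unlinked,
    }


# ---------------------------------------------------------------------------
# generation


def _vary_case(rng: random.Random, token: str) -> str:
    return rng.choice((token, token.lower(), token.capitalize(), token.upper()))


def generate(spec: FixtureSpec, out_dir: Union[str, Path, None]) -> GroundTruth:
    """Generate a three-dialect fixture corpus plus ground truth.

    Writes ``uniprot.xml``, ``biogrid.xml``, ``ncbigene.xml`` and
    ``ground_truth.json`` under ``out_dir`` (pass ``None`` to skip
    writing); deterministic per seed, byte-identical across runs.
    """
    rng = random.Random(spec.seed)
    species = _species_pool(spec.n_species) if spec.n_entities else []
    n_unlinked = int(spec.unlinked_fraction * spec.n_entities)
    unlinked_from = spec.n_entities - n_unlinked

    # plan per-entity name material first so collision planting can refer to it
    plans: list[dict] = []
    for i in range(spec.n_entities):
        base = "".join(rng.choices(string.ascii_uppercase, k=4)) + str(i)
        k = rng.randint(*spec.synonyms_per_entity)
        tokens = [f"{base}S{j}" for j in range(k)]
        n_shared = round(spec.overlap_fraction * k)
        plans.append(
            {
                "index": i,
                "base": base,
                "tax": species[i % spec.n_species],
                "shared": tokens[:n_shared],
                "rest": tokens[n_shared:],
                "linked": i < unlinked_from,
                "accession": f"ACC{i:04d}",
                "gene_id": str(1000 + i),
                "interactor_id": str(2000 + i),
                "extra_biogrid": [],
                "extra_ncbi": [],
            }
        )

    # plant cross-species collisions: one unique token shared by the BioGRID
    # record of one entity and the NCBI Gene record of a different-species
    # entity — exactly the mappings the taxonomy filter must ignore
    n = spec.n_entities
    for j in range(spec.cross_species_collision_count):
        a = j % n
        b = a
        for off in range(1, n):
            candidate = (a + off) % n
            if plans[candidate]["tax"] != plans[a]["tax"]:
                b = candidate
                break
        token = f"XSPC{j}C"
        plans[a]["extra_biogrid"].append(token)
        plans[b]["extra_ncbi"].append(token)

    records: dict[Source, list[SourceRecord]] = {
        Source.UNIPROT: [],
        Source.BIOGRID: [],
        Source.NCBIGENE: [],
    }
    links: list[CrossRefLink] = []
    entity_groups: list[dict] = []

    for plan in plans:
        shared, rest = plan["shared"], plan["rest"]
        # split the non-shared tokens round-robin over the three sources
        up_extra = [t for i, t in enumerate(rest) if i % 3 == 0]
        bg_extra = [t for i, t in enumerate(rest) if i % 3 == 1]
        nc_extra = [t for i, t in enumerate(rest) if i % 3 == 2]
        base = plan["base"]
        tax = plan["tax"]

        bg = build_biogrid_record(
            plan["interactor_id"],
            tax,
            short_label=_vary_case(rng, base),
            aliases=[_vary_case(rng, t) for t in shared + bg_extra] + plan["extra_biogrid"],
            uniprot_accession=plan["accession"] if plan["linked"] else None,
        )
        nc = build_ncbigene_record(
            plan["gene_id"],
            tax,
            symbol=_vary_case(rng, base),
            synonyms=[_vary_case(rng, t) for t in shared + nc_extra] + plan["extra_ncbi"],
            uniprot_accession=plan["accession"] if plan["linked"] else None,
        )
        records[Source.BIOGRID].append(bg)
        records[Source.NCBIGENE].append(nc)

        if plan["linked"]:
            up = build_uniprot_record(
                plan["accession"],
                tax,
                recommended_name=f"{base.capitalize()} protein",
                primary_gene_name=base,
                gene_synonyms=[_vary_case(rng, t) for t in shared + up_extra],
                gene_id=plan["gene_id"],
            )
            records[Source.UNIPROT].append(up)
            links.append(
                CrossRefLink(Source.BIOGRID, bg.native_id, up.native_id, LinkKind.PROTEIN_ID)
            )
            links.append(
                CrossRefLink(Source.NCBIGENE, nc.native_id, up.native_id, LinkKind.GENE_ID)
            )
            entity_groups.append(
                _entity_dict(
                    up.native_id,
                    up.primary_name,
                    tax,
                    [up, bg, nc],
                    [nc.native_id],
                    unlinked=False,
                )
            )
        else:
            entity_groups.append(
                _entity_dict(
                    f"biogrid:{bg.native_id}", bg.primary_name, tax, [bg], [], unlinked=True
                )
            )
            entity_groups.append(
                _entity_dict(
                    f"ncbigene:{nc.native_id}",
                    nc.primary_name,
                    tax,
                    [nc],
                    [nc.native_id],
                    unlinked=True,
                )
            )

    truth = _ground_truth(records, links, entity_groups)
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_xml_files(records, out_dir)
        truth.save(out_dir / "ground_truth.json")
    return truth


# ---------------------------------------------------------------------------
# the two-entity worked example


def table1_fixture(out_dir: Union[str, Path, None] = None) -> GroundTruth:
    """The PPP2R3B_HUMAN / ZNT10_HUMAN worked example as a fixture corpus.

    Two human entities whose per-source synonym rows overlap partially:
    PPP2R3B has six distinct case-insensitive synonyms across the three
    sources, ZNT10 eight.
    """
    ppp_acc, znt_acc = "P0A0001", "P0A0002"
    records: dict[Source, list[SourceRecord]] = {
        Source.UNIPROT: [
            build_uniprot_record(
                ppp_acc, 9606, recommended_name="PPP2R3 L", gene_id="101"
            ),
            build_uniprot_record(
                znt_acc,
                9606,
                recommended_name="Zinc transporter 10",
                primary_gene_name="SLC30A10",
                gene_synonyms=["ZNT10", "ZNT8"],
                gene_id="102",
            ),
        ],
        Source.BIOGRID: [
            build_biogrid_record(
                "2001",
                9606,
                short_label="PPP2R3 L",
                aliases=["PR48", "NYREN8", "PPP2R3LY", "LL0YNC03-56G10.1"],
                uniprot_accession=ppp_acc,
            ),
            build_biogrid_record(
                "2002",
                9606,
                short_label="SLC30A10",
                aliases=["ZNT10", "ZNT8", "HMDPC", "ZRC1", "ZnT-10"],
                uniprot_accession=znt_acc,
            ),
        ],
        Source.NCBIGENE: [
            build_ncbigene_record(
                "101",
                9606,
                symbol="PPP2R3 L",
                synonyms=["PR48", "NYREN8", "PPP2R3LY", "PR70"],
                uniprot_accession=ppp_acc,
            ),
            build_ncbigene_record(
                "102",
                9606,
                symbol="SLC30A10",
                synonyms=["ZNT10", "ZNT8", "HMDPC", "ZRC1", "ZnT-10", "HMNDYT1"],
                uniprot_accession=znt_acc,
            ),
        ],
    }
    links = [
        CrossRefLink(Source.BIOGRID, "2001", ppp_acc, LinkKind.PROTEIN_ID),
        CrossRefLink(Source.BIOGRID, "2002", znt_acc, LinkKind.PROTEIN_ID),
        CrossRefLink(Source.NCBIGENE, "101", ppp_acc, LinkKind.GENE_ID),
        CrossRefLink(Source.NCBIGENE, "102", znt_acc, LinkKind.GENE_ID),
    ]
    entity_groups = [
        _entity_dict(
            ppp_acc,
            "PPP2R3 L",
            9606,
            [records[Source.UNIPROT][0], records[Source.BIOGRID][0], records[Source.NCBIGENE][0]],
            ["101"],
            unlinked=False,
        ),
        _entity_dict(
            znt_acc,
            "Zinc transporter 10",
            9606,
            [records[Source.UNIPROT][1], records[Source.BIOGRID][1], records[Source.NCBIGENE][1]],
            ["102"],
            unlinked=False,
        ),
    ]
    truth = _ground_truth(records, links, entity_groups)
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_xml_files(records, out_dir)
        truth.save(Path(out_dir) / "ground_truth.json")
    return truth
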