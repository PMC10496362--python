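"""Entity and attribute alignment: tag→ontology mappings and id links.

Two alignment mechanisms connect the three sources:

* **Semantic tag mappings** — declarative tables assigning each source XML
  tag to one of the three protein-ontology slot classes (``Name``,
  ``TaxId``, ``Synonym``).  The tables are data, not code: they can be
  serialized to and loaded from a YAML config file, so a new source dialect
  can be aligned without touching the pipeline.
* **Cross-reference links** — directed identifier links from BioGRID
  interactors (UniProt xref) and NCBI genes (shared GeneID) to the UniProt
  hub accession under which records are merged.

Name matching is exact on normalized (trimmed, lowercased) forms only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import yaml

from .readers import Source, SourceRecord

__all__ = [
    "SlotClass",
    "LinkKind",
    "TagMapping",
    "CrossRefLink",
    "MappedSlots",
    "ConfigurationError",
    "DEFAULT_MAPPINGS",
    "UNIPROT_DB_NAMES",
    "GENEID_DB_NAMES",
    "normalize_name",
    "apply_mapping",
    "link_biogrid",
    "link_ncbigene",
    "load_mappings",
    "dump_mappings",
]


class SlotClass(str, Enum):
    """The three slot classes of the protein-ontology schema."""

    NAME = "Name"
    TAX_ID = "TaxId"
    SYNONYM = "Synonym"


class LinkKind(str, Enum):
    PROTEIN_ID = "protein_id"  # biogrid interactor -> uniprot accession
    GENE_ID = "gene_id"  # ncbigene gene -> uniprot accession via GeneID


class ConfigurationError(ValueError):
    """A mapping table was applied to a record from a different source."""


@dataclass(frozen=True)
class TagMapping:
    """Declarative mapping from source XML tags to ontology slot classes."""

    source: Source
    entries: tuple[tuple[str, SlotClass], ...]

    def __post_init__(self) -> None:
        for tag, slot in self.entries:
            if not isinstance(slot, SlotClass):
                raise ValueError(f"invalid ontology class for tag {tag!r}: {slot!r}")

    def slot_for(self, tag: str) -> SlotClass | None:
        for entry_tag, slot in self.entries:
            if entry_tag == tag:
                return slot
        return None


#: Default mapping tables for the three supported dialects.
DEFAULT_MAPPINGS: dict[Source, TagMapping] = {
    Source.UNIPROT: TagMapping(
        Source.UNIPROT,
        (
            ("recommendedName", SlotClass.NAME),
            ("PrimaryName", SlotClass.NAME),
            ("alternativeName", SlotClass.SYNONYM),
            ("synonymName", SlotClass.SYNONYM),
            ("NCBI TaxonomyId", SlotClass.TAX_ID),
        ),
    ),
    Source.BIOGRID: TagMapping(
        Source.BIOGRID,
        (
            ("shortLabel", SlotClass.NAME),
            ("ncbiTaxId", SlotClass.TAX_ID),
            ("alias", SlotClass.SYNONYM),
        ),
    ),
    Source.NCBIGENE: TagMapping(
        Source.NCBIGENE,
        (
            ("Symbol", SlotClass.NAME),
            ("taxId", SlotClass.TAX_ID),
            ("Synonym", SlotClass.SYNONYM),
        ),
    ),
}

#: Database labels recognised as UniProt in BioGRID cross-references.
#: Real dumps vary in spelling; comparison is case-insensitive.
UNIPROT_DB_NAMES = frozenset(
    {"uniprot", "uniprotkb", "swiss-prot", "uniprot/swiss-prot", "uniprot knowledge base"}
)

#: Database labels recognised as NCBI GeneID cross-references.
GENEID_DB_NAMES = frozenset({"geneid", "ncbi gene", "entrez gene", "gene"})


def normalize_name(name: str) -> str:
    """Normalize a protein/gene name: trim whitespace and lowercase.

    All name matching in the pipeline is exact matching on this normalized
    form.  Idempotent; raises :class:`ValueError` on empty or
    whitespace-only input.
    """
    trimmed = name.strip()
    if not trimmed:
        raise ValueError("cannot normalize an empty or whitespace-only name")
    return trimmed.lower()


@dataclass(frozen=True)
class CrossRefLink:
    """A directed link from a source record to a UniProt hub accession."""

    from_source: Source
    from_id: str
    hub_accession: str
    link_kind: LinkKind

    def __post_init__(self) -> None:
        if self.link_kind is LinkKind.PROTEIN_ID and self.from_source is not Source.BIOGRID:
            raise ValueError("protein_id links originate from BioGRID only")
        if self.link_kind is LinkKind.GENE_ID and self.from_source is not Source.NCBIGENE:
            raise ValueError("gene_id links originate from NCBI Gene only")


def link_biogrid(records: Iterable[SourceRecord]) -> list[CrossRefLink]:
    """Build protein-id links from BioGRID interactors to UniProt accessions.

    One link per cross-reference whose database label identifies UniProt;
    interactors without such an xref yield no link (not an error — they are
    later stored under surrogate hubs).
    """
    links: list[CrossRefLink] = []
    for record in records:
        if record.source is not Source.BIOGRID:
            raise ConfigurationError("link_biogrid expects biogrid records")
        for xref in record.xrefs:
            if xref.target_db.lower() in UNIPROT_DB_NAMES:
                links.append(
                    CrossRefLink(Source.BIOGRID, record.native_id, xref.target_id, LinkKind.PROTEIN_ID)
                )
    return links


def link_ncbigene(
    records: Iterable[SourceRecord], uniprot_records: Iterable[SourceRecord]
) -> list[CrossRefLink]:
    """Build gene-id links from NCBI genes to UniProt accessions via GeneID.

    A UniProt entry cross-referencing GeneID ``g`` is linked from the NCBI
    gene whose own GeneID is ``g``; a gene matched by *k* entries yields
    *k* links, one per entry (the many-to-many case).
    """
    by_geneid: dict[str, list[str]] = {}
    for up in uniprot_records:
        if up.source is not Source.UNIPROT:
            raise ConfigurationError("link_ncbigene expects uniprot records as second argument")
        for xref in up.xrefs:
            if xref.target_db.lower() in GENEID_DB_NAMES:
                by_geneid.setdefault(xref.target_id, []).append(up.native_id)

    links: list[CrossRefLink] = []
    for record in records:
        if record.source is not Source.NCBIGENE:
            raise ConfigurationError("link_ncbigene expects ncbigene records as first argument")
        for accession in by_geneid.get(record.native_id, ()):
            links.append(CrossRefLink(Source.NCBIGENE, record.native_id, accession, LinkKind.GENE_ID))
    return links


@dataclass(frozen=True)
class MappedSlots:
    """Result of applying a tag mapping to one record.

    ``synonyms`` maps normalized form → first-seen surface form.  Primary
    (``Name``-class) values are inserted into the Synonym slot as well, so
    queries by primary name and by synonym behave uniformly.
    ``n_name_values`` counts mapped name-bearing inputs before
    deduplication (count conservation check).
    """

    names: tuple[str, ...]
    tax_id: int | None
    synonyms: dict[str, str]
    n_name_values: int


def apply_mapping(record: SourceRecord, mapping: TagMapping) -> MappedSlots:
    """Assign every mapped tag value of ``record`` to its ontology slot."""
    if mapping.source is not record.source:
        raise ConfigurationError(
            f"mapping for source {mapping.source.value!r} applied to a {record.source.value!r} record"
        )

    names: list[str] = []
    synonyms: dict[str, str] = {}
    tax_id: int | None = None
    n_name_values = 0

    for tv in record.tagged_values:
        slot = mapping.slot_for(tv.tag)
        if slot is None:
            continue
        if slot is SlotClass.TAX_ID:
            tax_id = int(tv.value)
        else:
            n_name_values += 1
            if slot is SlotClass.NAME and tv.value not in names:
                names.append(tv.value)
            synonyms.setdefault(normalize_name(tv.value), tv.value)

    return MappedSlots(tuple(names), tax_id, synonyms, n_name_values)


# ---------------------------------------------------------------------------
# mapping tables as config


def dump_mappings(mappings: Mapping[Source, TagMapping], path: Union[str, Path]) -> None:
    """Serialize mapping tables to a YAML config file."""
    doc = {
        source.value: [{"tag": tag, "class": slot.value} for tag, slot in mapping.entries]
        for source, mapping in mappings.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def load_mappings(path: Union[str, Path]) -> dict[Source, TagMapping]:
    """Load mapping tables from a YAML config file."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    mappings: dict[Source, TagMapping] = {}
    for source_name, entries in doc.items():
        source = Source(source_name)
        mappings[source] = TagMapping(
            source,
            tuple((e["tag"], SlotClass(e["class"])) for e in entries),
        )
    return mappings
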