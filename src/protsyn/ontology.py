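"""Lightweight protein ontology: schema, populated instances, provenance.

The schema is deliberately small: an ``Entity`` (a protein together with
its encoding gene) carrying three slot classes — ``Name`` (primary names),
``TaxId`` (NCBI Taxonomy species id) and ``Synonym`` (alternative names)
— plus a gene-identifier link.  Records from all sources are stored as
instances under a hub accession: the UniProt accession when the record is
cross-reference linked, otherwise a source-qualified surrogate id
(``"biogrid:12345"``), so nothing is silently dropped.

Every synonym keeps both its original surface form and its normalized
(lowercased) form, plus the set of source databases that attest it.  The
normalized form is the deduplication key; surface forms are what writers
emit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

from .alignment import DEFAULT_MAPPINGS, SlotClass, TagMapping, apply_mapping
from .readers import Source, SourceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "OntologySchema",
    "DEFAULT_SCHEMA",
    "ProvenancedTerm",
    "OntologyInstance",
    "InstanceStore",
    "SOURCE_PRECEDENCE",
    "surrogate_accession",
]

#: Order in which sources win ties (surface form kept per normalized key,
#: primary-name choice): UniProt is the hub, NCBI Gene next, BioGRID last.
SOURCE_PRECEDENCE: dict[Source, int] = {
    Source.UNIPROT: 0,
    Source.NCBIGENE: 1,
    Source.BIOGRID: 2,
}


def surrogate_accession(record: SourceRecord) -> str:
    """Hub key for a record with no UniProt link: ``"<source>:<native id>"``."""
    return f"{record.source.value}:{record.native_id}"


@dataclass(frozen=True)
class OntologySchema:
    """The class and relation inventory of the protein ontology."""

    classes: frozenset[str] = frozenset({"Entity", "Name", "TaxId", "Synonym"})
    relations: frozenset[tuple[str, str]] = frozenset(
        {
            ("Entity", "Name"),
            ("Entity", "TaxId"),
            ("Entity", "Synonym"),
            ("Entity", "Gene"),
        }
    )

    def __post_init__(self) -> None:
        missing = {"Name", "TaxId", "Synonym"} - self.classes
        if missing:
            raise ValueError(f"schema must contain the slot classes, missing: {sorted(missing)}")


DEFAULT_SCHEMA = OntologySchema()


@dataclass(frozen=True)
class ProvenancedTerm:
    """A synonym with its surface form, normalized form and source set."""

    surface: str
    normalized: str
    sources: frozenset[Source]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("ProvenancedTerm must cite at least one source")
        if self.normalized != self.surface.strip().lower():
            raise ValueError("normalized form must equal the trimmed, lowercased surface")


@dataclass
class _SynonymSlot:
    """Mutable accumulator for one normalized synonym inside an instance."""

    sources: set[Source] = field(default_factory=set)
    # (source precedence, surface) — min is the emitted surface form
    surface_rank: tuple[int, str] = (99, "")

    def add(self, surface: str, source: Source) -> None:
        self.sources.add(source)
        candidate = (SOURCE_PRECEDENCE[source], surface)
        if candidate < self.surface_rank:
            self.surface_rank = candidate


@dataclass
class OntologyInstance:
    """A populated protein-ontology individual."""

    hub_accession: str
    names: set[str] = field(default_factory=set)
    tax_id: int | None = None
    gene_ids: set[str] = field(default_factory=set)
    unlinked: bool = False
    _synonyms: dict[str, _SynonymSlot] = field(default_factory=dict)
    _record_keys: set[tuple[Source, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.hub_accession:
            raise ValueError("hub_accession must be non-empty")

    @property
    def synonyms(self) -> frozenset[ProvenancedTerm]:
        return frozenset(
            ProvenancedTerm(slot.surface_rank[1], normalized, frozenset(slot.sources))
            for normalized, slot in self._synonyms.items()
        )

    @property
    def record_keys(self) -> frozenset[tuple[Source, str]]:
        """The (source, native id) pairs of every contributing record."""
        return frozenset(self._record_keys)

    def add_synonym(self, normalized: str, surface: str, source: Source) -> None:
        self._synonyms.setdefault(normalized, _SynonymSlot()).add(surface, source)


class InstanceStore:
    """Container of ontology instances keyed by hub accession."""

    def __init__(self, schema: OntologySchema = DEFAULT_SCHEMA) -> None:
        self.schema = schema
        self._instances: dict[str, OntologyInstance] = {}

    def __len__(self) -> int:
        return len(self._instances)

    def __iter__(self) -> Iterator[OntologyInstance]:
        return iter(self._instances.values())

    def add_instance(
        self,
        record: SourceRecord,
        mapping: TagMapping | None = None,
        hub_accession: str | None = None,
    ) -> OntologyInstance:
        """Populate (or extend) the instance for a record's hub accession.

        The record's tag values are assigned to the Name/TaxId/Synonym
        slots through the mapping table; repeated addition of the same
        record is idempotent.  Without an explicit ``hub_accession``,
        UniProt records live under their own accession and other records
        under a surrogate hub flagged unlinked.
        """
        if mapping is None:
            mapping = DEFAULT_MAPPINGS[record.source]
        slots = apply_mapping(record, mapping)  # raises on source mismatch

        if hub_accession is None:
            if record.source is Source.UNIPROT:
                hub_accession = record.native_id
                unlinked = False
            else:
                hub_accession = surrogate_accession(record)
                unlinked = True
        else:
            unlinked = False

        instance = self._instances.get(hub_accession)
        if instance is None:
            instance = OntologyInstance(hub_accession=hub_accession, unlinked=unlinked)
            self._instances[hub_accession] = instance

        instance.names.update(slots.names)
        for normalized, surface in slots.synonyms.items():
            instance.add_synonym(normalized, surface, record.source)
        if slots.tax_id is not None:
            if instance.tax_id is None:
                instance.tax_id = slots.tax_id
            elif instance.tax_id != slots.tax_id:
                logger.warning(
                    "instance %s: conflicting tax ids %s and %s; keeping the first",
                    hub_accession,
                    instance.tax_id,
                    slots.tax_id,
                )
        if record.source is Source.NCBIGENE:
            instance.gene_ids.add(record.native_id)
        for xref in record.xrefs:
            if xref.target_db.lower() in ("geneid", "gene"):
                instance.gene_ids.add(xref.target_id)
        instance._record_keys.add((record.source, record.native_id))
        return instance

    def get_instance(self, hub_accession: str) -> OntologyInstance | None:
        """Return the stored instance for an accession, or ``None``."""
        return self._instances.get(hub_accession)

    def to_triples(self) -> "rdflib.Graph":  # noqa: F821 — imported lazily
        """Export the store as subject–predicate–object triples.

        One triple per slot value, in a flat ``urn:protsyn:`` namespace;
        intended for downstream knowledge-graph use.
        """
        import rdflib
        from rdflib import Literal, Namespace, RDF

        ns = Namespace("urn:protsyn:")
        graph = rdflib.Graph()
        graph.bind("protsyn", ns)
        for instance in self:
            subject = ns[f"entity/{instance.hub_accession}"]
            graph.add((subject, RDF.type, ns.Entity))
            for name in sorted(instance.names):
                graph.add((subject, ns.hasName, Literal(name)))
            if instance.tax_id is not None:
                graph.add((subject, ns.hasTaxId, Literal(instance.tax_id)))
            for term in sorted(instance.synonyms, key=lambda t: t.normalized):
                graph.add((subject, ns.hasSynonym, Literal(term.surface)))
            for gene_id in sorted(instance.gene_ids):
                graph.add((subject, ns.encodedBy, Literal(gene_id)))
        return graph
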