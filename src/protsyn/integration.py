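"""Synonym integration: species-consistent matching, merging, deduplication.

Names are shared promiscuously across databases and across species —
human *PURH* and bacterial *purH* are different entities that collide on
a case-insensitive name key.  In the source corpora most erroneous
many-to-many name correspondences arise exactly this way, so every
candidate name mapping is checked against the NCBI Taxonomy ids of the
two records involved: a mapping is **kept** only when both tax ids are
present and equal, and **ignored** otherwise.

Merging itself is anchored on hard identifier links (BioGRID→UniProt
cross-references, GeneID joins), with the same species-consistency rule
applied to the links; records with no link are stored under surrogate
hubs so nothing is lost.  Synonym sets are unioned case-insensitively
with per-source provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence, Union

from .alignment import (
    ConfigurationError,
    CrossRefLink,
    TagMapping,
    link_biogrid,
    link_ncbigene,
    normalize_name,
)
from .ontology import (
    SOURCE_PRECEDENCE,
    InstanceStore,
    OntologyInstance,
    ProvenancedTerm,
    surrogate_accession,
)
from .readers import Source, SourceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RecordKey",
    "NameMapping",
    "IntegratedEntity",
    "IntegrationStats",
    "IntegrationResult",
    "build_name_mappings",
    "resolve_mappings",
    "merge_entities",
    "compute_stats",
    "integrate",
]

KEPT = "kept"
IGNORED = "ignored"

# fixed source order used wherever determinism requires one
_SOURCE_ORDER = (Source.UNIPROT, Source.NCBIGENE, Source.BIOGRID)


@dataclass(frozen=True)
class RecordKey:
    """Identity of one source record inside a name mapping."""

    source: Source
    native_id: str
    tax_id: int | None


@dataclass(frozen=True)
class NameMapping:
    """A candidate name-level correspondence between two source records."""

    name_normalized: str
    left: RecordKey
    right: RecordKey
    status: str | None = None  # None until resolved; then "kept" or "ignored"


@dataclass(frozen=True)
class IntegratedEntity:
    """The merged, deduplicated synonym record for one hub accession."""

    hub_accession: str
    primary_name: str | None
    tax_id: int | None
    synonyms: frozenset[ProvenancedTerm]
    gene_ids: frozenset[str]
    unlinked: bool = False

    def __post_init__(self) -> None:
        normalized = [t.normalized for t in self.synonyms]
        if len(normalized) != len(set(normalized)):
            raise ValueError("synonyms must be unique by normalized form")

    @property
    def synonyms_normalized(self) -> frozenset[str]:
        return frozenset(t.normalized for t in self.synonyms)


@dataclass(frozen=True)
class IntegrationStats:
    """Summary statistics over an integrated entity set."""

    n_entities: int
    n_species: int
    n_terms: int  # (entity, distinct normalized synonym) pairs
    n_mappings_kept: int
    n_mappings_ignored: int


@dataclass(frozen=True)
class IntegrationResult:
    entities: tuple[IntegratedEntity, ...]
    name_mappings: tuple[NameMapping, ...]
    links: tuple[CrossRefLink, ...]
    stats: IntegrationStats


def _record_key(record: SourceRecord) -> RecordKey:
    return RecordKey(record.source, record.native_id, record.tax_id)


def _normalized_names(record: SourceRecord) -> frozenset[str]:
    return frozenset(normalize_name(s) for s in record.synonyms)


def build_name_mappings(
    records_by_source: Mapping[Source, Sequence[SourceRecord]],
    links: Sequence[CrossRefLink] = (),
) -> list[NameMapping]:
    """Enumerate candidate name mappings between sources.

    One candidate per (left record, right record, shared normalized name)
    triple, for every pair of records from different sources sharing that
    name.  Identifier links join the same record pairs, so link-mediated
    name sharing is subsumed by the name-key enumeration; the ``links``
    argument is accepted for interface symmetry.  Every candidate carries
    both records' tax ids; output order is deterministic.
    """
    index: dict[Source, dict[str, list[SourceRecord]]] = {}
    for source in _SOURCE_ORDER:
        per_name: dict[str, list[SourceRecord]] = {}
        for record in records_by_source.get(source, ()):
            for name in sorted(_normalized_names(record)):
                per_name.setdefault(name, []).append(record)
        index[source] = per_name

    candidates: list[NameMapping] = []
    for i, left_source in enumerate(_SOURCE_ORDER):
        for right_source in _SOURCE_ORDER[i + 1 :]:
            left_index = index[left_source]
            right_index = index[right_source]
            for name in sorted(set(left_index) & set(right_index)):
                for left in left_index[name]:
                    for right in right_index[name]:
                        candidates.append(
                            NameMapping(name, _record_key(left), _record_key(right))
                        )
    return candidates


def resolve_mappings(candidates: Sequence[NameMapping]) -> list[NameMapping]:
    """Assign kept/ignored status to candidate mappings by species identity.

    A mapping is kept if and only if both tax ids are present and equal;
    mappings with differing or missing species are ignored.  Input order
    is preserved.
    """
    resolved: list[NameMapping] = []
    for candidate in candidates:
        consistent = (
            candidate.left.tax_id is not None
            and candidate.right.tax_id is not None
            and candidate.left.tax_id == candidate.right.tax_id
        )
        resolved.append(replace(candidate, status=KEPT if consistent else IGNORED))
    return resolved


# ---------------------------------------------------------------------------
# merging


def _filter_links(
    links: Sequence[CrossRefLink],
    records_by_source: Mapping[Source, Sequence[SourceRecord]],
) -> list[CrossRefLink]:
    """Drop links joining records whose present tax ids differ.

    Identifier links are species-unambiguous when either side lacks a tax
    id, but a link between two records with differing present species is
    treated like an inconsistent name mapping and discarded with a warning.
    """
    uniprot_tax = {
        r.native_id: r.tax_id for r in records_by_source.get(Source.UNIPROT, ())
    }
    record_tax = {
        (r.source, r.native_id): r.tax_id
        for source in (Source.BIOGRID, Source.NCBIGENE)
        for r in records_by_source.get(source, ())
    }
    kept: list[CrossRefLink] = []
    for link in links:
        if link.hub_accession not in uniprot_tax:
            # link to an accession absent from the input: no hub to merge into
            continue
        hub_tax = uniprot_tax[link.hub_accession]
        rec_tax = record_tax.get((link.from_source, link.from_id))
        if hub_tax is not None and rec_tax is not None and hub_tax != rec_tax:
            logger.warning(
                "dropping species-inconsistent link %s:%s -> %s (tax %s vs %s)",
                link.from_source.value,
                link.from_id,
                link.hub_accession,
                rec_tax,
                hub_tax,
            )
            continue
        kept.append(link)
    return kept


_PRIMARY_PRECEDENCE = {Source.UNIPROT: 0, Source.NCBIGENE: 1, Source.BIOGRID: 2}


def _merge_entity_sequence(entities: Iterable[IntegratedEntity]) -> list[IntegratedEntity]:
    """Re-merge already-integrated entities by hub key (idempotent path)."""
    by_hub: dict[str, list[IntegratedEntity]] = {}
    for entity in entities:
        by_hub.setdefault(entity.hub_accession, []).append(entity)

    merged: list[IntegratedEntity] = []
    for hub in sorted(by_hub):
        group = by_hub[hub]
        if len(group) == 1:
            merged.append(group[0])
            continue
        terms: dict[str, tuple[str, set[Source]]] = {}
        for entity in group:
            for term in entity.synonyms:
                surface, sources = terms.get(term.normalized, (term.surface, set()))
                sources |= term.sources
                terms[term.normalized] = (min(surface, term.surface), sources)
        merged.append(
            IntegratedEntity(
                hub_accession=hub,
                primary_name=min((e.primary_name for e in group if e.primary_name), default=None),
                tax_id=next((e.tax_id for e in group if e.tax_id is not None), None),
                synonyms=frozenset(
                    ProvenancedTerm(surface, normalized, frozenset(sources))
                    for normalized, (surface, sources) in terms.items()
                ),
                gene_ids=frozenset().union(*(e.gene_ids for e in group)),
                unlinked=all(e.unlinked for e in group),
            )
        )
    return merged


def merge_entities(
    records_by_source: Union[Mapping[Source, Sequence[SourceRecord]], Sequence[IntegratedEntity]],
    links: Sequence[CrossRefLink] = (),
    resolved_mappings: Sequence[NameMapping] = (),
    mappings: Mapping[Source, TagMapping] | None = None,
) -> list[IntegratedEntity]:
    """Merge source records into deduplicated, provenance-tracked entities.

    Records sharing a hub accession (via species-consistent identifier
    links) are merged: their synonym sets are unioned case-insensitively,
    with the surface form per normalized key chosen by source precedence
    (UniProt, NCBI Gene, BioGRID) then lexicographically.  Unlinked
    records become surrogate-hub entities flagged ``unlinked``.  Should
    records with conflicting present tax ids end up under one hub, the
    entity is split per tax id with a warning.

    Passing a sequence of already-integrated entities re-merges them by
    hub key, which is the identity on any previous output of this
    function.  Output is sorted by hub accession.
    """
    if not isinstance(records_by_source, Mapping):
        seq = list(records_by_source)
        if all(isinstance(e, IntegratedEntity) for e in seq):
            return _merge_entity_sequence(seq)
        raise TypeError("expected a records-by-source mapping or a sequence of IntegratedEntity")

    links = _filter_links(links, records_by_source)

    # hub assignment: uniprot records anchor their own accession; linked
    # records contribute to every hub they link to; the rest get surrogates
    contributions: list[tuple[str, SourceRecord, bool]] = []  # (hub, record, unlinked)
    links_by_record: dict[tuple[Source, str], list[str]] = {}
    for link in links:
        links_by_record.setdefault((link.from_source, link.from_id), []).append(
            link.hub_accession
        )

    for source in _SOURCE_ORDER:
        for record in records_by_source.get(source, ()):
            if source is Source.UNIPROT:
                contributions.append((record.native_id, record, False))
                continue
            hubs = links_by_record.get((source, record.native_id), ())
            if hubs:
                for hub in sorted(set(hubs)):
                    contributions.append((hub, record, False))
            else:
                contributions.append((surrogate_accession(record), record, True))

    # split hubs whose contributing records disagree on present tax ids
    by_hub: dict[str, list[tuple[SourceRecord, bool]]] = {}
    for hub, record, unlinked in contributions:
        by_hub.setdefault(hub, []).append((record, unlinked))

    store = InstanceStore()
    hub_meta: dict[str, dict] = {}
    for hub in sorted(by_hub):
        group = by_hub[hub]
        present_taxes = sorted({r.tax_id for r, _ in group if r.tax_id is not None})
        anchor_tax = None
        for record, _ in group:
            if record.source is Source.UNIPROT and record.tax_id is not None:
                anchor_tax = record.tax_id
                break
        if anchor_tax is None and present_taxes:
            anchor_tax = present_taxes[0]
        if len(present_taxes) > 1:
            logger.warning(
                "hub %s merges records of species %s; splitting per tax id",
                hub,
                present_taxes,
            )
        for record, unlinked in group:
            if len(present_taxes) > 1 and record.tax_id not in (None, anchor_tax):
                hub_key = f"{hub}@tax{record.tax_id}"
            else:
                hub_key = hub
            mapping = mappings[record.source] if mappings else None
            store.add_instance(record, mapping=mapping, hub_accession=hub_key)
            meta = hub_meta.setdefault(hub_key, {"unlinked": True, "primary": []})
            meta["unlinked"] = meta["unlinked"] and unlinked
            if record.primary_name:
                meta["primary"].append(
                    (_PRIMARY_PRECEDENCE[record.source], record.primary_name)
                )

    entities: list[IntegratedEntity] = []
    for instance in sorted(store, key=lambda i: i.hub_accession):
        meta = hub_meta[instance.hub_accession]
        primary = min(meta["primary"])[1] if meta["primary"] else None
        entities.append(
            IntegratedEntity(
                hub_accession=instance.hub_accession,
                primary_name=primary,
                tax_id=instance.tax_id,
                synonyms=instance.synonyms,
                gene_ids=frozenset(instance.gene_ids),
                unlinked=meta["unlinked"],
            )
        )
    return entities


def compute_stats(
    entities: Sequence[IntegratedEntity],
    resolved_mappings: Sequence[NameMapping] = (),
) -> IntegrationStats:
    """Exact, deterministic counts over an integrated entity set."""
    return IntegrationStats(
        n_entities=len(entities),
        n_species=len({e.tax_id for e in entities if e.tax_id is not None}),
        n_terms=sum(len(e.synonyms) for e in entities),
        n_mappings_kept=sum(1 for m in resolved_mappings if m.status == KEPT),
        n_mappings_ignored=sum(1 for m in resolved_mappings if m.status == IGNORED),
    )


def integrate(
    records_by_source: Mapping[Source, Sequence[SourceRecord]],
    mappings: Mapping[Source, TagMapping] | None = None,
) -> IntegrationResult:
    """Run the full alignment + integration stage over parsed records."""
    uniprot = list(records_by_source.get(Source.UNIPROT, ()))
    biogrid = list(records_by_source.get(Source.BIOGRID, ()))
    ncbigene = list(records_by_source.get(Source.NCBIGENE, ()))
    records = {Source.UNIPROT: uniprot, Source.BIOGRID: biogrid, Source.NCBIGENE: ncbigene}

    links = tuple(link_biogrid(biogrid) + link_ncbigene(ncbigene, uniprot))
    candidates = build_name_mappings(records, links)
    resolved = tuple(resolve_mappings(candidates))
    entities = merge_entities(records, links, resolved, mappings)
    stats = compute_stats(entities, resolved)
    logger.info(
        "integrated %d entities, %d species, %d terms (%d mappings kept, %d ignored)",
        stats.n_entities,
        stats.n_species,
        stats.n_terms,
        stats.n_mappings_kept,
        stats.n_mappings_ignored,
    )
    return IntegrationResult(tuple(entities), resolved, links, stats)
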