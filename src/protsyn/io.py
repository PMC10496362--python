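"""Writers (and a TSV reader) for the integrated synonym set.

All writers emit deterministically ordered, UTF-8 text so that repeated
runs over the same inputs are byte-identical and diffs stay meaningful.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence, Union

from .integration import IntegratedEntity
from .ontology import ProvenancedTerm
from .readers import Source

__all__ = ["write_tsv", "read_tsv", "write_json", "write_triples", "TSV_COLUMNS"]

TSV_COLUMNS = (
    "hub_accession",
    "primary_name",
    "tax_id",
    "synonym_surface",
    "synonym_normalized",
    "sources",
)


def write_tsv(entities: Sequence[IntegratedEntity], path: Union[str, Path]) -> None:
    """Write one row per (entity, synonym) pair, sorted and header-first."""
    rows = []
    for entity in entities:
        for term in entity.synonyms:
            rows.append(
                (
                    entity.hub_accession,
                    entity.primary_name or "",
                    str(entity.tax_id) if entity.tax_id is not None else "",
                    term.surface,
                    term.normalized,
                    ",".join(sorted(s.value for s in term.sources)),
                )
            )
    rows.sort(key=lambda r: (r[0], r[4]))
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        writer.writerows(rows)


def read_tsv(path: Union[str, Path]) -> dict[str, dict]:
    """Read a synonym TSV back into per-entity dictionaries.

    Inverse of :func:`write_tsv` up to entity metadata not stored per row
    (gene ids, unlinked flag).
    """
    entities: dict[str, dict] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            entity = entities.setdefault(
                row["hub_accession"],
                {
                    "primary_name": row["primary_name"] or None,
                    "tax_id": int(row["tax_id"]) if row["tax_id"] else None,
                    "synonyms": set(),
                },
            )
            entity["synonyms"].add(
                ProvenancedTerm(
                    row["synonym_surface"],
                    row["synonym_normalized"],
                    frozenset(Source(s) for s in row["sources"].split(",") if s),
                )
            )
    return entities


def write_json(entities: Sequence[IntegratedEntity], path: Union[str, Path]) -> None:
    """Write one JSON object per entity (sorted by hub accession)."""
    doc = [
        {
            "hub_accession": e.hub_accession,
            "primary_name": e.primary_name,
            "tax_id": e.tax_id,
            "unlinked": e.unlinked,
            "gene_ids": sorted(e.gene_ids),
            "synonyms": [
                {
                    "surface": t.surface,
                    "normalized": t.normalized,
                    "sources": sorted(s.value for s in t.sources),
                }
                for t in sorted(e.synonyms, key=lambda t: t.normalized)
            ],
        }
        for e in sorted(entities, key=lambda e: e.hub_accession)
    ]
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def write_triples(entities: Sequence[IntegratedEntity], path: Union[str, Path]) -> None:
    """Export entities as N-Triples (one triple per slot value), sorted."""
    from rdflib import Graph, Literal, Namespace, RDF

    ns = Namespace("urn:protsyn:")
    graph = Graph()
    for entity in entities:
        subject = ns[f"entity/{entity.hub_accession}"]
        graph.add((subject, RDF.type, ns.Entity))
        if entity.primary_name:
            graph.add((subject, ns.hasName, Literal(entity.primary_name)))
        if entity.tax_id is not None:
            graph.add((subject, ns.hasTaxId, Literal(entity.tax_id)))
        for term in entity.synonyms:
            graph.add((subject, ns.hasSynonym, Literal(term.surface)))
        for gene_id in sorted(entity.gene_ids):
            graph.add((subject, ns.encodedBy, Literal(gene_id)))
    lines = sorted(graph.serialize(format="nt").splitlines())
    Path(path).write_text("\n".join(line for line in lines if line) + "\n", encoding="utf-8")
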