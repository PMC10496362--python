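# Methods

## Data model

The integration target is a deliberately small protein ontology: an
`Entity` class (a protein together with its encoding gene) with three slot
classes — `Name` (primary names), `TaxId` (NCBI Taxonomy id of the species)
and `Synonym` (all alternative names) — plus a gene-identifier link. Records
from each source are projected onto these slots by declarative mapping
tables:

| source    | tag                          | slot    |
|-----------|------------------------------|---------|
| uniprot   | `recommendedName`, `PrimaryName` | Name |
| uniprot   | `alternativeName`, `synonymName` | Synonym |
| uniprot   | `NCBI TaxonomyId`            | TaxId   |
| biogrid   | `shortLabel`                 | Name    |
| biogrid   | `alias`                      | Synonym |
| biogrid   | `ncbiTaxId`                  | TaxId   |
| ncbigene  | `Symbol`                     | Name    |
| ncbigene  | `Synonym`                    | Synonym |
| ncbigene  | `taxId`                      | TaxId   |

The tables are data, not code (`alignment.DEFAULT_MAPPINGS`, serializable to
YAML), so aligning a new dialect means writing a table, not a parser branch.
Each parser records which tag every name came from (`SourceRecord.
tagged_values`), which is what lets the tables actually drive slot
assignment. `Name`-class values are additionally inserted into the Synonym
slot, so querying by primary name and by synonym behaves uniformly; the
per-source rows of real synonym listings include the primary symbol among
the synonyms, which supports this choice.

## Parsing

All XML goes through `lxml.etree.iterparse` with subtree clearing, so memory
is bounded per record rather than per file; the real source releases are
multi-gigabyte dumps and must be streamable. Only the name, taxonomy and
cross-reference element subset is interpreted; unknown elements are ignored,
not errors. Records missing their identifying element (UniProt accession,
GeneID) are skipped with a logged error; a BioGRID interactor without
`ncbiTaxId` is kept with the tax id absent and a warning, since dropping it
would silently lose names — such a record can never pass the
taxonomy-consistency check against a taxed record, but still merges through
a hard identifier link.

One primitive is hand-written rather than delegated to the XML parser:
`extract_tag_value(fragment, tag)` returns the text between an opening and
closing tag of a printed one-line fragment, tolerating whitespace inside the
angle brackets (`<TaxID > 8355 </TaxID >` → `"8355"`), because such
fragments appear in human-readable listings and are not well-formed XML.

## Linking and species-consistent integration

Two kinds of hard identifier links anchor the merge: BioGRID interactor →
UniProt accession (from the interactor's UniProt cross-reference; database
labels are compared case-insensitively against the common spellings
`uniprot`, `uniprotkb`, `swiss-prot`, `uniprot/swiss-prot`) and NCBI gene →
UniProt accession (equi-join on GeneID; a gene matched by *k* entries yields
*k* links).

Name-level candidate mappings are enumerated as one candidate per (record
pair, shared normalized name) triple across distinct sources. The resolver
keeps a candidate iff both tax ids are present and equal, and ignores it
otherwise — most erroneous many-to-many name correspondences in real corpora
are cross-species reuses of the same string, and this check is the
pipeline's disambiguation step. The same rule is applied to identifier
links: a link joining two records with differing *present* tax ids is
dropped with a warning before merging. Kept name mappings corroborate and
are reported in the statistics, but do not merge hubs on their own: merging
is anchored exclusively on identifiers, because name-only merging would
reintroduce exactly the ambiguity the filter removes. Should records of
conflicting present species still meet under one hub (possible only when the
hub's own entry lacks a tax id), the entity is split per tax id
(`ACC@tax10090`) with a warning.

Per entity the synonym set is the union over contributing records,
deduplicated by normalized form. Ties are broken deterministically: the
surface form emitted per normalized key is the first in source-precedence
order (uniprot, ncbigene, biogrid), then lexicographic; the primary name is
chosen by the same source precedence (UniProt `recommendedName` > NCBI
`Symbol` > BioGRID `shortLabel`) because UniProt is the hub vocabulary. This
makes all outputs byte-stable regardless of input file order; writers
additionally sort rows by (hub accession, normalized synonym).

`n_terms` counts (entity, distinct normalized synonym) pairs — the most
defensible reading of a "terminology count" over an integrated set; unique
strings or raw source rows would either under- or over-count synonyms shared
between entities.

## Synthetic data

`fixtures.generate(FixtureSpec, out_dir)` emits a three-dialect corpus plus
JSON ground truth. It emulates the structural features the pipeline must
handle: per-entity synonym lists that only partially overlap between sources
(`overlap_fraction`, default 0.5), case variation of the same token across
databases, identifier cross-references into UniProt, records without any
link (`unlinked_fraction`, default 0.25 of entities, which appear in BioGRID
and NCBI Gene only), and planted cross-species collisions
(`cross_species_collision_count`, default 2): a unique token placed in the
BioGRID record of one entity and the NCBI Gene record of a different-species
entity, which is exactly the set of mappings the resolver must ignore.
Defaults are 8 entities over 3 species with 2–5 synonyms each — small enough
to enumerate by brute force, large enough that every code path (overlap,
case-folding, unlinked surrogates, collisions) is exercised. Species ids
come from a small pool of real taxa (9606, 10090, …) extended with synthetic
ids ≥ 10⁶ so no accidental real-taxon semantics attach to them.

Ground truth is computed by the generator's own bookkeeping, independently
of the pipeline: expected mapping counts by a nested-loop all-pairs
enumeration, expected entity synonym sets by direct union over the records
it assigned to each entity. Same seed, same bytes.

What the generator does **not** emulate: realistic dump sizes and tag
richness, protein sequences and interaction edges, malformed or partially
filled real-world records, and the heavy-tailed synonym-count distribution
of real databases. Passing tests therefore demonstrate correctness of the
parsing, alignment, filtering and merging logic on structurally faithful
miniatures — not recall/precision on the actual 2019–2020 releases, whose
full-scale counts (10⁸ terms, 10⁵–10⁷ entities) this package does not
attempt to reproduce.

## Numerical and degenerate-input choices

- Name normalization is trim + lowercase only; no Unicode case folding
  beyond `str.lower()`, no punctuation stripping, no fuzzy matching —
  matching is exact by design.
- Empty or whitespace-only names are rejected at the normalization boundary;
  parsers never emit them.
- A non-numeric or non-positive taxonomy value is treated as absent, with a
  warning.
- Zero-entity fixture specs produce valid empty container documents.
- Problem sizes in the test-suite property checks (100 seeded corpora for
  the deduplication oracle, 50 random generator configurations for the
  round-trip check, 10⁴ records for the streaming-memory bound) keep the
  whole suite in the low seconds while covering every branch of the
  generator's parameter space.

## Known limitations

- Only the documented element subset of each dialect is read; the full
  Entrezgene ASN.1-derived XML nesting is not traversed (the flattened
  `GeneID`/`Symbol`/`Synonyms`/`TaxID`/`dbXrefs` form is).
- Merging requires an identifier path to the hub; two unlinked records of
  the same entity in different sources remain separate surrogate entities
  even when they share same-species names (by design — see above).
- The optional triple export is a flat instance dump, not an OWL ontology;
  no reasoning or class hierarchy is provided.
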