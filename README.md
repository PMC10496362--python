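# protsyn

Species-aware integration of protein and encoding-gene synonyms from three
heterogeneous XML sources — UniProtKB/Swiss-Prot entry XML, BioGRID PSI-MI 2.5
interactor XML and NCBI Entrezgene XML — into a single provenance-tracked
synonym set.

## The problem

Proteins and their coding genes accumulate names: *PPP2R3B* is also *PR48*,
*NYREN8*, *PPP2R3LY*, *LL0YNC03-56G10.1* and *PR70*, and no single database
records all of them. Worse, the same surface name is reused across species
(human *PURH* vs bacterial *purH*), so naive case-insensitive matching merges
records that belong to different organisms. `protsyn` is for anyone building
text-mining vocabularies, identifier-mapping tables or protein
knowledge-graph entity layers who needs one synonym list per protein, with
each name's source databases attested and cross-species homonyms kept apart.

## Method

Records from all sources are aligned to a small protein ontology — an entity
with `Name`, `TaxId` and `Synonym` slots — via declarative tag→class mapping
tables (e.g. BioGRID `<shortLabel>` → `Name`, `<ncbiTaxId>` → `TaxId`,
`<alias>` → `Synonym`). Entities are merged under a UniProt **hub accession**
reached through hard identifier links: BioGRID interactor → UniProt xref, and
NCBI gene → UniProt entry joined on shared GeneID. All names are matched on
their normalized form `norm(s) = lowercase(trim(s))`.

Candidate name mappings between sources are then filtered by taxonomy
consistency: a mapping between records with tax ids *t₁*, *t₂* is

- **kept** iff *t₁* and *t₂* are both present and *t₁ = t₂*,
- **ignored** otherwise,

and identifier links joining records of differing species are dropped the
same way. Per entity, the synonym set is the case-insensitive union over all
contributing records, deduplicated by normalized form, each term carrying the
set of sources that attest it. Records with no link are preserved under
surrogate hubs (`biogrid:12345`) rather than discarded.

## Worked example

The built-in worked-example fixture holds two human entities whose per-source
synonym rows overlap only partially:

```
$ protsyn fixture --table1 --out demo/fixture
$ protsyn integrate --uniprot demo/fixture/uniprot.xml \
    --biogrid demo/fixture/biogrid.xml --ncbi-gene demo/fixture/ncbigene.xml \
    --out demo/out
...
entities=2 species=1 terms=14 mappings_kept=18 mappings_ignored=0
```

`entities=2`: the six records merged into two hub entities. `terms=14`:
PPP2R3B contributes 6 distinct case-insensitive synonyms and ZNT10 8.
`mappings_kept=18, mappings_ignored=0`: all cross-source name coincidences
were same-species, so none was discarded. The TSV output (one row per
entity/synonym pair) starts:

```
hub_accession  primary_name  tax_id  synonym_surface   synonym_normalized  sources
P0A0001        PPP2R3 L      9606    LL0YNC03-56G10.1  ll0ync03-56g10.1    biogrid
P0A0001        PPP2R3 L      9606    NYREN8            nyren8              biogrid,ncbigene
P0A0001        PPP2R3 L      9606    PPP2R3 L          ppp2r3 l            biogrid,ncbigene,uniprot
...
```

The `sources` column is the provenance: *PR70* is attested only by NCBI Gene,
*ppp2r3 l* by all three databases. Output is byte-stable across runs and
input-file orderings; `--format json` and `--format triples` (N-Triples for
knowledge-graph loading) are also available, and `--mappings FILE` overrides
the tag-mapping tables from YAML.

The same pipeline is available as a library:

```python
from protsyn import Source, integrate, parse_uniprot, parse_biogrid, parse_ncbigene

records = {
    Source.UNIPROT: list(parse_uniprot("uniprot.xml")),
    Source.BIOGRID: list(parse_biogrid("biogrid.xml")),
    Source.NCBIGENE: list(parse_ncbigene("ncbigene.xml")),
}
result = integrate(records)
result.stats         # entity/species/term and kept/ignored-mapping counts
result.entities[0]   # IntegratedEntity with provenance-tracked synonyms
```

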