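"""Species-consistent name matching, merging, deduplication, statistics."""

from __future__ import annotations

import random

import pytest

from protsyn.alignment import CrossRefLink, LinkKind, normalize_name
from protsyn.fixtures import (
    FixtureSpec,
    build_biogrid_record,
    build_ncbigene_record,
    build_uniprot_record,
    generate,
)
from protsyn.integration import (
    IGNORED,
    KEPT,
    NameMapping,
    RecordKey,
    build_name_mappings,
    compute_stats,
    integrate,
    merge_entities,
    resolve_mappings,
)
from protsyn.readers import Source


def _records_by_source(*records):
    out = {Source.UNIPROT: [], Source.BIOGRID: [], Source.NCBIGENE: []}
    for record in records:
        out[record.source].append(record)
    return out


def _candidate_key(name, left, right):
    """Canonical, order-insensitive identity of one candidate mapping."""
    ends = sorted([(left[0].value, left[1]), (right[0].value, right[1])])
    return (name, *ends)


def _brute_force_candidates(records_by_source):
    """Nested-loop all-pairs enumeration — the oracle for candidate mappings."""
    all_records = [r for recs in records_by_source.values() for r in recs]
    found = []
    for i, a in enumerate(all_records):
        for b in all_records[i + 1 :]:
            if a.source is b.source:
                continue
            shared = {normalize_name(s) for s in a.synonyms} & {
                normalize_name(s) for s in b.synonyms
            }
            for name in shared:
                found.append(
                    _candidate_key(name, (a.source, a.native_id), (b.source, b.native_id))
                )
    return sorted(found)


class TestBuildNameMappings:
    def test_same_species_pair_shares_one_candidate(self):
        a = build_uniprot_record("P1", 9606, recommended_name="purh")
        b = build_biogrid_record("1", 9606, short_label="PURH")
        (candidate,) = build_name_mappings(_records_by_source(a, b))
        assert candidate.name_normalized == "purh"
        assert candidate.left.tax_id == candidate.right.tax_id == 9606

    def test_cross_species_homonym_yields_candidate_with_differing_taxids(self):
        """Human PURH vs the bacterial purH homonym: one candidate, two species."""
        human = build_uniprot_record("P1", 9606, recommended_name="PURH")
        other = build_biogrid_record("1", 1000001, short_label="purH")
        (candidate,) = build_name_mappings(_records_by_source(human, other))
        assert candidate.left.tax_id != candidate.right.tax_id

    @pytest.mark.parametrize("seed", range(5))
    def test_candidate_multiset_equals_all_pairs_enumeration(self, seed):
        truth = generate(FixtureSpec(seed=seed, cross_species_collision_count=3), None)
        got = sorted(
            _candidate_key(
                m.name_normalized,
                (m.left.source, m.left.native_id),
                (m.right.source, m.right.native_id),
            )
            for m in build_name_mappings(truth.records)
        )
        assert got == _brute_force_candidates(truth.records)


class TestResolveMappings:
    def _candidate(self, tax_left, tax_right):
        return NameMapping(
            "x",
            RecordKey(Source.UNIPROT, "P1", tax_left),
            RecordKey(Source.BIOGRID, "1", tax_right),
        )

    def test_equal_present_taxids_kept(self):
        (resolved,) = resolve_mappings([self._candidate(9606, 9606)])
        assert resolved.status == KEPT

    @pytest.mark.parametrize("taxes", [(9606, 10090), (None, 9606), (9606, None), (None, None)])
    def test_differing_or_missing_taxids_ignored(self, taxes):
        (resolved,) = resolve_mappings([self._candidate(*taxes)])
        assert resolved.status == IGNORED

    def test_planted_cross_species_candidates_are_counted_out(self):
        """Seven of ten candidates planted cross-species leaves three kept."""
        candidates = [self._candidate(9606, 9606) for _ in range(3)] + [
            self._candidate(9606, 10090) for _ in range(7)
        ]
        resolved = resolve_mappings(candidates)
        assert sum(m.status == KEPT for m in resolved) == 3
        assert sum(m.status == IGNORED for m in resolved) == 7

    def test_output_order_is_stable(self):
        candidates = [self._candidate(9606, 9606), self._candidate(9606, 10090)]
        resolved = resolve_mappings(candidates)
        assert [(m.left, m.right) for m in resolved] == [
            (m.left, m.right) for m in candidates
        ]


class TestMergeEntities:
    def test_table1_rows_merge_to_six_and_eight_synonyms(self, table1_records):
        result = integrate(table1_records)
        by_hub = {e.hub_accession: e for e in result.entities}
        ppp = by_hub["P0A0001"]
        znt = by_hub["P0A0002"]
        assert len(ppp.synonyms) == 6
        assert len(znt.synonyms) == 8
        assert ppp.primary_name == "PPP2R3 L"
        assert znt.primary_name == "Zinc transporter 10"

    @pytest.mark.parametrize("seed", range(5))
    def test_dedup_equals_brute_force_distinct_normalized_forms(self, seed):
        """Per entity, |synonyms| is the count of distinct normalized forms
        over its contributing records."""
        truth = generate(FixtureSpec(seed=seed), None)
        result = integrate(truth.records)
        expected = {e["hub_accession"]: set(e["synonyms_normalized"]) for e in truth.entities}
        got = {e.hub_accession: set(e.synonyms_normalized) for e in result.entities}
        assert got == expected

    def test_merge_is_idempotent_on_its_own_output(self, table1_records):
        entities = integrate(table1_records).entities
        assert merge_entities(list(entities)) == list(entities)

    def test_merge_is_order_insensitive(self):
        truth = generate(FixtureSpec(seed=42), None)
        result_a = integrate(truth.records)
        shuffled = {
            source: random.Random(1).sample(records, len(records))
            for source, records in truth.records.items()
        }
        result_b = integrate(shuffled)
        assert result_a.entities == result_b.entities

    def test_adding_a_source_never_shrinks_synonym_sets(self):
        """Monotone union: a third source can only grow each entity's set."""
        truth = generate(FixtureSpec(seed=7, unlinked_fraction=0.0), None)
        partial = dict(truth.records)
        partial[Source.NCBIGENE] = []
        before = {
            e.hub_accession: set(e.synonyms_normalized)
            for e in integrate(partial).entities
        }
        after = {
            e.hub_accession: set(e.synonyms_normalized)
            for e in integrate(truth.records).entities
        }
        for hub, names in before.items():
            assert names <= after[hub]

    def test_absent_taxid_record_merges_via_hard_link(self):
        """An id-linked interactor without species still joins its hub."""
        up = build_uniprot_record("P1", 9606, recommended_name="ABC", gene_id="5")
        bg = build_biogrid_record("1", None, short_label="DEF", uniprot_accession="P1")
        result = integrate(_records_by_source(up, bg))
        (entity,) = result.entities
        assert entity.hub_accession == "P1"
        assert entity.synonyms_normalized == {"abc", "def"}
        assert entity.tax_id == 9606

    def test_species_inconsistent_link_is_dropped(self):
        """A cross-species identifier link must not pool synonyms."""
        up = build_uniprot_record("P1", 9606, recommended_name="ABC")
        bg = build_biogrid_record("1", 10090, short_label="DEF", uniprot_accession="P1")
        result = integrate(_records_by_source(up, bg))
        by_hub = {e.hub_accession: e for e in result.entities}
        assert by_hub["P1"].synonyms_normalized == {"abc"}
        assert by_hub["biogrid:1"].synonyms_normalized == {"def"}
        assert by_hub["biogrid:1"].unlinked

    def test_gene_matching_k_entries_contributes_to_k_hubs(self):
        gene = build_ncbigene_record("5", 9606, symbol="G5", synonyms=["ALT"])
        entries = [
            build_uniprot_record("P1", 9606, recommended_name="A", gene_id="5"),
            build_uniprot_record("P2", 9606, recommended_name="B", gene_id="5"),
        ]
        result = integrate(_records_by_source(gene, *entries))
        by_hub = {e.hub_accession: e for e in result.entities}
        assert {"alt", "g5"} <= by_hub["P1"].synonyms_normalized
        assert {"alt", "g5"} <= by_hub["P2"].synonyms_normalized

    def test_unlinked_records_are_preserved_as_surrogates(self):
        bg = build_biogrid_record("9", 9606, short_label="Lone")
        result = integrate(_records_by_source(bg))
        (entity,) = result.entities
        assert entity.hub_accession == "biogrid:9"
        assert entity.unlinked


class TestComputeStats:
    def test_empty_entity_set_all_zero(self):
        stats = compute_stats([])
        assert (
            stats.n_entities,
            stats.n_species,
            stats.n_terms,
            stats.n_mappings_kept,
            stats.n_mappings_ignored,
        ) == (0, 0, 0, 0, 0)

    def test_two_human_entities_count_one_species(self, table1_records):
        result = integrate(table1_records)
        assert result.stats.n_entities == 2
        assert result.stats.n_species == 1
        assert result.stats.n_terms == 14  # 6 + 8 (entity, normalized synonym) pairs

    def test_kept_plus_ignored_equals_candidates(self):
        truth = generate(FixtureSpec(seed=5), None)
        result = integrate(truth.records)
        assert (
            result.stats.n_mappings_kept + result.stats.n_mappings_ignored
            == len(result.name_mappings)
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_stats_match_generator_bookkeeping(self, seed):
        truth = generate(FixtureSpec(seed=seed), None)
        result = integrate(truth.records)
        assert result.stats.n_entities == truth.stats["n_entities"]
        assert result.stats.n_species == truth.stats["n_species"]
        assert result.stats.n_terms == truth.stats["n_terms"]
        assert result.stats.n_mappings_kept == truth.stats["n_mappings_kept"]
        assert result.stats.n_mappings_ignored == truth.stats["n_mappings_ignored"]
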