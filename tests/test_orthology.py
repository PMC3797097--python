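import numpy as np
import pandas as pd
import pytest

from gidphylo.domain_annotation import DomainAnnotation
from gidphylo.orthology import (
    all_vs_all_search,
    assign_orthologue,
    best_hits,
    count_paralogues,
    classify_proteomes,
    e_value,
    bit_score,
    reciprocal_best_hits,
)
from gidphylo.pipeline_cli import evaluate_calls, pick_references
from gidphylo.seqio_align import AMINO_ACIDS, ProteinRecord


def _random_protein(rng, name, length=120):
    return ProteinRecord(
        name, "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    )


class TestSearch:
    def test_self_hit_ranks_first(self, rng):
        database = [_random_protein(rng, f"d{i}") for i in range(5)]
        query = ProteinRecord("q", database[2].sequence)
        hits = all_vs_all_search([query], database)
        assert hits.iloc[0]["subject"] == "d2"

    def test_evalue_decreasing_in_bitscore(self):
        assert e_value(50, 100, 1000) < e_value(40, 100, 1000)
        assert bit_score(200) > bit_score(100)

    def test_random_query_vs_unrelated_database_mostly_empty(self, rng):
        # shuffled-sequence null: at 1e-5 nearly all random pairs fail
        database = [_random_protein(rng, f"d{i}", 200) for i in range(10)]
        hits = 0
        for k in range(10):
            query = _random_protein(rng, f"q{k}", 200)
            hits += len(all_vs_all_search([query], database, evalue_cutoff=1e-5))
        assert hits <= 2

    def test_within_family_outranks_cross_family(self, benchmark):
        fam_a = benchmark.families["TWA1"].records
        fam_b = benchmark.families["Rmnd5"].records
        query = [fam_a[0]]
        hits = all_vs_all_search(query, fam_a[1:] + fam_b, evalue_cutoff=1.0)
        ranked = hits["subject"].tolist()
        a_ids = {r.id for r in fam_a[1:]}
        split = len(a_ids)
        assert set(ranked[:split]) == a_ids

    def test_empty_database_rejected(self, rng):
        with pytest.raises(ValueError):
            all_vs_all_search([_random_protein(rng, "q")], [])


class TestReciprocalBestHits:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["query", "subject", "bitscore", "evalue"])

    def test_mutual_best_pair(self):
        ab = self._hits([("a", "b", 50, 1e-20)])
        ba = self._hits([("b", "a", 50, 1e-20)])
        assert reciprocal_best_hits(ab, ba) == [("a", "b")]

    def test_non_mutual_best_excluded(self):
        ab = self._hits([("a", "b", 50, 1e-20)])
        ba = self._hits([("b", "a2", 60, 1e-30), ("b", "a", 50, 1e-20)])
        assert reciprocal_best_hits(ab, ba) == []

    def test_symmetric_under_table_swap(self):
        ab = self._hits([("a", "b", 50, 1e-20), ("a2", "b2", 40, 1e-10)])
        ba = self._hits([("b", "a", 50, 1e-20), ("b2", "a2", 40, 1e-10)])
        forward = set(reciprocal_best_hits(ab, ba))
        backward = {(y, x) for x, y in reciprocal_best_hits(ba, ab)}
        assert forward == backward

    def test_tie_breaks_lexicographically(self):
        ab = self._hits([("a", "b2", 50, 1e-20), ("a", "b1", 50, 1e-20)])
        ba = self._hits([("b1", "a", 50, 1e-20), ("b2", "a", 50, 1e-20)])
        assert reciprocal_best_hits(ab, ba) == [("a", "b1")]

    def test_lower_cutoff_never_adds_pairs(self, benchmark):
        records = [r for fam in benchmark.families.values() for r in fam.records][:12]
        half_a, half_b = records[:6], records[6:]
        pairs = {}
        for cutoff in (1e-5, 1e-15, 1e-30):
            ab = all_vs_all_search(half_a, half_b, evalue_cutoff=cutoff)
            ba = all_vs_all_search(half_b, half_a, evalue_cutoff=cutoff)
            pairs[cutoff] = set(reciprocal_best_hits(ab, ba))
        assert pairs[1e-30] <= pairs[1e-15] <= pairs[1e-5]


class TestAssignOrthologue:
    def _refs(self, rng):
        return {"TWA1": [_random_protein(rng, "ref_h", 120),
                         _random_protein(rng, "ref_y", 140)]}

    def test_reference_itself_is_orthologue(self, rng):
        refs = self._refs(rng)
        candidate = refs["TWA1"][0]
        anns = [DomainAnnotation(candidate.id, "LisH", 10, 44),
                DomainAnnotation(candidate.id, "CTLH", 50, 99),
                DomainAnnotation(candidate.id, "CRA", 105, 119)]
        call = assign_orthologue(candidate, "TWA1", True, anns, refs)
        assert call.verdict == "orthologue"
        assert call.architecture_ok and call.rbh_ok and call.length_ok

    def test_ring_without_lish_ctlh_rejected(self, rng):
        refs = self._refs(rng)
        candidate = _random_protein(rng, "cand", 120)
        anns = [DomainAnnotation("cand", "RING", 10, 59)]
        call = assign_orthologue(candidate, "TWA1", True, anns, refs)
        assert not call.architecture_ok and call.verdict == "rejected"

    def test_length_tolerance_window(self, rng):
        refs = self._refs(rng)
        short = _random_protein(rng, "tiny", 30)
        anns = [DomainAnnotation("tiny", "LisH", 1, 10),
                DomainAnnotation("tiny", "CTLH", 11, 25)]
        call = assign_orthologue(short, "TWA1", True, anns, refs,
                                 length_tolerance=0.4)
        assert not call.length_ok
        assert call.verdict == "orthologue"  # soft criterion by default
        hard = assign_orthologue(short, "TWA1", True, anns, refs,
                                 length_tolerance=0.4, length_hard=True)
        assert hard.verdict != "orthologue"

    def test_missing_exemplar_rejected(self, rng):
        with pytest.raises(KeyError):
            assign_orthologue(_random_protein(rng, "c"), "nonesuch", True, [], {})


class TestBenchmarkRecovery:
    def test_per_component_precision_and_recall(self, benchmark, benchmark_calls):
        truth = benchmark.truth_orthology()
        components = {comp for comp, _ in truth.values()}
        accepted = {
            c.candidate_id: c.component for c in benchmark_calls
            if c.verdict in ("orthologue", "paralogue")
        }
        for component in components:
            true_genes = {g for g, (comp, _) in truth.items() if comp == component}
            called = {g for g, comp in accepted.items() if comp == component}
            tp = len(true_genes & called)
            precision = tp / len(called) if called else 0.0
            recall = tp / len(true_genes) if true_genes else 1.0
            assert precision >= 0.9, component
            assert recall >= 0.9, component

    def test_identity_map_at_zero_duplication(self, benchmark, benchmark_calls):
        # lambda = mu = 0: every gene is its species' single orthologue
        summary = evaluate_calls(benchmark_calls, benchmark.truth_orthology())
        assert summary["precision"] == 1.0
        assert summary["recall"] == 1.0


class TestCountParalogues:
    def test_single_copy_counts_one(self, benchmark, benchmark_calls):
        counts = count_paralogues(benchmark_calls)
        present = benchmark.families["TWA1"].presence
        for species, is_present in present.items():
            assert counts.loc[species, "TWA1"] == (1 if is_present else 0)

    def test_species_without_family_counts_zero(self, benchmark, benchmark_calls):
        counts = count_paralogues(benchmark_calls)
        for species, group in benchmark.supergroups.items():
            if group != "Opisthokonta":
                assert counts.loc[species, "muskelin"] == 0

    def test_planted_duplication_counts_two(self):
        from gidphylo.synthetic_data import SimulationConfig, generate_benchmark

        config = SimulationConfig(
            seed=19, n_species=4, supergroups=("A", "B"),
            components=("TWA1", "Rmnd5"),
            duplication_rate={"TWA1": 8.0},
            restricted_components={},
        )
        bench = generate_benchmark(config)
        assert bench.families["TWA1"].n_duplications >= 1
        proteomes = bench.proteomes()
        references = pick_references(
            proteomes, bench.truth_orthology(), bench.supergroups
        )
        calls = classify_proteomes(proteomes, references, bench.true_annotations())
        counts = count_paralogues(calls)
        duplicated = [
            r.species for fam in bench.families.values() for r in fam.records
        ]
        assert counts["TWA1"].max() >= 2
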