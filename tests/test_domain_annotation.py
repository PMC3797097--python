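import io

import numpy as np
import pytest

from gidphylo.domain_annotation import (
    DomainAnnotation,
    Pssm,
    architecture_match,
    infer_missing_domain,
    parse_domain_table,
    scan_motif,
)


def ann(dom, start, end, protein="p1", source="annotated"):
    return DomainAnnotation(protein, dom, start, end, source=source)


class TestParseDomainTable:
    def test_simple_row(self):
        table = "p1\tLisH\t10\t44\t1e-8\n"
        result = parse_domain_table(io.StringIO(table))
        assert result == [DomainAnnotation("p1", "LisH", 10, 44, 1e-8)]

    def test_interpro_ids_mapped_and_unknown_kept_as_other(self):
        table = "p1\tIPR006594\t10\t44\t1e-8\np1\tIPR999999\t60\t90\t1e-4\n"
        result = parse_domain_table(io.StringIO(table))
        assert [a.domain_type for a in result] == ["LisH", "other"]

    def test_unsorted_rows_sorted_by_start(self):
        table = "p1\tCTLH\t50\t99\t1\np1\tLisH\t10\t44\t1\n"
        starts = [a.start for a in parse_domain_table(io.StringIO(table))]
        assert starts == [10, 50]

    def test_invalid_rows_listed(self):
        table = "p1\tLisH\t44\t10\t1\n"
        with pytest.raises(ValueError, match="p1 LisH 44-10"):
            parse_domain_table(io.StringIO(table))

    def test_coordinates_beyond_sequence_rejected(self):
        table = "p1\tLisH\t10\t44\t1\n"
        with pytest.raises(ValueError, match="length 40"):
            parse_domain_table(io.StringIO(table), sequence_lengths={"p1": 40})

    def test_synthetic_table_matches_truth(self, benchmark, tmp_path):
        from gidphylo.synthetic_data import emit_benchmark

        bench = emit_benchmark(benchmark.config, tmp_path / "bench")
        parsed = parse_domain_table(tmp_path / "bench" / "domains.tsv")
        truth = {
            (a.protein_id, a.domain_type, a.start, a.end)
            for anns in bench.true_annotations().values() for a in anns
        }
        assert {(a.protein_id, a.domain_type, a.start, a.end) for a in parsed} == truth


class TestInferMissingDomain:
    def test_lish_window_before_ctlh(self):
        result = infer_missing_domain([ann("CTLH", 101, 150)], 300)
        lish = next(a for a in result if a.domain_type == "LisH")
        assert (lish.start, lish.end) == (51, 100)
        assert lish.source == "inferred_window"

    def test_ctlh_window_after_lish(self):
        result = infer_missing_domain([ann("LisH", 10, 44)], 300)
        ctlh = next(a for a in result if a.domain_type == "CTLH")
        assert (ctlh.start, ctlh.end) == (45, 114)

    def test_window_clipped_at_n_terminus(self):
        result = infer_missing_domain([ann("CTLH", 20, 70)], 300)
        lish = next(a for a in result if a.domain_type == "LisH")
        assert (lish.start, lish.end) == (1, 19)

    def test_window_clipped_at_c_terminus(self):
        result = infer_missing_domain([ann("LisH", 260, 294)], 300)
        ctlh = next(a for a in result if a.domain_type == "CTLH")
        assert (ctlh.start, ctlh.end) == (295, 300)

    def test_window_truncated_at_neighbour(self):
        result = infer_missing_domain(
            [ann("RING", 30, 60), ann("CTLH", 101, 150)], 300
        )
        lish = next(a for a in result if a.domain_type == "LisH")
        assert lish.start == 61  # clipped at the RING's end

    def test_collapsed_window_adds_nothing(self):
        with pytest.warns(UserWarning, match="collapsed"):
            result = infer_missing_domain([ann("CTLH", 1, 50)], 300)
        assert [a.domain_type for a in result] == ["CTLH"]

    def test_both_or_neither_is_noop_with_warning(self):
        anns = [ann("LisH", 10, 44), ann("CTLH", 50, 99)]
        assert infer_missing_domain(anns, 300) == sorted(anns, key=lambda a: a.start)
        with pytest.warns(UserWarning):
            assert infer_missing_domain([ann("RING", 10, 50)], 300) == [ann("RING", 10, 50)]

    def test_idempotent(self):
        once = infer_missing_domain([ann("CTLH", 101, 150)], 300)
        assert infer_missing_domain(once, 300) == once


class TestScanMotif:
    def test_consensus_hit_is_maximal(self, rng):
        training = ["MKVLITAWC"] * 10
        pssm = Pssm.from_sequences(training, "LisH")
        seq = "GGGG" + pssm.consensus + "GGGG"
        hits = scan_motif(seq, pssm, threshold=5.0)
        assert hits and hits[0].start == 5
        assert hits[0].score == pytest.approx(
            pssm.score_window(pssm.consensus)
        )

    def test_threshold_above_maximum_yields_nothing(self, rng):
        pssm = Pssm.from_sequences(["MKVLITAWC"] * 10)
        assert scan_motif("MKVLITAWCMKVLITAWC", pssm, pssm.max_score + 1) == []

    def test_pssm_longer_than_sequence_warns_empty(self):
        pssm = Pssm.from_sequences(["MKVLITAWC"] * 3)
        with pytest.warns(UserWarning):
            assert scan_motif("MKV", pssm, 0.0) == []

    def test_planted_motif_recall(self, rng):
        # plant an invariant 12-mer in 30 random 120-mers: recall >= 0.9
        from gidphylo.seqio_align import AMINO_ACIDS

        motif = "MKVLITAWCHEY"
        pssm = Pssm.from_sequences([motif] * 20, "LisH")
        found = 0
        for _ in range(30):
            backbone = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=120))
            offset = int(rng.integers(0, 108))
            seq = backbone[:offset] + motif + backbone[offset + 12 :]
            hits = scan_motif(seq, pssm, threshold=0.5 * pssm.max_score)
            if any(h.start == offset + 1 for h in hits):
                found += 1
        assert found / 30 >= 0.9


class TestArchitectureMatch:
    def test_full_rmnd5_architecture(self):
        anns = [ann("LisH", 10, 44), ann("CTLH", 50, 99),
                ann("CRA", 110, 209), ann("RING", 220, 269)]
        result = architecture_match(anns, "Rmnd5")
        assert result.matched and result.matched_domains == 4

    def test_inverted_order_rejected(self):
        anns = [ann("CTLH", 10, 59), ann("LisH", 70, 104)]
        assert not architecture_match(anns, "Rmnd5").matched

    def test_single_domain_below_two_domain_limit(self):
        # a lone Rmnd5-like RING without LisH/CTLH is not accepted
        assert not architecture_match([ann("RING", 10, 59)], "Rmnd5").matched

    def test_extra_domains_ignored(self):
        anns = [ann("LisH", 10, 44), ann("WD40", 50, 89), ann("CTLH", 100, 149)]
        assert architecture_match(anns, "Rmnd5").matched

    def test_monotone_under_non_template_insertions(self):
        base = [ann("LisH", 10, 44), ann("CTLH", 50, 99)]
        extended = base + [ann("other", 150, 200)]
        assert architecture_match(base, "Rmnd5").matched
        assert architecture_match(extended, "Rmnd5").matched

    def test_unknown_template_rejected(self):
        with pytest.raises(KeyError):
            architecture_match([], "nonesuch")
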