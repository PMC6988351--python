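"""HSP dedup, exon chaining, translation and the homolog filters."""

import itertools
import random

import pytest

from conftest import make_hsp
from gobymine.chaining import (
    ChainingConfig,
    GeneModel,
    HomologFilter,
    chain_hsps,
    extract_and_translate,
    filter_models,
    filter_orthologs,
    select_best_per_locus,
)
from gobymine.io import GenomicInterval, SequenceRecord
from oracles import greedy_partitions, joinable_oracle

CFG = ChainingConfig()


class TestSelectBestPerLocus:
    def test_overlap_keeps_higher_score(self):
        a = make_hsp(s_start=101, s_end=400, bit_score=200)
        b = make_hsp(query_id="q2", s_start=301, s_end=600, bit_score=150)
        kept = select_best_per_locus([a, b], CFG)
        assert kept == [a]

    def test_disjoint_both_kept(self):
        a = make_hsp(s_start=101, s_end=400)
        b = make_hsp(query_id="q2", s_start=501, s_end=800)
        assert len(select_best_per_locus([a, b], CFG)) == 2

    def test_evalue_gate_applied_first(self):
        weak = make_hsp(evalue=1e-10)
        assert select_best_per_locus([weak], CFG) == []

    def test_empty_input(self):
        assert select_best_per_locus([], CFG) == []

    def test_tiebreak_exhaustive_permutations(self):
        # equal bit scores on overlapping hits: lower evalue wins, then
        # lexicographically smaller query id
        a = make_hsp(query_id="qa", evalue=1e-70, bit_score=200)
        b = make_hsp(query_id="qb", evalue=1e-60, bit_score=200)
        c = make_hsp(query_id="qc", evalue=1e-70, bit_score=200)
        for perm in itertools.permutations([a, b, c]):
            assert select_best_per_locus(list(perm), CFG) == [a]

    def test_idempotent_and_nonoverlapping_on_random_inputs(self, rng):
        for _ in range(100):
            hsps = [
                make_hsp(
                    query_id=f"q{rng.randrange(3)}",
                    subject_id=f"ctg{rng.randrange(2)}",
                    s_start=(s := rng.randrange(1, 3000)),
                    s_end=s + rng.randrange(30, 600),
                    bit_score=rng.randrange(50, 300),
                    evalue=10 ** -rng.randrange(51, 90),
                )
                for _ in range(rng.randrange(0, 12))
            ]
            kept = select_best_per_locus(hsps, CFG)
            # survivors are pairwise non-overlapping
            for x, y in itertools.combinations(kept, 2):
                assert not x.interval.overlaps(y.interval)
            # every dropped hit overlaps a survivor (or failed the gate)
            for h in hsps:
                if h in kept:
                    continue
                assert h.evalue > CFG.max_evalue or any(
                    h.interval.overlaps(k.interval) for k in kept
                )
            assert select_best_per_locus(kept, CFG) == kept


class TestChainHsps:
    def test_two_exon_join(self):
        a = make_hsp(q_start=1, q_end=100, s_start=5001, s_end=5300)
        b = make_hsp(q_start=95, q_end=180, s_start=9001, s_end=9258)
        (model,) = chain_hsps([a, b], CFG)
        assert len(model.exons) == 2

    def test_gap_at_bound_not_joined(self):
        # distance must be strictly below 10 kb
        a = make_hsp(q_start=1, q_end=100, s_start=5001, s_end=5300)
        b = make_hsp(q_start=95, q_end=180, s_start=15301, s_end=15558)
        assert len(chain_hsps([a, b], CFG)) == 2

    @pytest.mark.parametrize(
        "gap,expected_models", [(9_999, 1), (10_000, 2), (10_001, 2)]
    )
    def test_gap_boundary(self, gap, expected_models):
        a = make_hsp(q_start=1, q_end=100, s_start=5001, s_end=5300)
        b = make_hsp(q_start=101, q_end=180, s_start=5301 + gap, s_end=5540 + gap)
        assert len(chain_hsps([a, b], CFG)) == expected_models

    @pytest.mark.parametrize("overlap,expected_models", [(15, 1), (16, 2)])
    def test_query_overlap_boundary(self, overlap, expected_models):
        a = make_hsp(q_start=1, q_end=100, s_start=5001, s_end=5300)
        b = make_hsp(q_start=101 - overlap, q_end=180, s_start=9001, s_end=9240)
        assert len(chain_hsps([a, b], CFG)) == expected_models

    def test_minus_strand_transcription_order(self):
        # minus strand: transcription runs from high to low coordinates
        a = make_hsp(q_start=1, q_end=100, s_start=9300, s_end=9001)
        b = make_hsp(q_start=95, q_end=180, s_start=5300, s_end=5001)
        (model,) = chain_hsps([a, b], CFG)
        assert model.strand == "-"
        assert [iv.start for iv in model.exons] == [9000, 5000]

    def test_different_queries_not_merged(self):
        a = make_hsp(query_id="q1", q_start=1, q_end=100, s_start=5001, s_end=5300)
        b = make_hsp(query_id="q2", q_start=101, q_end=180, s_start=9001, s_end=9240)
        assert len(chain_hsps([a, b], CFG)) == 2

    def test_partition_property(self, rng):
        for _ in range(50):
            hsps = _random_dedup_hsps(rng)
            models = chain_hsps(hsps, CFG)
            assigned = [h for m in models for h in m.source_hsps]
            assert len(assigned) == len(hsps)
            assert {id(h) for h in assigned} == {id(h) for h in hsps}
            for m in models:
                for prev, nxt in zip(m.source_hsps, m.source_hsps[1:]):
                    assert joinable_oracle(
                        prev, nxt, m.strand, CFG.max_query_overlap_aa,
                        CFG.max_genomic_gap_bp,
                    )

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            hsps = _random_dedup_hsps(rng, max_n=12)
            models = chain_hsps(hsps, CFG)
            got = {}
            for m in models:
                key = (m.contig, m.strand, m.query_id)
                got.setdefault(key, []).append(
                    [h.interval for h in m.source_hsps]
                )
            groups = {}
            for h in hsps:
                groups.setdefault((h.subject_id, h.strand, h.query_id), []).append(h)
            for key, members in groups.items():
                strand = key[1]
                ordered = sorted(
                    members, key=lambda h: h.interval.start, reverse=strand == "-"
                )
                expected = greedy_partitions(
                    ordered, strand, CFG.max_query_overlap_aa, CFG.max_genomic_gap_bp
                )
                exp_sets = sorted([h.interval for h in run] for run in expected)
                assert sorted(got[key]) == exp_sets


def _random_dedup_hsps(rng, max_n=10):
    """Random genomically disjoint hits (the post-dedup precondition)."""
    hsps = []
    cursor = {}
    for _ in range(rng.randrange(1, max_n + 1)):
        contig = f"ctg{rng.randrange(2)}"
        strand = rng.choice("+-")
        query = f"q{rng.randrange(2)}"
        start = cursor.get(contig, 1) + rng.randrange(0, 15000)
        aa = rng.randrange(20, 150)
        end = start + 3 * aa - 1
        cursor[contig] = end + 1
        q_start = rng.randrange(1, 300)
        q_end = q_start + aa - 1
        if strand == "+":
            s_start, s_end = start, end
        else:
            s_start, s_end = end, start
        hsps.append(
            make_hsp(
                query_id=query, subject_id=contig, q_start=q_start, q_end=q_end,
                s_start=s_start, s_end=s_end,
                bit_score=rng.randrange(100, 300),
            )
        )
    return hsps


class TestExtractAndTranslate:
    def _genome(self, seq, name="ctg1"):
        return [SequenceRecord(name, seq, alphabet="dna")]

    def test_canonical_orf(self):
        model = GeneModel("m", "ctg1", "+", [GenomicInterval("ctg1", 0, 9)])
        out = extract_and_translate(model, self._genome("ATGGCCTAA"))
        assert out.protein == "MA" and out.flags == set()

    def test_minus_strand_symmetry(self):
        from gobymine.simulate import _revcomp

        seq = _revcomp("ATGGCCTAA")
        model = GeneModel("m", "ctg1", "-", [GenomicInterval("ctg1", 0, 9, "-")])
        out = extract_and_translate(model, self._genome(seq))
        assert out.protein == "MA"

    def test_internal_stop_flagged(self):
        model = GeneModel("m", "ctg1", "+", [GenomicInterval("ctg1", 0, 12)])
        out = extract_and_translate(model, self._genome("ATGTAAGCCTAA"))
        assert "internal_stop" in out.flags

    def test_multi_exon_concatenation(self):
        # ATG GCC | intron | AAA TAA
        seq = "ATGGCC" + "G" * 50 + "AAATAA"
        model = GeneModel(
            "m", "ctg1", "+",
            [GenomicInterval("ctg1", 0, 6), GenomicInterval("ctg1", 56, 62)],
        )
        out = extract_and_translate(model, self._genome(seq))
        assert out.cds == "ATGGCCAAATAA" and out.protein == "MAK"

    def test_no_atg_uses_frame0_stretch(self):
        model = GeneModel("m", "ctg1", "+", [GenomicInterval("ctg1", 0, 9)])
        out = extract_and_translate(model, self._genome("GGGCCCAAA"))
        assert out.protein == "GPK"
        assert "no_start" in out.flags

    def test_missing_contig_and_bounds(self):
        model = GeneModel("m", "ctgX", "+", [GenomicInterval("ctgX", 0, 9)])
        with pytest.raises(KeyError):
            extract_and_translate(model, self._genome("ATGGCCTAA"))
        model2 = GeneModel("m", "ctg1", "+", [GenomicInterval("ctg1", 0, 99)])
        with pytest.raises(ValueError, match="beyond end"):
            extract_and_translate(model2, self._genome("ATGGCCTAA"))


class TestFilterModels:
    def _model(self, protein):
        return GeneModel(
            "m", "c", "+", [GenomicInterval("c", 0, 3 * len(protein))],
            protein=protein,
        )

    @pytest.mark.parametrize("length,kept", [(249, 0), (250, 1), (251, 1)])
    def test_length_boundary(self, length, kept):
        models = [self._model("M" * length)]
        assert len(filter_models(models, CFG)) == kept

    def test_untranslated_model_rejected(self):
        m = GeneModel("m", "c", "+", [GenomicInterval("c", 0, 30)])
        with pytest.raises(ValueError, match="extract_and_translate"):
            filter_models([m], CFG)

    def test_empty(self):
        assert filter_models([], CFG) == []


class TestFilterOrthologs:
    FLT = HomologFilter()

    def test_coverage_exactly_at_bound_retained(self):
        h = make_hsp(q_start=1, q_end=70, pct_identity=40.0, evalue=1e-21)
        assert filter_orthologs([h], {"q1": 100}, self.FLT) == [h]

    def test_identity_below_bound_removed(self):
        h = make_hsp(q_start=1, q_end=70, pct_identity=39.9, evalue=1e-21)
        assert filter_orthologs([h], {"q1": 100}, self.FLT) == []

    def test_evalue_bound_is_strict(self):
        h = make_hsp(q_start=1, q_end=70, pct_identity=50.0, evalue=1e-20)
        assert filter_orthologs([h], {"q1": 100}, self.FLT) == []

    def test_missing_query_length_names_query(self):
        h = make_hsp(query_id="qz")
        with pytest.raises(KeyError, match="qz"):
            filter_orthologs([h], {}, self.FLT)
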