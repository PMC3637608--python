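"""Alignment, homology-region, span and structure tests.

The global aligner is checked against two independent oracles: an explicit
enumeration of every possible alignment (scored from scratch) for short
strings, and Biopython's PairwiseAligner score under identical scoring for
longer random pairs.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paralogasym.align import (
    AlignScoring,
    HomologyRegion,
    PairNotHomologousError,
    Structure,
    classify_structure,
    duplication_span,
    find_homology_region,
    global_align,
)
from paralogasym.seq_io import Alphabet, GeneAnnotation, SequenceRecord


# ---------------------------------------------------------------------------
# enumeration oracle: score every alignment of a and b


def _all_alignment_scores(a, b, match=1.0, mismatch=-1.0, go=-4.0, ge=-1.0):
    """Yield the score of every distinct global alignment (op sequences)."""

    def rec(i, j, ops):
        if i == len(a) and j == len(b):
            yield _score_ops(a, b, ops, match, mismatch, go, ge)
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, ops + "M")
        if i < len(a):
            yield from rec(i + 1, j, ops + "X")  # gap in b
        if j < len(b):
            yield from rec(i, j + 1, ops + "Y")  # gap in a

    yield from rec(0, 0, "")


def _score_ops(a, b, ops, match, mismatch, go, ge):
    score = 0.0
    i = j = 0
    prev = None
    for op in ops:
        if op == "M":
            score += match if a[i] == b[j] else mismatch
            i += 1
            j += 1
        else:
            score += ge if op == prev else go
            if op == "X":
                i += 1
            else:
                j += 1
        prev = op
    return score


class TestGlobalAlign:
    def test_identical_sequences(self):
        al = global_align("ACGT", "ACGT")
        assert al.aligned_a == al.aligned_b == "ACGT"
        assert al.score == 4.0

    def test_single_gap_scoring(self):
        # 3 matches + one opened gap of length 1
        al = global_align("ACGT", "AGT")
        assert al.score == 3 * 1.0 + (-4.0)
        assert al.score == max(_all_alignment_scores("ACGT", "AGT"))
        assert al.aligned_a.replace("-", "") == "ACGT"
        assert al.aligned_b.replace("-", "") == "AGT"

    def test_all_mismatch_preferred_over_gaps(self):
        al = global_align("AAAA", "TTTT")
        assert al.aligned_a == "AAAA" and al.aligned_b == "TTTT"
        assert al.score == -4.0
        assert al.score == max(_all_alignment_scores("AAAA", "TTTT"))

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nts = "ACGT"
        a = "".join(rng.choice(list(nts), size=rng.integers(1, 8)))
        b = "".join(rng.choice(list(nts), size=rng.integers(1, 8)))
        assert global_align(a, b).score == max(_all_alignment_scores(a, b))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.data())
    def test_score_matches_biopython_and_gaps_recover_inputs(self, data):
        from Bio import Align as BioAlign

        a = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=40))
        b = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=40))
        al = global_align(a, b)
        assert al.aligned_a.replace("-", "") == a
        assert al.aligned_b.replace("-", "") == b
        aligner = BioAlign.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -4.0
        aligner.extend_gap_score = -1.0
        assert al.score == pytest.approx(aligner.score(a, b))

    def test_determinism(self):
        a, b = "ACGTACGTAC", "ACGACGTC"
        first = global_align(a, b)
        for _ in range(3):
            again = global_align(a, b)
            assert (again.aligned_a, again.aligned_b) == (first.aligned_a, first.aligned_b)

    def test_amino_acid_scoring_uses_blosum(self):
        al = global_align(
            SequenceRecord("x", "MKW", Alphabet.AMINO_ACID),
            SequenceRecord("y", "MKW", Alphabet.AMINO_ACID),
        )
        assert al.score == 5 + 5 + 11  # BLOSUM62 diagonal for M, K, W

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError, match="mixed alphabets"):
            global_align(
                SequenceRecord("x", "ACGT", Alphabet.NUCLEOTIDE),
                SequenceRecord("y", "MKW", Alphabet.AMINO_ACID),
            )

    def test_empty_and_gapped_inputs_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")
        with pytest.raises(ValueError):
            global_align("AC-GT", "ACGT")


# ---------------------------------------------------------------------------
# homology region


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, seq, p):
    out = []
    for c in seq:
        if rng.random() < p:
            out.append(rng.choice([x for x in "ACGT" if x != c]))
        else:
            out.append(c)
    return "".join(out)


class TestHomologyRegion:
    def test_identical_contexts_flank_exhausted(self, rng):
        seq = _random_seq(rng, 3000)
        region = find_homology_region(seq, seq, a_orf=(1000, 2000))
        assert region.a_start == 0 and region.a_end == 3000
        assert region.b_start == 0 and region.b_end == 3000
        assert not region.terminated_5prime and not region.terminated_3prime

    def test_embedded_tract_recovered_within_window(self, rng):
        tract = _random_seq(rng, 1500)
        a = _random_seq(rng, 1800) + tract + _random_seq(rng, 1800)
        b = _random_seq(rng, 1500) + _mutate(rng, tract, 0.05) + _random_seq(rng, 1500)
        region = find_homology_region(a, b, a_orf=(1900, 3200))
        assert abs(region.a_start - 1800) <= 100
        assert abs(region.a_end - 3300) <= 100
        assert abs(region.b_start - 1500) <= 100
        assert abs(region.b_end - 3000) <= 100
        assert region.terminated_5prime and region.terminated_3prime

    def test_sub_kilobase_gap_does_not_terminate(self, rng):
        # homology resumes 800 bp after a non-homologous insert: still one region
        t1, t2 = _random_seq(rng, 1200), _random_seq(rng, 1200)
        a = _random_seq(rng, 1500) + t1 + _random_seq(rng, 800) + t2 + _random_seq(rng, 1500)
        b = _random_seq(rng, 1200) + t1 + _random_seq(rng, 760) + t2 + _random_seq(rng, 1200)
        region = find_homology_region(a, b, a_orf=(1500, 2700))
        assert region.a_end >= 1500 + 1200 + 800 + 1100  # includes the resumed tract
        assert region.terminated_3prime

    def test_supra_kilobase_gap_terminates(self, rng):
        t1, t2 = _random_seq(rng, 1200), _random_seq(rng, 1200)
        a = _random_seq(rng, 1500) + t1 + _random_seq(rng, 1400) + t2 + _random_seq(rng, 1500)
        b = _random_seq(rng, 1200) + t1 + _random_seq(rng, 1400) + t2 + _random_seq(rng, 1200)
        region = find_homology_region(a, b, a_orf=(1500, 2700))
        assert region.a_end <= 1500 + 1200 + 100
        assert region.terminated_3prime

    def test_unrelated_sequences_raise(self, rng):
        with pytest.raises(PairNotHomologousError):
            find_homology_region(_random_seq(rng, 2000), _random_seq(rng, 2000))

    def test_span_monotone_in_true_tract_length(self, rng):
        spans = []
        base = _random_seq(rng, 4000)
        for tract_len in (500, 1000, 2000):
            tract = base[:tract_len]
            a = _random_seq(rng, 1500) + tract + _random_seq(rng, 1500)
            b = _random_seq(rng, 1500) + _mutate(rng, tract, 0.03) + _random_seq(rng, 1500)
            region = find_homology_region(a, b, a_orf=(1500, 1500 + tract_len))
            spans.append(duplication_span(region).span)
        assert spans == sorted(spans)


class TestDuplicationSpan:
    def test_full_homology_identical_lengths(self):
        r = HomologyRegion(0, 2000, 0, 2000, True, True)
        s = duplication_span(r)
        assert s.span_a == s.span_b == s.span == 2000

    def test_deletion_in_one_copy_takes_lower_span(self, rng):
        # B carries a 50 bp deletion inside the tract: the conservative
        # (smaller) of the two per-paralog spans is reported
        tract = _random_seq(rng, 2000)
        b_tract = tract[:1000] + tract[1050:]
        a = _random_seq(rng, 1500) + tract + _random_seq(rng, 1500)
        b = _random_seq(rng, 1500) + b_tract + _random_seq(rng, 1500)
        region = find_homology_region(a, b, a_orf=(1500, 3500))
        s = duplication_span(region)
        assert s.span == min(s.span_a, s.span_b)
        assert abs(s.span_a - 2000) <= 100
        assert abs(s.span_b - 1950) <= 100

    def test_min_rule_invariant(self):
        r = HomologyRegion(10, 500, 20, 400, True, False)
        s = duplication_span(r)
        assert s.span <= s.span_a and s.span <= s.span_b


# ---------------------------------------------------------------------------
# structural classification


def _ann(gene_id, exons, start=0, end=None):
    end = end or max(e for _, e in exons)
    return GeneAnnotation(gene_id, "I", "+", start, end, tuple(exons))


class TestClassifyStructure:
    REGION = HomologyRegion(0, 1000, 0, 1000, True, True)

    def test_all_exons_inside_is_complete(self):
        a = _ann("a", [(0, 300), (400, 900)])
        b = _ann("b", [(0, 300), (400, 800)])
        res = classify_structure(a, b, self.REGION)
        assert res.value is Structure.COMPLETE
        assert res.unique_exons_a == res.unique_exons_b == 0

    def test_one_sided_unique_exon_is_partial(self):
        a = _ann("a", [(0, 300), (400, 900), (1200, 1500)])
        b = _ann("b", [(0, 300), (400, 900)])
        res = classify_structure(a, b, self.REGION)
        assert res.value is Structure.PARTIAL
        assert res.unique_exons_a == 1

    def test_both_sided_unique_exons_is_chimeric(self):
        a = _ann("a", [(0, 300), (1200, 1500)])
        b = _ann("b", [(0, 300), (1100, 1400)])
        res = classify_structure(a, b, self.REGION)
        assert res.value is Structure.CHIMERIC

    def test_half_overlap_threshold(self):
        # exon 60% inside bounds is shared; 40% inside is unique
        a_in = _ann("a", [(0, 300), (900, 1150)])   # 250 bp exon, 100 inside: unique
        b = _ann("b", [(0, 300)])
        assert classify_structure(a_in, b, self.REGION).value is Structure.PARTIAL
        a_out = _ann("a", [(0, 300), (850, 1100)])  # 250 bp exon, 150 inside: shared
        assert classify_structure(a_out, b, self.REGION).value is Structure.COMPLETE

    def test_label_swap_invariance(self):
        a = _ann("a", [(0, 300), (1200, 1500)])
        b = _ann("b", [(0, 300), (400, 900)])
        ab = classify_structure(a, b, self.REGION)
        region_swapped = self.REGION  # symmetric bounds
        ba = classify_structure(b, a, region_swapped)
        assert ab.value == ba.value == Structure.PARTIAL

    def test_offsets_map_chromosome_to_context(self):
        a = _ann("a", [(10_000, 10_300)], start=10_000, end=10_300)
        b = _ann("b", [(0, 300)])
        res = classify_structure(a, b, self.REGION, a_offset=10_000)
        assert res.value is Structure.COMPLETE
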