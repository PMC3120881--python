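"""Coordinate arithmetic, splicing and conceptual translation."""

import pytest
from hypothesis import given, settings, strategies as st

from asmannot.core import (
    GenomeAssembly,
    GenomicInterval,
    Transcript,
    conceptual_translation,
    interval_length,
    overlap_length,
    revcomp,
    splice,
)
from oracles import naive_translate


@pytest.mark.parametrize(
    "start,end,expected",
    [
        (49_071_505, 49_071_619, 115),  # a printed 115-bp exon, 1-based inclusive
        (5, 5, 1),
        (45_880_245, 45_886_101, 5_857),
    ],
)
def test_interval_length_is_one_based_inclusive(start, end, expected):
    assert interval_length(GenomicInterval("chr", start, end)) == expected


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((1, 100), (200, 300), 0),
        ((1, 100), (51, 150), 50),
        ((1, 100), (1, 100), 100),
        ((10, 20), (20, 30), 1),
    ],
)
def test_overlap_length(a, b, expected):
    ia = GenomicInterval("chr1", *a)
    ib = GenomicInterval("chr1", *b)
    assert overlap_length(ia, ib) == expected
    assert overlap_length(ib, ia) == expected


def test_overlap_zero_across_chromosomes():
    a = GenomicInterval("chr1", 1, 100)
    b = GenomicInterval("chr2", 1, 100)
    assert overlap_length(a, b) == 0


@settings(max_examples=100, deadline=None)
@given(
    s1=st.integers(1, 1000), l1=st.integers(1, 500),
    s2=st.integers(1, 1000), l2=st.integers(1, 500),
)
def test_overlap_properties(s1, l1, s2, l2):
    a = GenomicInterval("c", s1, s1 + l1 - 1)
    b = GenomicInterval("c", s2, s2 + l2 - 1)
    ov = overlap_length(a, b)
    assert ov == overlap_length(b, a)
    assert 0 <= ov <= min(interval_length(a), interval_length(b))


def test_invalid_intervals_rejected():
    with pytest.raises(ValueError):
        GenomicInterval("c", 0, 5)
    with pytest.raises(ValueError):
        GenomicInterval("c", 10, 5)
    with pytest.raises(ValueError):
        GenomicInterval("c", 1, 5, strand="x")


def test_splice_single_exon_forward(toy_genome):
    t = Transcript("t", [GenomicInterval("chr1", 3, 8, "+")])
    assert splice(t, toy_genome) == "GTACGT"


def test_splice_two_exons_reverse_strand_by_hand(toy_genome):
    # exons 3-7 and 15-19 on '-': concatenation then whole reverse complement
    t = Transcript(
        "t",
        [GenomicInterval("chr1", 3, 7, "-"), GenomicInterval("chr1", 15, 19, "-")],
    )
    concat = toy_genome.placed["chr1"][2:7] + toy_genome.placed["chr1"][14:19]
    assert splice(t, toy_genome) == revcomp(concat)


def test_splice_length_equals_sum_of_exons(tiny_bundle):
    for t in tiny_bundle.annot_a:
        assert len(splice(t, tiny_bundle.genome_a)) == t.spliced_length


def test_splice_matches_generated_model_mrnas(tiny_bundle):
    for t in tiny_bundle.annot_a:
        assert splice(t, tiny_bundle.genome_a) == tiny_bundle.mrnas[t.id]


def test_splice_out_of_bounds_exon_raises(toy_genome):
    t = Transcript("t", [GenomicInterval("chr1", 30, 99, "+")])
    with pytest.raises(ValueError):
        splice(t, toy_genome)


def _single_exon_gene(seq, cds):
    genome = GenomeAssembly("g", {"c": seq})
    t = Transcript("t", [GenomicInterval("c", 1, len(seq), "+")], cds=cds)
    return t, genome


def test_translation_standard_code():
    t, g = _single_exon_gene("ATGAAATAA", (1, 9))
    assert conceptual_translation(t, g).sequence == "MK"


def test_translation_frameshift_matches_naive_oracle():
    # 30-bp clean CDS, then delete one base mid-frame: read-through with
    # whatever stops the shifted frame produces, exactly as a codon walk says
    clean = "ATGGCTGAAACCCTTGGTCATCAAGGTTAA"
    shifted = clean[:10] + clean[11:] + "ACT"  # pad to keep length % 3 == 0
    t, g = _single_exon_gene(shifted, (1, len(shifted) // 3 * 3))
    assert conceptual_translation(t, g).sequence == naive_translate(shifted)


def test_translation_n_codons_become_x():
    t, g = _single_exon_gene("ATGANATAA", (1, 9))
    assert conceptual_translation(t, g).sequence == "MX"


def test_translation_requires_cds():
    t, g = _single_exon_gene("ATGAAATAA", None)
    with pytest.raises(ValueError):
        conceptual_translation(t, g)


def test_translation_length_invariant(tiny_bundle):
    for t in tiny_bundle.annot_a:
        prot = conceptual_translation(t, tiny_bundle.genome_a)
        s, e = t.cds
        assert len(prot.sequence) == (e - s + 1) // 3 - 1  # trailing stop dropped


def test_transcript_invariants_enforced():
    with pytest.raises(ValueError):  # overlapping exons
        Transcript("t", [GenomicInterval("c", 1, 10), GenomicInterval("c", 10, 20)])
    with pytest.raises(ValueError):  # zero-length intron
        Transcript("t", [GenomicInterval("c", 1, 10), GenomicInterval("c", 11, 20)])
    with pytest.raises(ValueError):  # CDS not divisible by 3
        Transcript("t", [GenomicInterval("c", 1, 30)], cds=(1, 10))


def test_genomic_position_round_trip(tiny_bundle):
    t = tiny_bundle.annot_a.transcripts[0]
    mrna = tiny_bundle.mrnas[t.id]
    g = tiny_bundle.genome_a
    for tpos in (1, 7, t.spliced_length):
        gpos = t.genomic_position(tpos)
        base = g.sequence(t.chrom)[gpos - 1]
        expected = mrna[tpos - 1] if t.strand == "+" else revcomp(mrna[tpos - 1])
        assert base == expected
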