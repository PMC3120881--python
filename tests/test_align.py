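"""Seeded spliced aligner: indexing, candidate windows, exon recovery,
filtering conventions and coverage curves."""

import re

import numpy as np
import pytest
import edlib

from asmannot.align import (
    AlignmentBlock,
    KmerIndex,
    SplicedAlignment,
    coverage_curve,
    filter_alignments,
    find_candidates,
    map_query,
    select_primary,
)
from asmannot.core import GenomeAssembly, GenomicInterval, revcomp


# --- k-mer index ---------------------------------------------------------


def test_index_counts_positions_on_toy_sequence():
    seq = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 bp
    idx = KmerIndex({"c": seq}, k=10)
    total = sum(len(v) for v in idx._table.values())
    assert total == 21  # 30 - 10 + 1


def test_index_skips_n_kmers():
    seq = "ACGTACGTACGTACGNACGTACGTACGTAC"
    idx = KmerIndex({"c": seq}, k=10)
    total = sum(len(v) for v in idx._table.values())
    assert total == 21 - 10  # every window covering the N is dropped


def test_index_lookup_absent_kmer_and_duplicates():
    rng = np.random.default_rng(0)
    core = "".join(rng.choice(list("ACGT"), size=1000))
    seq = core + "T" * 50 + core
    idx = KmerIndex({"c": seq}, k=20)
    assert idx.lookup("A" * 20) == []
    hits = idx.lookup(core[:20])
    assert len(hits) == 2


def test_index_k_floor():
    with pytest.raises(ValueError):
        KmerIndex({"c": "ACGTACGTACGT"}, k=4)


# --- candidate windows ---------------------------------------------------


def test_candidates_for_planted_mrna_cover_the_locus(tiny_bundle):
    idx = KmerIndex.from_assembly(tiny_bundle.genome_a, k=20)
    t = tiny_bundle.annot_a.transcripts[0]
    wins = find_candidates(tiny_bundle.mrnas[t.id], idx)
    hit = [
        w
        for w in wins
        if w.chrom == t.chrom and w.strand == t.strand and w.start <= t.start and w.end >= t.end
    ]
    assert hit


def test_candidates_empty_for_foreign_query(tiny_bundle):
    idx = KmerIndex.from_assembly(tiny_bundle.genome_a, k=20)
    rng = np.random.default_rng(99)
    query = "".join(rng.choice(list("ACGT"), size=500))
    assert find_candidates(query, idx) == []


def test_candidates_duplicate_locus_gives_two_windows():
    rng = np.random.default_rng(1)
    core = "".join(rng.choice(list("ACGT"), size=1000))
    filler = "".join(rng.choice(list("ACGT"), size=5000))
    genome = GenomeAssembly("g", {"c": filler + core + filler + core + filler})
    idx = KmerIndex.from_assembly(genome, k=20)
    wins = find_candidates(core[100:900], idx, cluster_gap=2000)
    assert len([w for w in wins if w.strand == "+"]) == 2


# --- spliced alignment round trips --------------------------------------


def test_round_trip_recovers_exact_exons(tiny_bundle):
    """For every planted, event-free gene the alignment reproduces the
    exon set boundary-exactly, strand-exactly, at identity/coverage 1."""
    idx = KmerIndex.from_assembly(tiny_bundle.genome_a, k=20)
    for t in tiny_bundle.annot_a:
        alns = map_query(t.id, tiny_bundle.mrnas[t.id], tiny_bundle.genome_a, idx)
        best = max(alns, key=lambda a: a.coverage)
        assert best.strand == t.strand
        assert best.identity == 1.0
        assert best.coverage == 1.0
        assert [(b.genome.start, b.genome.end) for b in best.blocks] == [
            (e.start, e.end) for e in t.exons
        ]


def test_missing_exon_reduces_coverage_by_exon_fraction():
    from asmannot.scenarios import gap_disrupted_exon_scenario

    bundle = gap_disrupted_exon_scenario(seed=11)
    t = bundle.annot_a.transcripts[0]
    mrna = bundle.mrnas[t.id]
    exon_len = len(bundle.annot_a[t.id].exons[2])
    idx = KmerIndex.from_assembly(bundle.genome_b, k=20)
    alns = map_query(t.id, mrna, bundle.genome_b, idx)
    best = max(alns, key=lambda a: a.coverage)
    expected = 1 - exon_len / len(mrna)
    assert abs(best.coverage - expected) <= 5 / len(mrna)
    assert best.identity == 1.0


def test_identity_matches_full_dp_oracle_small():
    """On single-exon instances with substitution noise, the aligner's
    identity agrees with full edit-distance DP within 0.01."""
    rng = np.random.default_rng(7)
    for trial in range(30):
        n = int(rng.integers(150, 501))
        true = "".join(rng.choice(list("ACGT"), size=n))
        noisy = list(true)
        n_sub = int(rng.integers(0, max(1, n // 10)))
        for pos in rng.choice(n, size=n_sub, replace=False):
            noisy[pos] = rng.choice([b for b in "ACGT" if b != noisy[pos]])
        noisy = "".join(noisy)
        pad = "".join(rng.choice(list("ACGT"), size=300))
        genome = GenomeAssembly("g", {"c": pad + true + pad})
        idx = KmerIndex.from_assembly(genome, k=11)
        alns = map_query("q", noisy, genome, idx, min_shared_kmers=1)
        assert alns, f"trial {trial}: no alignment"
        best = max(alns, key=lambda a: a.coverage)
        res = edlib.align(noisy, true, task="path", mode="NW")
        cols = sum(int(x[:-1]) for x in re.findall(r"\d+[=XID]", res["cigar"]))
        oracle = 1 - res["editDistance"] / cols
        assert abs(best.identity - oracle) <= 0.01, f"trial {trial}"


# --- filtering and primary selection -------------------------------------


def _mk(qid, span, identity, coverage=1.0):
    block = AlignmentBlock(1, span, GenomicInterval("c", 1, span), span, 0, 0)
    return SplicedAlignment(qid, "c", "+", [block], identity, coverage, span)


@pytest.mark.parametrize(
    "span,identity,kept",
    [
        (99, 1.0, False),  # not longer than 100 bp
        (100, 1.0, False),
        (101, 1.0, True),
        (1000, 0.951, True),
        (1000, 0.949, False),
        (1000, 0.95, True),  # "95% or higher" is inclusive
    ],
)
def test_filter_alignments_thresholds(span, identity, kept):
    out = filter_alignments([_mk("q", span, identity)])
    assert bool(out) is kept


def test_filter_output_is_subset():
    alns = [_mk("q", s, i) for s, i in [(99, 1.0), (500, 0.99), (2000, 0.9)]]
    out = filter_alignments(alns)
    assert set(map(id, out)) <= set(map(id, alns))


def test_select_primary_single_and_ties():
    a = _mk("q", 500, 1.0)
    select_primary([a])
    assert a.is_primary
    b1, b2 = _mk("q", 500, 1.0), _mk("q", 500, 1.0)
    select_primary([b1, b2])
    assert b1.is_primary and b2.is_primary  # equal best scores both primary


def test_select_primary_prefers_coverage_over_identity():
    lo_cov = _mk("q", 450, 1.0, coverage=0.9)
    hi_cov = _mk("q", 500, 0.96, coverage=1.0)
    select_primary([lo_cov, hi_cov])
    assert hi_cov.is_primary and not lo_cov.is_primary


def test_select_primary_nonempty_whenever_input_nonempty():
    alns = [_mk("q", s, 0.96) for s in (200, 300, 400)]
    select_primary(alns)
    assert any(a.is_primary for a in alns)


# --- coverage curves -----------------------------------------------------


def test_coverage_curve_perfect_queries():
    alns = [_mk(f"q{i}", 200, 1.0) for i in range(5)]
    for a in alns:
        a.is_primary = True
    curve = coverage_curve({f"q{i}": 200 for i in range(5)}, alns, mode="all")
    assert all(n == 5 for _x, n in curve)


def test_coverage_curve_monotone_and_all_ge_best(tiny_bundle, tiny_result):
    qlens = {qid: len(s) for qid, s in tiny_bundle.mrnas.items()}
    flat = [a for g in tiny_result.structures.alignments.values() for a in g]
    call = coverage_curve(qlens, flat, mode="all")
    cbest = coverage_curve(qlens, flat, mode="best")
    for curve in (call, cbest):
        counts = [n for _x, n in curve]
        assert counts == sorted(counts, reverse=True)
    assert all(na >= nb for (_x, na), (_x2, nb) in zip(call, cbest))


def test_coverage_curve_half_covered_query():
    block = AlignmentBlock(1, 100, GenomicInterval("c", 1, 100), 100, 0, 0)
    a = SplicedAlignment("q", "c", "+", [block], 1.0, 0.5, 200, is_primary=True)
    curve = dict(coverage_curve({"q": 200}, [a], mode="best"))
    assert curve[0.5] == 1 and curve[0.55] == 0
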