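"""The synthetic dual-assembly generator: determinism, construction
invariants and event semantics."""

import pytest

from asmannot.core import GenomicInterval, revcomp, splice
from asmannot.simulate import (
    EventSpec,
    apply_events,
    generate_genome,
    plant_genes,
    plant_snps,
    read_events,
    write_events,
)
from asmannot.scenarios import (
    duplicated_gene_scenario,
    gap_disrupted_exon_scenario,
    inverted_frameshift_scenario,
    relocated_exon_scenario,
    split_inversion_scenario,
)


def test_generate_genome_deterministic():
    a = generate_genome(2, 20_000, seed=7)
    b = generate_genome(2, 20_000, seed=7)
    assert a.placed == b.placed
    assert generate_genome(2, 20_000, seed=8).placed != a.placed


def test_generate_genome_gc_concentration():
    g = generate_genome(1, 500_000, gc_fraction=0.5, seed=3)
    seq = g.placed["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert 0.48 <= gc <= 0.52


def test_generate_genome_shape_and_validation():
    g = generate_genome(2, 20_000, seed=1)
    assert list(g.placed) == ["chr1", "chr2"]
    assert not g.unplaced
    with pytest.raises(ValueError):
        generate_genome(0, 20_000)
    with pytest.raises(ValueError):
        generate_genome(1, 500)


def test_planted_genes_have_canonical_splice_sites(tiny_bundle):
    g = tiny_bundle.genome_a
    for t in tiny_bundle.annot_a:
        for s, e in t.introns:
            intron = g.sequence(t.chrom)[s - 1 : e]
            if t.strand == "-":
                intron = revcomp(intron)
            assert intron[:2] == "GT" and intron[-2:] == "AG"


def test_planted_proteins_are_stop_free(tiny_bundle):
    for seq in tiny_bundle.proteins.values():
        assert "*" not in seq
        assert seq.startswith("M")


def test_planted_genes_do_not_overlap(tiny_bundle):
    by_chrom = {}
    for t in tiny_bundle.annot_a:
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    for spans in by_chrom.values():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 > e1


def test_plant_genes_deterministic():
    g = generate_genome(1, 100_000, seed=5)
    _, a1, m1, p1 = plant_genes(g, 5, seed=9)
    _, a2, m2, p2 = plant_genes(g, 5, seed=9)
    assert m1 == m2 and p1 == p2
    assert [(t.id, t.start, t.end) for t in a1] == [(t.id, t.start, t.end) for t in a2]


def test_empty_event_list_is_identity(tiny_bundle):
    b, annot_b, truth = apply_events(tiny_bundle.genome_a, tiny_bundle.annot_a, [], seed=1)
    assert b.placed == tiny_bundle.genome_a.placed
    assert all(r.expected_structure == "identical" for r in truth)
    for t in tiny_bundle.annot_a:
        u = annot_b[t.id]
        assert [(e.start, e.end) for e in u.exons] == [(e.start, e.end) for e in t.exons]


def test_inversion_containing_gene_preserves_spliced_sequence(tiny_bundle):
    g = tiny_bundle.genome_a
    t = tiny_bundle.annot_a.transcripts[0]
    ev = EventSpec("inversion", GenomicInterval(t.chrom, t.start - 50, t.end + 50))
    b, annot_b, truth = apply_events(g, tiny_bundle.annot_a, [ev], seed=1)
    u = annot_b[t.id]
    assert u.strand != t.strand
    assert splice(u, b) == tiny_bundle.mrnas[t.id]
    rec = {r.subject_id: r for r in truth}[t.id]
    assert rec.expected_structure == "identical"


def test_deletion_removes_exon_sequence_from_b():
    bundle = gap_disrupted_exon_scenario(seed=11)
    t = bundle.annot_a.transcripts[0]
    exon = t.exons[2]
    exon_seq = bundle.genome_a.fetch(exon)
    assert exon_seq in bundle.genome_a.sequence(t.chrom)
    assert exon_seq not in bundle.genome_b.sequence(t.chrom)
    # N-gap deletions preserve chromosome length
    assert len(bundle.genome_b.sequence(t.chrom)) == len(bundle.genome_a.sequence(t.chrom))


def test_sequence_conservation_under_events():
    bundle = relocated_exon_scenario(seed=12)
    total_a = sum(len(s) for s in bundle.genome_a.sequences().values())
    ev = bundle.events[0]
    seg = ev.target.end - ev.target.start + 1
    total_b = sum(len(s) for s in bundle.genome_b.sequences().values())
    assert total_b == total_a + seg  # N-filled slot stays, segment re-inserted


def test_duplication_inserts_second_copy():
    bundle = duplicated_gene_scenario(seed=14)
    t = bundle.annot_a.transcripts[0]
    mrna = bundle.mrnas[t.id]
    assert t.id + "_dup" in bundle.annot_b
    dup = bundle.annot_b[t.id + "_dup"]
    assert splice(dup, bundle.genome_b) == mrna
    total_a = sum(len(s) for s in bundle.genome_a.sequences().values())
    total_b = sum(len(s) for s in bundle.genome_b.sequences().values())
    assert total_b == total_a + (bundle.events[0].target.end - bundle.events[0].target.start + 1)


def test_unplace_moves_sequence_to_contig_pool():
    g = generate_genome(1, 50_000, seed=2)
    seg = GenomicInterval("chr1", 10_001, 20_000)
    seg_seq = g.fetch(seg)
    from asmannot.core import AnnotationSet

    b, _annot, _truth = apply_events(g, AnnotationSet("g", []), [EventSpec("unplace", seg)], seed=1)
    assert len(b.placed["chr1"]) == 40_000
    assert b.unplaced["chrUn_1"] == seg_seq
    assert seg_seq not in b.placed["chr1"]


def test_overlapping_structural_events_rejected():
    g = generate_genome(1, 50_000, seed=2)
    from asmannot.core import AnnotationSet

    events = [
        EventSpec("inversion", GenomicInterval("chr1", 1000, 2000)),
        EventSpec("deletion", GenomicInterval("chr1", 1500, 2500)),
    ]
    with pytest.raises(ValueError, match="overlapping"):
        apply_events(g, AnnotationSet("g", []), events, seed=1)


def test_split_inversion_strands_part_of_the_gene():
    bundle = split_inversion_scenario(seed=13)
    t = bundle.annot_a.transcripts[0]
    # the first three exons survive in place; the rest is reverse-complemented
    surviving = bundle.genome_a.fetch(t.exons[0])
    assert surviving in bundle.genome_b.sequence(t.chrom)
    inverted_exon = bundle.genome_a.fetch(t.exons[4])
    assert inverted_exon not in bundle.genome_b.sequence(t.chrom)
    assert revcomp(inverted_exon) in bundle.genome_b.sequence(t.chrom)


def test_inverted_frameshift_scenario_breaks_translation():
    from asmannot.core import conceptual_translation

    bundle = inverted_frameshift_scenario(seed=15)
    t = bundle.annot_b.transcripts[0]
    predicted = conceptual_translation(t, bundle.genome_b).sequence
    assert predicted != bundle.proteins[t.id]


def test_plant_snps_contexts_unique_and_deterministic(tiny_bundle):
    g = tiny_bundle.genome_a
    snps, truth, positions = plant_snps(g, 10, flank_bp=100, seed=50)
    snps2, _, _ = plant_snps(g, 10, flank_bp=100, seed=50)
    assert snps == snps2
    whole = "".join(g.placed.values())
    for s, pos in zip(snps, positions):
        ref = g.sequence(pos.chrom)[pos.start - 1]
        assert ref in s.alleles
        context = s.flank5 + ref + s.flank3
        assert whole.count(context) == 1


def test_plant_snps_rejects_zero_flanks(tiny_bundle):
    with pytest.raises(ValueError):
        plant_snps(tiny_bundle.genome_a, 5, flank_bp=0, seed=1)


def test_event_tsv_round_trip(tmp_path):
    events = [
        EventSpec("inversion", GenomicInterval("chr1", 100, 200)),
        EventSpec("duplication", GenomicInterval("chr1", 300, 400), {"dest": ("chr2", 50)}),
        EventSpec("substitution_noise", GenomicInterval("chr1", 1, 1000), {"rate": 0.01}),
        EventSpec("frameshift_indel", GenomicInterval("chr1", 500, 500), {"delta": -1}),
    ]
    path = tmp_path / "events.tsv"
    write_events(events, path)
    back = read_events(path)
    assert [(e.kind, e.target, {k: v for k, v in e.params.items() if not k.startswith("_")}) for e in back] == [
        (e.kind, e.target, {k: v for k, v in e.params.items() if not k.startswith("_")}) for e in events
    ]
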