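"""Named simulation scenarios: the study conditions every evaluation runs on.

Each builder returns a :class:`SimBundle` — a source assembly with planted
genes/SNPs, a derived assembly carrying labeled events, the projected
annotation of the derived assembly, and ground-truth expectations.

The catalogue covers both the systematic benchmarks (null run, per-event
recovery, SNP tiers) and single-gene fixtures reproducing the classic
mis-assembly failure modes: an exon falling into a scaffold gap, an exon
relocated by a translocated contig, a gene split across an inversion
breakpoint, a segmental duplication of a whole gene, and an inverted
contig inside a gene that leaves a frameshifted, stop-riddled protein
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnnotationSet, GenomeAssembly, GenomicInterval, Transcript
from .io import SNPContext
from .simulate import (
    EventSpec,
    TruthRecord,
    apply_events,
    generate_genome,
    plant_genes,
    plant_snps,
)


@dataclass
class SimBundle:
    genome_a: GenomeAssembly
    genome_b: GenomeAssembly
    annot_a: AnnotationSet
    annot_b: AnnotationSet
    mrnas: dict[str, str]
    proteins: dict[str, str]
    truth: list[TruthRecord]
    events: list[EventSpec]
    snps: list[SNPContext] = field(default_factory=list)

    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {r.subject_id: r for r in self.truth}


def null_scenario(
    seed: int,
    n_chrom: int = 2,
    chrom_length: int = 500_000,
    n_genes: int = 100,
    n_snps: int = 500,
) -> SimBundle:
    """No events at all: assembly B is byte-identical to A. Every
    downstream stage must report perfect agreement."""
    g = generate_genome(n_chrom, chrom_length, seed=seed)
    g, annot, mrnas, prots = plant_genes(g, n_genes, seed=seed + 1)
    genome_b, annot_b, truth = apply_events(g, annot, [], seed=seed + 2, name_b="genomeB")
    snps, snp_truth, _pos = plant_snps(g, n_snps, seed=seed + 3)
    return SimBundle(g, genome_b, annot, annot_b, mrnas, prots, truth + snp_truth, [], snps)


def _free_position(
    rng: np.random.Generator,
    genome: GenomeAssembly,
    forbidden: list[GenomicInterval],
    margin: int = 1500,
) -> tuple[str, int]:
    chroms = list(genome.placed)
    for _ in range(5000):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(margin, len(genome.placed[chrom]) - margin))
        if all(
            not (iv.chrom == chrom and iv.start - margin <= pos <= iv.end + margin)
            for iv in forbidden
        ):
            return chrom, pos
    raise RuntimeError("no free position for event destination")


def event_for_gene(
    t: Transcript,
    kind: str,
    rng: np.random.Generator,
    forbidden: list[GenomicInterval],
    genome: GenomeAssembly,
) -> EventSpec:
    """Build one gene-targeted event of the requested benchmark kind."""
    if kind == "terminal_exon_deletion":
        exon = t.exons[-1]
        return EventSpec("deletion", GenomicInterval(t.chrom, exon.start, exon.end))
    if kind == "internal_exon_deletion":
        exon = t.exons[1]
        return EventSpec("deletion", GenomicInterval(t.chrom, exon.start, exon.end))
    if kind == "intragenic_inversion":
        exon = t.exons[1]
        return EventSpec(
            "inversion", GenomicInterval(t.chrom, exon.start - 10, exon.end + 10)
        )
    if kind == "whole_gene_translocation":
        dest = _free_position(rng, genome, forbidden)
        return EventSpec(
            "translocation",
            GenomicInterval(t.chrom, t.start - 100, t.end + 100),
            {"dest": dest},
        )
    if kind == "frameshift_indel":
        assert t.cds is not None
        s, e = t.cds
        mid = s + 2 * (e - s) // 3
        gpos = t.genomic_position(mid)
        return EventSpec(
            "frameshift_indel", GenomicInterval(t.chrom, gpos, gpos), {"delta": -1}
        )
    if kind == "whole_gene_duplication":
        dest = _free_position(rng, genome, forbidden)
        return EventSpec(
            "duplication",
            GenomicInterval(t.chrom, t.start - 100, t.end + 100),
            {"dest": dest},
        )
    if kind == "substitution_noise":
        return EventSpec(
            "substitution_noise",
            GenomicInterval(t.chrom, t.start, t.end),
            {"rate": 0.01},
        )
    raise ValueError(f"unknown benchmark event kind {kind!r}")


EVENT_CATEGORIES = [
    "terminal_exon_deletion",
    "internal_exon_deletion",
    "intragenic_inversion",
    "whole_gene_translocation",
    "frameshift_indel",
]


def event_recovery_scenario(
    seed: int,
    genes_per_event: int = 20,
    n_event_free: int = 20,
    n_chrom: int = 3,
    chrom_length: int = 500_000,
) -> tuple[SimBundle, dict[str, str]]:
    """One cohort of genes per event category plus event-free controls.

    Returns the bundle and a gene-id -> category map."""
    rng = np.random.default_rng(seed)
    n_genes = genes_per_event * len(EVENT_CATEGORIES) + n_event_free
    g = generate_genome(n_chrom, chrom_length, seed=seed)
    g, annot, mrnas, prots = plant_genes(
        g, n_genes, exon_count_range=(4, 8), seed=seed + 1
    )
    gene_ids = [t.id for t in annot]
    order = rng.permutation(len(gene_ids))
    categories: dict[str, str] = {}
    events: list[EventSpec] = []
    forbidden = [GenomicInterval(t.chrom, t.start - 300, t.end + 300) for t in annot]
    k = 0
    for cat in EVENT_CATEGORIES:
        for _ in range(genes_per_event):
            tid = gene_ids[order[k]]
            k += 1
            categories[tid] = cat
            ev = event_for_gene(annot[tid], cat, rng, forbidden, g)
            events.append(ev)
            forbidden.append(ev.target)
    for i in range(k, len(gene_ids)):
        categories[gene_ids[order[i]]] = "event_free"
    genome_b, annot_b, truth = apply_events(g, annot, events, seed=seed + 2)
    bundle = SimBundle(g, genome_b, annot, annot_b, mrnas, prots, truth, events)
    return bundle, categories


def snp_tier_scenario(
    seed: int,
    n_snps: int = 1000,
    n_duplicated: int = 100,
    n_unplaced: int = 100,
    flank_bp: int = 250,
    n_chrom: int = 2,
    chrom_length: int = 500_000,
    segment_length: int = 40_000,
) -> SimBundle:
    """SNP cohorts in unique, duplicated and unplaced-moved sequence.

    Unique-region SNPs should tier as mapped on both assemblies; SNPs in
    the duplicated segment match two loci on B (found, not mapped); SNPs
    in the unplaced segment disappear from B's chromosomes (unmapped)
    unless the search is rescued with B's unplaced contigs."""
    g = generate_genome(n_chrom, chrom_length, seed=seed)
    dup_seg = GenomicInterval("chr1", 100_001, 100_000 + segment_length)
    unp_seg = GenomicInterval("chr2", 300_001, 300_000 + segment_length)
    dest = ("chr2", 50_000)
    events = [
        EventSpec("duplication", dup_seg, {"dest": dest}),
        EventSpec("unplace", unp_seg),
    ]
    avoid = [
        GenomicInterval(dup_seg.chrom, dup_seg.start - flank_bp, dup_seg.end + flank_bp),
        GenomicInterval(unp_seg.chrom, unp_seg.start - flank_bp, unp_seg.end + flank_bp),
        GenomicInterval(dest[0], dest[1] - flank_bp, dest[1] + flank_bp),
    ]
    n_unique = n_snps - n_duplicated - n_unplaced
    snps_u, truth_u, _ = plant_snps(
        g, n_unique, flank_bp=flank_bp, seed=seed + 1, avoid=avoid, expected="mapped"
    )
    snps_d, truth_d, _ = plant_snps(
        g,
        n_duplicated,
        flank_bp=flank_bp,
        seed=seed + 2,
        within=[dup_seg],
        expected="found",
        rsid_start=n_unique + 1,
    )
    snps_n, truth_n, _ = plant_snps(
        g,
        n_unplaced,
        flank_bp=flank_bp,
        seed=seed + 3,
        within=[unp_seg],
        expected="unmapped",
        rsid_start=n_unique + n_duplicated + 1,
    )
    empty = AnnotationSet(g.name, [])
    genome_b, annot_b, truth_g = apply_events(g, empty, events, seed=seed + 4)
    return SimBundle(
        g,
        genome_b,
        empty,
        annot_b,
        {},
        {},
        truth_u + truth_d + truth_n,
        events,
        snps_u + snps_d + snps_n,
    )


# ---------------------------------------------------------------------------
# Single-gene fixtures for the classic failure modes


def _single_gene_bundle(seed: int, events_fn, exon_count=(5, 5)) -> SimBundle:
    g = generate_genome(1, 60_000, seed=seed)
    g, annot, mrnas, prots = plant_genes(
        g, 1, exon_count_range=exon_count, intron_len_range=(200, 800), seed=seed + 1
    )
    t = annot.transcripts[0]
    events = events_fn(t, g)
    genome_b, annot_b, truth = apply_events(g, annot, events, seed=seed + 2)
    return SimBundle(g, genome_b, annot, annot_b, mrnas, prots, truth, events)


def gap_disrupted_exon_scenario(seed: int = 11) -> SimBundle:
    """An internal exon falls into a scaffold gap (N run) in B."""
    return _single_gene_bundle(
        seed,
        lambda t, g: [EventSpec("deletion", GenomicInterval(t.chrom, t.exons[2].start, t.exons[2].end))],
    )


def relocated_exon_scenario(seed: int = 12) -> SimBundle:
    """An internal exon's contig is translocated far from the gene; a
    secondary alignment still finds it at the new locus."""

    def events(t, g):
        exon = t.exons[2]
        dest_chrom = t.chrom
        dest_pos = 2000 if t.start > 10_000 else len(g.placed[t.chrom]) - 2000
        return [
            EventSpec(
                "translocation",
                GenomicInterval(t.chrom, exon.start - 20, exon.end + 20),
                {"dest": (dest_chrom, dest_pos)},
            )
        ]

    return _single_gene_bundle(seed, events)


def split_inversion_scenario(seed: int = 13) -> SimBundle:
    """An inversion breakpoint inside the gene strands half the exons the
    wrong way: the transcript maps as two alignments on opposite strands."""

    def events(t, g):
        # breakpoint inside the intron before the 4th exon, extending past the gene
        cut = t.exons[3].start - 30
        end = min(t.end + 500, len(g.placed[t.chrom]))
        return [EventSpec("inversion", GenomicInterval(t.chrom, cut, end))]

    return _single_gene_bundle(seed, events)


def duplicated_gene_scenario(seed: int = 14) -> SimBundle:
    """A segmental duplication carries a complete second copy of the gene."""

    def events(t, g):
        dest_pos = 2000 if t.start > 10_000 else len(g.placed[t.chrom]) - 2000
        return [
            EventSpec(
                "duplication",
                GenomicInterval(t.chrom, t.start - 100, t.end + 100),
                {"dest": (t.chrom, dest_pos)},
            )
        ]

    return _single_gene_bundle(seed, events)


def inverted_frameshift_scenario(seed: int = 15) -> SimBundle:
    """An inverted contig inside the gene leaves the annotated model with
    wrong-strand exons whose conceptual translation is frameshifted and
    riddled with stop codons."""

    def events(t, g):
        exon = t.exons[2]
        return [
            EventSpec("inversion", GenomicInterval(t.chrom, exon.start - 15, exon.end + 15))
        ]

    return _single_gene_bundle(seed, events)
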