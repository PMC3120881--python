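"""Two-tier SNP remapping by flanking-context alignment.

Each SNP's context sequence (5' flank + variant base + 3' flank, usually
250 bp a side) is mapped to the placed chromosomes of a target assembly
with a two-stage seeded search: stage 1 uses long (20-mer) seeds requiring
two shared seeds; stage 2, applied only when stage 1 finds nothing, drops
to short (11-mer) seeds to retrieve lower-similarity placements. Both
stages finish with dynamic-programming extension of the chained seed
region. The variant column scores as a free match by default, since the
sampled individual may carry either allele.

Tiers: a SNP is *found* if any hit reaches 90% identity over 90% of the
context, and *mapped* if exactly one location (after merging hits whose
intervals overlap by half or more) exceeds 95% identity at 90% coverage.
Unplaced contigs are excluded from the search target unless rescue is
requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .align import (
    KmerIndex,
    _best_prefix,
    _chain,
    _cigar_ops,
    _exact_segments,
    _nw_ops,
    find_candidates,
)
from .core import GenomeAssembly, GenomicInterval, revcomp
from .io import SNPContext


@dataclass
class SNPHit:
    """One qualifying placement of a SNP context."""

    location: GenomicInterval
    identity: float
    coverage: float
    snp_position: int | None  # projected genomic coordinate of the variant


@dataclass
class SNPStatus:
    rsid: str
    status: str  # unmapped | found | mapped
    hits: list[SNPHit] = field(default_factory=list)


@dataclass
class SNPMapParams:
    stage1_k: int = 20
    stage1_min_seeds: int = 2
    stage2_k: int = 11
    stage2_min_seeds: int = 2
    pad_bp: int = 200
    anchor_k: int = 13
    max_gap: int = 400  # contexts are contiguous genomic sequence
    found_identity: float = 0.90
    found_coverage: float = 0.90
    mapped_identity: float = 0.95  # strict: mapped needs identity > this
    free_variant_match: bool = True


def _align_context(
    query: str, wseq: str, anchor_k: int, max_gap: int
) -> tuple[int, int, int, int, list[str]] | None:
    """Chain anchors without introns and close gaps with edit-distance DP.

    Returns (q0, g0, qlen, glen, ops) in local 0-based coordinates, or
    None when no anchor chain exists."""
    segs = _exact_segments(query, wseq, anchor_k)
    if not segs:
        return None
    chain = _chain(segs, min_intron=10**9, max_intron=max_gap)
    if not chain:
        return None
    q0, g0 = chain[0][0], chain[0][2]
    ops: list[str] = ["="] * (chain[0][1] - chain[0][0] + 1)
    for prev, seg in zip(chain, chain[1:]):
        ops.extend(_nw_ops(query[prev[1] + 1 : seg[0]], wseq[prev[3] + 1 : seg[2]]))
        ops.extend("=" * (seg[1] - seg[0] + 1))
    # best-scoring end extensions (garbage tails stay unaligned)
    if q0 > 0 and g0 > 0:
        head = query[:q0]
        lo = max(0, g0 - len(head) - 20)
        res = edlib.align(head[::-1], wseq[lo:g0][::-1], task="path", mode="SHW")
        ext = _best_prefix(_cigar_ops(res["cigar"]))
        if ext:
            q0 -= sum(1 for op in ext if op in "=XI")
            g0 -= sum(1 for op in ext if op in "=XD")
            ops = ext[::-1] + ops
    qlen = sum(1 for op in ops if op in "=XI")
    glen = sum(1 for op in ops if op in "=XD")
    if q0 + qlen < len(query) and g0 + glen < len(wseq):
        tail = query[q0 + qlen :]
        target = wseq[g0 + glen : g0 + glen + len(tail) + 20]
        res = edlib.align(tail, target, task="path", mode="SHW")
        ext = _best_prefix(_cigar_ops(res["cigar"]))
        if ext:
            ops = ops + ext
            qlen = sum(1 for op in ops if op in "=XI")
            glen = sum(1 for op in ops if op in "=XD")
    return q0, g0, qlen, glen, ops


def map_context(
    snp: SNPContext,
    genome: GenomeAssembly,
    index: KmerIndex,
    stage2_index: KmerIndex | None = None,
    params: SNPMapParams | None = None,
) -> list[SNPHit]:
    """All placements of one SNP context on the indexed target sequences."""
    prm = params or SNPMapParams()
    ref = sorted(snp.alleles)[0]
    query = snp.context(ref)
    if len(query) < 40:
        raise ValueError(f"SNP {snp.rsid!r}: context shorter than 40 bp")
    hits = _map_stage(query, snp.variant_offset, genome, index, prm, prm.stage1_min_seeds)
    if not hits and stage2_index is not None:
        hits = _map_stage(query, snp.variant_offset, genome, stage2_index, prm, prm.stage2_min_seeds)
    return hits


def _map_stage(
    query: str,
    variant_offset: int,
    genome: GenomeAssembly,
    index: KmerIndex,
    prm: SNPMapParams,
    min_seeds: int,
) -> list[SNPHit]:
    lengths = {sid: len(s) for sid, s in genome.sequences().items()}
    windows = find_candidates(
        query,
        index,
        min_shared_kmers=min_seeds,
        pad_bp=prm.pad_bp,
        cluster_gap=prm.max_gap + len(query),
        seq_lengths=lengths,
    )
    hits: list[SNPHit] = []
    for w in windows:
        wseq = genome.sequence(w.chrom)[w.start - 1 : w.end]
        q = query if w.strand == "+" else revcomp(query)
        var_col = variant_offset if w.strand == "+" else len(query) - variant_offset + 1
        res = _align_context(q, wseq, prm.anchor_k, prm.max_gap)
        if res is None:
            continue
        q0, g0, qlen, glen, ops = res
        matches = ops.count("=")
        mismatches = ops.count("X")
        # project the variant column and apply free-match scoring
        snp_pos: int | None = None
        qpos, gpos = q0, g0  # 0-based next positions
        for op in ops:
            if op in "=X":
                if qpos == var_col - 1:
                    snp_pos = w.start + gpos
                    if op == "X" and prm.free_variant_match:
                        matches += 1
                        mismatches -= 1
                qpos += 1
                gpos += 1
            elif op == "I":
                qpos += 1
            else:
                gpos += 1
        if matches + mismatches == 0:
            continue
        identity = matches / (matches + mismatches)
        coverage = qlen / len(query)
        hits.append(
            SNPHit(
                GenomicInterval(w.chrom, w.start + g0, w.start + g0 + glen - 1, w.strand),
                identity,
                coverage,
                snp_pos,
            )
        )
    return _merge_hits(hits)


def _merge_hits(hits: list[SNPHit]) -> list[SNPHit]:
    """Collapse hits whose genomic intervals overlap by >= 50% of the
    shorter interval, keeping the best (identity, coverage)."""
    hits = sorted(hits, key=lambda h: (-h.identity, -h.coverage, h.location.chrom, h.location.start))
    kept: list[SNPHit] = []
    for h in hits:
        merged = False
        for k in kept:
            if k.location.chrom != h.location.chrom:
                continue
            ov = min(k.location.end, h.location.end) - max(k.location.start, h.location.start) + 1
            shorter = min(len(k.location), len(h.location))
            if ov >= 0.5 * shorter:
                merged = True
                break
        if not merged:
            kept.append(h)
    return kept


def classify_snp(rsid: str, hits: list[SNPHit], params: SNPMapParams | None = None) -> SNPStatus:
    """found: any hit at >= 90% identity and >= 90% coverage;
    mapped: exactly one hit at > 95% identity and >= 90% coverage."""
    prm = params or SNPMapParams()
    found_hits = [
        h for h in hits if h.identity >= prm.found_identity and h.coverage >= prm.found_coverage
    ]
    mapped_hits = [
        h for h in found_hits if h.identity > prm.mapped_identity
    ]
    if not found_hits:
        return SNPStatus(rsid, "unmapped", hits)
    if len(mapped_hits) == 1 and len(found_hits) == 1:
        return SNPStatus(rsid, "mapped", found_hits)
    return SNPStatus(rsid, "found", found_hits)


@dataclass
class SNPComparison:
    status_a: dict[str, str]
    status_b: dict[str, str]
    unique_to_a: set[str]  # found in A only
    unique_to_b: set[str]
    rescued_in_a: set[str] = field(default_factory=set)  # B-only SNPs found on A's unplaced
    rescued_in_b: set[str] = field(default_factory=set)

    def counts(self, which: str) -> dict[str, int]:
        st = self.status_a if which == "a" else self.status_b
        out = {"unmapped": 0, "found": 0, "mapped": 0}
        for s in st.values():
            out[s] += 1
        return out


def map_snps(
    snps: list[SNPContext],
    genome: GenomeAssembly,
    params: SNPMapParams | None = None,
    include_unplaced: bool = False,
) -> dict[str, SNPStatus]:
    """Map and tier a SNP set against one assembly's placed chromosomes
    (plus unplaced contigs when requested)."""
    prm = params or SNPMapParams()
    seqs = dict(genome.placed)
    if include_unplaced:
        seqs.update(genome.unplaced)
    target = GenomeAssembly(genome.name, seqs) if include_unplaced else genome
    idx1 = KmerIndex(seqs, k=prm.stage1_k)
    idx2 = KmerIndex(seqs, k=prm.stage2_k)
    out = {}
    for snp in snps:
        hits = map_context(snp, target, idx1, stage2_index=idx2, params=prm)
        out[snp.rsid] = classify_snp(snp.rsid, hits, prm)
    return out


def compare_assemblies(
    snps: list[SNPContext],
    genome_a: GenomeAssembly,
    genome_b: GenomeAssembly,
    params: SNPMapParams | None = None,
    rescue_unplaced: bool = False,
) -> SNPComparison:
    """Tier every SNP on both assemblies; optionally re-search assembly-
    specific SNPs against the other assembly's unplaced contigs."""
    prm = params or SNPMapParams()
    st_a = map_snps(snps, genome_a, prm)
    st_b = map_snps(snps, genome_b, prm)
    found_a = {r for r, s in st_a.items() if s.status in ("found", "mapped")}
    found_b = {r for r, s in st_b.items() if s.status in ("found", "mapped")}
    cmp = SNPComparison(
        status_a={r: s.status for r, s in st_a.items()},
        status_b={r: s.status for r, s in st_b.items()},
        unique_to_a=found_a - found_b,
        unique_to_b=found_b - found_a,
    )
    if rescue_unplaced:
        by_id = {s.rsid: s for s in snps}
        if cmp.unique_to_a and genome_b.unplaced:
            unp_b = GenomeAssembly(genome_b.name + "_unplaced", dict(genome_b.unplaced))
            st = map_snps([by_id[r] for r in sorted(cmp.unique_to_a)], unp_b, prm)
            cmp.rescued_in_b = {r for r, s in st.items() if s.status in ("found", "mapped")}
        if cmp.unique_to_b and genome_a.unplaced:
            unp_a = GenomeAssembly(genome_a.name + "_unplaced", dict(genome_a.unplaced))
            st = map_snps([by_id[r] for r in sorted(cmp.unique_to_b)], unp_a, prm)
            cmp.rescued_in_a = {r for r, s in st.items() if s.status in ("found", "mapped")}
    return cmp
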