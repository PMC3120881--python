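"""Exon-intron structure comparison, best-match assignment and rollup.

The comparator consumes the alignment-projected structure of a foreign
transcript (its exons on the *target* genome, from the spliced alignment)
and classifies it against each candidate transcript of the target genome's
own annotation:

* Two structures are *comparable* if their exons overlap by >= 50 bp and,
  when both are multi-exon, they share at least one intron (both
  boundaries within the margin V).
* A comparable pair is *compatible* if, restricted to the genomic interval
  covered by both, the structures have the same introns with every
  boundary within V bp (default V = 20).
* Compatible pairs are classified by how the mapped structure's extent
  relates to the annotated candidate: identical extent; extended beyond it
  at one or both ends; ending short of it (truncated) at one or both ends
  (a truncation at one end coupled with an extension at the other counts
  with the double-end truncations); incompatible pairs are complex.

Orientation note: "extension"/"truncation" describe the *mapped* transcript
relative to the local annotation — a gene whose terminal exon is lost in
the target assembly maps as a truncation of its annotated counterpart.

Best matches use the priority order P1..P7 below; ties are broken by the
largest number of common exons, then by genomic coordinate so runs are
reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import edlib

from .core import Transcript, GenomicInterval
from .align import SplicedAlignment


class MatchClass(enum.IntEnum):
    """Priority-ordered transcript pair classification (lower wins)."""

    P1_NAME_AND_EVIDENCE = 1
    P2_IDENTICAL = 2
    P3_SINGLE_EXTENSION = 3
    P4_DOUBLE_EXTENSION = 4
    P5_SINGLE_TRUNCATION = 5
    P6_TRUNCATION_OR_MIXED = 6
    P7_COMPLEX = 7


ROLLUP = {
    MatchClass.P1_NAME_AND_EVIDENCE: "identical",
    MatchClass.P2_IDENTICAL: "identical",
    MatchClass.P3_SINGLE_EXTENSION: "extensions",
    MatchClass.P4_DOUBLE_EXTENSION: "extensions",
    MatchClass.P5_SINGLE_TRUNCATION: "truncations",
    MatchClass.P6_TRUNCATION_OR_MIXED: "both",
    MatchClass.P7_COMPLEX: "complex",
}

ROLLUP_ORDER = ["identical", "extensions", "truncations", "both", "complex"]


def structure_from_alignment(aln: SplicedAlignment, source: Transcript | None = None) -> Transcript:
    """The exon structure a spliced alignment projects onto the target
    genome, carrying over the source transcript's name and evidence."""
    exons = [
        GenomicInterval(b.genome.chrom, b.genome.start, b.genome.end, aln.strand)
        for b in aln.blocks
    ]
    merged: list[GenomicInterval] = []
    for iv in exons:
        if merged and iv.start <= merged[-1].end + 1:
            merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, max(iv.end, merged[-1].end), iv.strand)
        else:
            merged.append(iv)
    return Transcript(
        aln.query_id,
        merged,
        gene_name=source.gene_name if source else None,
        evidence_accession=source.evidence_accession if source else None,
    )


def exonic_overlap(a: Transcript, b: Transcript) -> int:
    """Total bp of exon-exon overlap between two structures."""
    if a.chrom != b.chrom:
        return 0
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start) + 1)
    return total


def _shared_introns(a: Transcript, b: Transcript, margin: int) -> int:
    n = 0
    for s1, e1 in a.introns:
        for s2, e2 in b.introns:
            if abs(s1 - s2) <= margin and abs(e1 - e2) <= margin:
                n += 1
                break
    return n


def is_comparable(a: Transcript, b: Transcript, min_overlap: int = 50, margin: int = 20) -> bool:
    """Overlap >= min_overlap exonic bp; multi-exon pairs must share an
    intron within the margin."""
    if a.chrom != b.chrom:
        return False
    if exonic_overlap(a, b) < min_overlap:
        return False
    if len(a.exons) > 1 and len(b.exons) > 1:
        return _shared_introns(a, b, margin) >= 1
    return True


def is_compatible(a: Transcript, b: Transcript, margin: int = 20) -> bool:
    """Identical exon-intron structure along the common subinterval, with
    a ``margin`` bp tolerance at every boundary. Symmetric."""
    if a.chrom != b.chrom:
        return False
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    if hi < lo:
        return False
    ia = _introns_within(a, lo, hi, margin)
    ib = _introns_within(b, lo, hi, margin)
    if len(ia) != len(ib):
        return False
    for (s1, e1), (s2, e2) in zip(ia, ib):
        if abs(s1 - s2) > margin or abs(e1 - e2) > margin:
            return False
    return True


def _introns_within(t: Transcript, lo: int, hi: int, margin: int) -> list[tuple[int, int]]:
    """Introns lying inside [lo, hi] expanded by the margin (introns
    straddling the common-subinterval edge are not required to match)."""
    return [
        (s, e) for s, e in t.introns if s >= lo - margin and e <= hi + margin
    ]


def classify_pair(a: Transcript, b: Transcript, margin: int = 20, min_overlap: int = 50) -> MatchClass:
    """Classify a mapped structure ``a`` against an annotated candidate
    ``b``. Precondition: the pair is comparable."""
    if not is_comparable(a, b, min_overlap=min_overlap, margin=margin):
        raise ValueError(f"pair {a.id!r}/{b.id!r} is not comparable")
    if not is_compatible(a, b, margin=margin):
        return MatchClass.P7_COMPLEX
    d_left = a.start - b.start
    d_right = a.end - b.end
    ext = int(d_left < -margin) + int(d_right > margin)
    trunc = int(d_left > margin) + int(d_right < -margin)
    if ext == 0 and trunc == 0:
        if (
            a.gene_name is not None
            and b.gene_name is not None
            and a.gene_name == b.gene_name
            and a.evidence_accession is not None
            and a.evidence_accession == b.evidence_accession
        ):
            return MatchClass.P1_NAME_AND_EVIDENCE
        return MatchClass.P2_IDENTICAL
    if trunc == 0:
        return MatchClass.P3_SINGLE_EXTENSION if ext == 1 else MatchClass.P4_DOUBLE_EXTENSION
    if ext == 0 and trunc == 1:
        return MatchClass.P5_SINGLE_TRUNCATION
    return MatchClass.P6_TRUNCATION_OR_MIXED


def common_exons(a: Transcript, b: Transcript, margin: int = 20) -> int:
    """Exon pairs with both boundaries within the margin."""
    n = 0
    used: set[int] = set()
    for ea in a.exons:
        for i, eb in enumerate(b.exons):
            if i in used:
                continue
            if abs(ea.start - eb.start) <= margin and abs(ea.end - eb.end) <= margin:
                n += 1
                used.add(i)
                break
    return n


@dataclass
class BestMatch:
    query_id: str
    candidate_id: str
    match_class: MatchClass
    n_common_exons: int


def assign_best_match(
    mapped: Transcript,
    candidates: list[Transcript],
    margin: int = 20,
    min_overlap: int = 50,
) -> BestMatch | None:
    """Minimal priority wins; ties by most common exons, then lowest
    genomic start, then id (deterministic)."""
    scored = []
    for c in candidates:
        if not is_comparable(mapped, c, min_overlap=min_overlap, margin=margin):
            continue
        mc = classify_pair(mapped, c, margin=margin, min_overlap=min_overlap)
        scored.append((int(mc), -common_exons(mapped, c, margin), c.start, c.id, mc, c))
    if not scored:
        return None
    scored.sort(key=lambda x: x[:4])
    _p, neg_common, _s, _id, mc, c = scored[0]
    return BestMatch(mapped.id, c.id, mc, -neg_common)


@dataclass
class CompatSummary:
    """Counts of best-match classes rolled up Table-2 style."""

    counts: dict[str, int] = field(default_factory=lambda: {k: 0 for k in ROLLUP_ORDER})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[str, float]:
        from .pipeline import percent

        return {k: percent(v, self.total) for k, v in self.counts.items()}


def summarize_classes(best_matches: list[BestMatch]) -> CompatSummary:
    s = CompatSummary()
    for bm in best_matches:
        s.counts[ROLLUP[bm.match_class]] += 1
    return s


def agreement_curve(
    mapped_structures: dict[str, list[Transcript]],
    spliced_lengths: dict[str, int],
    annotation,
    step: float = 0.05,
) -> list[tuple[float, int]]:
    """(x, number of genes whose mapped exonic bases are covered by the
    local annotation for a fraction >= x of the gene's exonic length).

    ``mapped_structures`` holds, per query, the structures of the
    alignments to include (all retained, or primary only, per the caller's
    mode); the denominator is the query's spliced (exonic) length.
    """
    fracs = []
    for qid, structs in mapped_structures.items():
        covered: set[tuple[str, int]] = set()
        for st in structs:
            cands = annotation.overlapping(st.chrom, st.start, st.end)
            for exon in st.exons:
                for c in cands:
                    for ce in c.exons:
                        lo = max(exon.start, ce.start)
                        hi = min(exon.end, ce.end)
                        if hi >= lo:
                            covered.update((st.chrom, p) for p in range(lo, hi + 1))
        fracs.append(min(1.0, len(covered) / spliced_lengths[qid]))
    xs = [round(i * step, 10) for i in range(int(round(1 / step)) + 1)]
    return [(x, sum(1 for f in fracs if f >= x - 1e-9)) for x in xs]


def reciprocal_one_to_one(
    best_ab: dict[str, str], best_ba: dict[str, str]
) -> set[tuple[str, str]]:
    """Pairs (a, b) that are mutual best matches and whose endpoints are
    nobody else's best match."""
    hits_b: dict[str, int] = {}
    for b in best_ab.values():
        hits_b[b] = hits_b.get(b, 0) + 1
    hits_a: dict[str, int] = {}
    for a in best_ba.values():
        hits_a[a] = hits_a.get(a, 0) + 1
    out = set()
    for a, b in best_ab.items():
        if best_ba.get(b) == a and hits_b[b] == 1 and hits_a.get(a, 0) == 1:
            out.add((a, b))
    return out


@dataclass
class SequenceHit:
    query_id: str
    target_id: str
    identity: float
    complete: bool


def validate_unique(
    unique_mrnas: dict[str, str],
    other_mrnas: dict[str, str],
    min_identity: float = 0.95,
) -> list[SequenceHit]:
    """Sequence-level search of annotation-unique transcripts against the
    other set's spliced mRNAs; a hit is complete when the whole query
    aligns, partial when only an infix of the query does."""
    from .core import revcomp

    out = []
    for qid, qseq in unique_mrnas.items():
        for tid, tseq in other_mrnas.items():
            best = None
            for q in (qseq, revcomp(qseq)):
                if len(q) <= len(tseq):
                    res = edlib.align(q, tseq, mode="HW")
                    ident = 1 - res["editDistance"] / len(q)
                    cand = (ident, True)
                else:
                    res = edlib.align(tseq, q, mode="HW")
                    ident = 1 - res["editDistance"] / len(tseq)
                    cand = (ident, False)
                if best is None or cand[0] > best[0]:
                    best = cand
            if best and best[0] >= min_identity:
                out.append(SequenceHit(qid, tid, round(best[0], 4), best[1]))
    return out
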