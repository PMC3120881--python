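"""Synthetic dual-assembly generator with ground-truth labels.

Builds a random source genome, plants multi-exon genes (GT-AG introns,
ATG..stop CDS free of internal stops) and SNPs with flanking context, then
derives a second assembly carrying labeled mis-assembly events: contig
inversion, translocation, deletion (scaffold-gap N run by default),
segmental duplication, relocation to the unplaced pool, substitution noise
and frameshifting indels. Every planted gene and SNP receives a
TruthRecord stating the category the comparison pipeline is expected to
report for it.

Assembly B's annotation is emitted by the generator as the *naive
coordinate projection* of the source annotation through the event edits:
exon slots whose sequence was replaced by Ns or by inverted sequence are
kept in the projected model. This emulates an evidence-guided annotator
that preserves the known extent of a gene across assembly artifacts (the
failure mode in which a mis-oriented contig leaves an annotated model with
weakly supported, frameshifted exons), and it is what makes assembly
damage visible as structure- and protein-level disagreement downstream.

Translocation is implemented as "contig moved out of its scaffold slot":
the source span is N-filled and the segment is re-inserted at the
destination, so the vacated slot remains as a gap, as it would between
scaffolded contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AnnotationSet,
    GenomeAssembly,
    GenomicInterval,
    Transcript,
    conceptual_translation,
    revcomp,
    splice,
)
from .io import SNPContext, write_tsv, read_tsv

EVENT_KINDS = {
    "inversion",
    "translocation",
    "deletion",
    "duplication",
    "unplace",
    "substitution_noise",
    "frameshift_indel",
}

STRUCTURE_OUTCOMES = {"identical", "extensions", "truncations", "both", "complex"}
# protein outcome "not_near" means: any class except identical/near_identical


@dataclass(frozen=True)
class EventSpec:
    """One labeled assembly event.

    params by kind: translocation/duplication need ``dest=(chrom, pos)``
    (source coordinates, 1-based insertion point); substitution_noise needs
    ``rate``; frameshift_indel needs ``delta`` (negative = deletion of
    ``|delta|`` bp at target.start, positive = insertion of ``delta``
    random bp before target.start), with ``|delta|`` in {1, 2}.
    """

    kind: str
    target: GenomicInterval
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in ("translocation", "duplication") and "dest" not in self.params:
            raise ValueError(f"{self.kind} event needs a 'dest' param")
        if self.kind == "substitution_noise" and "rate" not in self.params:
            raise ValueError("substitution_noise event needs a 'rate' param")
        if self.kind == "frameshift_indel":
            delta = self.params.get("delta")
            if delta not in (-2, -1, 1, 2):
                raise ValueError("frameshift_indel needs delta in {-2,-1,1,2}")


@dataclass
class TruthRecord:
    """Ground-truth expectation for one planted gene or SNP."""

    subject_id: str
    subject_type: str  # "gene" | "snp"
    event_kinds: tuple[str, ...] = ()
    expected_structure: str | None = None
    expected_protein: str | None = None
    expected_snp: str | None = None


def write_truth(records: list[TruthRecord], path) -> None:
    rows = [
        [
            r.subject_id,
            r.subject_type,
            ",".join(r.event_kinds) or ".",
            r.expected_structure or ".",
            r.expected_protein or ".",
            r.expected_snp or ".",
        ]
        for r in records
    ]
    write_tsv(
        path,
        ["subject_id", "type", "events", "expected_structure", "expected_protein", "expected_snp"],
        rows,
    )


def read_truth(path) -> list[TruthRecord]:
    _header, rows = read_tsv(path)
    out = []
    for sid, stype, ev, es, ep, esnp in rows:
        out.append(
            TruthRecord(
                sid,
                stype,
                tuple(ev.split(",")) if ev != "." else (),
                None if es == "." else es,
                None if ep == "." else ep,
                None if esnp == "." else esnp,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Genome and gene planting


def generate_genome(
    n_chrom: int,
    chrom_length_bp: int,
    gc_fraction: float = 0.42,
    seed: int = 0,
    name: str = "genomeA",
) -> GenomeAssembly:
    """Random i.i.d. genome with the requested GC content."""
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length_bp < 10_000:
        raise ValueError("chromosomes must be at least 10 kb")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    bases = np.frombuffer(b"ACGT", dtype="S1")
    placed = {}
    for i in range(1, n_chrom + 1):
        arr = rng.choice(bases, size=chrom_length_bp, p=probs)
        placed[f"chr{i}"] = arr.tobytes().decode()
    return GenomeAssembly(name, placed)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n).tobytes().decode()


_STOPS = {"TAA", "TAG", "TGA"}


def _make_cds_clean(rng: np.random.Generator, spliced: list[str], cds_start: int, cds_len: int) -> None:
    """In-place edit of a spliced sequence (as a char list): ATG start, TAA
    stop, no internal stop codons."""
    s0 = cds_start - 1
    spliced[s0 : s0 + 3] = list("ATG")
    spliced[s0 + cds_len - 3 : s0 + cds_len] = list("TAA")
    for i in range(s0 + 3, s0 + cds_len - 3, 3):
        codon = "".join(spliced[i : i + 3])
        if codon in _STOPS:
            spliced[i + 1] = "C"  # TCA/TCG are not stops


def plant_genes(
    genome: GenomeAssembly,
    n_genes: int,
    exon_count_range: tuple[int, int] = (2, 8),
    exon_len_range: tuple[int, int] = (100, 300),
    intron_len_range: tuple[int, int] = (60, 2000),
    seed: int = 0,
    utr5: int = 12,
    utr3: int = 18,
    margin: int = 300,
) -> tuple[GenomeAssembly, AnnotationSet, dict[str, str], dict[str, str]]:
    """Overwrite random loci with constructed genes.

    Returns (genome with genes written in, annotation, model mRNAs, model
    proteins). Genes land on both strands with equal probability and never
    overlap (a ``margin`` of untouched sequence separates them).
    """
    rng = np.random.default_rng(seed)
    chroms = {c: bytearray(s, "ascii") for c, s in genome.placed.items()}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    chrom_ids = list(chroms)
    weights = np.array([len(chroms[c]) for c in chrom_ids], dtype=float)
    weights /= weights.sum()

    transcripts: list[Transcript] = []
    mrnas: dict[str, str] = {}
    for gi in range(1, n_genes + 1):
        n_ex = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        exon_lens = [int(rng.integers(exon_len_range[0], exon_len_range[1] + 1)) for _ in range(n_ex)]
        intron_lens = [int(rng.integers(intron_len_range[0], intron_len_range[1] + 1)) for _ in range(n_ex - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        span = sum(exon_lens) + sum(intron_lens)

        placed_at = None
        for _attempt in range(300):
            chrom = chrom_ids[int(rng.choice(len(chrom_ids), p=weights))]
            limit = len(chroms[chrom]) - span - margin
            if limit <= margin:
                continue
            start = int(rng.integers(margin, limit))  # 0-based
            if all(start + span + margin <= s or start >= e + margin for s, e in occupied[chrom]):
                placed_at = (chrom, start)
                break
        if placed_at is None:
            raise RuntimeError(f"could not place gene {gi}: insufficient space")
        chrom, start0 = placed_at
        occupied[chrom].append((start0, start0 + span))

        spliced_len = sum(exon_lens)
        spliced = list(_random_dna(rng, spliced_len))
        cds_len = 3 * ((spliced_len - utr5 - utr3) // 3)
        _make_cds_clean(rng, spliced, utr5 + 1, cds_len)
        spliced_str = "".join(spliced)

        # assemble the sense-strand gene region
        parts = []
        off = 0
        exon_sense_offsets = []
        for i, el in enumerate(exon_lens):
            exon_sense_offsets.append(off + sum(intron_lens[:i]))
            parts.append(spliced_str[off : off + el])
            off += el
            if i < n_ex - 1:
                intron = list(_random_dna(rng, intron_lens[i]))
                intron[0:2] = list("GT")
                intron[-2:] = list("AG")
                parts.append("".join(intron))
        region = "".join(parts)
        assert len(region) == span

        gstart = start0 + 1  # 1-based
        gend = start0 + span
        if strand == "+":
            chroms[chrom][start0 : start0 + span] = region.encode()
            exons = [
                GenomicInterval(chrom, gstart + o, gstart + o + el - 1, "+")
                for o, el in zip(_sense_offsets(exon_lens, intron_lens), exon_lens)
            ]
        else:
            chroms[chrom][start0 : start0 + span] = revcomp(region).encode()
            exons = sorted(
                (
                    GenomicInterval(chrom, gend - (o + el - 1), gend - o, "-")
                    for o, el in zip(_sense_offsets(exon_lens, intron_lens), exon_lens)
                ),
                key=lambda iv: iv.start,
            )
        tid = f"T{gi:04d}"
        t = Transcript(
            tid,
            exons,
            gene_name=f"GENE{gi:04d}",
            evidence_accession=f"EVD{gi:06d}",
            cds=(utr5 + 1, utr5 + cds_len),
        )
        transcripts.append(t)
        mrnas[tid] = spliced_str

    new_genome = GenomeAssembly(genome.name, {c: bytes(b).decode() for c, b in chroms.items()}, dict(genome.unplaced))
    annotation = AnnotationSet(genome.name, transcripts)
    proteins = {}
    for t in transcripts:
        assert splice(t, new_genome) == mrnas[t.id], f"round-trip failure for {t.id}"
        prot = conceptual_translation(t, new_genome)
        assert "*" not in prot.sequence, f"internal stop in planted gene {t.id}"
        proteins[t.id] = prot.sequence
    return new_genome, annotation, mrnas, proteins


def _sense_offsets(exon_lens: list[int], intron_lens: list[int]) -> list[int]:
    out, off = [], 0
    for i, el in enumerate(exon_lens):
        out.append(off)
        off += el + (intron_lens[i] if i < len(intron_lens) else 0)
    return out


# ---------------------------------------------------------------------------
# Event application


def _contains(outer: GenomicInterval, start: int, end: int) -> bool:
    return outer.start <= start and end <= outer.end


def _overlaps(iv: GenomicInterval, chrom: str, start: int, end: int) -> bool:
    return iv.chrom == chrom and iv.start <= end and iv.end >= start


def validate_events(genome: GenomeAssembly, events: list[EventSpec]) -> None:
    structural = [e for e in events if e.kind != "substitution_noise"]
    for ev in events:
        if ev.target.chrom not in genome:
            raise ValueError(f"event target on unknown chromosome {ev.target.chrom!r}")
        if ev.target.end > len(genome.sequence(ev.target.chrom)):
            raise ValueError(f"event target {ev.target} exceeds chromosome")
    for i, a in enumerate(structural):
        for b in structural[i + 1 :]:
            if _overlaps(a.target, b.target.chrom, b.target.start, b.target.end):
                raise ValueError(f"overlapping structural events: {a.target} / {b.target}")


def apply_events(
    genome: GenomeAssembly,
    annotation: AnnotationSet,
    events: list[EventSpec],
    seed: int = 0,
    name_b: str = "genomeB",
    deletion_as_gap: bool = True,
) -> tuple[GenomeAssembly, AnnotationSet, list[TruthRecord]]:
    """Derive assembly B from the source, projecting the annotation and
    labeling every gene with its expected comparison outcome.

    Returns (assembly B, B's projected annotation, gene truth records).
    """
    validate_events(genome, events)
    rng = np.random.default_rng(seed)
    chroms = {c: bytearray(s, "ascii") for c, s in genome.placed.items()}
    unplaced: dict[str, str] = dict(genome.unplaced)

    # --- phase A: length-preserving in-place edits (source coordinates) ---
    for ev in events:
        tgt = ev.target
        buf = chroms[tgt.chrom]
        if ev.kind == "substitution_noise":
            rate = float(ev.params["rate"])
            span = tgt.end - tgt.start + 1
            hits = np.nonzero(rng.random(span) < rate)[0]
            for h in hits:
                pos = tgt.start - 1 + int(h)
                old = chr(buf[pos])
                if old == "N":
                    continue
                choices = [b for b in "ACGT" if b != old]
                buf[pos] = ord(choices[int(rng.integers(3))])
        elif ev.kind == "deletion" and deletion_as_gap:
            buf[tgt.start - 1 : tgt.end] = b"N" * (tgt.end - tgt.start + 1)
        elif ev.kind == "inversion":
            seg = bytes(buf[tgt.start - 1 : tgt.end]).decode()
            buf[tgt.start - 1 : tgt.end] = revcomp(seg).encode()
        elif ev.kind == "translocation":
            ev.params["_segment"] = bytes(buf[tgt.start - 1 : tgt.end]).decode()
            buf[tgt.start - 1 : tgt.end] = b"N" * (tgt.end - tgt.start + 1)
        elif ev.kind == "duplication":
            ev.params["_segment"] = bytes(buf[tgt.start - 1 : tgt.end]).decode()

    # --- phase B: length-changing edits, expressed in source coordinates ---
    # each edit: (start0, end0_exclusive, replacement, tag)
    edits: dict[str, list[tuple[int, int, str, str]]] = {c: [] for c in chroms}
    unplace_count = 0
    for ei, ev in enumerate(events):
        tgt = ev.target
        if ev.kind == "deletion" and not deletion_as_gap:
            edits[tgt.chrom].append((tgt.start - 1, tgt.end, "", f"del{ei}"))
        elif ev.kind == "unplace":
            unplace_count += 1
            contig_id = ev.params.setdefault("contig_id", f"chrUn_{unplace_count}")
            seg = bytes(chroms[tgt.chrom][tgt.start - 1 : tgt.end]).decode()
            unplaced[contig_id] = seg
            edits[tgt.chrom].append((tgt.start - 1, tgt.end, "", f"unplace{ei}"))
        elif ev.kind in ("translocation", "duplication"):
            dchrom, dpos = ev.params["dest"]
            ev.params["_tag"] = f"ins{ei}"
            edits[dchrom].append((dpos - 1, dpos - 1, ev.params["_segment"], f"ins{ei}"))
        elif ev.kind == "frameshift_indel":
            delta = ev.params["delta"]
            p0 = tgt.start - 1
            if delta < 0:
                edits[tgt.chrom].append((p0, p0 - delta, "", f"fs{ei}"))
            else:
                edits[tgt.chrom].append((p0, p0, _random_dna(rng, delta), f"fs{ei}"))

    new_placed: dict[str, str] = {}
    insert_final_start: dict[str, int] = {}  # tag -> final 1-based start
    lifts: dict[str, list[tuple[int, int, int]]] = {}  # chrom -> sorted (s0, e0, delta_len)
    for chrom, buf in chroms.items():
        elist = sorted(edits[chrom])
        for (s1, e1, _r1, _t1), (s2, _e2, _r2, _t2) in zip(elist, elist[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping edits on {chrom}")
        pieces = []
        cursor = 0
        delta = 0
        lift_entries = []
        for s0, e0, repl, tag in elist:
            pieces.append(bytes(buf[cursor:s0]).decode())
            if repl:
                insert_final_start[tag] = s0 + delta + 1
                pieces.append(repl)
            delta += len(repl) - (e0 - s0)
            lift_entries.append((s0, e0, len(repl) - (e0 - s0)))
            cursor = e0
        pieces.append(bytes(buf[cursor:]).decode())
        new_placed[chrom] = "".join(pieces)
        lifts[chrom] = lift_entries

    def lift(chrom: str, pos: int) -> int | None:
        """Map a source 1-based position to B; None if it was removed."""
        p0 = pos - 1
        delta = 0
        for s0, e0, d in lifts.get(chrom, []):
            if e0 <= p0:
                delta += d
            elif s0 <= p0 < e0:
                return None
            else:
                break
        return p0 + delta + 1

    genome_b = GenomeAssembly(name_b, new_placed, unplaced)

    # --- project the annotation and build gene truth ---
    structural = [e for e in events if e.kind != "substitution_noise"]
    b_transcripts: list[Transcript] = []
    truth: list[TruthRecord] = []
    for t in annotation:
        overlapping = [
            ev
            for ev in events
            if _overlaps(ev.target, t.chrom, t.start, t.end)
            and not (ev.kind == "substitution_noise" and ev.params["rate"] == 0)
        ]
        kinds = tuple(ev.kind for ev in overlapping)
        container = next(
            (ev for ev in structural if _overlaps(ev.target, t.chrom, t.start, t.end) and _contains(ev.target, t.start, t.end)),
            None,
        )
        projected = _project_transcript(t, overlapping, container, lift, insert_final_start, genome_b)
        if projected is not None:
            b_transcripts.append(projected)
        if container is not None and container.kind == "duplication":
            base = insert_final_start[container.params["_tag"]]
            seg_start = container.target.start
            dchrom = container.params["dest"][0]
            dup_exons = [
                GenomicInterval(dchrom, base + (e.start - seg_start), base + (e.end - seg_start), t.strand)
                for e in t.exons
            ]
            dup = Transcript(
                t.id + "_dup",
                dup_exons,
                gene_name=t.gene_name,
                evidence_accession=t.evidence_accession,
                cds=t.cds,
            )
            b_transcripts.append(dup)
        truth.append(_gene_truth(t, overlapping, container))

    annot_b = AnnotationSet(name_b, b_transcripts)
    annot_b.validate_against(genome_b)
    return genome_b, annot_b, truth


def _project_transcript(
    t: Transcript,
    overlapping: list[EventSpec],
    container: EventSpec | None,
    lift,
    insert_final_start: dict[str, int],
    genome_b: GenomeAssembly,
) -> Transcript | None:
    """Naive coordinate projection of one transcript into B."""
    if container is not None and container.kind == "translocation":
        base = insert_final_start[container.params["_tag"]]
        dchrom = container.params["dest"][0]
        seg_start = container.target.start
        exons = [
            GenomicInterval(dchrom, base + (e.start - seg_start), base + (e.end - seg_start), t.strand)
            for e in t.exons
        ]
        return _with_exons(t, exons, t.cds)
    if container is not None and container.kind == "unplace":
        contig = container.params["contig_id"]
        seg_start = container.target.start
        exons = [
            GenomicInterval(contig, e.start - seg_start + 1, e.end - seg_start + 1, t.strand)
            for e in t.exons
        ]
        return _with_exons(t, exons, t.cds)
    if container is not None and container.kind == "inversion":
        S, E = container.target.start, container.target.end
        flipped = "-" if t.strand == "+" else "+"
        exons = sorted(
            (
                GenomicInterval(t.chrom, S + E - e.end, S + E - e.start, flipped)
                for e in t.exons
            ),
            key=lambda iv: iv.start,
        )
        exons = [_lift_interval(iv, lift) for iv in exons]
        if any(iv is None for iv in exons):
            return None
        return _with_exons(t, exons, t.cds)  # type: ignore[arg-type]

    # everything else (incl. intra-genic breakpoints): keep exon slots
    exons = [_lift_interval(e, lift) for e in t.exons]
    if any(iv is None for iv in exons):
        return None
    cds = t.cds
    fs = [ev for ev in overlapping if ev.kind == "frameshift_indel"]
    if fs and cds is not None:
        new_len = sum(iv.end - iv.start + 1 for iv in exons)  # type: ignore[union-attr]
        s, e = cds
        e = min(e, new_len)
        e = s - 1 + 3 * ((e - s + 1) // 3)
        cds = (s, e) if e >= s + 2 else None
    return _with_exons(t, exons, cds)  # type: ignore[arg-type]


def _lift_interval(iv: GenomicInterval, lift) -> GenomicInterval | None:
    s = lift(iv.chrom, iv.start)
    e = lift(iv.chrom, iv.end)
    if s is None or e is None or e < s:
        return None
    return GenomicInterval(iv.chrom, s, e, iv.strand)


def _with_exons(t: Transcript, exons: list[GenomicInterval], cds) -> Transcript:
    return Transcript(
        t.id,
        exons,
        gene_name=t.gene_name,
        evidence_accession=t.evidence_accession,
        cds=cds,
    )


def _gene_truth(
    t: Transcript, overlapping: list[EventSpec], container: EventSpec | None
) -> TruthRecord:
    kinds = tuple(ev.kind for ev in overlapping)
    rec = TruthRecord(t.id, "gene", kinds)
    if not overlapping:
        rec.expected_structure = "identical"
        rec.expected_protein = "identical"
        return rec
    if all(ev.kind == "substitution_noise" for ev in overlapping):
        rec.expected_structure = "identical"
        rec.expected_protein = "near_identical"
        return rec
    if container is not None:
        # whole gene inside one event: position/strand change only
        rec.expected_structure = "identical"
        rec.expected_protein = "identical"
        return rec
    fs = [ev for ev in overlapping if ev.kind == "frameshift_indel"]
    if fs and all(ev.kind in ("frameshift_indel", "substitution_noise") for ev in overlapping):
        rec.expected_structure = "identical"
        rec.expected_protein = "not_near"
        return rec
    dels = [ev for ev in overlapping if ev.kind == "deletion"]
    if dels and all(ev.kind in ("deletion", "substitution_noise") for ev in overlapping):
        ev = dels[0]
        covered = [e for e in t.exons if _contains(ev.target, e.start, e.end)]
        if covered and (t.exons[0] in covered or t.exons[-1] in covered) and len(covered) < len(t.exons):
            rec.expected_structure = "truncations"
            return rec
        rec.expected_structure = "complex"
        return rec
    # intra-genic inversion/translocation breakpoint, or mixtures
    rec.expected_structure = "complex"
    return rec


# ---------------------------------------------------------------------------
# SNP planting


def plant_snps(
    genome: GenomeAssembly,
    n_snps: int,
    flank_bp: int = 250,
    seed: int = 0,
    within: list[GenomicInterval] | None = None,
    avoid: list[GenomicInterval] | None = None,
    expected: str = "mapped",
    rsid_start: int = 1,
) -> tuple[list[SNPContext], list[TruthRecord], list[GenomicInterval]]:
    """Plant SNPs with verbatim flanking context copied from the genome.

    ``within`` restricts placement to the given intervals (e.g. segments a
    later event will duplicate or unplace); ``avoid`` keeps whole contexts
    out of the given intervals. ``expected`` is recorded as the truth
    outcome. Returns (contexts, truth records, planted positions).
    """
    if flank_bp < 1:
        raise ValueError("flank_bp must be >= 1 (a SNP needs flanking context)")
    rng = np.random.default_rng(seed)
    chrom_ids = list(genome.placed)
    positions: list[tuple[str, int]] = []
    taken: set[tuple[str, int]] = set()
    attempts = 0
    while len(positions) < n_snps:
        attempts += 1
        if attempts > 200 * n_snps:
            raise RuntimeError("could not place SNPs: too many rejected positions")
        if within:
            iv = within[int(rng.integers(len(within)))]
            lo, hi = iv.start + flank_bp, iv.end - flank_bp
            if hi < lo:
                raise RuntimeError(f"interval {iv} too small for flank {flank_bp}")
            chrom = iv.chrom
            pos = int(rng.integers(lo, hi + 1))
        else:
            chrom = chrom_ids[int(rng.integers(len(chrom_ids)))]
            L = len(genome.placed[chrom])
            if L < 2 * flank_bp + 1:
                continue
            pos = int(rng.integers(flank_bp + 1, L - flank_bp + 1))
        if (chrom, pos) in taken:
            continue
        if genome.placed[chrom][pos - 1] == "N":
            continue
        if avoid and any(
            _overlaps(av, chrom, pos - flank_bp, pos + flank_bp) for av in avoid
        ):
            continue
        taken.add((chrom, pos))
        positions.append((chrom, pos))

    snps, truth, placed_at = [], [], []
    for i, (chrom, pos) in enumerate(positions):
        seq = genome.placed[chrom]
        ref = seq[pos - 1]
        alt = "ACGT"[int(rng.integers(4))]
        while alt == ref:
            alt = "ACGT"[int(rng.integers(4))]
        rsid = f"snp{rsid_start + i:06d}"
        snps.append(
            SNPContext(
                rsid,
                seq[pos - 1 - flank_bp : pos - 1],
                frozenset({ref, alt}),
                seq[pos : pos + flank_bp],
            )
        )
        truth.append(TruthRecord(rsid, "snp", (), expected_snp=expected))
        placed_at.append(GenomicInterval(chrom, pos, pos))
    return snps, truth, placed_at


# ---------------------------------------------------------------------------
# Event list I/O (TSV: kind, chrom, start, end, params as key=value;...)


def write_events(events: list[EventSpec], path) -> None:
    rows = []
    for ev in events:
        parts = []
        for k, v in ev.params.items():
            if k.startswith("_"):
                continue
            if k == "dest":
                parts.append(f"dest={v[0]}:{v[1]}")
            else:
                parts.append(f"{k}={v}")
        rows.append([ev.kind, ev.target.chrom, ev.target.start, ev.target.end, ";".join(parts) or "."])
    write_tsv(path, ["kind", "chrom", "start", "end", "params"], rows)


def read_events(path) -> list[EventSpec]:
    _header, rows = read_tsv(path)
    out = []
    for kind, chrom, start, end, params_s in rows:
        params: dict = {}
        if params_s != ".":
            for part in params_s.split(";"):
                k, v = part.split("=", 1)
                if k == "dest":
                    dchrom, dpos = v.rsplit(":", 1)
                    params["dest"] = (dchrom, int(dpos))
                elif k in ("rate",):
                    params[k] = float(v)
                elif k in ("delta",):
                    params[k] = int(v)
                else:
                    params[k] = v
        out.append(EventSpec(kind, GenomicInterval(chrom, int(start), int(end)), params))
    return out
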