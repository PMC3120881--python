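"""Domain types and coordinate arithmetic shared by every pipeline stage.

Conventions used throughout the package:

* Genomic coordinates are **1-based, fully inclusive** (``start=5, end=5`` is a
  single base), matching the convention of GFF3 and of every printed genome
  coordinate in the annotation-comparison literature this package serves.
* Exons of a transcript are stored in ascending genomic order regardless of
  strand; the order along the mRNA is derived from the strand.
* A CDS is a ``(start, end)`` pair in 1-based *transcript* (spliced)
  coordinates, so it survives relocation of the gene unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_RC)[::-1]


class CoordinateError(ValueError):
    """An interval or position falls outside its chromosome."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp of a 1-based inclusive interval (end - start + 1)."""
    return iv.end - iv.start + 1


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the intersection of two intervals; 0 if disjoint or on
    different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


@dataclass
class GenomeAssembly:
    """Named chromosome sequences plus a pool of unplaced contigs.

    The placed/unplaced distinction matters downstream: SNP remapping
    searches placed chromosomes only, unless unplaced rescue is requested.
    """

    name: str
    placed: dict[str, str]
    unplaced: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = set(self.placed) & set(self.unplaced)
        if dup:
            raise ValueError(f"sequence ids duplicated across placed/unplaced: {sorted(dup)}")
        for sid, seq in self.sequences().items():
            if not seq:
                raise ValueError(f"empty sequence {sid!r}")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)} in sequence {sid!r}")

    def sequences(self) -> dict[str, str]:
        out = dict(self.placed)
        out.update(self.unplaced)
        return out

    def sequence(self, chrom: str) -> str:
        try:
            return self.placed[chrom]
        except KeyError:
            try:
                return self.unplaced[chrom]
            except KeyError:
                raise KeyError(f"no sequence {chrom!r} in assembly {self.name!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.placed or chrom in self.unplaced

    def fetch(self, iv: GenomicInterval) -> str:
        """Forward-strand slice of an interval (strand is not applied)."""
        seq = self.sequence(iv.chrom)
        if iv.end > len(seq):
            raise CoordinateError(
                f"{iv.chrom}:{iv.start}-{iv.end} exceeds length {len(seq)}"
            )
        return seq[iv.start - 1 : iv.end]


@dataclass
class Transcript:
    """An exon-intron structure with optional gene name, evidence accession
    and CDS.

    ``exons`` are ascending, same chromosome/strand, separated by at least
    1 bp (the introns). ``cds`` is in transcript coordinates and must have
    length divisible by three.
    """

    id: str
    exons: list[GenomicInterval]
    gene_name: str | None = None
    evidence_accession: str | None = None
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id!r} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.id!r} mixes chromosomes or strands")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start <= prev.end + 1:
                raise ValueError(
                    f"transcript {self.id!r}: exons not ascending/separated "
                    f"({prev.start}-{prev.end} then {cur.start}-{cur.end})"
                )
        if self.cds is not None:
            s, e = self.cds
            if not (1 <= s <= e <= self.spliced_length):
                raise ValueError(f"transcript {self.id!r}: CDS {s}-{e} outside spliced length")
            if (e - s + 1) % 3 != 0:
                raise ValueError(f"transcript {self.id!r}: CDS length not divisible by 3")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic (start, end) of every intron, ascending."""
        return [
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        ]

    def exons_in_transcript_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def genomic_position(self, tpos: int) -> int:
        """Map a 1-based transcript coordinate to its genomic position."""
        if not (1 <= tpos <= self.spliced_length):
            raise CoordinateError(f"transcript position {tpos} outside 1..{self.spliced_length}")
        off = tpos
        for exon in self.exons_in_transcript_order():
            if off <= len(exon):
                if self.strand == "+":
                    return exon.start + off - 1
                return exon.end - off + 1
            off -= len(exon)
        raise AssertionError("unreachable")

    def cds_genomic_intervals(self) -> list[GenomicInterval]:
        """The CDS as ascending genomic intervals (empty if no CDS)."""
        if self.cds is None:
            return []
        s, e = self.cds
        out: list[GenomicInterval] = []
        off = 0  # transcript bases consumed so far
        for exon in self.exons_in_transcript_order():
            lo, hi = off + 1, off + len(exon)
            if hi >= s and lo <= e:
                a, b = max(lo, s), min(hi, e)
                if self.strand == "+":
                    out.append(
                        GenomicInterval(self.chrom, exon.start + (a - lo), exon.start + (b - lo), "+")
                    )
                else:
                    out.append(
                        GenomicInterval(self.chrom, exon.end - (b - lo), exon.end - (a - lo), "-")
                    )
            off = hi
        return sorted(out, key=lambda iv: iv.start)


@dataclass
class ProteinRecord:
    """An amino-acid sequence; internal stops are kept as ``*`` and
    untranslatable (N-containing) codons as ``X``."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} is empty")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"illegal residues {sorted(bad)} in protein {self.id!r}")


class AnnotationSet:
    """A set of transcripts on one assembly with a per-chromosome interval
    index for overlap queries."""

    def __init__(self, assembly_name: str, transcripts: list[Transcript]):
        self.assembly_name = assembly_name
        self.transcripts = list(transcripts)
        ids = [t.id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate transcript ids in annotation set")
        self._by_id = {t.id: t for t in self.transcripts}
        self._index: dict[str, list[Transcript]] = {}
        for t in self.transcripts:
            self._index.setdefault(t.chrom, []).append(t)
        for lst in self._index.values():
            lst.sort(key=lambda t: (t.start, t.end, t.id))

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def __getitem__(self, tid: str) -> Transcript:
        return self._by_id[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self._by_id

    def overlapping(self, chrom: str, start: int, end: int) -> list[Transcript]:
        """Transcripts whose genomic span intersects [start, end]."""
        return [
            t
            for t in self._index.get(chrom, [])
            if t.start <= end and t.end >= start
        ]

    def validate_against(self, genome: GenomeAssembly) -> None:
        for t in self.transcripts:
            if t.chrom not in genome:
                raise ValueError(f"transcript {t.id!r} on unknown chromosome {t.chrom!r}")
            if t.end > len(genome.sequence(t.chrom)):
                raise CoordinateError(f"transcript {t.id!r} exceeds chromosome {t.chrom!r}")


def splice(t: Transcript, genome: GenomeAssembly) -> str:
    """Spliced (mRNA) sequence of a transcript.

    Exon substrings are concatenated in ascending genomic order and the
    whole result is reverse-complemented for '-' strand transcripts.
    """
    parts = [genome.fetch(e) for e in t.exons]
    seq = "".join(parts)
    return revcomp(seq) if t.strand == "-" else seq


def translate_cds(cds_seq: str) -> str:
    """Standard-code translation: internal stops read through as '*',
    N-containing codons become 'X', one trailing stop is dropped."""
    if len(cds_seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    aa = str(Seq(cds_seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def conceptual_translation(t: Transcript, genome: GenomeAssembly) -> ProteinRecord:
    """Direct translation of the annotated CDS from the genome, with no
    frameshift correction: assembly damage shows up as '*' and 'X' runs."""
    if t.cds is None:
        raise ValueError(f"transcript {t.id!r} has no CDS")
    s, e = t.cds
    mrna = splice(t, genome)
    return ProteinRecord(t.id, translate_cds(mrna[s - 1 : e]))
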