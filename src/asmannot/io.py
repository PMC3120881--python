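"""Readers and writers for the formats the pipeline touches.

Supported formats: multi-record wrapped FASTA; GFF3 (gene/mRNA/exon/CDS rows
with ``ID``/``Parent`` and the package's ``gene_name``/``evidence``
attributes); SNP tables in TSV or dbSNP-style bracket flanking syntax
(``ACGT...[A/G]...ACGT``); plain TSV reports with a ``#``-prefixed header.

All readers reject malformed input rather than repairing it; every writer
produces input its reader round-trips.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .core import (
    DNA_ALPHABET,
    AA_ALPHABET,
    AnnotationSet,
    GenomeAssembly,
    GenomicInterval,
    Transcript,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: frozenset[str] = DNA_ALPHABET) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence map.

    Ids are the first whitespace-delimited token; sequences are uppercased
    and validated against ``alphabet``. Empty records, duplicate ids and
    illegal characters are errors naming the offending record.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in out:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        if not seq:
            raise ParseError(f"empty FASTA record {rec.id!r} in {path}")
        bad = set(seq) - alphabet
        if bad:
            raise ParseError(
                f"illegal characters {sorted(bad)} in FASTA record {rec.id!r} in {path}"
            )
        out[rec.id] = seq
    return out


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    return read_fasta(path, alphabet=AA_ALPHABET)


def write_fasta(records: dict[str, str], path: str | Path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def _parse_attrs(field: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ParseError(f"GFF3 line {lineno}: malformed attribute {part!r}")
        k, v = part.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str | Path, genome: GenomeAssembly) -> AnnotationSet:
    """Assemble an AnnotationSet from GFF3 gene/mRNA/exon/CDS rows.

    CDS rows (genomic) are converted to transcript coordinates. Errors carry
    the 1-based line number of the offending row.
    """
    mrnas: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version 3"):
            raise ParseError(f"{path}: missing '##gff-version 3' pragma")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attr_field = cols
            if ftype == "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"GFF3 line {lineno}: non-integer coordinates") from None
            if chrom not in genome:
                raise ParseError(f"GFF3 line {lineno}: unknown chromosome {chrom!r}")
            if start_i < 1 or end_i < start_i or end_i > len(genome.sequence(chrom)):
                raise ParseError(
                    f"GFF3 line {lineno}: coordinates {start_i}-{end_i} outside {chrom!r}"
                )
            attrs = _parse_attrs(attr_field, lineno)
            if ftype == "mRNA":
                tid = attrs.get("ID")
                if not tid:
                    raise ParseError(f"GFF3 line {lineno}: mRNA without ID")
                if tid in mrnas:
                    raise ParseError(f"GFF3 line {lineno}: duplicate mRNA ID {tid!r}")
                mrnas[tid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "gene_name": attrs.get("gene_name"),
                    "evidence": attrs.get("evidence"),
                    "exons": [],
                    "cds": [],
                }
                order.append(tid)
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if not parent or parent not in mrnas:
                    raise ParseError(
                        f"GFF3 line {lineno}: {ftype} without known parent mRNA"
                    )
                rec = mrnas[parent]
                if chrom != rec["chrom"]:
                    raise ParseError(
                        f"GFF3 line {lineno}: {ftype} on {chrom!r} but mRNA on {rec['chrom']!r}"
                    )
                rec["exons" if ftype == "exon" else "cds"].append(
                    (start_i, end_i, strand, lineno)
                )
            # other feature types are ignored
    transcripts = []
    for tid in order:
        rec = mrnas[tid]
        if not rec["exons"]:
            raise ParseError(f"mRNA {tid!r} has no exon rows")
        exons = sorted(rec["exons"])
        ivs = [GenomicInterval(rec["chrom"], s, e, rec["strand"]) for s, e, _st, _ln in exons]
        t = Transcript(
            tid,
            ivs,
            gene_name=rec["gene_name"],
            evidence_accession=rec["evidence"],
        )
        if rec["cds"]:
            t.cds = _cds_to_transcript_coords(t, rec["cds"])
            t.__post_init__()  # re-validate with CDS attached
        transcripts.append(t)
    return AnnotationSet(genome.name, transcripts)


def _cds_to_transcript_coords(
    t: Transcript, cds_rows: list[tuple[int, int, str, int]]
) -> tuple[int, int]:
    """Convert genomic CDS segments to a (start, end) transcript-coordinate
    pair, verifying every segment lies within the exons."""
    # transcript coordinate of each genomic position, walked in mRNA order
    tpos_of_start: dict[int, int] = {}
    off = 0
    for exon in t.exons_in_transcript_order():
        tpos_of_start[exon.start] = off
        off += len(exon)

    def to_tpos(gpos: int, lineno: int) -> int:
        for exon in t.exons:
            if exon.start <= gpos <= exon.end:
                base = tpos_of_start[exon.start]
                if t.strand == "+":
                    return base + (gpos - exon.start) + 1
                return base + (exon.end - gpos) + 1
        raise ParseError(f"GFF3 line {lineno}: CDS position {gpos} outside exons of {t.id!r}")

    tcoords = []
    for s, e, _st, lineno in cds_rows:
        tcoords.append(to_tpos(s, lineno))
        tcoords.append(to_tpos(e, lineno))
    return min(tcoords), max(tcoords)


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in annotation:
            attrs = [f"ID=gene:{t.id}"]
            if t.gene_name:
                attrs.append(f"gene_name={t.gene_name}")
            fh.write(
                "\t".join(
                    [t.chrom, "asmannot", "gene", str(t.start), str(t.end), ".", t.strand, ".", ";".join(attrs)]
                )
                + "\n"
            )
            mattrs = [f"ID={t.id}", f"Parent=gene:{t.id}"]
            if t.gene_name:
                mattrs.append(f"gene_name={t.gene_name}")
            if t.evidence_accession:
                mattrs.append(f"evidence={t.evidence_accession}")
            fh.write(
                "\t".join(
                    [t.chrom, "asmannot", "mRNA", str(t.start), str(t.end), ".", t.strand, ".", ";".join(mattrs)]
                )
                + "\n"
            )
            for exon in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, "asmannot", "exon", str(exon.start), str(exon.end), ".", t.strand, ".", f"Parent={t.id}"]
                    )
                    + "\n"
                )
            for seg in t.cds_genomic_intervals():
                fh.write(
                    "\t".join(
                        [t.chrom, "asmannot", "CDS", str(seg.start), str(seg.end), ".", t.strand, "0", f"Parent={t.id}"]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# SNP context records

_BRACKET_RE = re.compile(r"^([ACGTN]*)\[([ACGT](?:/[ACGT])+)\]([ACGTN]*)$")


@dataclass
class SNPContext:
    """A SNP and its flanking genomic context, dbSNP style."""

    rsid: str
    flank5: str
    alleles: frozenset[str]
    flank3: str

    def __post_init__(self) -> None:
        if not self.flank5 and not self.flank3:
            raise ParseError(f"SNP {self.rsid!r}: both flanks empty")
        if not self.alleles <= frozenset("ACGT") or len(self.alleles) < 2:
            raise ParseError(f"SNP {self.rsid!r}: invalid alleles {sorted(self.alleles)}")
        for name, fl in (("flank5", self.flank5), ("flank3", self.flank3)):
            bad = set(fl) - DNA_ALPHABET
            if bad:
                raise ParseError(f"SNP {self.rsid!r}: illegal characters in {name}")

    def context(self, ref: str | None = None) -> str:
        """flank5 + one allele + flank3 (the alphabetically first allele by
        default, which for generated SNPs is set to the reference)."""
        base = ref if ref is not None else sorted(self.alleles)[0]
        return self.flank5 + base + self.flank3

    @property
    def variant_offset(self) -> int:
        """1-based position of the variant base within the context."""
        return len(self.flank5) + 1


def parse_bracket_context(rsid: str, text: str) -> SNPContext:
    m = _BRACKET_RE.match(text.strip().upper())
    if not m:
        raise ParseError(f"SNP {rsid!r}: malformed bracket context {text!r}")
    flank5, alleles, flank3 = m.groups()
    return SNPContext(rsid, flank5, frozenset(alleles.split("/")), flank3)


def read_snp_table(path: str | Path) -> list[SNPContext]:
    """Read SNP records from TSV (rsid, flank5, alleles, flank3) or two-column
    bracket syntax (rsid, ``FLANK5[A/G]FLANK3``)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if len(cols) == 2:
                    out.append(parse_bracket_context(cols[0], cols[1]))
                elif len(cols) == 4:
                    rsid, flank5, alleles, flank3 = cols
                    allele_set = frozenset(re.split(r"[/,]", alleles.strip().upper()))
                    out.append(SNPContext(rsid, flank5.upper(), allele_set, flank3.upper()))
                else:
                    raise ParseError(f"expected 2 or 4 columns, got {len(cols)}")
            except ParseError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from None
    return out


def write_snp_table(snps: list[SNPContext], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#rsid\tflank5\talleles\tflank3\n")
        for s in snps:
            fh.write(f"{s.rsid}\t{s.flank5}\t{'/'.join(sorted(s.alleles))}\t{s.flank3}\n")


# ---------------------------------------------------------------------------
# Report TSVs

def write_tsv(path: str | Path, header: list[str], rows: list[list], comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"## {c}\n")
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    header: list[str] = []
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#"):
                header = line[1:].split("\t")
                continue
            rows.append(line.split("\t"))
    return header, rows


# ---------------------------------------------------------------------------
# Spliced-alignment TSV (block list encoded as qs-qe:gs-ge pairs)


def write_alignments_tsv(alns, path: str | Path) -> None:
    from .align import SplicedAlignment  # noqa: F401  (type reference)

    rows = []
    for a in alns:
        blocks = ",".join(
            f"{b.query_start}-{b.query_end}:{b.genome.start}-{b.genome.end}" for b in a.blocks
        )
        rows.append(
            [
                a.query_id,
                a.chrom,
                a.strand,
                blocks,
                f"{a.identity:.4f}",
                f"{a.coverage:.4f}",
                str(a.query_length),
                "1" if a.is_primary else "0",
            ]
        )
    write_tsv(
        path,
        ["query", "chrom", "strand", "blocks", "identity", "coverage", "query_length", "primary"],
        rows,
    )


def read_alignments_tsv(path: str | Path):
    from .align import AlignmentBlock, SplicedAlignment

    _header, rows = read_tsv(path)
    out = []
    for qid, chrom, strand, blocks_s, ident, cov, qlen, primary in rows:
        blocks = []
        for part in blocks_s.split(","):
            qspan, gspan = part.split(":")
            qs, qe = (int(x) for x in qspan.split("-"))
            gs, ge = (int(x) for x in gspan.split("-"))
            blocks.append(
                AlignmentBlock(qs, qe, GenomicInterval(chrom, gs, ge, strand), 0, 0, 0)
            )
        out.append(
            SplicedAlignment(
                query_id=qid,
                chrom=chrom,
                strand=strand,
                blocks=blocks,
                identity=float(ident),
                coverage=float(cov),
                query_length=int(qlen),
                is_primary=primary == "1",
            )
        )
    return out
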