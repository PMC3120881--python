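#!/usr/bin/env python
"""Map the source annotation's transcript sequences onto the derived
assembly with the seeded spliced aligner (alignments longer than 100 bp at
>= 95% identity retained; best alignment flagged primary) and tabulate the
coverage curves that show how much of each gene the other assembly still
carries.

Reads results/sim/, writes alignments.tsv and coverage_{all,best}.tsv
under results/.
"""

from pathlib import Path

from asmannot import io as aio
from asmannot.align import coverage_curve
from asmannot.core import GenomeAssembly
from asmannot.pipeline import PipelineConfig, map_transcripts, render_curve

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
OUT = ROOT / "results"


def load_genome(path: Path) -> GenomeAssembly:
    seqs = aio.read_fasta(path)
    placed = {k: v for k, v in seqs.items() if not k.startswith("chrUn")}
    unplaced = {k: v for k, v in seqs.items() if k.startswith("chrUn")}
    return GenomeAssembly(path.stem, placed, unplaced)


def main() -> None:
    genome_b = load_genome(SIM / "genomeB.fa")
    mrnas = aio.read_fasta(SIM / "models_mrna.fa")
    cfg = PipelineConfig()
    alns = map_transcripts(mrnas, genome_b, cfg)
    flat = [a for group in alns.values() for a in group]
    aio.write_alignments_tsv(flat, OUT / "alignments.tsv")
    qlens = {q: len(s) for q, s in mrnas.items()}
    render_curve(coverage_curve(qlens, flat, mode="all"), OUT / "coverage_all.tsv")
    render_curve(coverage_curve(qlens, flat, mode="best"), OUT / "coverage_best.tsv")

    full = sum(
        1
        for group in alns.values()
        if any(a.is_primary and a.coverage >= 0.999 for a in group)
    )
    partial = sum(1 for group in alns.values() if group) - full
    missing = sum(1 for group in alns.values() if not group)
    print(f"mapped {len(mrnas)} transcripts onto {genome_b.name}:")
    print(f"  fully covered by their primary alignment: {full}")
    print(f"  partially covered (fragmented/incomplete): {partial}")
    print(f"  no retained alignment: {missing}")
    print(f"alignments and coverage curves in {OUT}")


if __name__ == "__main__":
    main()
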