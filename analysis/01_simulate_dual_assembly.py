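#!/usr/bin/env python
"""Build the study's dual assembly: a source genome with planted genes and
a derived assembly carrying one labeled mis-assembly event per gene cohort
(terminal-exon deletion, internal-exon deletion, intra-genic inversion,
whole-gene translocation, frameshift indel) plus event-free controls.

Writes the simulated inputs (FASTA/GFF3/TSV) under results/sim/ for the
later analysis steps to consume, and reports what was planted.
"""

from pathlib import Path

from asmannot import io as aio
from asmannot.scenarios import event_recovery_scenario
from asmannot.simulate import write_events, write_truth

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "sim"  # large generated inputs stay out of results/
SEED = 2011


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle, categories = event_recovery_scenario(SEED, genes_per_event=10, n_event_free=10)
    aio.write_fasta(bundle.genome_a.sequences(), OUT / "genomeA.fa")
    aio.write_fasta(bundle.genome_b.sequences(), OUT / "genomeB.fa")
    aio.write_gff3(bundle.annot_a, OUT / "annotA.gff3")
    aio.write_gff3(bundle.annot_b, OUT / "annotB.gff3")
    aio.write_fasta(bundle.mrnas, OUT / "models_mrna.fa")
    aio.write_fasta(bundle.proteins, OUT / "models_protein.fa")
    write_events(bundle.events, OUT / "events.tsv")
    write_truth(bundle.truth, OUT / "truth.tsv")
    aio.write_tsv(
        OUT / "categories.tsv",
        ["gene", "category"],
        [[tid, cat] for tid, cat in sorted(categories.items())],
    )
    n_by_cat: dict[str, int] = {}
    for cat in categories.values():
        n_by_cat[cat] = n_by_cat.get(cat, 0) + 1
    print(f"planted {len(bundle.annot_a)} genes on {len(bundle.genome_a.placed)} chromosomes")
    for cat, n in sorted(n_by_cat.items()):
        print(f"  {cat}: {n} genes")
    print(f"derived assembly carries {len(bundle.events)} events; inputs in {OUT}")


if __name__ == "__main__":
    main()
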