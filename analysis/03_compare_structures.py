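#!/usr/bin/env python
"""Compare the alignment-projected exon-intron structures against the
derived assembly's own annotation: priority-coded best matches, the
classification rollup (identical / extensions / truncations / both /
complex), agreement curves and the recovery of the planted ground truth.

Reads results/sim/ and results/alignments.tsv; writes structure tables
under results/.
"""

from pathlib import Path

from asmannot import io as aio
from asmannot.pipeline import (
    PipelineConfig,
    compare_structures_direction,
    render_curve,
    render_structure_summary,
)
from asmannot.simulate import read_truth
from asmannot.structures import ROLLUP

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
OUT = ROOT / "results"


def main() -> None:
    from importlib import import_module
    load_genome = import_module("02_map_transcripts").load_genome  # type: ignore

    genome_b = load_genome(SIM / "genomeB.fa")
    genome_a = load_genome(SIM / "genomeA.fa")
    annot_a = aio.read_gff3(SIM / "annotA.gff3", genome_a)
    annot_b = aio.read_gff3(SIM / "annotB.gff3", genome_b)
    mrnas = aio.read_fasta(SIM / "models_mrna.fa")
    alns = aio.read_alignments_tsv(OUT / "alignments.tsv")
    by_query: dict[str, list] = {q: [] for q in mrnas}
    for a in alns:
        by_query.setdefault(a.query_id, []).append(a)

    cfg = PipelineConfig()
    rep = compare_structures_direction(mrnas, annot_a, genome_b, annot_b, cfg, alignments=by_query)
    render_structure_summary(rep.summary_counts, OUT / "structure_summary.tsv", cfg)
    render_curve(rep.agreement_all, OUT / "agreement_all.tsv")
    render_curve(rep.agreement_best, OUT / "agreement_best.tsv")
    aio.write_tsv(
        OUT / "structure_matches.tsv",
        ["query", "best_match", "class", "rollup"],
        [
            [q, bm.candidate_id, bm.match_class.name, ROLLUP[bm.match_class]]
            for q, bm in sorted(rep.best_matches.items())
        ],
    )

    truth = {r.subject_id: r for r in read_truth(SIM / "truth.tsv") if r.subject_type == "gene"}
    hits = misses = 0
    for tid, rec in truth.items():
        if rec.expected_structure is None:
            continue
        if rep.rollup.get(tid) == rec.expected_structure:
            hits += 1
        else:
            misses += 1
    total = sum(rep.summary_counts.values())
    print(f"best matches for {total} transcripts:")
    for k, v in rep.summary_counts.items():
        print(f"  {k}: {v}")
    print(f"ground-truth structure classes recovered: {hits}/{hits + misses}")
    print(f"tables in {OUT}")


if __name__ == "__main__":
    import sys

    sys.path.insert(0, str(Path(__file__).resolve().parent))
    main()
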