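#!/usr/bin/env python
"""Translate the derived assembly's annotated CDSs directly from its
genomic sequence (no frameshift correction) and classify each conceptual
translation against its model protein: identical, near-identical,
extension, truncation, divergent ends, gapped, different, other.

Reads results/sim/; writes protein tables under results/.
"""

from pathlib import Path

from asmannot import io as aio
from asmannot.core import ProteinRecord, conceptual_translation
from asmannot.pipeline import PipelineConfig, render_protein_summary
from asmannot.proteins import classify_protein_pair, summarize_protein_classes

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
OUT = ROOT / "results"


def main() -> None:
    import sys
    from importlib import import_module

    sys.path.insert(0, str(Path(__file__).resolve().parent))
    load_genome = import_module("02_map_transcripts").load_genome  # type: ignore

    genome_b = load_genome(SIM / "genomeB.fa")
    annot_b = aio.read_gff3(SIM / "annotB.gff3", genome_b)
    models = aio.read_protein_fasta(SIM / "models_protein.fa")

    cfg = PipelineConfig()
    rows, classes = [], []
    n_with_stops = 0
    for t in annot_b:
        model_id = t.id[:-4] if t.id.endswith("_dup") else t.id
        if model_id not in models or t.cds is None:
            continue
        predicted = conceptual_translation(t, genome_b)
        cls = classify_protein_pair(predicted, ProteinRecord(model_id, models[model_id]), cfg.protein)
        classes.append(cls)
        if "*" in predicted.sequence:
            n_with_stops += 1
        rows.append([t.id, model_id, cls, len(predicted.sequence), len(models[model_id])])
    aio.write_tsv(
        OUT / "protein_classes.tsv",
        ["predicted", "model", "class", "predicted_aa", "model_aa"],
        rows,
    )
    summary = summarize_protein_classes(classes)
    render_protein_summary(summary, OUT / "protein_summary.tsv", cfg)
    print(f"classified {len(classes)} conceptual translations against their models:")
    for k, v in summary.items():
        if v:
            print(f"  {k}: {v}")
    print(f"translations containing in-frame stops (assembly damage): {n_with_stops}")
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
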