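"""End-to-end orchestration: simulate -> align -> compare -> report.

Every stage consumes and produces plain files (FASTA/GFF3/TSV), so any
stage can be run standalone on externally produced inputs; the in-memory
entry points below are what the tests, the analysis scripts and the
acceptance harness drive directly.

Percentages in all rendered tables are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from .align import (
    KmerIndex,
    SplicedAlignment,
    coverage_curve,
    filter_alignments,
    map_query,
    select_primary,
)
from .core import AnnotationSet, GenomeAssembly, ProteinRecord, conceptual_translation
from .io import write_tsv
from .proteins import (
    PROTEIN_CLASSES,
    ProteinThresholds,
    classify_protein_pair,
    summarize_protein_classes,
)
from .scenarios import SimBundle
from .snps import SNPMapParams, map_snps
from .structures import (
    ROLLUP,
    ROLLUP_ORDER,
    BestMatch,
    agreement_curve,
    assign_best_match,
    structure_from_alignment,
    summarize_classes,
)


def percent(count: int, total: int) -> float:
    """count/total as a percentage rounded half-up to one decimal."""
    if total == 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """All thresholds, at their standard defaults."""

    aligner_k: int = 20
    min_align_len: int = 100  # keep alignments strictly longer than this
    min_align_identity: float = 0.95
    min_intron: int = 30
    margin: int = 20  # V: boundary tolerance for structure comparison
    min_overlap: int = 50  # exonic bp for comparability
    protein: ProteinThresholds = field(default_factory=ProteinThresholds)
    snp: SNPMapParams = field(default_factory=SNPMapParams)
    seed: int = 0

    def describe(self) -> list[str]:
        return [f"{k}={v}" for k, v in asdict(self).items()]


@dataclass
class StructureReport:
    best_matches: dict[str, BestMatch]
    rollup: dict[str, str]  # query id -> rollup class ("no_match" if none)
    summary_counts: dict[str, int]
    coverage_all: list[tuple[float, int]]
    coverage_best: list[tuple[float, int]]
    agreement_all: list[tuple[float, int]]
    agreement_best: list[tuple[float, int]]
    alignments: dict[str, list[SplicedAlignment]]


def map_transcripts(
    mrnas: dict[str, str],
    genome: GenomeAssembly,
    config: PipelineConfig,
    index: KmerIndex | None = None,
) -> dict[str, list[SplicedAlignment]]:
    """Retained (filtered, primary-flagged) spliced alignments per query."""
    idx = index or KmerIndex.from_assembly(genome, k=config.aligner_k, include_unplaced=True)
    out: dict[str, list[SplicedAlignment]] = {}
    all_alns: list[SplicedAlignment] = []
    for qid, seq in mrnas.items():
        alns = map_query(qid, seq, genome, idx, min_intron=config.min_intron)
        alns = filter_alignments(alns, min_len=config.min_align_len, min_identity=config.min_align_identity)
        out[qid] = alns
        all_alns.extend(alns)
    select_primary(all_alns)
    return out


def compare_structures_direction(
    mrnas: dict[str, str],
    source_annot: AnnotationSet,
    target_genome: GenomeAssembly,
    target_annot: AnnotationSet,
    config: PipelineConfig,
    alignments: dict[str, list[SplicedAlignment]] | None = None,
) -> StructureReport:
    """Map one annotation's transcripts onto the other genome and compare
    the projected structures with the local annotation."""
    alns = alignments if alignments is not None else map_transcripts(mrnas, target_genome, config)
    best: dict[str, BestMatch] = {}
    rollup: dict[str, str] = {}
    structs_all: dict[str, list] = {}
    structs_best: dict[str, list] = {}
    for qid, qalns in alns.items():
        source = source_annot[qid] if qid in source_annot else None
        for a in qalns:
            st = structure_from_alignment(a, source)
            structs_all.setdefault(qid, []).append(st)
            if a.is_primary:
                structs_best.setdefault(qid, []).append(st)
        primaries = [a for a in qalns if a.is_primary]
        if not primaries:
            rollup[qid] = "no_match"
            continue
        st = structure_from_alignment(primaries[0], source)
        candidates = target_annot.overlapping(st.chrom, st.start, st.end)
        bm = assign_best_match(st, candidates, margin=config.margin, min_overlap=config.min_overlap)
        if bm is None:
            rollup[qid] = "no_match"
        else:
            best[qid] = bm
            rollup[qid] = ROLLUP[bm.match_class]
    summary = summarize_classes(list(best.values()))
    qlens = {qid: len(seq) for qid, seq in mrnas.items()}
    flat = [a for qalns in alns.values() for a in qalns]
    spliced_lengths = {qid: qlens[qid] for qid in structs_all}
    return StructureReport(
        best_matches=best,
        rollup=rollup,
        summary_counts=summary.counts,
        coverage_all=coverage_curve(qlens, flat, mode="all"),
        coverage_best=coverage_curve(qlens, flat, mode="best"),
        agreement_all=agreement_curve(structs_all, spliced_lengths, target_annot),
        agreement_best=agreement_curve(
            {q: s for q, s in structs_best.items()},
            {q: qlens[q] for q in structs_best},
            target_annot,
        ),
        alignments=alns,
    )


def compare_proteins_direction(
    target_annot: AnnotationSet,
    target_genome: GenomeAssembly,
    model_proteins: dict[str, str],
    config: PipelineConfig,
) -> dict[str, str]:
    """Classify the conceptual translation of every annotated gene on the
    target assembly against its model protein (matched by the transcript
    id the model was derived from)."""
    classes: dict[str, str] = {}
    for t in target_annot:
        model_id = t.id[:-4] if t.id.endswith("_dup") else t.id
        if model_id not in model_proteins or t.cds is None:
            continue
        predicted = conceptual_translation(t, target_genome)
        model = ProteinRecord(model_id, model_proteins[model_id])
        classes[t.id] = classify_protein_pair(predicted, model, config.protein)
    return classes


@dataclass
class PipelineResult:
    structures: StructureReport
    protein_classes: dict[str, str]
    protein_summary: dict[str, int]
    snp_status: dict[str, str]
    snp_counts: dict[str, int]


def run_pipeline(bundle: SimBundle, config: PipelineConfig | None = None, rescue_unplaced: bool = False) -> PipelineResult:
    """Full comparison of a simulated bundle: structures (A mapped onto B
    vs B's annotation), proteins (B's conceptual translations vs models),
    and SNP tiers on assembly B."""
    cfg = config or PipelineConfig()
    structures = compare_structures_direction(
        bundle.mrnas, bundle.annot_a, bundle.genome_b, bundle.annot_b, cfg
    )
    protein_classes = compare_proteins_direction(
        bundle.annot_b, bundle.genome_b, bundle.proteins, cfg
    )
    snp_status: dict[str, str] = {}
    if bundle.snps:
        statuses = map_snps(bundle.snps, bundle.genome_b, cfg.snp)
        snp_status = {r: s.status for r, s in statuses.items()}
        if rescue_unplaced:
            unmapped = [s for s in bundle.snps if snp_status[s.rsid] == "unmapped"]
            if unmapped and bundle.genome_b.unplaced:
                unp = GenomeAssembly("unplaced_pool", dict(bundle.genome_b.unplaced))
                rescued = map_snps(unmapped, unp, cfg.snp)
                for r, s in rescued.items():
                    if s.status in ("found", "mapped"):
                        snp_status[r] = "found"
    snp_counts = {"unmapped": 0, "found": 0, "mapped": 0}
    for s in snp_status.values():
        snp_counts[s] += 1
    return PipelineResult(
        structures=structures,
        protein_classes=protein_classes,
        protein_summary=summarize_protein_classes(list(protein_classes.values())),
        snp_status=snp_status,
        snp_counts=snp_counts,
    )


# ---------------------------------------------------------------------------
# Truth scoring and report rendering


STRUCTURE_TRUTH_SETS = {
    "identical": {"identical"},
    "extensions": {"extensions"},
    "truncations": {"truncations"},
    "both": {"both"},
    "complex": {"complex"},
}

PROTEIN_TRUTH_SETS = {
    "identical": {"identical"},
    "near_identical": {"identical", "near_identical"},
    "not_near": set(PROTEIN_CLASSES) - {"identical", "near_identical"},
}


def score_against_truth(bundle: SimBundle, result: PipelineResult) -> dict[str, dict[str, int]]:
    """Per expected-category counts of hits/misses against the truth table."""
    out: dict[str, dict[str, int]] = {}
    for rec in bundle.truth:
        if rec.subject_type == "gene":
            if rec.expected_structure and rec.expected_structure in STRUCTURE_TRUTH_SETS:
                key = f"structure:{rec.expected_structure}"
                got = result.structures.rollup.get(rec.subject_id, "no_match")
                ok = got in STRUCTURE_TRUTH_SETS[rec.expected_structure]
                d = out.setdefault(key, {"hit": 0, "miss": 0})
                d["hit" if ok else "miss"] += 1
            if rec.expected_protein and rec.expected_protein in PROTEIN_TRUTH_SETS:
                key = f"protein:{rec.expected_protein}"
                got_p = result.protein_classes.get(rec.subject_id)
                ok = got_p in PROTEIN_TRUTH_SETS[rec.expected_protein]
                d = out.setdefault(key, {"hit": 0, "miss": 0})
                d["hit" if ok else "miss"] += 1
        elif rec.subject_type == "snp" and rec.expected_snp:
            key = f"snp:{rec.expected_snp}"
            got = result.snp_status.get(rec.subject_id, "unmapped")
            d = out.setdefault(key, {"hit": 0, "miss": 0})
            d["hit" if got == rec.expected_snp else "miss"] += 1
    return out


def render_structure_summary(counts: dict[str, int], path: Path | str, config: PipelineConfig | None = None) -> None:
    total = sum(counts.values())
    rows = [
        [label, counts[key], percent(counts[key], total)]
        for key, label in zip(
            ROLLUP_ORDER,
            ["Identical", "Extensions", "Truncations", "Both extensions & truncations", "Complex structural differences"],
        )
    ]
    rows.append(["Total", total, ""])
    comments = config.describe() if config else []
    write_tsv(path, ["classification", "n_transcripts", "pct"], rows, comments)


def render_protein_summary(counts: dict[str, int], path: Path | str, config: PipelineConfig | None = None) -> None:
    total = sum(counts.values())
    labels = {
        "identical": "Identical",
        "near_identical": "Near-identical",
        "extension": "Extensions",
        "truncation": "Truncations",
        "divergent_ends": "Divergent ends",
        "gapped": "Gapped",
        "different": "Different",
        "other": "Other",
    }
    rows = [[labels[k], counts.get(k, 0), percent(counts.get(k, 0), total)] for k in PROTEIN_CLASSES]
    rows.append(["Total", total, ""])
    comments = config.describe() if config else []
    write_tsv(path, ["classification", "n_proteins", "pct"], rows, comments)


def render_curve(curve: list[tuple[float, int]], path: Path | str) -> None:
    write_tsv(path, ["x", "count"], [[f"{x:.2f}", n] for x, n in curve])


def render_snp_summary(counts: dict[str, int], path: Path | str) -> None:
    total = sum(counts.values())
    rows = [[k, v, percent(v, total)] for k, v in counts.items()]
    rows.append(["Total", total, ""])
    write_tsv(path, ["status", "n_snps", "pct"], rows)
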