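"""Conceptual-translation vs model-protein alignment and difference taxonomy.

Each predicted protein (direct translation of the genomic annotation, with
frameshifts and internal stops left in) is globally aligned to its model
protein with free end gaps, BLOSUM62 scoring and affine gap penalties.
The pair is then classified, in fixed decision order, as::

    identical        exact sequence equality
    near_identical   end-to-end alignment, identity >= 0.90, < 10 gap
                     openings, no overhang > 10 aa
    extension        predicted-side overhang > 10 aa only, aligned region
                     of near-identical quality
    truncation       model-side overhang > 10 aa only, likewise
    divergent_ends   overhangs > 10 aa on both sequences
    gapped           modified identity >= 0.90 (identity over aligned
                     residues only, excluding gap columns) with >= 10 gap
                     openings or a single gap >= 30 aa, overhangs <= 10 aa
    different        identity over aligned residues < 0.50
    other            anything else

'*' (an in-frame stop) counts as a mismatch against every residue,
including another '*': a stop codon is annotation damage, not sequence
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

from .core import ProteinRecord

PROTEIN_CLASSES = [
    "identical",
    "near_identical",
    "extension",
    "truncation",
    "divergent_ends",
    "gapped",
    "different",
    "other",
]


def _make_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.end_gap_score = 0.0
    return a


_ALIGNER = _make_aligner()


@dataclass
class ProteinAlignment:
    """Column bookkeeping of one free-end-gap global protein alignment.

    ``columns`` counts internal columns only (aligned pairs + internal gap
    columns). Overhangs are *effective*: the residues of each sequence
    lying outside the best-scoring aligned core (+1 per identical column,
    -1 otherwise), which subsumes plain end gaps and also exposes
    scrambled termini that the global DP aligned residue-against-residue
    (two same-length proteins sharing only a prefix have no end gaps, yet
    both carry large unalignable tails).
    """

    columns: int
    identical: int
    gap_columns: int
    gap_openings: int
    max_gap: int
    overhang_p_head: int
    overhang_p_tail: int
    overhang_q_head: int
    overhang_q_tail: int
    score: float

    @property
    def aligned_pairs(self) -> int:
        return self.columns - self.gap_columns

    @property
    def identity(self) -> float:
        """Identity over all internal columns (gap columns count)."""
        return self.identical / self.columns if self.columns else 0.0


def align_proteins(p: ProteinRecord, q: ProteinRecord) -> ProteinAlignment:
    """Align predicted protein ``p`` to model ``q``."""
    aln = _ALIGNER.align(p.sequence, q.sequence)[0]
    blocks = aln.aligned  # [[target blocks], [query blocks]] (target = p)
    pb, qb = blocks[0], blocks[1]
    if len(pb) == 0:  # nothing alignable at all: both sequences overhang
        return ProteinAlignment(
            columns=0, identical=0, gap_columns=0, gap_openings=0, max_gap=0,
            overhang_p_head=len(p.sequence), overhang_p_tail=0,
            overhang_q_head=len(q.sequence), overhang_q_tail=0,
            score=float(aln.score),
        )
    # explicit internal columns: '=' identical pair, 'X' aligned non-identical,
    # 'P'/'Q' gap column consuming only p / only q
    ops: list[str] = []
    gap_openings = 0
    max_gap = 0
    prev = None
    for (ps, pe), (qs, qe) in zip(pb, qb):
        if prev is not None:
            dp = ps - prev[0]
            dq = qs - prev[1]
            ops.extend("P" * dp)
            ops.extend("Q" * dq)
            if dp > 0:
                gap_openings += 1
                max_gap = max(max_gap, dp)
            if dq > 0:
                gap_openings += 1
                max_gap = max(max_gap, dq)
        for cp, cq in zip(p.sequence[ps:pe], q.sequence[qs:qe]):
            ops.append("=" if cp == cq and cp != "*" else "X")
        prev = (pe, qe)
    # best-scoring core window (+1 identical, -1 otherwise)
    best, best_span = 0, (0, 0)
    cur, cur_start = 0, 0
    for i, op in enumerate(ops):
        cur += 1 if op == "=" else -1
        if cur <= 0:
            cur, cur_start = 0, i + 1
        elif cur > best:
            best, best_span = cur, (cur_start, i + 1)
    lo, hi = best_span

    def consumed(seg: list[str], which: str) -> int:
        return sum(1 for op in seg if op in ("=", "X", which))

    p_head = int(pb[0][0]) + consumed(ops[:lo], "P")
    p_tail = len(p.sequence) - int(pb[-1][1]) + consumed(ops[hi:], "P")
    q_head = int(qb[0][0]) + consumed(ops[:lo], "Q")
    q_tail = len(q.sequence) - int(qb[-1][1]) + consumed(ops[hi:], "Q")
    return ProteinAlignment(
        columns=len(ops),
        identical=ops.count("="),
        gap_columns=ops.count("P") + ops.count("Q"),
        gap_openings=gap_openings,
        max_gap=max_gap,
        overhang_p_head=p_head,
        overhang_p_tail=p_tail,
        overhang_q_head=q_head,
        overhang_q_tail=q_tail,
        score=float(aln.score),
    )


def modified_identity(aln: ProteinAlignment) -> float:
    """Identity of the aligned residues only, excluding gap columns."""
    nongap = aln.columns - aln.gap_columns
    if nongap == 0:
        raise ZeroDivisionError("alignment has no aligned residue columns")
    return aln.identical / nongap


@dataclass
class ProteinThresholds:
    min_identity: float = 0.90  # near-identical / aligned-region quality
    max_gap_openings: int = 10  # "few gaps": openings strictly below this
    max_overhang: int = 10  # aa; longer counts as an unaligned overhang
    big_gap: int = 30  # single gap >= this qualifies as "gapped"
    low_identity: float = 0.50  # below this over aligned residues: different


def classify_protein_pair(
    p: ProteinRecord, q: ProteinRecord, thresholds: ProteinThresholds | None = None
) -> str:
    """Classify predicted protein ``p`` against model ``q``."""
    th = thresholds or ProteinThresholds()
    if p.sequence == q.sequence:
        return "identical"
    a = align_proteins(p, q)
    p_over = max(a.overhang_p_head, a.overhang_p_tail)
    q_over = max(a.overhang_q_head, a.overhang_q_tail)
    near_quality = a.identity >= th.min_identity and a.gap_openings < th.max_gap_openings
    if p_over <= th.max_overhang and q_over <= th.max_overhang and near_quality:
        return "near_identical"
    if p_over > th.max_overhang and q_over <= th.max_overhang and near_quality:
        return "extension"
    if q_over > th.max_overhang and p_over <= th.max_overhang and near_quality:
        return "truncation"
    if p_over > th.max_overhang and q_over > th.max_overhang:
        return "divergent_ends"
    if (
        p_over <= th.max_overhang
        and q_over <= th.max_overhang
        and a.aligned_pairs > 0
        and modified_identity(a) >= th.min_identity
        and (a.gap_openings >= th.max_gap_openings or a.max_gap >= th.big_gap)
    ):
        return "gapped"
    if a.aligned_pairs > 0 and modified_identity(a) < th.low_identity:
        return "different"
    return "other"


def summarize_protein_classes(classes: list[str]) -> dict[str, int]:
    out = {k: 0 for k in PROTEIN_CLASSES}
    for c in classes:
        out[c] += 1
    return out
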