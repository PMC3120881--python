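"""Two-stage seeded spliced aligner.

Maps cDNA (and SNP-context) queries onto a genome the way large-scale
cDNA-to-genome mappers work: candidate regions are located from shared
k-mers (default 20-mers), then each candidate window is aligned with an
exon-chaining procedure — maximal exact anchor segments are chained
collinearly, inter-anchor gaps are closed with banded edit-distance DP
(edlib), genomic gaps of at least ``min_intron`` bp are treated as introns
at zero column cost, and intron junctions are slid within +/-10 bp onto
splice-site dinucleotides (GT..AG on the aligned strand) when the slide
does not change any aligned column.

Identity counts aligned (non-gap) columns only by default; coverage is the
fraction of query bases inside aligned blocks. Query bases that cannot be
placed at an intron junction (e.g. an exon whose genomic copy was deleted)
are left out of both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .core import GenomeAssembly, GenomicInterval, revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _cigar_ops(cigar: str) -> list[str]:
    """Expand an edlib extended cigar ('=XID') to one char per column."""
    ops: list[str] = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            ops.extend(ch * n)
            n = 0
    return ops


def _nw_ops(a: str, b: str) -> list[str]:
    """Global-alignment column ops of query a vs target b.

    Unit-cost edit distance is ambiguous between a substitution pair and
    an indel pair; identity bookkeeping excludes indel columns, so paths
    are normalized to prefer substitutions (gap cost 1.5 vs mismatch 1)
    whenever edlib's minimal path contains gaps."""
    if not a:
        return ["D"] * len(b)
    if not b:
        return ["I"] * len(a)
    res = edlib.align(a, b, task="path", mode="NW")
    ops = _cigar_ops(res["cigar"])
    if "I" in ops or "D" in ops:
        ops = _nw_ops_gap_averse(a, b)
    return ops


def _nw_ops_gap_averse(a: str, b: str, mismatch: int = 2, gap: int = 3) -> list[str]:
    """Plain global DP with gaps costlier than mismatches; used to
    normalize short gap fills."""
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    back: list[list[int]] = [[1] * (m + 1)]  # 0 diag, 1 left(D), 2 up(I)
    back[0][0] = -1
    for i in range(1, n + 1):
        cur = [prev[0] + gap] + [0] * m
        row = [2] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (0 if ai == b[j - 1] else mismatch)
            left = cur[j - 1] + gap
            up = prev[j] + gap
            best = min(diag, left, up)
            cur[j] = best
            row[j] = 0 if best == diag else (1 if best == left else 2)
        prev = cur
        back.append(row)
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = back[i][j] if i > 0 and j > 0 else (1 if i == 0 else 2)
        if move == 0:
            ops.append("=" if a[i - 1] == b[j - 1] else "X")
            i -= 1
            j -= 1
        elif move == 1:
            ops.append("D")
            j -= 1
        else:
            ops.append("I")
            i -= 1
    ops.reverse()
    return ops


class KmerIndex:
    """Forward-strand k-mer index of a set of sequences.

    k-mers containing N are skipped. Strand search is handled by the caller
    reverse-complementing the query.
    """

    def __init__(self, sequences: dict[str, str], k: int = 20):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = k
        self.seq_ids = list(sequences)
        self._table: dict[int, list[tuple[int, int]]] = {}
        for sidx, sid in enumerate(self.seq_ids):
            for pos, code in _iter_kmer_codes(sequences[sid], k):
                self._table.setdefault(code, []).append((sidx, pos))

    @classmethod
    def from_assembly(
        cls, genome: GenomeAssembly, k: int = 20, include_unplaced: bool = False
    ) -> "KmerIndex":
        seqs = dict(genome.placed)
        if include_unplaced:
            seqs.update(genome.unplaced)
        return cls(seqs, k=k)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Positions (seq id, 0-based) of an exact k-mer; empty if absent or
        if the k-mer contains N."""
        if len(kmer) != self.k:
            raise ValueError(f"expected {self.k}-mer, got {len(kmer)} bases")
        code = 0
        for ch in kmer:
            if ch not in _CODE:
                return []
            code = (code << 2) | _CODE[ch]
        return [(self.seq_ids[i], p) for i, p in self._table.get(code, [])]

    def hits(self, query: str) -> dict[int, list[tuple[int, int]]]:
        """seq-index -> [(qpos, gpos)] for every shared k-mer, 0-based."""
        out: dict[int, list[tuple[int, int]]] = {}
        for qpos, code in _iter_kmer_codes(query, self.k):
            for sidx, gpos in self._table.get(code, ()):
                out.setdefault(sidx, []).append((qpos, gpos))
        return out


def _iter_kmer_codes(seq: str, k: int):
    """(position, 2-bit code) of every N-free k-mer, rolling."""
    mask = (1 << (2 * k)) - 1
    code = 0
    run = 0  # valid bases accumulated
    for i, ch in enumerate(seq):
        v = _CODE.get(ch)
        if v is None:
            run = 0
            code = 0
            continue
        code = ((code << 2) | v) & mask
        run += 1
        if run >= k:
            yield i - k + 1, code


@dataclass(frozen=True)
class CandidateWindow:
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int


def find_candidates(
    query: str,
    index: KmerIndex,
    min_shared_kmers: int = 2,
    pad_bp: int = 1000,
    cluster_gap: int = 20000,
    seq_lengths: dict[str, int] | None = None,
) -> list[CandidateWindow]:
    """Cluster shared-k-mer seed hits into padded candidate windows on both
    strands."""
    if len(query) < index.k:
        return []
    windows: list[CandidateWindow] = []
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        for sidx, pairs in index.hits(q).items():
            sid = index.seq_ids[sidx]
            gpos = sorted({g for _q, g in pairs})
            cluster: list[int] = []
            for g in gpos + [None]:  # type: ignore[list-item]
                if cluster and (g is None or g - cluster[-1] > cluster_gap):
                    if len(cluster) >= min_shared_kmers:
                        lo = max(1, cluster[0] + 1 - pad_bp)
                        hi = cluster[-1] + index.k + pad_bp
                        if seq_lengths and sid in seq_lengths:
                            hi = min(hi, seq_lengths[sid])
                        windows.append(CandidateWindow(sid, strand, lo, hi))
                    cluster = []
                if g is not None:
                    cluster.append(g)
    return windows


@dataclass
class AlignmentBlock:
    """One gap-free-in-the-large exon block of a spliced alignment.

    Query coordinates are 1-based in the aligned orientation of the query
    (reverse-complemented frame for '-' strand alignments)."""

    query_start: int
    query_end: int
    genome: GenomicInterval
    matches: int
    mismatches: int
    indels: int


@dataclass
class SplicedAlignment:
    query_id: str
    chrom: str
    strand: str
    blocks: list[AlignmentBlock]
    identity: float
    coverage: float
    query_length: int
    is_primary: bool = False

    @property
    def aligned_query_bases(self) -> int:
        return sum(b.query_end - b.query_start + 1 for b in self.blocks)

    @property
    def genome_start(self) -> int:
        return self.blocks[0].genome.start

    @property
    def genome_end(self) -> int:
        return self.blocks[-1].genome.end

    def query_positions(self) -> set[int]:
        """Aligned query positions in the original query orientation."""
        out: set[int] = set()
        for b in self.blocks:
            if self.strand == "+":
                out.update(range(b.query_start, b.query_end + 1))
            else:
                lo = self.query_length - b.query_end + 1
                hi = self.query_length - b.query_start + 1
                out.update(range(lo, hi + 1))
        return out


# ---------------------------------------------------------------------------
# Exact anchor segments and chaining


def _exact_segments(q: str, w: str, k: int) -> list[list[int]]:
    """Maximal exact matches >= k bp as [qs, qe, gs, ge] (0-based incl.)."""
    table: dict[int, list[int]] = {}
    for pos, code in _iter_kmer_codes(w, k):
        table.setdefault(code, []).append(pos)
    # group hits by diagonal, merge consecutive q positions into runs
    diag_hits: dict[int, list[int]] = {}
    for qpos, code in _iter_kmer_codes(q, k):
        for gpos in table.get(code, ()):
            diag_hits.setdefault(gpos - qpos, []).append(qpos)
    segs: list[list[int]] = []
    for d, qs_list in diag_hits.items():
        qs_list.sort()
        run_start = prev = qs_list[0]
        for qp in qs_list[1:] + [None]:  # type: ignore[list-item]
            if qp is None or qp != prev + 1:
                qe = prev + k - 1
                segs.append([run_start, qe, run_start + d, qe + d])
                if qp is not None:
                    run_start = qp
            prev = qp if qp is not None else prev
    segs.sort(key=lambda s: (s[0], s[2]))
    return segs


def _chain(segs: list[list[int]], min_intron: int, max_intron: int) -> list[list[int]]:
    """Collinear chain of anchor segments maximizing covered query bases,
    lightly penalizing gaps and junctions."""
    n = len(segs)
    if n == 0:
        return []
    score = [0.0] * n
    back = [-1] * n
    for i, s in enumerate(segs):
        length = s[1] - s[0] + 1
        score[i] = float(length)
        for j in range(i):
            p = segs[j]
            q_adv = s[0] - p[1]  # >0 means no query overlap
            g_adv = s[2] - p[3]
            cut = max(0, 1 - q_adv, 1 - g_adv)  # bases trimmed from s later
            gain = length - cut
            if gain <= 0:
                continue
            qgap = max(0, q_adv - 1)
            ggap = max(0, g_adv - 1)
            if ggap > max_intron:
                continue
            if ggap >= min_intron:
                penalty = 2.0 + 0.01 * qgap
            else:
                penalty = 0.02 * (qgap + ggap)
            cand = score[j] + gain - penalty
            if cand > score[i]:
                score[i] = cand
                back[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain = []
    i = best
    while i != -1:
        chain.append(segs[i])
        i = back[i]
    chain.reverse()
    # trim residual overlaps so consecutive segments strictly advance
    out = [list(chain[0])]
    for s in chain[1:]:
        s = list(s)
        prev = out[-1]
        cut = max(prev[1] - s[0] + 1, prev[3] - s[2] + 1, 0)
        s[0] += cut
        s[2] += cut
        if s[0] > s[1] or s[2] > s[3]:
            continue
        out.append(s)
    return out


def _shw_ops_gap_averse(a: str, b: str, mismatch: int = 2, gap: int = 3) -> list[str]:
    """Align all of ``a`` to a prefix of ``b`` (free trailing target) with
    gaps costlier than mismatches; used to normalize end extensions."""
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    back: list[list[int]] = [[1] * (m + 1)]
    back[0][0] = -1
    rows = [prev]
    for i in range(1, n + 1):
        cur = [prev[0] + gap] + [0] * m
        row = [2] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (0 if ai == b[j - 1] else mismatch)
            left = cur[j - 1] + gap
            up = prev[j] + gap
            best = min(diag, left, up)
            cur[j] = best
            row[j] = 0 if best == diag else (1 if best == left else 2)
        prev = cur
        rows.append(cur)
        back.append(row)
    j = min(range(m + 1), key=lambda jj: (rows[n][jj], jj))
    ops: list[str] = []
    i = n
    while i > 0 or j > 0:
        move = back[i][j] if i > 0 and j > 0 else (1 if i == 0 else 2)
        if move == 0:
            ops.append("=" if a[i - 1] == b[j - 1] else "X")
            i -= 1
            j -= 1
        elif move == 1:
            ops.append("D")
            j -= 1
        else:
            ops.append("I")
            i -= 1
    ops.reverse()
    return ops


def _extension_ops(query_part: str, target_part: str) -> list[str]:
    """Semi-global extension ops of a query end against adjacent genome
    sequence, normalized to prefer substitutions over gaps."""
    res = edlib.align(query_part, target_part, task="path", mode="SHW")
    ops = _cigar_ops(res["cigar"])
    if "I" in ops or "D" in ops:
        ops = _shw_ops_gap_averse(query_part, target_part)
    return ops


def _best_prefix(ops: list[str]) -> list[str]:
    """Accepted portion of an end extension.

    The whole extension is kept when its match fraction clears 2/3 —
    random DNA aligned by edit distance stays below that bar, genuinely
    homologous sequence with moderate noise clears it. Short extensions
    (a handful of trailing bases) are always kept. Otherwise only the
    best-scoring prefix (+1 match, -2 otherwise) is kept, so garbage tails
    (e.g. an exon whose genomic copy is gone) stay unaligned."""
    if ops and (len(ops) <= 30 or ops.count("=") / len(ops) >= 2 / 3):
        return ops
    best_score, best_len, cur = 0, 0, 0
    for i, op in enumerate(ops, start=1):
        cur += 1 if op == "=" else -2
        if cur > best_score:
            best_score, best_len = cur, i
    return ops[:best_len]


_SPLICE = {"+": ("GT", "AG"), "-": ("CT", "AC")}


def align_spliced(
    query_id: str,
    query: str,
    genome: GenomeAssembly,
    window: CandidateWindow,
    k_anchor: int = 12,
    min_intron: int = 30,
    max_intron: int = 500_000,
    splice_slide: int = 10,
    end_extension_pad: int = 20,
) -> SplicedAlignment | None:
    """Align one query within one candidate window; None if no anchors."""
    wseq = genome.sequence(window.chrom)[window.start - 1 : window.end]
    q = query if window.strand == "+" else revcomp(query)
    segs = _exact_segments(q, wseq, k_anchor)
    if not segs:
        return None
    chain = _chain(segs, min_intron=min_intron, max_intron=max_intron)
    if not chain:
        return None

    # blocks as (q0, g0, ops[]) in local 0-based coordinates
    blocks: list[tuple[int, int, list[str]]] = []
    q0, g0 = chain[0][0], chain[0][2]
    ops: list[str] = ["="] * (chain[0][1] - chain[0][0] + 1)
    for prev, seg in zip(chain, chain[1:]):
        qgap = seg[0] - prev[1] - 1
        ggap = seg[2] - prev[3] - 1
        if ggap >= min_intron and ggap - qgap >= min_intron:
            # intron junction: place query-gap bases greedily by exact match
            left_ext = 0
            while (
                left_ext < qgap
                and q[prev[1] + 1 + left_ext] == wseq[prev[3] + 1 + left_ext]
            ):
                left_ext += 1
            right_ext = 0
            while (
                right_ext < qgap - left_ext
                and q[seg[0] - 1 - right_ext] == wseq[seg[2] - 1 - right_ext]
            ):
                right_ext += 1
            ops.extend("=" * left_ext)
            blocks.append((q0, g0, ops))
            q0 = seg[0] - right_ext
            g0 = seg[2] - right_ext
            ops = ["="] * right_ext + ["="] * (seg[1] - seg[0] + 1)
        else:
            ops.extend(
                _nw_ops(q[prev[1] + 1 : seg[0]], wseq[prev[3] + 1 : seg[2]])
            )
            ops.extend("=" * (seg[1] - seg[0] + 1))
    blocks.append((q0, g0, ops))

    blocks = _extend_ends(blocks, q, wseq, end_extension_pad)
    blocks = [b for b in blocks if any(op in "=X" for op in b[2])]
    if not blocks:
        return None
    blocks = _slide_junctions(blocks, wseq, _SPLICE[window.strand], splice_slide)

    out_blocks: list[AlignmentBlock] = []
    matches = mismatches = indels = 0
    for q0, g0, ops in blocks:
        m = ops.count("=")
        x = ops.count("X")
        ind = ops.count("I") + ops.count("D")
        qlen = m + x + ops.count("I")
        glen = m + x + ops.count("D")
        matches += m
        mismatches += x
        indels += ind
        out_blocks.append(
            AlignmentBlock(
                query_start=q0 + 1,
                query_end=q0 + qlen,
                genome=GenomicInterval(
                    window.chrom,
                    window.start + g0,
                    window.start + g0 + glen - 1,
                    window.strand,
                ),
                matches=m,
                mismatches=x,
                indels=ind,
            )
        )
    if matches + mismatches == 0:
        return None
    identity = matches / (matches + mismatches)
    coverage = sum(b.query_end - b.query_start + 1 for b in out_blocks) / len(query)
    return SplicedAlignment(
        query_id=query_id,
        chrom=window.chrom,
        strand=window.strand,
        blocks=out_blocks,
        identity=identity,
        coverage=min(coverage, 1.0),
        query_length=len(query),
    )


def _extend_ends(
    blocks: list[tuple[int, int, list[str]]],
    q: str,
    wseq: str,
    pad: int,
) -> list[tuple[int, int, list[str]]]:
    """Extend the alignment to the query ends with semi-global DP, keeping
    only the best-scoring portion (garbage tails stay unaligned)."""
    q0, g0, ops = blocks[0]
    if q0 > 0 and g0 > 0:
        head = q[:q0]
        lo = max(0, g0 - len(head) - pad)
        target = wseq[lo:g0]
        if target:
            ext = _best_prefix(_extension_ops(head[::-1], target[::-1]))
            if ext:
                dq = sum(1 for op in ext if op in "=XI")
                dg = sum(1 for op in ext if op in "=XD")
                blocks[0] = (q0 - dq, g0 - dg, ext[::-1] + ops)
    q0, g0, ops = blocks[-1]
    qlen = sum(1 for op in ops if op in "=XI")
    glen = sum(1 for op in ops if op in "=XD")
    q_end, g_end = q0 + qlen, g0 + glen  # exclusive
    if q_end < len(q) and g_end < len(wseq):
        tail = q[q_end:]
        target = wseq[g_end : g_end + len(tail) + pad]
        if target:
            ext = _best_prefix(_extension_ops(tail, target))
            if ext:
                blocks[-1] = (q0, g0, ops + ext)
    return blocks


def _slide_junctions(
    blocks: list[tuple[int, int, list[str]]],
    wseq: str,
    motifs: tuple[str, str],
    max_slide: int,
) -> list[tuple[int, int, list[str]]]:
    """Slide each intron junction within +/-max_slide columns onto the
    splice motifs, moving only exactly-matching columns."""
    donor, acceptor = motifs
    for bi in range(len(blocks) - 1):
        lq0, lg0, lops = blocks[bi]
        rq0, rg0, rops = blocks[bi + 1]
        l_glen = sum(1 for op in lops if op in "=XD")
        intron_s = lg0 + l_glen  # 0-based first intron base
        intron_e = rg0 - 1

        def motif_at(delta: int) -> bool:
            s, e = intron_s + delta, intron_e + delta
            if s < 0 or e + 1 > len(wseq) or e < s + 3:
                return False
            return wseq[s : s + 2] == donor and wseq[e - 1 : e + 1] == acceptor

        # how far can we slide over exactly-matching columns?
        left_room = 0
        while (
            left_room < max_slide
            and left_room < len(lops) - 1
            and lops[-1 - left_room] == "="
            and intron_s - left_room - 1 >= 0
            and wseq[intron_s - left_room - 1] == wseq[intron_e - left_room]
        ):
            left_room += 1
        right_room = 0
        while (
            right_room < max_slide
            and right_room < len(rops) - 1
            and rops[right_room] == "="
            and intron_e + right_room + 1 < len(wseq)
            and wseq[intron_s + right_room] == wseq[intron_e + right_room + 1]
        ):
            right_room += 1
        chosen = None
        for mag in range(0, max_slide + 1):
            for delta in ((-mag, mag) if mag else (0,)):
                if delta < 0 and -delta > left_room:
                    continue
                if delta > 0 and delta > right_room:
                    continue
                if motif_at(delta):
                    chosen = delta
                    break
            if chosen is not None:
                break
        if chosen is None or chosen == 0:
            continue
        d = chosen
        if d < 0:
            moved = -d
            blocks[bi] = (lq0, lg0, lops[:-moved])
            blocks[bi + 1] = (rq0 - moved, rg0 - moved, ["="] * moved + rops)
        else:
            blocks[bi] = (lq0, lg0, lops + ["="] * d)
            blocks[bi + 1] = (rq0 + d, rg0 + d, rops[d:])
    return blocks


# ---------------------------------------------------------------------------
# Whole-query mapping, filtering, primary selection, coverage curves


def map_query(
    query_id: str,
    query: str,
    genome: GenomeAssembly,
    index: KmerIndex,
    min_shared_kmers: int = 2,
    pad_bp: int = 1000,
    cluster_gap: int = 20000,
    **align_kwargs,
) -> list[SplicedAlignment]:
    """All candidate-window alignments of one query."""
    lengths = {sid: len(s) for sid, s in genome.sequences().items()}
    wins = find_candidates(
        query,
        index,
        min_shared_kmers=min_shared_kmers,
        pad_bp=pad_bp,
        cluster_gap=cluster_gap,
        seq_lengths=lengths,
    )
    out = []
    for w in wins:
        aln = align_spliced(query_id, query, genome, w, **align_kwargs)
        if aln is not None:
            out.append(aln)
    return out


def filter_alignments(
    alns: list[SplicedAlignment],
    min_len: int = 100,
    min_identity: float = 0.95,
) -> list[SplicedAlignment]:
    """Keep alignments with aligned query span strictly greater than
    ``min_len`` bp and identity at least ``min_identity``."""
    return [
        a
        for a in alns
        if a.aligned_query_bases > min_len and a.identity >= min_identity
    ]


def select_primary(alns: list[SplicedAlignment]) -> list[SplicedAlignment]:
    """Flag, per query, the maximal (coverage, identity, aligned bp)
    alignment(s) as primary; ties at the maximum all stay primary."""
    by_query: dict[str, list[SplicedAlignment]] = {}
    for a in alns:
        a.is_primary = False
        by_query.setdefault(a.query_id, []).append(a)
    for group in by_query.values():
        key = lambda a: (a.coverage, a.identity, a.aligned_query_bases)
        best = max(key(a) for a in group)
        for a in group:
            if key(a) == best:
                a.is_primary = True
    return alns


def coverage_curve(
    query_lengths: dict[str, int],
    alns: list[SplicedAlignment],
    mode: str = "all",
    step: float = 0.05,
) -> list[tuple[float, int]]:
    """(x, number of queries with coverage >= x) for x = 0, step, ..., 1.

    'all' merges the union of aligned query positions over every retained
    alignment; 'best' uses primary alignments only. Queries with no retained
    alignment do not contribute at any x.
    """
    if mode not in ("all", "best"):
        raise ValueError("mode must be 'all' or 'best'")
    cov: dict[str, set[int]] = {}
    for a in alns:
        if mode == "best" and not a.is_primary:
            continue
        cov.setdefault(a.query_id, set()).update(a.query_positions())
    fracs = [len(pos) / query_lengths[qid] for qid, pos in cov.items()]
    xs = [round(i * step, 10) for i in range(int(round(1 / step)) + 1)]
    return [(x, sum(1 for f in fracs if f >= x - 1e-9)) for x in xs]
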