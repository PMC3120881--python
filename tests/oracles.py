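"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method available
(full dynamic programming, naive translation) without sharing code with
the package's implementation paths.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def gotoh_free_end_score(
    a: str, b: str, open_gap: float = -11.0, extend_gap: float = -1.0
) -> float:
    """Affine-gap global alignment score with free end gaps (Gotoh DP),
    BLOSUM62 scoring. O(len(a)*len(b)); intended for short sequences."""
    n, m = len(a), len(b)
    # M: a[i] aligned to b[j]; X: gap in b (a consumed); Y: gap in a
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # leading gap in b is free
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # leading gap in a is free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1]][b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            # a length-k gap costs open + (k-1)*extend
            X[i][j] = max(M[i - 1][j] + open_gap, X[i - 1][j] + extend_gap)
            Y[i][j] = max(M[i][j - 1] + open_gap, Y[i][j - 1] + extend_gap)
    best = NEG_INF
    for i in range(n + 1):  # free trailing gap in a and/or b
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def naive_translate(cds: str) -> str:
    """Codon-table translation; N-containing codons -> X; trailing stop
    dropped, internal stops kept."""
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aa.append(_CODONS.get(codon, "X"))
    if aa and aa[-1] == "*":
        aa.pop()
    return "".join(aa)
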