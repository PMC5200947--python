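"""Independent reference implementations used only to check the package.

Each oracle takes the most direct route available — full-matrix dynamic
programming, six-frame translate-and-split via Biopython, brute-force
scans — with no shared code with the implementation under test.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

NEG_INF = float("-inf")


def blosum62_linker_neutral() -> Dict[Tuple[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    table = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = 0.0 if "Z" in (a, b) else float(mat[a, b])
    return table


def gotoh_local_score(
    a: str,
    b: str,
    sub: Dict[Tuple[str, str], float],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> int:
    """Exhaustive affine-gap local alignment score (Gotoh recurrences).

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + sub[(a[i - 1], b[j - 1])]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(round(best))


def six_frame_orfs(seq: str, min_aa: int) -> List[Tuple[str, int, int, str]]:
    """Brute-force ORF enumeration: translate all six frames with
    Biopython, split on '*', recover forward-strand coordinates.

    Returns a set-comparable list of (strand, nt_start, nt_end, aa).
    """
    out = []
    L = len(seq)
    for strand, s in (("forward", seq), ("reverse", str(Seq(seq).reverse_complement()))):
        for off in range(3):
            trimmed = s[off : off + 3 * ((L - off) // 3)]
            if len(trimmed) < 3:
                continue
            aa = str(Seq(trimmed).translate())
            pos = 0
            for chunk in aa.split("*"):
                if len(chunk) >= min_aa:
                    ss = off + 3 * pos + 1
                    se = off + 3 * (pos + len(chunk))
                    if strand == "forward":
                        out.append((strand, ss, se, chunk))
                    else:
                        out.append((strand, L - se + 1, L - ss + 1, chunk))
                pos += len(chunk) + 1
    return out


def brute_best_hits(hits):
    """Per-query minimum by (evalue, -bitscore), first occurrence wins."""
    best = {}
    for h in hits:
        group = [
            x for x in hits if x.query_id == h.query_id
        ]
        chosen = group[0]
        for x in group[1:]:
            if (x.evalue, -x.bitscore) < (chosen.evalue, -chosen.bitscore):
                chosen = x
        best[h.query_id] = chosen
    return best


def brute_longest_overlap(a: str, b: str, min_len: int) -> int:
    best = 0
    for n in range(min_len, min(len(a), len(b)) + 1):
        if a.endswith(b[:n]):
            best = n
    return best


def brute_substring_dedup(seqs: Dict[str, str]) -> set:
    """Ids surviving exact-substring removal: longest wins, lexicographic
    smallest id on exact ties."""
    survivors = set(seqs)
    for i, si in seqs.items():
        for j, sj in seqs.items():
            if i == j:
                continue
            if si in sj and (len(si) < len(sj) or i > j):
                survivors.discard(i)
                break
    return survivors
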