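"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive results by different routes: the ORF oracle
enumerates (start, first-stop) pairs directly instead of streaming codons,
and the alignment oracle is a plain Gotoh dynamic program.
"""

from __future__ import annotations

START = ("ATG", "GTG", "TTG")
STOP = ("TAA", "TAG", "TGA")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_force_orfs(seq: str, min_aa: int, max_aa: int) -> set[tuple[int, int, int]]:
    """All longest-per-stop ORFs as (low, high, strand) 1-based genome spans."""
    L = len(seq)
    found: dict[tuple[int, int], int] = {}  # (strand, stop_end_local) -> min start_local
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        for i in range(L - 2):
            if s[i : i + 3] not in START:
                continue
            j = i + 3
            while j + 3 <= L:
                if s[j : j + 3] in STOP:
                    key = (strand, j + 3)
                    if key not in found or i < found[key]:
                        found[key] = i
                    break
                j += 3
    out = set()
    for (strand, stop_end), start in found.items():
        aa_len = (stop_end - start) // 3 - 1
        if not (min_aa <= aa_len <= max_aa):
            continue
        s = seq if strand == 1 else revcomp(seq)
        if "N" in s[start:stop_end]:
            continue
        if strand == 1:
            out.add((start + 1, stop_end, 1))
        else:
            out.add((L - stop_end + 1, L - start, -1))
    return out


def gotoh_local_score(a: str, b: str, matrix, gap_open: float = 11.0,
                      gap_extend: float = 1.0) -> float:
    """Smith–Waterman score with affine gaps costing ``gap_open + k*gap_extend``
    for a gap of length k, by the full Gotoh dynamic program."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    first_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first_cost, F[i - 1][j] - gap_extend)
            sub = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
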