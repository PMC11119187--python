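"""Independent brute-force oracles used to check the vectorised code paths.

Everything here is written from first principles (character loops, full DP)
and shares no code with the package implementation.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "N": {"A", "C", "G", "T"},
}


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def bf_iupac_match(pattern: str, seq: str) -> bool:
    return len(pattern) == len(seq) and all(b in IUPAC_SETS[c] for c, b in zip(pattern, seq))


def bf_protospacers(seq: str, pattern: str, g: int) -> list[tuple[int, str]]:
    """(protospacer_start, strand) for every valid half-site, by exhaustion."""
    seq = seq.upper()
    L = len(pattern)
    n = len(seq)
    out = []
    for s in range(n):
        if s + g + L <= n and bf_iupac_match(pattern, seq[s + g : s + g + L]):
            out.append((s, "+"))
        if s >= L and s + g <= n and bf_iupac_match(pattern, rc(seq[s - L : s])):
            out.append((s, "-"))
    return sorted(out)


def bf_paired(seq: str, left_pam: str, right_pam: str, g: int, lo: int, hi: int) -> list[tuple[int, int]]:
    """(left_start, right_start) of every PAM-out pair, by double loop."""
    minus = [s for s, st in bf_protospacers(seq, left_pam, g) if st == "-"]
    plus = {s for s, st in bf_protospacers(seq, right_pam, g) if st == "+"}
    return sorted(
        (ls, ls + g + d) for ls in minus for d in range(lo, hi + 1) if ls + g + d in plus
    )


def bf_single_hits(seq: str, guide: str, pattern: str, max_mm: int) -> list[tuple[int, str, int]]:
    """(start, strand, mismatches) of every half-site hit, by exhaustion."""
    seq = seq.upper()
    g = len(guide)
    out = []
    for start, strand in bf_protospacers(seq, pattern, g):
        proto = seq[start : start + g] if strand == "+" else rc(seq[start : start + g])
        mm = sum(a != b for a, b in zip(proto, guide))
        if mm <= max_mm:
            out.append((start, strand, mm))
    return sorted(out)


def bf_paired_hits(
    seq: str, lg: str, rg: str, lp: str, rp: str, max_mm: int, lo: int, hi: int
) -> list[tuple[int, int]]:
    g = len(lg)
    left = {s for s, st, _ in bf_single_hits(seq, lg, lp, max_mm) if st == "-"}
    right = {s for s, st, _ in bf_single_hits(seq, rg, rp, max_mm) if st == "+"}
    return sorted(
        (ls, ls + g + d) for ls in left for d in range(lo, hi + 1) if ls + g + d in right
    )


def gotoh_score(a: str, b: str, match: float, mismatch: float, gap_open: float, gap_extend: float) -> float:
    """Optimal affine-gap global alignment score (gap of length L costs
    open + (L-1)*extend), by full dynamic programming."""
    inf = float("-inf")
    n, m = len(a), len(b)
    M = [[inf] * (m + 1) for _ in range(n + 1)]
    X = [[inf] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[inf] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend, Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend, X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
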