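"""Independent reference implementations used to cross-check the package.

Each oracle takes a deliberately different route from the implementation it
checks: the folding oracle is a memoized recursion instead of an iterative
DP table, the mapping oracle scans every window with numpy instead of
pigeonhole candidate generation, and the antisense oracle is a plain
per-position Python loop instead of a vectorized sliding-window scan.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CANONICAL_PAIRS = {
    frozenset(("A", "T")),
    frozenset(("G", "C")),
    frozenset(("G", "T")),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


sys.setrecursionlimit(max(sys.getrecursionlimit(), 20_000))


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of AU/GC/GU pairs, memoized top-down recursion."""
    s = seq.upper().replace("U", "T")
    n = len(s)

    @lru_cache(maxsize=None)
    def opt(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = opt(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if frozenset((s[i], s[k])) in _CANONICAL_PAIRS:
                best = max(best, 1 + opt(i + 1, k - 1) + opt(k + 1, j))
        return best

    result = opt(0, n - 1) if n else 0
    opt.cache_clear()
    return result


def structure_is_valid(seq: str, structure: str, min_loop: int = 3) -> bool:
    """Balanced brackets, legal pair identities, loops >= min_loop."""
    s = seq.upper().replace("U", "T")
    if len(s) != len(structure):
        return False
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                return False
            j = stack.pop()
            if i - j <= min_loop:
                return False
            if frozenset((s[j], s[i])) not in _CANONICAL_PAIRS:
                return False
        elif c != ".":
            return False
    return not stack


def exhaustive_map(
    tag: str,
    reference: dict[str, str],
    seed_len: int = 18,
    seed_mm: int = 1,
    total_mm: int = 1,
) -> set[tuple[str, int, int, str, int]]:
    """All qualifying loci of one tag, by scanning every window via numpy.

    Returns ``{(ref, start_1based, end_1based, strand, mismatches)}``.
    """
    t = tag.upper().replace("U", "T")
    L = len(t)
    eff_seed = min(seed_len, L)
    out: set[tuple[str, int, int, str, int]] = set()
    for name, rseq in reference.items():
        r = np.frombuffer(rseq.upper().replace("U", "T").encode(), dtype=np.uint8)
        if len(r) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(r, L)
        for strand, query in (("+", t), ("-", revcomp(t))):
            q = np.frombuffer(query.encode(), dtype=np.uint8)
            neq = win != q
            # mismatch positions in tag coordinates (5'->3' of the tag)
            if strand == "+":
                seed_cols = np.arange(0, eff_seed)
            else:
                seed_cols = np.arange(L - eff_seed, L)
            ok = (neq.sum(axis=1) <= total_mm) & (
                neq[:, seed_cols].sum(axis=1) <= seed_mm
            )
            for s in np.flatnonzero(ok):
                out.add((name, int(s) + 1, int(s) + L, strand, int(neq[s].sum())))
    return out


def exhaustive_ncrna_match(
    tag: str, reference: dict[str, str], max_mismatch: int = 1
) -> bool:
    """Brute-force: does the tag occur on either strand of any reference
    sequence with at most ``max_mismatch`` substitutions?"""
    t = tag.upper().replace("U", "T")
    L = len(t)
    for rseq in reference.values():
        r = rseq.upper().replace("U", "T")
        for query in (t, revcomp(t)):
            for s in range(len(r) - L + 1):
                mm = sum(1 for a, b in zip(query, r[s : s + L]) if a != b)
                if mm <= max_mismatch:
                    return True
    return False


def exhaustive_antisense(
    mirna: str, mrna: str, max_mm: int = 1, max_gu: int = 2
) -> set[tuple[int, int, int, int, bool, int]]:
    """All antisense sites of one miRNA on one transcript, plain loops.

    Returns ``{(start_1based, end_1based, mismatches, gu, seed_perfect,
    score)}`` under the pipeline's site definition: pattern = reverse
    complement of the miRNA, G:U wobble allowed where the pattern has C
    over a template T or A over a template G, no non-wobble mismatch in
    the miRNA seed (positions 2-8, i.e. pattern indices L-8..L-2), and
    score = -(3 GC + 2 AU + 1 GU) + 1 per mismatch.
    """
    m = mirna.upper().replace("U", "T")
    s = mrna.upper().replace("U", "T")
    L = len(m)
    comp = revcomp(m)
    seed_lo, seed_hi = max(L - 8, 0), L - 1  # pattern indices, half-open
    out = set()
    for j in range(len(s) - L + 1):
        window = s[j : j + L]
        mm = gu = score = 0
        seed_mm = seed_gu = 0
        for p in range(L):
            a, b = comp[p], window[p]
            if a == b:
                score -= 3 if a in "GC" else 2
            elif (a == "C" and b == "T") or (a == "A" and b == "G"):
                gu += 1
                score -= 1
                if seed_lo <= p < seed_hi:
                    seed_gu += 1
            else:
                mm += 1
                score += 1
                if seed_lo <= p < seed_hi:
                    seed_mm += 1
        if mm <= max_mm and gu <= max_gu and seed_mm == 0:
            out.add((j + 1, j + L, mm, gu, seed_mm + seed_gu == 0, score))
    return out
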