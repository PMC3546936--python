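"""RNA secondary structure by base-pair maximization.

The precursor criterion used throughout the pipeline is stated in *paired
base counts* (a stem-loop must contain at least 18 base pairs), which a
Nussinov-style maximum-matching dynamic program tests directly.  Allowed
pairs are the canonical Watson-Crick pairs plus the G:U wobble; hairpin
loops must contain at least ``min_loop`` unpaired bases.

A simple weighted pair score (GC=3, AU=2, GU=1, negated) stands in for a
thermodynamic free energy: it is monotone in stem content, cheap, and a
full nearest-neighbour engine can be slotted in behind the same contract.

The O(n^3) fill is JIT-compiled with numba when available; a pure-Python
fill with identical semantics is used otherwise.
"""

from __future__ import annotations

import numpy as np

from .seq import canonical

MIN_LOOP_DEFAULT = 3

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# canonical + wobble pair matrix over the encoding above
_PAIRS = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in (("A", "T"), ("G", "C"), ("G", "T")):
    _PAIRS[_ENC[_a], _ENC[_b]] = True
    _PAIRS[_ENC[_b], _ENC[_a]] = True

_PAIR_WEIGHT = {frozenset("GC"): 3, frozenset("AT"): 2, frozenset("GT"): 1}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(canonical(seq).encode(), dtype=np.uint8).copy()


_BASE_LUT = np.full(256, 4, dtype=np.int8)
for _c, _i in _ENC.items():
    _BASE_LUT[ord(_c)] = _i


def _fill_kernel(code, min_loop, pairs):  # compiled by numba when available
    n = code.shape[0]
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pairs[code[i], code[k]]:
                    inner = m[i + 1, k - 1] if k - 1 > i + 1 else 0
                    right = m[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            m[i, j] = best
    return m


try:  # pragma: no cover - exercised implicitly when numba is installed
    from numba import njit

    _fill_nb = njit(cache=True)(_fill_kernel)
except Exception:  # pragma: no cover
    _fill_nb = None


def _fill(code: np.ndarray, min_loop: int) -> np.ndarray:
    if _fill_nb is not None:
        return _fill_nb(code, min_loop, _PAIRS)
    return _fill_kernel(code, min_loop, _PAIRS)


def max_pair_structure(seq: str, min_loop: int = MIN_LOOP_DEFAULT) -> tuple[str, int]:
    """Predict the maximum-base-pair structure of *seq*.

    Returns ``(dot_bracket, paired_bases)``.  Tie-breaking is deterministic:
    the traceback pairs the leftmost pairable base with its smallest optimal
    partner, which biases opening brackets as early as possible.
    """
    s = canonical(seq)
    n = len(s)
    if n == 0:
        return "", 0
    code = _BASE_LUT[_encode(s)]
    m = _fill(code, min_loop)

    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if m[i, j] == m[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            if not _PAIRS[code[i], code[k]]:
                continue
            inner = m[i + 1, k - 1] if k - 1 > i + 1 else 0
            right = m[k + 1, j] if k + 1 <= j else 0
            if 1 + inner + right == m[i, j]:
                struct[i], struct[k] = "(", ")"
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
    db = "".join(struct)
    return db, int(m[0, n - 1])


def pair_table(structure: str) -> list[int]:
    """Partner index for every position (-1 when unpaired).

    Raises ``ValueError`` on unbalanced brackets.
    """
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return partner


def fold_energy(seq: str, structure: str) -> int:
    """Weighted pair score: -(3*GC + 2*AU + 1*GU); lower = more stable.

    Pairs outside {AU, GC, GU} contribute nothing.
    """
    s = canonical(seq)
    if len(s) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    partner = pair_table(structure)
    score = 0
    for i, j in enumerate(partner):
        if j > i:
            score += _PAIR_WEIGHT.get(frozenset((s[i], s[j])), 0)
    return -score


def count_pairs(structure: str) -> int:
    """Number of base pairs encoded by a dot-bracket string."""
    return sum(1 for i, j in enumerate(pair_table(structure)) if j > i)
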