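"""Sequence alphabet utilities shared across the pipeline.

The pipeline mixes DNA references (genome, EST/GSS contigs) with RNA miRNA
catalogues.  Internally every sequence is canonicalised to the DNA alphabet
(U -> T, uppercase); I/O layers may convert back to RNA where the output
convention calls for it.
"""

from __future__ import annotations

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TO_DNA = str.maketrans("uU", "tT")
_TO_RNA = str.maketrans("tT", "uU")


def canonical(seq: str) -> str:
    """Uppercase DNA-alphabet form of *seq* (U and T are equivalent)."""
    s = seq.translate(_TO_DNA).upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)!r}")
    return s


def to_rna(seq: str) -> str:
    """Lowercase-preserving T->U conversion for RNA-convention output."""
    return seq.translate(_TO_RNA)


def reverse_complement(seq: str) -> str:
    """Reverse complement on the canonical DNA alphabet.

    Accepts RNA input (U treated as T); output is DNA-convention.
    Involution: ``reverse_complement(reverse_complement(x)) == x``.
    """
    return canonical(seq).translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
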