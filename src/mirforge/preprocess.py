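"""Raw-read preprocessing: adapter trimming, size selection, collapsing.

Converts sequencer reads into high-quality unique tags: the 3' adapter is
located and removed, reads outside the 15-26 nt window are dropped, reads
are collapsed to unique tags with copy counts, and singleton tags (fewer
than two copies) are discarded.  Every input read lands in exactly one
accounting category.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .seq import canonical

MIN_ADAPTER_MATCH = 6


@dataclass
class SmallRNARead:
    """One sequencer read (quality scores optional)."""

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")


@dataclass(frozen=True)
class UniqueTag:
    """A collapsed read sequence with its copy count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


@dataclass
class ReadAccounting:
    """Partition of raw reads over the preprocessing stages.

    ``adapter_trimmed`` counts reads discarded because no 3' adapter prefix
    was found; ``n_discarded`` counts reads containing ambiguous (N) bases,
    which cannot take part in one-mismatch matching downstream.
    Invariant: ``raw == clean + adapter_trimmed + n_discarded +
    length_filtered + low_copy_removed``.
    """

    raw: int = 0
    adapter_trimmed: int = 0
    n_discarded: int = 0
    length_filtered: int = 0
    low_copy_removed: int = 0
    clean: int = 0

    def check(self) -> None:
        removed = (
            self.adapter_trimmed + self.n_discarded + self.length_filtered + self.low_copy_removed
        )
        if self.raw != self.clean + removed:
            raise AssertionError("read accounting does not partition the input")


def trim_adapter(read: SmallRNARead, adapter3: str) -> SmallRNARead | None:
    """Remove the 3' adapter; ``None`` when no adapter prefix is found.

    The insert is the subsequence preceding the leftmost position where the
    read matches a prefix of the adapter of length ``min(len(adapter),
    bases remaining)``, requiring at least 6 matched bases.  Matching is
    exact (no mismatches).
    """
    seq = canonical(read.sequence)
    insert_end = _find_adapter(seq, canonical(adapter3))
    if insert_end is None or insert_end == 0:
        # no adapter, or the read is pure adapter (empty insert)
        return None
    return SmallRNARead(
        id=read.id,
        sequence=seq[:insert_end],
        quality=read.quality[:insert_end] if read.quality else None,
    )


def filter_and_collapse(
    reads: list[SmallRNARead],
    min_len: int = 15,
    max_len: int = 26,
    min_copies: int = 2,
    accounting: ReadAccounting | None = None,
) -> tuple[list[UniqueTag], ReadAccounting]:
    """Size-select, drop N-containing reads, collapse, apply the copy filter.

    Returns tags sorted by descending count then sequence, and the read
    accounting.  When an ``accounting`` carrying upstream adapter losses is
    passed in it is extended in place.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    acct = accounting if accounting is not None else ReadAccounting()
    if accounting is None:
        acct.raw = len(reads)
    counter: Counter[str] = Counter()
    for read in reads:
        seq = canonical(read.sequence)
        if "N" in seq:
            acct.n_discarded += 1
        elif not (min_len <= len(seq) <= max_len):
            acct.length_filtered += 1
        else:
            counter[seq] += 1
    tags: list[UniqueTag] = []
    for seq, count in counter.items():
        if count >= min_copies:
            tags.append(UniqueTag(seq, count))
        else:
            acct.low_copy_removed += count
    acct.clean = sum(t.count for t in tags)
    acct.check()
    tags.sort(key=lambda t: (-t.count, t.sequence))
    return tags, acct


def preprocess_reads(
    reads: list[SmallRNARead],
    adapter3: str | None = None,
    min_len: int = 15,
    max_len: int = 26,
    min_copies: int = 2,
) -> tuple[list[UniqueTag], ReadAccounting]:
    """Full preprocessing stage: trim (optional), filter, collapse."""
    acct = ReadAccounting(raw=len(reads))
    if adapter3 is None:
        trimmed = reads
    else:
        trimmed = []
        for read in reads:
            seq = canonical(read.sequence)
            insert_end = _find_adapter(seq, canonical(adapter3))
            if insert_end is None:
                acct.adapter_trimmed += 1
            elif insert_end == 0:
                acct.length_filtered += 1  # pure-adapter read: zero-length insert
            else:
                trimmed.append(SmallRNARead(read.id, seq[:insert_end], None))
    return filter_and_collapse(trimmed, min_len, max_len, min_copies, acct)


def _find_adapter(seq: str, adapter: str) -> int | None:
    """Leftmost insert end before an adapter occurrence, else ``None``."""
    if len(adapter) < MIN_ADAPTER_MATCH:
        raise ValueError("3' adapter must be at least 6 nt")
    n = len(seq)
    for i in range(n - MIN_ADAPTER_MATCH + 1):
        k = min(len(adapter), n - i)
        if seq[i : i + k] == adapter[:k]:
            return i
    return None


def length_histogram(tags: list[UniqueTag]) -> dict[int, int]:
    """Read-count-weighted length distribution of a tag set."""
    if not tags:
        raise ValueError("length_histogram requires a non-empty tag set")
    hist: dict[int, int] = {}
    for t in tags:
        hist[len(t.sequence)] = hist.get(len(t.sequence), 0) + t.count
    return dict(sorted(hist.items()))


def length_fractions(tags: list[UniqueTag]) -> dict[int, float]:
    hist = length_histogram(tags)
    total = sum(hist.values())
    return {k: v / total for k, v in hist.items()}
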