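"""Non-miRNA ncRNA annotation and removal (rRNA / tRNA / snoRNA / snRNA).

A tag is annotated as ncRNA when it occurs as a substring of a labelled
reference sequence, on either strand, with at most ``max_mismatch``
substitutions.  Reference headers carry the class as a ``|class`` suffix.
Candidate positions come from an exact pigeonhole chunk match, so results
equal a brute-force slide of every tag over every reference position.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mapping import _candidate_starts
from .preprocess import UniqueTag
from .seq import canonical, reverse_complement

NCRNA_CLASSES = ("rRNA", "tRNA", "snoRNA", "snRNA", "other-ncRNA")
_CLASS_PRIORITY = {c: i for i, c in enumerate(NCRNA_CLASSES)}


@dataclass(frozen=True)
class NcRNAHit:
    tag: UniqueTag
    reference_id: str
    ncrna_class: str
    mismatches: int


def parse_class(header: str) -> tuple[str, str]:
    """Split ``id|class`` reference headers; unknown classes map to
    ``other-ncRNA``; a missing label is an input error."""
    if "|" not in header:
        raise ValueError(f"ncRNA reference record {header!r} carries no |class label")
    ref_id, label = header.rsplit("|", 1)
    label = label.strip()
    if label not in _CLASS_PRIORITY:
        label = "other-ncRNA"
    return ref_id.strip(), label


def _best_hit(tseq: str, refs: list[tuple[str, str, str]], max_mismatch: int) -> tuple[str, str, int] | None:
    """(ref_id, class, mismatches) of the best hit, or None.

    Ties on mismatch count are broken by fixed class priority
    rRNA > tRNA > snoRNA > snRNA > other, then reference id.
    """
    L = len(tseq)
    best: tuple[int, int, str, str] | None = None  # (mm, class_prio, ref_id, class)
    queries = (tseq, reverse_complement(tseq))
    for ref_id, label, rseq in refs:
        for query in queries:
            for s in _candidate_starts(query, rseq, max_mismatch + 1):
                mm = sum(1 for a, b in zip(query, rseq[s : s + L]) if a != b)
                if mm <= max_mismatch:
                    key = (mm, _CLASS_PRIORITY[label], ref_id, label)
                    if best is None or key < best:
                        best = key
    if best is None:
        return None
    return best[2], best[3], best[0]


def annotate_ncrna(
    tags: list[UniqueTag],
    reference: dict[str, str],
    max_mismatch: int = 1,
) -> tuple[list[NcRNAHit], list[UniqueTag], dict[str, int]]:
    """Partition tags into (removed ncRNA hits, retained tags, class counts).

    Class counts are copy-count weighted, mirroring a read-level annotation
    pie chart.
    """
    refs = [(*parse_class(header), canonical(seq)) for header, seq in reference.items()]
    removed: list[NcRNAHit] = []
    retained: list[UniqueTag] = []
    class_counts: dict[str, int] = {}
    for tag in tags:
        hit = _best_hit(canonical(tag.sequence), refs, max_mismatch)
        if hit is None:
            retained.append(tag)
        else:
            ref_id, label, mm = hit
            removed.append(NcRNAHit(tag, ref_id, label, mm))
            class_counts[label] = class_counts.get(label, 0) + tag.count
    return removed, retained, dict(sorted(class_counts.items()))
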