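"""Short-tag mapping to genome / EST / GSS references.

Tags are aligned ungapped on both strands, tolerating at most ``seed_mm``
substitutions within the first ``seed_len`` bases of the tag (5'->3' as
read) and at most ``total_mm`` substitutions overall.  Candidate positions
are found exactly by a pigeonhole split of the tag into ``total_mm + 1``
chunks, one of which must occur verbatim; every candidate is then verified
base by base, so the result is identical to an exhaustive window scan.

Coordinates are 1-based inclusive on the forward strand; the printed locus
string format is ``ref∶start.end:strand``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .preprocess import UniqueTag
from .seq import canonical, reverse_complement

LOCUS_SEP = "∶"  # the ratio character used in printed coordinate strings


@dataclass(frozen=True, order=True)
class GenomeLocus:
    ref: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid locus coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.ref}{LOCUS_SEP}{self.start}.{self.end}:{self.strand}"

    @classmethod
    def parse(cls, text: str) -> "GenomeLocus":
        """Parse ``ref∶start.end:strand`` (ASCII ':' accepted for '∶')."""
        s = text.strip()
        body, strand = s.rsplit(":", 1)
        strand = {"−": "-", "–": "-"}.get(strand.strip(), strand.strip())
        if LOCUS_SEP in body:
            ref, coords = body.rsplit(LOCUS_SEP, 1)
        else:
            ref, coords = body.rsplit(":", 1)
        start_s, end_s = coords.split(".", 1)
        return cls(ref=ref, start=int(start_s), end=int(end_s), strand=strand)

    def to_bed(self) -> tuple[str, int, int, str]:
        """0-based half-open BED triple plus strand."""
        return self.ref, self.start - 1, self.end, self.strand


@dataclass
class MappedTag:
    tag: UniqueTag
    loci: list[GenomeLocus] = field(default_factory=list)
    mismatches: list[int] = field(default_factory=list)
    multimap_flagged: bool = False


def _mismatch_positions(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def _candidate_starts(query: str, ref_seq: str, n_chunks: int) -> set[int]:
    """Alignment start positions where some pigeonhole chunk matches exactly."""
    L = len(query)
    starts: set[int] = set()
    bounds = [round(i * L / n_chunks) for i in range(n_chunks + 1)]
    for c in range(n_chunks):
        lo, hi = bounds[c], bounds[c + 1]
        chunk = query[lo:hi]
        if not chunk:
            continue
        pos = ref_seq.find(chunk)
        while pos != -1:
            s = pos - lo
            if 0 <= s <= len(ref_seq) - L:
                starts.add(s)
            pos = ref_seq.find(chunk, pos + 1)
    return starts


def map_tags(
    tags: list[UniqueTag],
    reference: dict[str, str],
    seed_len: int = 18,
    seed_mm: int = 1,
    total_mm: int = 1,
    max_loci: int = 10,
) -> tuple[list[MappedTag], list[UniqueTag]]:
    """Map tags to a reference set; returns (mapped, unmapped).

    All qualifying loci are reported, sorted by (mismatches, ref, start,
    strand); tags with more than ``max_loci`` loci keep the first
    ``max_loci`` and are flagged.
    """
    if not reference:
        raise ValueError("reference sequence set is empty")
    refs = {name: canonical(seq) for name, seq in reference.items()}
    mapped: list[MappedTag] = []
    unmapped: list[UniqueTag] = []
    n_chunks = total_mm + 1
    for tag in tags:
        tseq = canonical(tag.sequence)
        L = len(tseq)
        eff_seed = min(seed_len, L)
        hits: list[tuple[int, GenomeLocus]] = []
        for name, rseq in refs.items():
            for strand, query in (("+", tseq), ("-", reverse_complement(tseq))):
                for s in _candidate_starts(query, rseq, n_chunks):
                    window = rseq[s : s + L]
                    mmpos = _mismatch_positions(query, window)
                    if len(mmpos) > total_mm:
                        continue
                    # positions in tag coordinates (5'->3' of the tag)
                    tagpos = mmpos if strand == "+" else [L - 1 - p for p in mmpos]
                    if sum(1 for p in tagpos if p < eff_seed) > seed_mm:
                        continue
                    hits.append((len(mmpos), GenomeLocus(name, s + 1, s + L, strand)))
        if not hits:
            unmapped.append(tag)
            continue
        hits.sort(key=lambda h: (h[0], h[1]))
        flagged = len(hits) > max_loci
        hits = hits[:max_loci]
        mapped.append(
            MappedTag(
                tag=tag,
                loci=[h[1] for h in hits],
                mismatches=[h[0] for h in hits],
                multimap_flagged=flagged,
            )
        )
    return mapped, unmapped


def distribution_by_reference(mapped: list[MappedTag]) -> dict[str, dict[str, int]]:
    """Per-reference unique-tag and read counts (multi-reference tags count
    once per reference)."""
    if not mapped:
        raise ValueError("no mapped tags")
    out: dict[str, dict[str, int]] = {}
    for mt in mapped:
        for ref in sorted({loc.ref for loc in mt.loci}):
            entry = out.setdefault(ref, {"unique_tags": 0, "reads": 0})
            entry["unique_tags"] += 1
            entry["reads"] += mt.tag.count
    return dict(sorted(out.items()))
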