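"""Conserved and novel miRNA calling.

Conserved calls: a tag matches a known mature catalogue entry when an
ungapped alignment starting within +/-3 nt of the mature 5' end has at most
one substitution over the overlap (isomiR end heterogeneity would otherwise
push conserved tags into the novel branch).

Novel calls: leftover tags are mapped to the genome and EST/GSS contigs;
around every locus two candidate precursor windows are excised (tag as 5'
arm and tag as 3' arm), folded by base-pair maximization, and accepted when
the stem-loop holds at least 18 base pairs, the tag lies wholly within one
arm, and the weighted pair score clears the stability threshold.  Calls
sharing a precursor locus are merged; names are serial in descending read
support.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import fold
from .mapping import GenomeLocus, MappedTag, map_tags
from .preprocess import UniqueTag
from .seq import canonical, reverse_complement

_FAMILY_RE = re.compile(
    r"^(?:[a-z]{2,4}-)?((?:miR|mir|let)-\d+)[a-z]*(?:-[35]p)?(?:\*)?$", re.IGNORECASE
)


def mirna_family(name: str) -> str:
    """Family base name: species prefix, letter suffix and arm dropped.

    ``ipu-miR-7563a -> miR-7563``; ``dre-let-7a-5p -> let-7``.  Names that
    do not follow catalogue conventions are their own family.
    """
    m = _FAMILY_RE.match(name.strip())
    return m.group(1) if m else name.strip()


@dataclass
class HairpinCandidate:
    """An excised precursor window with its predicted structure."""

    sequence: str
    locus: GenomeLocus
    structure: str
    paired_bases: int
    fold_energy: float
    mature_arm: str  # '5p' | '3p'
    mature_span: tuple[int, int]  # 0-based half-open, precursor coordinates

    def __post_init__(self) -> None:
        if fold.count_pairs(self.structure) != self.paired_bases:
            raise ValueError("paired_bases inconsistent with structure")


@dataclass
class MiRNACall:
    name: str
    sequence: str
    status: str  # 'conserved' | 'novel'
    count: int
    family: str | None = None
    locus: GenomeLocus | None = None
    source: str | None = None  # 'genome' | 'EST/GSS'
    precursor: HairpinCandidate | None = None
    member_tags: list[UniqueTag] = field(default_factory=list)


def _overlap_mismatches(tag: str, mature: str, offset: int) -> tuple[int, int]:
    """(mismatches, overlap length) aligning tag[0] to mature[offset]."""
    start_t = max(0, -offset)
    start_m = max(0, offset)
    n = min(len(tag) - start_t, len(mature) - start_m)
    if n <= 0:
        return 10**6, 0
    mm = sum(
        1 for k in range(n) if tag[start_t + k] != mature[start_m + k]
    )
    return mm, n


def call_conserved(
    tags: list[UniqueTag],
    known_matures: dict[str, str],
    max_mm: int = 1,
    end_tol: int = 3,
) -> tuple[list[MiRNACall], list[UniqueTag]]:
    """Match tags against a known mature catalogue.

    Returns (conserved calls, leftover tags).  Each qualifying tag is
    assigned to its best mature (fewest mismatches, then longest overlap,
    then name); per mature, the most abundant qualifying tag becomes the
    call's representative sequence and the call count sums all its tags.
    """
    if not known_matures:
        raise ValueError("known mature catalogue is empty")
    names = list(known_matures)
    if len(set(names)) != len(names):
        raise ValueError("duplicate mature names in catalogue")
    matures = {name: canonical(seq) for name, seq in known_matures.items()}

    assigned: dict[str, list[UniqueTag]] = {}
    leftover: list[UniqueTag] = []
    for tag in tags:
        tseq = canonical(tag.sequence)
        best: tuple[int, int, str] | None = None  # (mm, -overlap, name)
        for name, mseq in matures.items():
            for off in range(-end_tol, end_tol + 1):
                mm, n = _overlap_mismatches(tseq, mseq, off)
                if n < len(tseq) - end_tol or mm > max_mm:
                    continue
                key = (mm, -n, name)
                if best is None or key < best:
                    best = key
        if best is None:
            leftover.append(tag)
        else:
            assigned.setdefault(best[2], []).append(tag)

    calls = []
    for name in names:
        members = assigned.get(name)
        if not members:
            continue
        rep = min(members, key=lambda t: (-t.count, t.sequence))
        calls.append(
            MiRNACall(
                name=name,
                sequence=rep.sequence,
                status="conserved",
                count=sum(t.count for t in members),
                family=mirna_family(name),
                member_tags=sorted(members, key=lambda t: (-t.count, t.sequence)),
            )
        )
    return calls, leftover


def family_counts(calls: list[MiRNACall]) -> dict[str, int]:
    """Number of distinct calls per miRNA family."""
    out: dict[str, int] = {}
    for c in calls:
        fam = c.family or mirna_family(c.name)
        out[fam] = out.get(fam, 0) + 1
    return dict(sorted(out.items()))


def excise_and_fold(
    locus: GenomeLocus,
    reference: dict[str, str],
    flank: int = 70,
    pad: int = 15,
    min_pairs: int = 18,
    energy_threshold: float = -25.0,
    min_loop: int = fold.MIN_LOOP_DEFAULT,
) -> HairpinCandidate | None:
    """Excise candidate precursor windows around a tag locus and fold them.

    Two windows are tried: tag near the 5' arm (long downstream flank) and
    tag near the 3' arm (long upstream flank); windows running off the
    reference are trimmed.  The better passing window (more pairs, then
    lower energy, then 5'-arm first) becomes the candidate.
    """
    if flank < 20:
        raise ValueError("flank must be at least 20 nt")
    rseq = canonical(reference[locus.ref])
    s0, e0 = locus.start - 1, locus.end  # 0-based half-open on forward strand
    windows = [
        ("5p", max(0, s0 - pad), min(len(rseq), e0 + flank)),
        ("3p", max(0, s0 - flank), min(len(rseq), e0 + pad)),
    ]
    best: tuple[tuple, HairpinCandidate] | None = None
    for which, ws, we in windows:
        window = rseq[ws:we]
        if locus.strand == "-":
            window = reverse_complement(window)
            tag_lo, tag_hi = we - e0, we - s0
        else:
            tag_lo, tag_hi = s0 - ws, e0 - ws
        structure, pairs = fold.max_pair_structure(window, min_loop)
        if pairs < min_pairs:
            continue
        energy = fold.fold_energy(window, structure)
        if energy > energy_threshold:
            continue
        arm = _tag_arm(structure, tag_lo, tag_hi)
        if arm is None:
            continue
        cand = HairpinCandidate(
            sequence=window,
            locus=GenomeLocus(locus.ref, ws + 1, we, locus.strand),
            structure=structure,
            paired_bases=pairs,
            fold_energy=energy,
            mature_arm=arm,
            mature_span=(tag_lo, tag_hi),
        )
        key = (-pairs, energy, 0 if which == "5p" else 1)
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1] if best else None


def _tag_arm(structure: str, lo: int, hi: int) -> str | None:
    """'5p'/'3p' when every paired base in [lo, hi) points one way, else None."""
    partner = fold.pair_table(structure)
    sides = set()
    for i in range(lo, hi):
        j = partner[i]
        if j < 0:
            continue
        if lo <= j < hi:
            return None  # the tag pairs with itself: it straddles a loop
        sides.add("5p" if j > i else "3p")
    if len(sides) != 1:
        return None
    return sides.pop()


def call_novel(
    leftover: list[UniqueTag],
    genome: dict[str, str],
    est_gss: dict[str, str] | None = None,
    known_matures: dict[str, str] | None = None,
    map_params: dict | None = None,
    fold_params: dict | None = None,
) -> list[MiRNACall]:
    """Hairpin-supported novel miRNA calls from leftover tags.

    Tags are mapped to the genome and (separately) EST/GSS contigs; loci
    with a passing hairpin are clustered by overlapping precursor windows
    and merged into one call whose representative mature is the most
    abundant member tag.  Loci overlapping a mapped known mature (when a
    catalogue is given) are skipped - they are isomiRs or star strands of
    known precursors, not new genes.  Names ``novel-mir-{n}`` are assigned
    in descending read support.
    """
    map_params = map_params or {}
    fold_params = fold_params or {}
    known_loci: dict[str, list[tuple[int, int, str]]] = {}
    sources = [("genome", genome)]
    if est_gss:
        sources.append(("EST/GSS", est_gss))
    if known_matures:
        kt = [UniqueTag(canonical(s), 1) for s in known_matures.values()]
        for _, ref in sources:
            km, _ = map_tags(kt, ref, **map_params)
            for mt in km:
                for loc in mt.loci:
                    known_loci.setdefault(loc.ref, []).append(
                        (loc.start - 150, loc.end + 150, loc.strand)
                    )

    clusters: list[dict] = []
    for source, ref in sources:
        if not ref:
            continue
        mapped, _ = map_tags(leftover, ref, **map_params)
        for mt in mapped:
            for loc in mt.loci:
                if any(
                    lo <= loc.start and loc.end <= hi and st == loc.strand
                    for lo, hi, st in known_loci.get(loc.ref, [])
                ):
                    continue
                cand = excise_and_fold(loc, ref, **fold_params)
                if cand is None:
                    continue
                _merge_into_clusters(clusters, source, mt.tag, cand)

    calls: list[MiRNACall] = []
    for cl in sorted(clusters, key=lambda c: (-c["count"], str(c["candidate"].locus))):
        rep_tag, rep_cand = cl["best"]
        calls.append(
            MiRNACall(
                name=f"novel-mir-{len(calls) + 1}",
                sequence=rep_tag.sequence,
                status="novel",
                count=cl["count"],
                locus=rep_cand.locus,
                source=cl["source"],
                precursor=rep_cand,
                member_tags=sorted(cl["tags"], key=lambda t: (-t.count, t.sequence)),
            )
        )
    return calls


def _merge_into_clusters(clusters: list[dict], source: str, tag: UniqueTag, cand: HairpinCandidate) -> None:
    loc = cand.locus
    for cl in clusters:
        other = cl["candidate"].locus
        # strand is deliberately ignored: overlapping hairpin windows on
        # opposite strands of one locus are the same candidate gene
        if (
            cl["source"] == source
            and other.ref == loc.ref
            and loc.start <= other.end
            and other.start <= loc.end
        ):
            if tag.sequence not in {t.sequence for t in cl["tags"]}:
                cl["tags"].append(tag)
                cl["count"] += tag.count
            if (-tag.count, tag.sequence) < (-cl["best"][0].count, cl["best"][0].sequence):
                cl["best"] = (tag, cand)
            return
    clusters.append(
        {
            "source": source,
            "candidate": cand,
            "tags": [tag],
            "count": tag.count,
            "best": (tag, cand),
        }
    )
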