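"""IsomiR characterization, cleavage-site inference and miRNA* detection.

Every tag attributed to a miRNA is decomposed against its precursor
context into 5'/3' end offsets, internal substitutions and a maximal 3'
non-template tail (trailing bases that mismatch the templated continuation,
up to 3 nt).  A trailing mismatch followed by matching bases is an internal
substitution, not a tail.  Read-weighted end-position modes estimate the
dominant Drosha/Dicer cleavage sites; tags on the arm opposite the mature
are tested for duplex geometry with the canonical 2-nt 3' overhangs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import Align

from . import fold
from .preprocess import UniqueTag
from .seq import canonical

SUBSTITUTION_CLASSES = [
    f"{a}-to-{b}" for a in "ACGU" for b in "ACGU" if a != b
]


@dataclass
class IsomiRRecord:
    parent: str
    sequence: str
    count: int
    offset5: int  # read 5' start minus mature 5' start (template coords)
    offset3: int  # templated read 3' end minus mature 3' end
    substitutions: list[tuple[int, str, str]]  # (read position, template, read)
    nta_tail: str
    category: str  # canonical | substitution | shift | NTA | mixed


@dataclass
class CleavageProfile:
    parent: str
    dominant5: int  # offset of the dominant 5' cleavage site vs the reference
    dominant3: int
    sites5: dict[int, int] = field(default_factory=dict)  # offset -> reads
    sites3: dict[int, int] = field(default_factory=dict)


@dataclass
class DuplexPair:
    precursor: str
    mature_seq: str
    star_seq: str
    mature_count: int
    star_count: int
    overhang_mature3: int
    overhang_star3: int
    star_dominant: bool

    @property
    def ratio(self) -> float:
        return self.star_count / self.mature_count


def _decompose_at(tag: str, context: str, start: int, max_nta: int) -> tuple[list, str] | None:
    """(substitutions, tail) aligning tag at context position *start*."""
    L = len(tag)
    if start < 0 or start + L > len(context):
        return None
    template = context[start : start + L]
    mism = [i for i in range(L) if tag[i] != template[i]]
    tail_len = 0
    while tail_len < max_nta and (L - 1 - tail_len) in mism:
        tail_len += 1
    core_mism = [i for i in mism if i < L - tail_len]
    subs = [(i, template[i], tag[i]) for i in core_mism]
    return subs, tag[L - tail_len :] if tail_len else ""


def classify_isomirs(
    tags: list[UniqueTag],
    parent: str,
    mature_span: tuple[int, int],
    context: str,
    context_offset: int = 0,
    window: int = 5,
    max_nta: int = 3,
    max_substitutions: int = 3,
) -> list[IsomiRRecord]:
    """Decompose tags against the precursor context around the mature.

    ``mature_span`` is 0-based half-open in precursor coordinates and
    ``context`` holds the precursor plus templated flanks starting at
    ``context_offset``.  Alignments are tried with the tag 5' end within
    +/-``window`` nt of the mature 5' end; the best one minimises
    (substitutions, tail length, |5' offset|).  Tags with no acceptable
    alignment are skipped with a warning.
    """
    ctx = canonical(context)
    m0 = context_offset + mature_span[0]
    m_len = mature_span[1] - mature_span[0]
    records: list[IsomiRRecord] = []
    for tag in tags:
        tseq = canonical(tag.sequence)
        best = None  # (n_subs, tail_len, |off5|, off5, subs, tail)
        for off5 in range(-window, window + 1):
            dec = _decompose_at(tseq, ctx, m0 + off5, max_nta)
            if dec is None:
                continue
            subs, tail = dec
            key = (len(subs), len(tail), abs(off5), off5)
            if best is None or key < best[:4]:
                best = (*key, subs, tail)
        if best is None or best[0] > max_substitutions:
            warnings.warn(f"tag {tseq} not alignable to {parent}; skipped")
            continue
        n_subs, tail_len, _, off5, subs, tail = best
        off3 = off5 + len(tseq) - tail_len - m_len
        has_shift = off5 != 0 or off3 != 0
        kinds = sum([bool(subs), bool(tail), has_shift])
        if kinds == 0:
            category = "canonical"
        elif kinds > 1:
            category = "mixed"
        elif subs:
            category = "substitution"
        elif tail:
            category = "NTA"
        else:
            category = "shift"
        records.append(
            IsomiRRecord(
                parent=parent,
                sequence=tseq,
                count=tag.count,
                offset5=off5,
                offset3=off3,
                substitutions=subs,
                nta_tail=tail,
                category=category,
            )
        )
    return records


def reconstruct(record: IsomiRRecord, mature_span: tuple[int, int], context: str, context_offset: int = 0) -> str:
    """Rebuild the tag from its decomposition (round-trip identity)."""
    start = context_offset + mature_span[0] + record.offset5
    end = context_offset + mature_span[1] + record.offset3
    core = list(canonical(context)[start:end])
    for pos, _, alt in record.substitutions:
        core[pos] = alt
    return "".join(core) + record.nta_tail


def substitution_spectrum(records: list[IsomiRRecord], weight: str = "reads") -> dict[str, float]:
    """Directed substitution fractions over the 12 classes (RNA alphabet).

    ``weight='reads'`` (default) weights by copy count, ``'tags'`` counts
    each distinct tag once.
    """
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0.0)
    for rec in records:
        w = rec.count if weight == "reads" else 1
        for _, ref, alt in rec.substitutions:
            key = f"{ref}-to-{alt}".replace("T", "U")
            counts[key] += w
    total = sum(counts.values())
    if total == 0:
        return counts
    return {k: v / total for k, v in counts.items()}


def nta_base_counts(records: list[IsomiRRecord]) -> dict[str, int]:
    """Read-weighted counts of 3' non-template added bases (RNA alphabet)."""
    counts: dict[str, int] = {}
    for rec in records:
        for base in rec.nta_tail.replace("T", "U"):
            counts[base] = counts.get(base, 0) + rec.count
    return dict(sorted(counts.items()))


def infer_cleavage_sites(records: list[IsomiRRecord], parent: str | None = None) -> CleavageProfile:
    """Dominant 5' and 3' cleavage sites as read-weighted end-offset modes.

    Non-template tails are already excluded from 3' offsets by
    classification; ties break toward the reference mature end (offset 0).
    """
    if not records:
        raise ValueError("cannot infer cleavage sites from an empty record set")
    sites5: dict[int, int] = {}
    sites3: dict[int, int] = {}
    for rec in records:
        sites5[rec.offset5] = sites5.get(rec.offset5, 0) + rec.count
        sites3[rec.offset3] = sites3.get(rec.offset3, 0) + rec.count
    pick = lambda d: min(d, key=lambda o: (-d[o], abs(o), o))
    return CleavageProfile(
        parent=parent or records[0].parent,
        dominant5=pick(sites5),
        dominant3=pick(sites3),
        sites5=dict(sorted(sites5.items())),
        sites3=dict(sorted(sites3.items())),
    )


def _nearest_partner(partner: list[int], pos: int, direction: int, span: int = 3) -> int | None:
    """Partner of the first paired base at/near *pos*, offset-corrected."""
    for k in range(span + 1):
        p = pos + direction * k
        if 0 <= p < len(partner) and partner[p] >= 0:
            return partner[p] + direction * k
    return None


def detect_star(
    precursor: str,
    structure: str,
    mature_span: tuple[int, int],
    arm_tags: list[tuple[UniqueTag, int]],
    precursor_name: str = "",
    overhang: int = 2,
    overhang_tol: int = 2,
) -> DuplexPair | None:
    """Test tags on the opposite arm for miRNA:miRNA* duplex geometry.

    ``arm_tags`` holds (tag, 0-based start within the precursor) for every
    tag attributed to the precursor.  The most abundant tag whose span lies
    entirely on the far side of the mature's pairing partners is the star
    candidate; it is accepted when both duplex ends show a 3' overhang of
    ``overhang +/- overhang_tol`` nt.
    """
    partner = fold.pair_table(structure)
    ms, me = mature_span
    mature_on_5p = any(partner[i] > i for i in range(ms, me) if partner[i] >= 0)

    opposite = []
    mature_tags = []
    for tag, start in arm_tags:
        end = start + len(tag.sequence)
        if start >= ms - 2 and end <= me + 2 or (start < me and end > ms):
            mature_tags.append((tag, start))
        elif (start >= me) == mature_on_5p:
            opposite.append((tag, start))
    if not opposite or not mature_tags:
        return None
    star_tag, ss = min(opposite, key=lambda x: (-x[0].count, x[0].sequence))
    se = ss + len(star_tag.sequence)
    mature_count = sum(t.count for t, _ in mature_tags)

    p_m5 = _nearest_partner(partner, ms, +1)
    p_s5 = _nearest_partner(partner, ss, +1)
    if p_m5 is None or p_s5 is None:
        return None
    overhang_star3 = (se - 1) - p_m5
    overhang_mature3 = (me - 1) - p_s5
    if not (
        abs(overhang_star3 - overhang) <= overhang_tol
        and abs(overhang_mature3 - overhang) <= overhang_tol
    ):
        return None
    return DuplexPair(
        precursor=precursor_name,
        mature_seq=precursor[ms:me],
        star_seq=star_tag.sequence,
        mature_count=mature_count,
        star_count=star_tag.count,
        overhang_mature3=overhang_mature3,
        overhang_star3=overhang_star3,
        star_dominant=star_tag.count > mature_count,
    )


def seed_conservation(
    sequences: list[str],
    stars: list[str] | None = None,
    seed: tuple[int, int] = (2, 8),
) -> dict:
    """Cross-species conservation profile via pairwise global alignment.

    All sequences are aligned to the first (the reference) with match +1,
    mismatch -1, gap -2.  Returns per-reference-position identity fractions
    and the mean identity over the seed region (reference positions 2-8,
    1-based); star-strand profiles are added when ``stars`` is given.
    """
    if len(sequences) < 2:
        raise ValueError("conservation analysis needs at least 2 sequences")
    out = {
        "mature_profile": _identity_profile(sequences),
    }
    lo, hi = seed
    out["mature_seed_identity"] = float(
        sum(out["mature_profile"][lo - 1 : hi]) / (hi - lo + 1)
    )
    if stars is not None:
        if len(stars) < 2:
            raise ValueError("conservation analysis needs at least 2 star sequences")
        out["star_profile"] = _identity_profile(stars)
        out["star_seed_identity"] = float(
            sum(out["star_profile"][lo - 1 : hi]) / (hi - lo + 1)
        )
    return out


def _identity_profile(sequences: list[str]) -> list[float]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    ref = canonical(sequences[0])
    n_others = len(sequences) - 1
    identical = [0] * len(ref)
    for other in sequences[1:]:
        oseq = canonical(other)
        aln = aligner.align(ref, oseq)[0]
        for (rs, re_), (qs, _) in zip(*aln.aligned):
            for k in range(re_ - rs):
                if ref[rs + k] == oseq[qs + k]:
                    identical[rs + k] += 1
    return [c / n_others for c in identical]
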