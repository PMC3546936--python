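"""Scoring analysis output against the generator's ground truth.

These helpers close the loop between :mod:`mirforge.synth` and the analysis
stages: reads are pushed through preprocessing and isomiR classification,
and the planted per-read rates (substitution rate, 3' tailing rate, tail
base composition) are re-estimated from the classified records.  Standard
errors are plain binomial errors on the classified read totals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .isomir import IsomiRRecord, classify_isomirs
from .preprocess import UniqueTag
from .synth import GroundTruth, PlantedPrecursor


def mature_locus(p: PlantedPrecursor) -> tuple[str, int, int]:
    """1-based inclusive genomic interval of a planted mature arm."""
    return p.ref, p.start + p.mature_span[0], p.start + p.mature_span[1] - 1


def recovered_novel_precursors(novel_calls: list, truth: GroundTruth) -> list[PlantedPrecursor]:
    """Planted novel precursors whose mature locus lies inside a call window.

    The excised window around the most abundant tag can clip a few flank
    bases of the planted hairpin, so recovery is judged on the mature-arm
    interval, which every correct call must cover.
    """
    out = []
    for p in truth.novel_precursors:
        ref, lo, hi = mature_locus(p)
        if any(
            c.locus is not None
            and c.locus.ref == ref
            and c.locus.start <= lo
            and hi <= c.locus.end
            for c in novel_calls
        ):
            out.append(p)
    return out


@dataclass
class RateEstimates:
    n_reads_classified: int
    substitution_rate: float
    substitution_rate_se: float
    nta_rate: float
    nta_rate_se: float
    nta_base_fractions: dict[str, float]
    nta_base_se: dict[str, float]
    n_tail_bases: int


def classify_against_truth(
    tags: list[UniqueTag], truth: GroundTruth, window: int = 5
) -> list[IsomiRRecord]:
    """IsomiR records of every tag alignable to a planted precursor arm.

    Each tag is tried against the mature and star windows of every planted
    precursor; contaminant and background tags align nowhere and drop out.
    """
    records: list[IsomiRRecord] = []
    remaining = list(tags)
    for p in truth.precursors:
        if not remaining:
            break
        matched: set[str] = set()
        for arm, span in (("mature", p.mature_span), ("star", p.star_span)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # unalignable tags are expected here
                recs = classify_isomirs(
                    remaining, f"{p.name}/{arm}", span, p.context,
                    context_offset=p.context_offset, window=window,
                )
            records.extend(recs)
            matched.update(r.sequence for r in recs)
        remaining = [t for t in remaining if t.sequence not in matched]
    return records


def estimate_rates(records: list[IsomiRRecord]) -> RateEstimates:
    """Read-weighted substitution / tailing rates with binomial errors."""
    n = sum(r.count for r in records)
    if n == 0:
        raise ValueError("no classified reads to estimate rates from")
    n_sub = sum(r.count for r in records if r.substitutions)
    n_nta = sum(r.count for r in records if r.nta_tail)
    p_sub, p_nta = n_sub / n, n_nta / n

    tail_bases: dict[str, int] = {}
    n_tail = 0
    for r in records:
        for base in r.nta_tail:
            tail_bases[base] = tail_bases.get(base, 0) + r.count
            n_tail += r.count
    fractions = {b: c / n_tail for b, c in sorted(tail_bases.items())} if n_tail else {}
    base_se = {
        b: math.sqrt(f * (1 - f) / n_tail) for b, f in fractions.items()
    }
    return RateEstimates(
        n_reads_classified=n,
        substitution_rate=p_sub,
        substitution_rate_se=math.sqrt(p_sub * (1 - p_sub) / n),
        nta_rate=p_nta,
        nta_rate_se=math.sqrt(p_nta * (1 - p_nta) / n),
        nta_base_fractions=fractions,
        nta_base_se=base_se,
        n_tail_bases=n_tail,
    )
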