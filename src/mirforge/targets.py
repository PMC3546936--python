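"""miRNA target prediction by antisense complementarity.

A target site is an ungapped antisense alignment of a mature miRNA to an
mRNA with at most ``max_mm`` non-wobble mismatches and ``max_gu`` G:U
wobbles, and no non-wobble mismatch in the miRNA seed (positions 2-8).
The scan is vectorised over every window of every transcript, so results
equal a position-by-position exhaustive search.  A simple weighted duplex
score (GC=3, AU=2, GU=1, negated, +1 per mismatch) ranks hits in place of
a thermodynamic hybridisation energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq import canonical, reverse_complement


@dataclass(frozen=True)
class TargetHit:
    mirna: str
    mrna: str
    start: int  # 1-based inclusive on the mRNA
    end: int
    region: str  # 5'UTR | CDS | 3'UTR | unannotated
    mismatches: int  # non-wobble mismatches
    gu_pairs: int
    seed_perfect: bool
    duplex_score: int


def duplex_score(mirna: str, site: str) -> int:
    """Weighted duplex score of a miRNA against an equal-length mRNA site.

    The site is given 5'->3' on the mRNA; score = -(3*GC + 2*AU + 1*GU)
    over paired positions plus +1 per mismatched position.
    """
    m = canonical(mirna)
    s = canonical(site)
    if len(m) != len(s):
        raise ValueError("site length must equal miRNA length")
    comp = reverse_complement(m)  # aligned 5'->3' with the site
    score = 0
    for p_base, s_base in zip(comp, s):
        if p_base == s_base:
            score -= 3 if p_base in "GC" else 2
        elif (p_base == "C" and s_base == "T") or (p_base == "A" and s_base == "G"):
            score -= 1  # G:U wobble
        else:
            score += 1
    return score


def _region_of(start: int, end: int, cds: tuple[int, int] | None) -> str:
    if cds is None:
        return "unannotated"
    cs, ce = cds
    if end < cs:
        return "5'UTR"
    if start > ce:
        return "3'UTR"
    return "CDS"


def antisense_search(
    mirnas: dict[str, str],
    mrnas: dict[str, str],
    max_mm: int = 1,
    max_gu: int = 2,
    cds_annotation: dict[str, tuple[int, int]] | None = None,
) -> list[TargetHit]:
    """Scan every transcript window for antisense miRNA sites.

    ``cds_annotation`` optionally maps transcript ids to 1-based inclusive
    CDS (start, end) for region labelling.  All qualifying positions are
    reported, ordered by (miRNA, transcript, start).
    """
    if not mrnas:
        raise ValueError("mRNA sequence set is empty")
    hits: list[TargetHit] = []
    encoded = {
        name: np.frombuffer(canonical(seq).encode(), dtype=np.uint8)
        for name, seq in mrnas.items()
    }
    for mname in sorted(mirnas):
        m = canonical(mirnas[mname])
        L = len(m)
        comp = np.frombuffer(reverse_complement(m).encode(), dtype=np.uint8)
        # seed (miRNA positions 2-8, 1-based) sits at pattern indices L-8..L-2
        seed_idx = np.arange(max(L - 8, 0), L - 1)
        weights = np.where((comp == ord("G")) | (comp == ord("C")), 3, 2)
        for tname in sorted(encoded):
            s = encoded[tname]
            if len(s) < L:
                continue
            win = np.lib.stride_tricks.sliding_window_view(s, L)
            eq = win == comp
            gu = ((comp == ord("C")) & (win == ord("T"))) | (
                (comp == ord("A")) & (win == ord("G"))
            )
            mm = ~eq & ~gu
            ok = (
                (mm.sum(axis=1) <= max_mm)
                & (gu.sum(axis=1) <= max_gu)
                & (mm[:, seed_idx].sum(axis=1) == 0)
            )
            if not ok.any():
                continue
            scores = -(eq * weights).sum(axis=1) - gu.sum(axis=1) + mm.sum(axis=1)
            seed_perfect = mm[:, seed_idx].sum(axis=1) + gu[:, seed_idx].sum(axis=1) == 0
            cds = cds_annotation.get(tname) if cds_annotation else None
            for j in np.flatnonzero(ok):
                start, end = int(j) + 1, int(j) + L
                hits.append(
                    TargetHit(
                        mirna=mname,
                        mrna=tname,
                        start=start,
                        end=end,
                        region=_region_of(start, end, cds),
                        mismatches=int(mm[j].sum()),
                        gu_pairs=int(gu[j].sum()),
                        seed_perfect=bool(seed_perfect[j]),
                        duplex_score=int(scores[j]),
                    )
                )
    return hits


def hits_to_frame(hits: list[TargetHit]) -> pd.DataFrame:
    cols = [
        "mirna", "mrna", "start", "end", "region",
        "mismatches", "gu_pairs", "seed_perfect", "duplex_score",
    ]
    if not hits:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([h.__dict__ for h in hits])[cols]


def aggregate_targets(hits: list[TargetHit]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-miRNA, per-mRNA) summaries of targets, sites and partners."""
    df = hits_to_frame(hits)
    if df.empty:
        per_mirna = pd.DataFrame(columns=["n_targets", "n_sites"])
        per_mrna = pd.DataFrame(columns=["n_mirnas", "n_sites"])
        return per_mirna, per_mrna
    per_mirna = df.groupby("mirna").agg(
        n_targets=("mrna", "nunique"), n_sites=("mrna", "size")
    )
    per_mrna = df.groupby("mrna").agg(
        n_mirnas=("mirna", "nunique"), n_sites=("mirna", "size")
    )
    return per_mirna, per_mrna
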