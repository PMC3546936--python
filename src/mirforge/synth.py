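"""Synthetic small-RNA study generator.

Emulates the inputs of a pooled-tissue small-RNA sequencing experiment:
a reference genome with planted stem-loop miRNA precursors, adapter-ligated
size-selected reads sampled from the precursor arms with isomiR structure
(5'/3' end shifts, internal substitutions, 3' non-template tails), ncRNA
contaminant fragments, unmappable background reads, and stem-loop RT-PCR
Ct tables with planted tissue effects.  Every emitted read traces to
exactly one provenance record, so downstream stages can be scored against
ground truth.

Planted precursors are perfect inverted repeats: a stem of ``arm + 2``
base pairs around a short loop, which guarantees the 18-base-pair stem-loop
criterion and gives the mature:star duplex the canonical 2-nt 3' overhang
at both ends.  The base templated immediately 3' of each arm is fixed to G
so that a non-template tail drawn from the default A/U/C weights is always
recognisable as non-templated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import SmallRNARead
from .seq import canonical, reverse_complement

TISSUES = (
    "liver", "gill", "head_kidney", "spleen", "heart",
    "brain", "muscle", "stomach", "intestines", "skin",
)

# widely used small-RNA library 3' adapter
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults follow the simulated experiment used throughout the test
    suite: 8 planted precursors of which 3 are in the known catalogue
    (leaving 5 novel), 10% ncRNA contamination, 5% unmappable background,
    a 2% per-read substitution rate and a 10% 3'-tailing rate with A/U/C
    tail weights, and 16-30 nt size selection.
    """

    seed: int = 0
    n_precursors: int = 8
    n_conserved: int = 3
    n_est_precursors: int = 0
    n_chromosomes: int = 4
    genome_len: int = 60_000
    n_reads: int = 10_000
    adapter3: str = DEFAULT_ADAPTER3
    substitution_rate: float = 0.02
    nta_rate: float = 0.10
    nta_base_weights: dict[str, float] = field(
        default_factory=lambda: {"A": 0.6, "T": 0.3, "C": 0.1, "G": 0.0}
    )
    nta_len_probs: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    end_shift_probs: dict[int, float] = field(
        default_factory=lambda: {-2: 0.02, -1: 0.08, 0: 0.80, 1: 0.08, 2: 0.02}
    )
    ncrna_fraction: float = 0.10
    background_fraction: float = 0.05
    star_fraction: float = 0.15
    length_range: tuple[int, int] = (16, 30)
    copy_mean: float = 8.0
    arm_len_range: tuple[int, int] = (20, 23)
    loop_len_range: tuple[int, int] = (8, 12)
    tissues: tuple[str, ...] = TISSUES
    ct_noise_sd: float = 0.15
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "nta_rate", "ncrna_fraction",
                     "background_fraction", "star_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ncrna_fraction + self.background_fraction > 1.0:
            raise ValueError("contaminant + background fractions exceed 1")
        for name in ("nta_base_weights", "nta_len_probs", "end_shift_probs"):
            w = getattr(self, name)
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        lo, hi = self.length_range
        if not (16 <= lo <= hi <= 30):
            raise ValueError("length_range must lie within [16, 30]")
        if any(abs(k) > 2 for k in self.end_shift_probs):
            raise ValueError("end shifts limited to -2..+2")
        if not (0 <= self.n_conserved + 0 <= self.n_precursors):
            raise ValueError("n_conserved exceeds n_precursors")
        if self.n_est_precursors > self.n_precursors:
            raise ValueError("n_est_precursors exceeds n_precursors")

    def _rngs(self) -> list[np.random.Generator]:
        """Independent per-stage generators derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return [np.random.default_rng(c) for c in children]


@dataclass
class PlantedPrecursor:
    name: str
    sequence: str
    ref: str
    start: int  # 1-based position of the precursor on its reference
    strand: str
    mature_arm: str  # '5p' | '3p'
    mature_span: tuple[int, int]  # 0-based half-open, precursor coordinates
    star_span: tuple[int, int]
    conserved: bool
    context: str = ""  # precursor plus a few templated flank bases
    context_offset: int = 0  # precursor start within context

    @property
    def mature_seq(self) -> str:
        return self.sequence[self.mature_span[0] : self.mature_span[1]]

    @property
    def star_seq(self) -> str:
        return self.sequence[self.star_span[0] : self.star_span[1]]


@dataclass
class ReadEvent:
    """Provenance of one unique tag event (emitted ``count`` times)."""

    kind: str  # mature | star | ncrna | background
    count: int
    sequence: str
    precursor: str | None = None
    offset5: int = 0
    offset3: int = 0
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    nta: str = ""
    ncrna_class: str | None = None


@dataclass
class GroundTruth:
    precursors: list[PlantedPrecursor] = field(default_factory=list)
    ncrna: dict[str, str] = field(default_factory=dict)
    est_contigs: dict[str, str] = field(default_factory=dict)
    read_events: list[ReadEvent] = field(default_factory=list)
    ct_effects: "object | None" = None  # pandas DataFrame, miRNA x tissue ΔCt
    specific_mirna: str | None = None
    specific_tissue: str | None = None

    @property
    def novel_precursors(self) -> list[PlantedPrecursor]:
        return [p for p in self.precursors if not p.conserved]

    def catalogue(self) -> dict[str, str]:
        """Known mature catalogue: matures of the conserved precursors."""
        return {
            p.name.replace("mir", "miR"): p.mature_seq
            for p in self.precursors
            if p.conserved
        }

    def read_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for ev in self.read_events:
            totals[ev.kind] = totals.get(ev.kind, 0) + ev.count
        return totals


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _build_precursor(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, tuple, tuple]:
    """One planted hairpin precursor: (sequence, armA span, armB span).

    The stem is an inverted repeat with two G:U wobbles planted in the 3'
    arm: natural stems are imperfect, and the wobbles break the strand
    symmetry of a perfect palindrome (the arms would otherwise map to both
    genome strands and look like two loci).  G:U pairs still count as
    paired, so the >= 18-pair criterion is untouched.
    """
    L = int(rng.integers(cfg.arm_len_range[0], cfg.arm_len_range[1] + 1))
    loop_len = int(rng.integers(cfg.loop_len_range[0], cfg.loop_len_range[1] + 1))
    stem5 = _random_seq(rng, L + 2)
    loop = "G" + _random_seq(rng, loop_len - 1)
    pre = list(stem5 + loop + reverse_complement(stem5))
    n = len(pre)
    arm_a = (2, L + 2)  # 5' arm; templated continuation = loop[0] = G
    arm_b = (n - L, n)  # 3' arm; templated continuation = genomic flank (forced G)
    # wobble candidates: 3' arm positions (within both duplex windows) whose
    # 5'-arm partner is G or T, so the pair can become G:U by editing one base
    lo, hi = n - L + 4, n - 6
    cands = [j for j in range(lo, hi) if pre[n - 1 - j] in "GT"]
    picks = rng.choice(len(cands), size=min(2, len(cands)), replace=False) if cands else []
    for idx in sorted(int(i) for i in np.atleast_1d(picks)):
        j = cands[idx]
        pre[j] = "T" if pre[n - 1 - j] == "G" else "G"
    return "".join(pre), arm_a, arm_b


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Reference set with planted hairpin precursors plus ground truth.

    The genome is split into ``n_chromosomes`` contigs; ``n_est_precursors``
    of the precursors are planted on separate EST/GSS-style contigs held in
    ``truth.est_contigs`` instead of the genome.
    """
    n_genomic = config.n_precursors - config.n_est_precursors
    if n_genomic > 0 and config.genome_len < 10 * config.n_precursors * 150:
        raise ValueError("genome_len too small for the requested precursor count")
    rng = config._rngs()[0]
    chrom_len = max(config.genome_len // max(config.n_chromosomes, 1), 1)
    chroms = {
        f"chr{i + 1}": list(_random_seq(rng, chrom_len))
        for i in range(config.n_chromosomes)
    }
    truth = GroundTruth()

    flank = 6
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for idx in range(config.n_precursors):
        pre, arm_a, arm_b = _build_precursor(rng, config)
        mature_arm = "5p" if rng.random() < 0.5 else "3p"
        mature_span, star_span = (arm_a, arm_b) if mature_arm == "5p" else (arm_b, arm_a)
        name = f"syn-mir-{idx + 1}"
        on_est = idx >= n_genomic
        if on_est:
            left = _random_seq(rng, 30)
            right = _random_seq(rng, 30)
            contig = left + pre + "G" + right[1:]
            serial = int(rng.integers(10_000_000, 99_999_999))
            header = f"gi|{serial}|gb|SYN{idx + 1:04d}.1|SYN{idx + 1:04d}"
            truth.est_contigs[header] = contig
            ref, start0 = header, 30
            context = contig[start0 - flank : start0 + len(pre) + flank]
        else:
            chrom = f"chr{(idx % config.n_chromosomes) + 1}"
            seq = chroms[chrom]
            for _ in range(1000):
                pos = int(rng.integers(flank, len(seq) - len(pre) - flank))
                if all(not (pos < e + 150 and s - 150 < pos + len(pre)) for s, e in occupied[chrom]):
                    break
            else:  # pragma: no cover - genome_len precondition prevents this
                raise RuntimeError("could not place precursor without overlap")
            occupied[chrom].append((pos, pos + len(pre)))
            seq[pos : pos + len(pre)] = list(pre)
            seq[pos + len(pre)] = "G"  # non-template continuation of the 3' arm
            ref, start0 = chrom, pos
            context = "".join(seq[pos - flank : pos + len(pre) + flank])
        truth.precursors.append(
            PlantedPrecursor(
                name=name,
                sequence=pre,
                ref=ref,
                start=start0 + 1,
                strand="+",
                mature_arm=mature_arm,
                mature_span=mature_span,
                star_span=star_span,
                conserved=idx < config.n_conserved,
                context=context,
                context_offset=flank,
            )
        )

    genome = {name: "".join(seq) for name, seq in chroms.items()}
    truth.ncrna = _make_ncrna_reference(rng)
    return genome, truth


def _make_ncrna_reference(rng: np.random.Generator) -> dict[str, str]:
    """Labelled contaminant reference, including the 5S rRNA normaliser."""
    specs = [
        ("5S_rRNA|rRNA", 120),
        ("28S_rRNA_frag|rRNA", 300),
        ("tRNA-Ala|tRNA", 76),
        ("tRNA-Gly|tRNA", 76),
        ("U6|snRNA", 106),
        ("SNORD-like|snoRNA", 130),
    ]
    return {header: _random_seq(rng, n) for header, n in specs}


def _sample_discrete(rng: np.random.Generator, probs: dict) -> object:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def simulate_reads(
    genome: dict[str, str],
    truth: GroundTruth,
    config: SimConfig,
) -> list[SmallRNARead]:
    """Adapter-ligated reads with per-read isomiR edits and contaminants.

    Unique tag events are drawn until their geometric copy counts sum to
    ``n_reads``; each event is appended to ``truth.read_events``.
    """
    if not genome and not truth.est_contigs:
        raise ValueError("cannot simulate reads from an empty genome")
    rng = config._rngs()[1]
    precursors = truth.precursors
    weights = None
    if precursors:
        w = 1.0 / (1 + np.arange(len(precursors)))
        weights = w / w.sum()
    ncrna = list(truth.ncrna.items())
    lo, hi = config.length_range
    total = 0
    events: list[ReadEvent] = []
    while total < config.n_reads:
        count = int(rng.geometric(1.0 / config.copy_mean))
        count = min(count, config.n_reads - total)
        u = rng.random()
        if u < config.ncrna_fraction and ncrna:
            header, seq = ncrna[int(rng.integers(len(ncrna)))]
            frag_len = int(rng.integers(lo, min(hi, len(seq)) + 1))
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            events.append(
                ReadEvent(
                    kind="ncrna",
                    count=count,
                    sequence=seq[start : start + frag_len],
                    ncrna_class=header.rsplit("|", 1)[1],
                )
            )
        elif u < config.ncrna_fraction + config.background_fraction or not precursors:
            events.append(
                ReadEvent(
                    kind="background",
                    count=count,
                    sequence=_random_seq(rng, int(rng.integers(lo, hi + 1))),
                )
            )
        else:
            pre = precursors[int(rng.choice(len(precursors), p=weights))]
            is_star = rng.random() < config.star_fraction
            span = pre.star_span if is_star else pre.mature_span
            off5 = int(_sample_discrete(rng, config.end_shift_probs))
            off3 = int(_sample_discrete(rng, config.end_shift_probs))
            nta = ""
            if rng.random() < config.nta_rate:
                off3 = 0  # a tail replaces any templated 3' extension
                tail_len = int(_sample_discrete(rng, config.nta_len_probs))
                bases = sorted(config.nta_base_weights)
                p = np.array([config.nta_base_weights[b] for b in bases])
                nta = "".join(
                    bases[int(rng.choice(len(bases), p=p / p.sum()))]
                    for _ in range(tail_len)
                )
            cs = pre.context_offset + span[0] + off5
            ce = pre.context_offset + span[1] + off3
            core = list(pre.context[cs:ce])
            subs: list[tuple[int, str, str]] = []
            if rng.random() < config.substitution_rate and len(core) >= 6:
                pos = int(rng.integers(2, len(core) - 2))
                alt = str(rng.choice([b for b in "ACGT" if b != core[pos]]))
                subs.append((pos, core[pos], alt))
                core[pos] = alt
            events.append(
                ReadEvent(
                    kind="star" if is_star else "mature",
                    count=count,
                    sequence="".join(core) + nta,
                    precursor=pre.name,
                    offset5=off5,
                    offset3=off3,
                    substitutions=subs,
                    nta=nta,
                )
            )
        total += count
    truth.read_events.extend(events)

    reads: list[SmallRNARead] = []
    serial = 0
    adapter = canonical(config.adapter3)
    for ev in events:
        for _ in range(ev.count):
            serial += 1
            reads.append(SmallRNARead(id=f"read{serial}", sequence=ev.sequence + adapter))
    return reads


def simulate_ct_table(
    mirnas: list[str],
    tissues: list[str] | tuple[str, ...],
    config: SimConfig,
    specific_mirna: str | None = None,
    specific_tissue: str = "stomach",
):
    """Triplicate Ct table (long format) with planted ΔCt tissue effects.

    Returns ``(ct_df, delta_ct_df)`` where ``delta_ct_df`` is the planted
    miRNA x tissue ΔCt matrix (Ct_miRNA - Ct_5S, noise-free truth).  The
    designated ``specific_mirna`` (default: the first in the list) is given
    a strongly tissue-specific profile centred on ``specific_tissue``.
    """
    import pandas as pd

    if not mirnas or not tissues:
        raise ValueError("need at least one miRNA and one tissue")
    tissues = list(tissues)
    rng = config._rngs()[2]
    if specific_mirna is None:
        specific_mirna = mirnas[0]
    if specific_tissue not in tissues:
        specific_tissue = tissues[0]
    base = rng.uniform(3.0, 9.0, size=len(mirnas))
    delta = base[:, None] + rng.normal(0.0, 0.75, size=(len(mirnas), len(tissues)))
    dct = pd.DataFrame(delta, index=list(mirnas), columns=tissues)
    dct.loc[specific_mirna, :] = base[mirnas.index(specific_mirna)] + 5.0
    dct.loc[specific_mirna, specific_tissue] = base[mirnas.index(specific_mirna)] - 2.0

    ct5s = {t: 15.0 + rng.normal(0.0, 0.5) for t in tissues}
    rows = []
    for t in tissues:
        for rep in range(1, config.n_replicates + 1):
            noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
            rows.append(("5S_rRNA", t, rep, ct5s[t] + noise))
    for m in mirnas:
        for t in tissues:
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                rows.append((m, t, rep, ct5s[t] + dct.loc[m, t] + noise))
    ct = pd.DataFrame(rows, columns=["mirna", "tissue", "replicate", "ct"])
    return ct, dct


def simulate_all(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Run all generator stages and write every pipeline input to *outdir*.

    Files: genome.fa, est_gss.fa (when EST precursors are requested),
    precursors.fa, matures.fa (known catalogue), ncrna.fa, reads.fastq,
    ct_table.tsv, truth.json.
    """
    from . import io as mio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(config)
    reads = simulate_reads(genome, truth, config)

    novel_names = [p.name.replace("mir", "miR") for p in truth.novel_precursors]
    ct_names = novel_names or [p.name.replace("mir", "miR") for p in truth.precursors]
    if ct_names:
        ct, dct = simulate_ct_table(ct_names, config.tissues, config)
        truth.ct_effects = dct
        truth.specific_mirna = ct_names[0]
        truth.specific_tissue = (
            "stomach" if "stomach" in config.tissues else config.tissues[0]
        )
        ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)

    mio.write_fasta(genome, out / "genome.fa")
    if truth.est_contigs:
        mio.write_fasta(truth.est_contigs, out / "est_gss.fa")
    mio.write_fasta({p.name: p.sequence for p in truth.precursors}, out / "precursors.fa")
    mio.write_fasta(truth.catalogue(), out / "matures.fa")
    mio.write_fasta(truth.ncrna, out / "ncrna.fa")
    mio.write_fastq(reads, out / "reads.fastq")
    with open(out / "truth.json", "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1)
    return truth


def _truth_to_json(truth: GroundTruth) -> dict:
    d = {
        "precursors": [
            {k: v for k, v in dataclasses.asdict(p).items()}
            for p in truth.precursors
        ],
        "read_events": [dataclasses.asdict(ev) for ev in truth.read_events],
        "specific_mirna": truth.specific_mirna,
        "specific_tissue": truth.specific_tissue,
    }
    if truth.ct_effects is not None:
        d["ct_effects"] = {
            m: dict(row) for m, row in truth.ct_effects.iterrows()
        }
    return d
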