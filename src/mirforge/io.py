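"""FASTA/FASTQ reading and writing (thin wrappers over Biopython SeqIO).

Collapsed unique tags use the conventional ``>tag{serial}_x{count}`` header
so copy counts survive a round trip through FASTA.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import SmallRNARead, UniqueTag

_COUNT_RE = re.compile(r"_x(\d+)$")


def read_fastq(path: str | Path) -> list[SmallRNARead]:
    with open(path) as handle:
        return [
            SmallRNARead(
                id=rec.id,
                sequence=str(rec.seq),
                quality=rec.letter_annotations.get("phred_quality"),
            )
            for rec in SeqIO.parse(handle, "fastq")
        ]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Reference FASTA as an ordered ``{id: sequence}`` mapping."""
    out: dict[str, str] = {}
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            out[rec.description.strip()] = str(rec.seq)
    return out


def read_reads_fasta(path: str | Path) -> list[SmallRNARead]:
    """FASTA reads, one record per read (use :func:`read_tags_fasta` for
    collapsed ``_x{count}`` tag files)."""
    with open(path) as handle:
        return [
            SmallRNARead(id=rec.id, sequence=str(rec.seq), quality=None)
            for rec in SeqIO.parse(handle, "fasta")
        ]


def read_tags_fasta(path: str | Path) -> list[UniqueTag]:
    tags = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            m = _COUNT_RE.search(rec.id)
            count = int(m.group(1)) if m else 1
            tags.append(UniqueTag(sequence=str(rec.seq).upper().replace("U", "T"), count=count))
    return tags


def write_tags_fasta(tags: Iterable[UniqueTag], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=f"tag{i + 1}_x{t.count}", description="")
        for i, t in enumerate(tags)
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name.split()[0], description=name) for name, s in seqs.items()]
    # avoid duplicated id/description when the name is a single token
    for rec in records:
        if rec.description == rec.id:
            rec.description = ""
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def write_fastq(reads: Iterable[SmallRNARead], path: str | Path, default_qual: int = 40) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = (
            list(r.quality) if r.quality is not None else [default_qual] * len(r.sequence)
        )
        records.append(rec)
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fastq")
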