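"""Published channel-catfish small-RNA study numbers shipped with the package.

The original sequencing dataset was never deposited, but the article prints
its read accounting and the full novel-miRNA tables; those tables are
bundled here as plain TSV/JSON so the arithmetic and coordinate formats
they imply can be checked against this implementation.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .mapping import GenomeLocus


def _data_path(name: str):
    return resources.files("mirforge").joinpath("data", name)


def published_counts() -> dict:
    """Printed dataset-level counts (raw/clean/removed/mapped reads etc.)."""
    with _data_path("published_counts.json").open() as fh:
        return json.load(fh)


def retained_reads(counts: dict | None = None) -> int:
    """Reads retained for miRNA analysis: clean minus annotated ncRNA."""
    c = counts or published_counts()
    return c["clean_reads"] - c["ncrna_reads_removed"]


def novel_mirna_table(source: str) -> pd.DataFrame:
    """Published novel-miRNA table; ``source`` is 'genome' or 'estgss'.

    Columns: mirna, sequence, read_count, locus (a parsed
    :class:`~mirforge.mapping.GenomeLocus` object).
    """
    fname = {"genome": "novel_mirnas_genome.tsv", "estgss": "novel_mirnas_estgss.tsv"}[source]
    with _data_path(fname).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["locus"] = df["locus"].map(GenomeLocus.parse)
    return df


def novel_mirna_counts() -> dict[str, int]:
    genome = novel_mirna_table("genome")
    estgss = novel_mirna_table("estgss")
    return {
        "genome": len(genome),
        "estgss": len(estgss),
        "total": len(genome) + len(estgss),
        "max_read_count_estgss": int(estgss["read_count"].max()),
    }
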