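"""End-to-end orchestration of the small-RNA analysis stages.

``run_all`` executes simulate (optional) -> preprocess -> ncRNA annotation
-> genome mapping -> miRNA calling -> isomiR/star characterization ->
expression profiling (when a Ct table is given) -> target prediction (when
mRNAs are given), and assembles a single read-accounting report in the
order raw -> unique -> clean -> ncRNA-removed -> retained -> mapped ->
conserved/novel.  All randomness flows from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import discover, expression, io as mio, isomir, ncrna, preprocess, synth, targets
from .mapping import map_tags
from .preprocess import UniqueTag

log = logging.getLogger("mirforge")


@dataclass
class PipelineConfig:
    outdir: str = "mirforge_out"
    seed: int = 0
    # inputs; any of these may be produced by the simulate stage instead
    reads_fastq: str | None = None
    genome_fasta: str | None = None
    est_gss_fasta: str | None = None
    matures_fasta: str | None = None
    ncrna_fasta: str | None = None
    ct_table: str | None = None
    mrna_fasta: str | None = None
    simulate: bool = True
    sim: synth.SimConfig | None = None
    # stage parameters
    adapter3: str | None = synth.DEFAULT_ADAPTER3
    min_len: int = 15
    max_len: int = 26
    min_copies: int = 2
    ncrna_max_mismatch: int = 1
    map_params: dict = field(default_factory=dict)
    fold_params: dict = field(default_factory=dict)
    conserved_max_mm: int = 1
    target_params: dict = field(default_factory=dict)
    specificity_threshold: float = 0.5


@dataclass
class PipelineResult:
    accounting: pd.DataFrame
    tags: list[UniqueTag]
    retained: list[UniqueTag]
    conserved_calls: list
    novel_calls: list
    isomir_records: dict
    cleavage_profiles: dict
    duplex_pairs: list
    expression_matrix: pd.DataFrame | None
    specificity: pd.DataFrame | None
    target_hits: list
    truth: synth.GroundTruth | None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: PipelineConfig) -> PipelineResult:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = None

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(name, exc) from exc

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim = config.sim or synth.SimConfig(seed=config.seed)
        truth = stage("simulate", synth.simulate_all, sim, out / "sim")
        sim_dir = out / "sim"
        reads = mio.read_fastq(sim_dir / "reads.fastq")
        genome = mio.read_fasta(sim_dir / "genome.fa")
        est_gss = mio.read_fasta(sim_dir / "est_gss.fa") if truth.est_contigs else {}
        matures = mio.read_fasta(sim_dir / "matures.fa")
        ncrna_ref = mio.read_fasta(sim_dir / "ncrna.fa")
        ct_path = sim_dir / "ct_table.tsv"
        ct = expression.load_ct_table(ct_path) if ct_path.exists() else None
        mrnas = mio.read_fasta(config.mrna_fasta) if config.mrna_fasta else {}
        adapter = sim.adapter3
    else:
        if not config.reads_fastq or not config.genome_fasta:
            raise ValueError("reads_fastq and genome_fasta are required when not simulating")
        reads = mio.read_fastq(config.reads_fastq)
        genome = mio.read_fasta(config.genome_fasta)
        est_gss = mio.read_fasta(config.est_gss_fasta) if config.est_gss_fasta else {}
        matures = mio.read_fasta(config.matures_fasta) if config.matures_fasta else {}
        ncrna_ref = mio.read_fasta(config.ncrna_fasta) if config.ncrna_fasta else {}
        ct = expression.load_ct_table(config.ct_table) if config.ct_table else None
        mrnas = mio.read_fasta(config.mrna_fasta) if config.mrna_fasta else {}
        adapter = config.adapter3
    if not reads:
        raise StageError("preprocess", ValueError("empty read file"))

    # --- preprocess -------------------------------------------------------
    tags, acct = stage(
        "preprocess",
        preprocess.preprocess_reads,
        reads,
        adapter3=adapter,
        min_len=config.min_len,
        max_len=config.max_len,
        min_copies=config.min_copies,
    )
    mio.write_tags_fasta(tags, out / "tags.fa")

    # --- ncRNA annotation -------------------------------------------------
    if ncrna_ref:
        removed, retained, class_counts = stage(
            "annotate", ncrna.annotate_ncrna, tags, ncrna_ref, config.ncrna_max_mismatch
        )
    else:
        removed, retained, class_counts = [], list(tags), {}
    ncrna_reads = sum(h.tag.count for h in removed)

    # --- mapping ----------------------------------------------------------
    mapped, unmapped = stage("map", map_tags, retained, genome, **config.map_params)
    if est_gss:
        est_mapped, _ = stage("map_est", map_tags, unmapped, est_gss, **config.map_params)
    else:
        est_mapped = []
    mapped_tags = {mt.tag.sequence: mt for mt in mapped + est_mapped}
    mapped_reads = sum(mt.tag.count for mt in mapped_tags.values())

    # --- miRNA calling ----------------------------------------------------
    if matures:
        conserved_calls, leftover = stage(
            "call_conserved", discover.call_conserved, retained, matures, config.conserved_max_mm
        )
    else:
        conserved_calls, leftover = [], list(retained)
    leftover_mapped = [t for t in leftover if t.sequence in mapped_tags]
    novel_calls = stage(
        "call_novel",
        discover.call_novel,
        leftover_mapped,
        genome,
        est_gss or None,
        matures or None,
        config.map_params,
        config.fold_params,
    )

    # --- isomiR / star ----------------------------------------------------
    isomir_records: dict[str, list] = {}
    cleavage_profiles: dict[str, isomir.CleavageProfile] = {}
    duplex_pairs: list[isomir.DuplexPair] = []
    for call in novel_calls:
        cand = call.precursor
        span = cand.mature_span
        arm_tags = _position_tags(call.member_tags, cand.sequence, span)
        near_mature = [t for t, s in arm_tags if abs(s - span[0]) <= 5]
        recs = stage(
            "isomir",
            isomir.classify_isomirs,
            near_mature,
            call.name,
            span,
            cand.sequence,
        )
        if recs:
            isomir_records[call.name] = recs
            cleavage_profiles[call.name] = isomir.infer_cleavage_sites(recs)
        pair = isomir.detect_star(
            cand.sequence, cand.structure, span, arm_tags, precursor_name=call.name
        )
        if pair is not None:
            duplex_pairs.append(pair)

    # --- expression -------------------------------------------------------
    matrix = specificity = None
    if ct is not None:
        matrix = stage("express", expression.relative_expression, ct)
        specificity = expression.tissue_specificity(matrix, config.specificity_threshold)
        matrix.to_csv(out / "expression_matrix.tsv", sep="\t")
        if matrix.shape[0] >= 2 and matrix.shape[1] >= 2:
            for axis in ("mirna", "tissue"):
                _, _, newick = expression.hierarchical_cluster(matrix, axis=axis)
                (out / f"dendrogram_{axis}.nwk").write_text(newick + "\n")

    # --- targets ----------------------------------------------------------
    target_hits = []
    if mrnas:
        mirna_seqs = {c.name: c.sequence for c in novel_calls}
        if mirna_seqs:
            target_hits = stage(
                "targets", targets.antisense_search, mirna_seqs, mrnas, **config.target_params
            )
            targets.hits_to_frame(target_hits).to_csv(out / "target_hits.tsv", sep="\t", index=False)

    # --- accounting report ------------------------------------------------
    accounting = pd.DataFrame(
        [
            ("raw_reads", acct.raw),
            ("unique_tags", len(tags)),
            ("clean_reads", acct.clean),
            ("adapter_unmatched_reads", acct.adapter_trimmed),
            ("ambiguous_base_reads", acct.n_discarded),
            ("length_filtered_reads", acct.length_filtered),
            ("low_copy_reads", acct.low_copy_removed),
            ("ncrna_reads_removed", ncrna_reads),
            ("retained_reads", acct.clean - ncrna_reads),
            ("mapped_reads", mapped_reads),
            ("mapped_unique_tags", len(mapped_tags)),
            ("conserved_mirnas", len(conserved_calls)),
            ("novel_mirnas", len(novel_calls)),
        ],
        columns=["category", "count"],
    )
    accounting.to_csv(out / "accounting.tsv", sep="\t", index=False)
    _write_calls(conserved_calls + novel_calls, out / "mirna_calls.tsv")

    return PipelineResult(
        accounting=accounting,
        tags=tags,
        retained=retained,
        conserved_calls=conserved_calls,
        novel_calls=novel_calls,
        isomir_records=isomir_records,
        cleavage_profiles=cleavage_profiles,
        duplex_pairs=duplex_pairs,
        expression_matrix=matrix,
        specificity=specificity,
        target_hits=target_hits,
        truth=truth,
    )


def _position_tags(tags: list[UniqueTag], precursor: str, mature_span: tuple[int, int]):
    """Best ungapped position of each tag on the precursor (<=2 mismatches)."""
    placed = []
    for tag in tags:
        seq = tag.sequence
        L = len(seq)
        best = None
        for s in range(0, len(precursor) - L + 1):
            mm = sum(1 for a, b in zip(seq, precursor[s : s + L]) if a != b)
            if best is None or mm < best[0]:
                best = (mm, s)
        if best is not None and best[0] <= 2:
            placed.append((tag, best[1]))
    return placed


def _write_calls(calls: list, path: Path) -> None:
    rows = [
        {
            "name": c.name,
            "sequence": c.sequence,
            "count": c.count,
            "status": c.status,
            "family": c.family or "",
            "locus": str(c.locus) if c.locus else "",
            "source": c.source or "",
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["name", "sequence", "count", "status", "family", "locus", "source"]).to_csv(
        path, sep="\t", index=False
    )
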