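import pytest

from mirforge.pipeline import PipelineConfig, run_all
from mirforge.synth import SimConfig


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One end-to-end run on the default synthetic study (seed 1)."""
    out = tmp_path_factory.mktemp("e2e")
    config = PipelineConfig(outdir=str(out), seed=1)
    result = run_all(config)
    return config, result


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study shared by stage-level tests (seed 7)."""
    from mirforge import synth

    cfg = SimConfig(seed=7, n_precursors=2, n_conserved=1, n_chromosomes=2,
                    genome_len=10_000, n_reads=1_500)
    genome, truth = synth.simulate_genome(cfg)
    reads = synth.simulate_reads(genome, truth, cfg)
    return cfg, genome, truth, reads
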