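import json

import pytest

from mirforge import fold, synth
from mirforge.seq import reverse_complement

from .oracles import structure_is_valid


def test_config_validation():
    with pytest.raises(ValueError):
        synth.SimConfig(substitution_rate=1.5)
    with pytest.raises(ValueError):
        synth.SimConfig(ncrna_fraction=0.7, background_fraction=0.5)
    with pytest.raises(ValueError):
        synth.SimConfig(nta_base_weights={"A": 0.5, "T": 0.2})
    with pytest.raises(ValueError):
        synth.SimConfig(length_range=(10, 26))
    with pytest.raises(ValueError):
        synth.SimConfig(end_shift_probs={-3: 0.5, 0: 0.5})
    with pytest.raises(ValueError):
        synth.SimConfig(n_precursors=2, n_conserved=3)
    with pytest.raises(ValueError):
        synth.simulate_genome(synth.SimConfig(genome_len=500))


def test_genome_determinism():
    g1, t1 = synth.simulate_genome(synth.SimConfig(seed=5))
    g2, t2 = synth.simulate_genome(synth.SimConfig(seed=5))
    assert g1 == g2
    assert [p.sequence for p in t1.precursors] == [p.sequence for p in t2.precursors]
    g3, _ = synth.simulate_genome(synth.SimConfig(seed=6))
    assert g1 != g3


def test_planted_precursors_fold_and_sit_in_genome(small_sim):
    cfg, genome, truth, _ = small_sim
    assert len(truth.precursors) == cfg.n_precursors
    for p in truth.precursors:
        # the precursor really is at its recorded locus
        assert genome[p.ref][p.start - 1 : p.start - 1 + len(p.sequence)] == p.sequence
        structure, pairs = fold.max_pair_structure(p.sequence)
        assert pairs >= 18
        assert structure_is_valid(p.sequence, structure)
        # mature and star on opposite arms, non-overlapping
        ms, me = p.mature_span
        ss, se = p.star_span
        assert me <= ss or se <= ms
        # the base templated 3' of each arm is G, so A/U/C tails are
        # always recognisably non-templated
        ctx = p.context
        off = p.context_offset
        assert ctx[off + me] == "G" and ctx[off + se] == "G"


def test_planted_stems_are_not_perfect_palindromes(small_sim):
    # the G:U wobbles must break the inverted-repeat symmetry, otherwise
    # every arm also occurs exactly on the minus strand of its own hairpin
    # and maps as two apparent loci
    _, _, truth, _ = small_sim
    for p in truth.precursors:
        rc_pre = reverse_complement(p.sequence)
        assert p.mature_seq not in rc_pre
        assert p.star_seq not in rc_pre


def test_catalogue_holds_conserved_matures(small_sim):
    _, _, truth, _ = small_sim
    cat = truth.catalogue()
    assert len(cat) == 1
    (name, seq), = cat.items()
    assert "miR" in name
    assert seq == truth.precursors[0].mature_seq


def test_reads_total_and_adapter(small_sim):
    cfg, _, truth, reads = small_sim
    assert len(reads) == cfg.n_reads
    assert all(r.sequence.endswith(cfg.adapter3) for r in reads)
    assert sum(ev.count for ev in truth.read_events) == cfg.n_reads


def test_read_events_reconstruct_reads(small_sim):
    cfg, _, truth, reads = small_sim
    by_seq = {}
    for r in reads:
        insert = r.sequence[: -len(cfg.adapter3)]
        by_seq[insert] = by_seq.get(insert, 0) + 1
    for ev in truth.read_events:
        assert by_seq.get(ev.sequence, 0) >= ev.count


def test_nta_events_suppress_templated_extension(small_sim):
    _, _, truth, _ = small_sim
    nta_events = [ev for ev in truth.read_events if ev.nta]
    assert nta_events, "default 10% tailing rate must produce tails"
    assert all(ev.offset3 == 0 for ev in nta_events)
    assert all(set(ev.nta) <= set("ATC") for ev in nta_events)


def test_ncrna_events_carry_class(small_sim):
    _, _, truth, _ = small_sim
    nc = [ev for ev in truth.read_events if ev.kind == "ncrna"]
    assert nc and all(ev.ncrna_class for ev in nc)


def test_ct_table_planted_effect():
    cfg = synth.SimConfig(seed=2, ct_noise_sd=0.0)
    names = ["syn-miR-1", "syn-miR-2", "syn-miR-3"]
    ct, dct = synth.simulate_ct_table(names, synth.TISSUES, cfg)
    assert set(ct["mirna"]) == set(names) | {"5S_rRNA"}
    assert dct.loc["syn-miR-1", "stomach"] == dct.loc["syn-miR-1"].min()
    # the planted contrast is exactly -7 vs the non-specific tissues
    others = [t for t in synth.TISSUES if t != "stomach"]
    assert dct.loc["syn-miR-1", others].max() - dct.loc["syn-miR-1", "stomach"] == pytest.approx(7.0)


def test_est_precursors_live_on_contigs():
    cfg = synth.SimConfig(seed=3, n_precursors=3, n_conserved=0, n_est_precursors=1,
                          genome_len=20_000, n_reads=500)
    genome, truth = synth.simulate_genome(cfg)
    est = [p for p in truth.precursors if p.ref in truth.est_contigs]
    assert len(est) == 1
    p = est[0]
    assert truth.est_contigs[p.ref][p.start - 1 : p.start - 1 + len(p.sequence)] == p.sequence
    assert "gb|" in p.ref


def test_simulate_all_writes_inputs(tmp_path):
    cfg = synth.SimConfig(seed=4, n_precursors=2, n_conserved=1,
                          genome_len=10_000, n_reads=400)
    truth = synth.simulate_all(cfg, tmp_path)
    for name in ("genome.fa", "precursors.fa", "matures.fa", "ncrna.fa",
                 "reads.fastq", "ct_table.tsv", "truth.json"):
        assert (tmp_path / name).exists(), name
    payload = json.loads((tmp_path / "truth.json").read_text())
    assert len(payload["precursors"]) == 2
    assert payload["specific_mirna"] == "syn-miR-2"  # first novel precursor


def test_empty_genome_read_simulation_raises():
    cfg = synth.SimConfig(seed=1)
    with pytest.raises(ValueError):
        synth.simulate_reads({}, synth.GroundTruth(), cfg)
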