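import numpy as np
import pytest

from mirforge import fold, isomir
from mirforge.preprocess import UniqueTag
from mirforge.seq import reverse_complement

# hand-built precursor context: 6-nt flank + 22-nt mature + downstream.
# The base after the mature is G so that A/U/C tails are non-templated.
FLANK5 = "TTAGCA"
MATURE = "TGGCTCAGTTCAGCAGGAACAG"
AFTER = "GTCCGAGGTT"
CONTEXT = FLANK5 + MATURE + AFTER
SPAN = (0, len(MATURE))  # precursor coordinates; context_offset = len(FLANK5)


def classify(seqs_counts, **kw):
    tags = [UniqueTag(s, c) for s, c in seqs_counts]
    return isomir.classify_isomirs(tags, "mir-x", SPAN, CONTEXT, context_offset=len(FLANK5), **kw)


def test_canonical_tag():
    (rec,) = classify([(MATURE, 10)])
    assert rec.category == "canonical"
    assert rec.offset5 == 0 and rec.offset3 == 0
    assert not rec.substitutions and not rec.nta_tail


def test_five_prime_shift():
    (rec,) = classify([(MATURE[2:], 4)])
    assert rec.category == "shift"
    assert rec.offset5 == 2 and rec.offset3 == 0


def test_templated_three_prime_extension_is_a_shift_not_a_tail():
    (rec,) = classify([(MATURE + AFTER[:2], 4)])
    assert rec.category == "shift"
    assert rec.offset3 == 2 and not rec.nta_tail


def test_nta_tail():
    (rec,) = classify([(MATURE + "A", 6)])
    assert rec.category == "NTA"
    assert rec.nta_tail == "A" and rec.offset3 == 0


def test_trailing_mismatch_followed_by_matches_is_a_substitution():
    seq = list(MATURE)
    seq[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[10]]
    (rec,) = classify([("".join(seq), 3)])
    assert rec.category == "substitution"
    assert rec.substitutions == [(10, MATURE[10], "".join(seq)[10])]


def test_mixed_category():
    # 5' shift plus a 2-nt tail; the templated continuation is "GT", so an
    # "AA" tail mismatches it at both positions
    (rec,) = classify([(MATURE[1:] + "AA", 2)])
    assert rec.category == "mixed"
    assert rec.offset5 == 1 and rec.nta_tail == "AA"


def test_unalignable_tag_warns_and_is_skipped():
    with pytest.warns(UserWarning, match="not alignable"):
        recs = classify([("ACACACACACACACACACACAC", 1)])
    assert recs == []


def test_reconstruct_round_trip():
    rng = np.random.default_rng(8)
    seqs = [
        MATURE,
        MATURE[2:],
        MATURE + "A",
        MATURE[:21] + "T" + "AC",
        MATURE[1:] + AFTER[0],
    ]
    recs = classify([(s, 1) for s in seqs])
    assert len(recs) == len(seqs)
    for rec, s in zip(recs, seqs):
        assert isomir.reconstruct(rec, SPAN, CONTEXT, len(FLANK5)) == s


def test_substitution_spectrum_weighting():
    seq_ac = list(MATURE)
    assert MATURE[3] == "C"
    seq_ac[3] = "A"  # C-to-A
    seq_cu = list(MATURE)
    assert MATURE[5] == "C"
    seq_cu[5] = "T"  # C-to-U
    recs = classify([("".join(seq_ac), 3), ("".join(seq_cu), 1)])
    by_reads = isomir.substitution_spectrum(recs, weight="reads")
    assert by_reads["C-to-A"] == pytest.approx(0.75)
    assert by_reads["C-to-U"] == pytest.approx(0.25)
    by_tags = isomir.substitution_spectrum(recs, weight="tags")
    assert by_tags["C-to-A"] == pytest.approx(0.5)
    assert sum(by_reads.values()) == pytest.approx(1.0)
    assert set(by_reads) == set(isomir.SUBSTITUTION_CLASSES)


def test_nta_base_counts_rna_alphabet():
    recs = classify([(MATURE + "A", 5), (MATURE + "T", 2), (MATURE + "C", 1)])
    assert isomir.nta_base_counts(recs) == {"A": 5, "C": 1, "U": 2}


def test_cleavage_sites_read_weighted_mode_with_tie_toward_zero():
    recs = classify([(MATURE, 5), (MATURE[1:], 5), (MATURE[2:], 3)])
    prof = isomir.infer_cleavage_sites(recs)
    assert prof.dominant5 == 0  # tie 5:5 breaks toward the reference end
    assert prof.dominant3 == 0
    assert prof.sites5 == {0: 5, 1: 5, 2: 3}
    with pytest.raises(ValueError):
        isomir.infer_cleavage_sites([])


def make_duplex_precursor():
    # stem of 24 pairs around an 8-nt loop; mature = 5' arm positions 2..24,
    # star = 3' arm, giving canonical 2-nt 3' overhangs at both duplex ends
    rng = np.random.default_rng(4)
    stem = "".join(rng.choice(list("ACGT"), 24))
    pre = stem + "GAATTCAA" + reverse_complement(stem)
    mature_span = (2, 24)
    star_span = (len(pre) - 22, len(pre))
    return pre, mature_span, star_span


def test_detect_star_canonical_overhangs():
    pre, mspan, sspan = make_duplex_precursor()
    structure, _ = fold.max_pair_structure(pre)
    mature = pre[mspan[0] : mspan[1]]
    star = pre[sspan[0] : sspan[1]]
    arm_tags = [(UniqueTag(mature, 30), mspan[0]), (UniqueTag(star, 6), sspan[0])]
    pair = isomir.detect_star(pre, structure, mspan, arm_tags, precursor_name="mir-y")
    assert pair is not None
    assert pair.overhang_mature3 == 2 and pair.overhang_star3 == 2
    assert pair.star_seq == star and pair.mature_count == 30 and pair.star_count == 6
    assert not pair.star_dominant
    assert pair.ratio == pytest.approx(0.2)


def test_detect_star_flags_star_dominance():
    pre, mspan, sspan = make_duplex_precursor()
    structure, _ = fold.max_pair_structure(pre)
    arm_tags = [
        (UniqueTag(pre[mspan[0] : mspan[1]], 5), mspan[0]),
        (UniqueTag(pre[sspan[0] : sspan[1]], 40), sspan[0]),
    ]
    pair = isomir.detect_star(pre, structure, mspan, arm_tags)
    assert pair is not None and pair.star_dominant


def test_detect_star_requires_opposite_arm_reads():
    pre, mspan, _ = make_duplex_precursor()
    structure, _ = fold.max_pair_structure(pre)
    arm_tags = [(UniqueTag(pre[mspan[0] : mspan[1]], 30), mspan[0])]
    assert isomir.detect_star(pre, structure, mspan, arm_tags) is None


def test_detect_star_rejects_bad_geometry():
    pre, mspan, sspan = make_duplex_precursor()
    structure, _ = fold.max_pair_structure(pre)
    # a loop-proximal fragment of the 3' arm breaks the 2-nt overhang rule
    bad_star = pre[sspan[0] - 8 : sspan[1] - 8]
    arm_tags = [
        (UniqueTag(pre[mspan[0] : mspan[1]], 30), mspan[0]),
        (UniqueTag(bad_star, 6), sspan[0] - 8),
    ]
    assert isomir.detect_star(pre, structure, mspan, arm_tags) is None


def test_seed_conservation_identical_sequences():
    seqs = [MATURE, MATURE, MATURE]
    out = isomir.seed_conservation(seqs)
    assert out["mature_seed_identity"] == pytest.approx(1.0)
    assert all(v == 1.0 for v in out["mature_profile"])


def test_seed_conservation_hand_case():
    ref = "TGGCTCAGTTCAGCAGGAACAG"
    var = list(ref)
    var[0] = "A"  # outside the seed (position 1)
    var[3] = "A"  # inside the seed (positions 2-8)
    out = isomir.seed_conservation([ref, "".join(var)])
    assert out["mature_seed_identity"] == pytest.approx(6 / 7)
    assert out["mature_profile"][0] == 0.0
    with pytest.raises(ValueError):
        isomir.seed_conservation([ref])
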