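import numpy as np
import pytest

from mirforge import targets
from mirforge.seq import reverse_complement

from .oracles import exhaustive_antisense


def test_duplex_score_all_gc():
    mirna = "G" * 21
    site = reverse_complement(mirna)  # all C
    assert targets.duplex_score(mirna, site) == -63


def test_duplex_score_all_au():
    mirna = "A" * 21
    assert targets.duplex_score(mirna, reverse_complement(mirna)) == -42


def test_duplex_score_all_mismatch():
    # pattern all T against an all-C site: no pair and no wobble anywhere
    assert targets.duplex_score("A" * 21, "C" * 21) == 21


def test_duplex_score_wobble():
    # miRNA G over site T -> pattern C over T = G:U wobble, scores -1
    assert targets.duplex_score("G", "T") == -1
    with pytest.raises(ValueError):
        targets.duplex_score("ACG", "AC")


def mk_mirna(seed=0, n=21):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


def embed(site, seed=1, flank=60):
    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(list("ACGT"), flank))
    right = "".join(rng.choice(list("ACGT"), flank))
    return left + site + right, flank


def test_perfect_antisense_site_is_found():
    mirna = mk_mirna(2)
    mrna, flank = embed(reverse_complement(mirna), 3)
    hits = targets.antisense_search({"mir-a": mirna}, {"tx1": mrna})
    exact = [h for h in hits if h.start == flank + 1]
    assert exact
    h = exact[0]
    assert h.end == flank + len(mirna)
    assert h.mismatches == 0 and h.seed_perfect
    assert h.duplex_score == targets.duplex_score(mirna, mrna[flank : flank + len(mirna)])


def test_seed_mismatch_disqualifies_site():
    mirna = mk_mirna(4)
    site = list(reverse_complement(mirna))
    L = len(mirna)
    # miRNA position 5 (1-based, inside the 2-8 seed) = pattern index L-5
    idx = L - 5
    wobble_safe = {"A": "C", "C": "G", "G": "A", "T": "A"}  # never a G:U
    site[idx] = wobble_safe[site[idx]]
    mrna, flank = embed("".join(site), 5)
    hits = targets.antisense_search({"mir-a": mirna}, {"tx1": mrna})
    assert not [h for h in hits if h.start == flank + 1]


def test_non_seed_mismatch_is_tolerated_up_to_limit():
    mirna = mk_mirna(6)
    site = list(reverse_complement(mirna))
    wobble_safe = {"A": "C", "C": "G", "G": "A", "T": "A"}
    site[0] = wobble_safe[site[0]]  # miRNA 3' end, outside the seed
    mrna, flank = embed("".join(site), 7)
    hits = targets.antisense_search({"mir-a": mirna}, {"tx1": mrna})
    match = [h for h in hits if h.start == flank + 1]
    assert match and match[0].mismatches == 1

    site[1] = wobble_safe[site[1]]
    mrna2, flank2 = embed("".join(site), 8)
    hits2 = targets.antisense_search({"mir-a": mirna}, {"tx1": mrna2})
    assert not [h for h in hits2 if h.start == flank2 + 1]


def test_gu_wobble_in_seed_breaks_seed_perfect_but_not_the_hit():
    mirna = mk_mirna(9)
    site = list(reverse_complement(mirna))
    L = len(mirna)
    # find a seed position where a wobble is possible (pattern C->site T
    # or pattern A->site G)
    for idx in range(L - 8, L - 1):
        if site[idx] == "C":
            site[idx] = "T"
            break
        if site[idx] == "A":
            site[idx] = "G"
            break
    else:
        pytest.fail("no wobble-capable seed position in this pattern")
    mrna, flank = embed("".join(site), 10)
    hits = targets.antisense_search({"mir-a": mirna}, {"tx1": mrna})
    match = [h for h in hits if h.start == flank + 1]
    assert match
    assert match[0].gu_pairs == 1 and match[0].mismatches == 0
    assert not match[0].seed_perfect


def test_region_annotation():
    mirna = mk_mirna(11)
    site = reverse_complement(mirna)
    mrna = site + "A" * 50 + site + "A" * 50 + site
    cds = {"tx1": (len(site) + 20, len(site) + 90)}
    hits = targets.antisense_search({"mir-a": mirna}, {"tx1": mrna}, cds_annotation=cds)
    regions = {h.start: h.region for h in hits}
    assert regions[1] == "5'UTR"
    assert regions[len(site) + 51] == "CDS"
    assert regions[2 * len(site) + 101] == "3'UTR"
    hits_plain = targets.antisense_search({"mir-a": mirna}, {"tx1": mrna})
    assert {h.region for h in hits_plain} == {"unannotated"}


def test_empty_mrna_set_raises():
    with pytest.raises(ValueError):
        targets.antisense_search({"mir-a": mk_mirna(12)}, {})


def test_antisense_matches_exhaustive_oracle():
    rng = np.random.default_rng(13)
    mirnas = {f"mir-{i}": mk_mirna(20 + i, int(rng.integers(20, 23))) for i in range(3)}
    mrnas = {}
    for t in range(3):
        seq = list("".join(rng.choice(list("ACGT"), 1500)))
        # plant some near-sites to make hits likely
        for name, m in mirnas.items():
            site = list(reverse_complement(m))
            if rng.random() < 0.7:
                pos = int(rng.integers(len(site)))
                site[pos] = str(rng.choice(list("ACGT")))
            s = int(rng.integers(0, len(seq) - len(site)))
            seq[s : s + len(site)] = site
        mrnas[f"tx{t}"] = "".join(seq)
    hits = targets.antisense_search(mirnas, mrnas)
    got = {
        (h.mirna, h.mrna, h.start, h.end, h.mismatches, h.gu_pairs, h.seed_perfect, h.duplex_score)
        for h in hits
    }
    expected = set()
    for mname, m in mirnas.items():
        for tname, s in mrnas.items():
            for (st, en, mm, gu, sp, sc) in exhaustive_antisense(m, s):
                expected.add((mname, tname, st, en, mm, gu, sp, sc))
    assert got == expected
    assert expected, "oracle comparison must exercise at least one hit"


def test_aggregate_targets():
    mirna = mk_mirna(30)
    site = reverse_complement(mirna)
    mrnas = {"tx1": site + "A" * 30 + site, "tx2": site + "C" * 10}
    hits = targets.antisense_search({"mir-a": mirna, "mir-b": mirna}, mrnas)
    per_mirna, per_mrna = targets.aggregate_targets(hits)
    assert per_mirna.loc["mir-a", "n_targets"] == 2
    assert per_mirna.loc["mir-a", "n_sites"] == 3
    assert per_mrna.loc["tx1", "n_mirnas"] == 2
    empty_m, empty_t = targets.aggregate_targets([])
    assert empty_m.empty and empty_t.empty


def test_hits_to_frame_columns():
    df = targets.hits_to_frame([])
    assert list(df.columns) == [
        "mirna", "mrna", "start", "end", "region",
        "mismatches", "gu_pairs", "seed_perfect", "duplex_score",
    ]
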