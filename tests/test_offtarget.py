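"""Mismatch-tolerant single and paired off-target search."""

import numpy as np
import pytest
from helpers_oracle import bf_paired_hits, bf_single_hits, random_dna, rc

from dimerscan.offtarget import (
    compare_hit_sets,
    footprint_length,
    paired_search,
    single_guide_search,
)
from dimerscan.simulate import plant_paired_sites, random_genome, simulate_offtargets
from dimerscan.scan import ScanRule


def test_footprint_length():
    assert footprint_length(20, 20, 16) == 56
    assert footprint_length(20, 20, 0) == 40
    assert footprint_length(0, 0, 7) == 7
    with pytest.raises(ValueError):
        footprint_length(20, -1, 16)


def test_planted_guide_found_exact():
    rng = np.random.default_rng(0)
    guide = random_dna(rng, 20)
    seq = random_dna(rng, 500) + guide + "TGG" + random_dna(rng, 100)
    hits = single_guide_search([("c", seq)], guide, "NGG", max_mm=0)
    assert any(h.mismatches == 0 and h.site.start == 500 and h.site.strand == "+" for h in hits)


def test_absent_guide_no_hits_at_zero_mm():
    rng = np.random.default_rng(1)
    seq = random_dna(rng, 2000)
    guide = "ACGT" * 5  # a 20-mer absent from 2 kb with overwhelming probability
    assert bf_single_hits(seq, guide, "NNN", 0) == []
    assert single_guide_search([("c", seq)], guide, "NNN", 0) == []


@pytest.mark.parametrize("pattern", ["NGG", "NNN"])
@pytest.mark.parametrize("seed", [0, 1])
def test_single_search_matches_bruteforce(pattern, seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 5000)
    # guide taken from the genome so hits exist at low mismatch counts
    guide = seq[1000:1020]
    got = [(h.site.start, h.site.strand, h.mismatches) for h in single_guide_search([("c", seq)], guide, pattern, 3)]
    assert sorted(got) == bf_single_hits(seq, guide, pattern, 3)


def test_single_search_monotone_in_max_mm():
    rng = np.random.default_rng(5)
    seq = random_dna(rng, 5000)
    guide = seq[100:120]
    counts = [len(single_guide_search([("c", seq)], guide, "NNN", mm)) for mm in (0, 2, 4, 6)]
    assert counts == sorted(counts)


def test_paired_requires_both_half_sites():
    rng = np.random.default_rng(2)
    guide_l, guide_r = random_dna(rng, 20), random_dna(rng, 20)
    seq = random_dna(rng, 200) + "CCA" + rc(guide_l) + random_dna(rng, 200)  # left half only
    assert paired_search([("c", seq)], guide_l, guide_r, "NGG", "NGG", 0, (13, 18)) == []


def test_paired_planted_with_mismatches():
    rng = np.random.default_rng(3)
    lg, rg = random_dna(rng, 20), random_dna(rng, 20)
    lg_mut = "A" + lg[1:] if lg[0] != "A" else "C" + lg[1:]
    rg_mut = rg[:-1] + ("A" if rg[-1] != "A" else "C")
    seq = random_dna(rng, 100) + "CCT" + rc(lg_mut) + random_dna(rng, 16) + rg_mut + "TGG" + random_dna(rng, 100)
    hits = paired_search([("c", seq)], lg, rg, "NGG", "NGG", 1, (13, 18))
    assert len(hits) == 1
    assert hits[0].total_mismatches == 2
    assert hits[0].spacer_len == 16


@pytest.mark.parametrize("seed", [0, 1])
def test_paired_search_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 5000)
    lg = rc(seq[2000:2020])
    rg = seq[2036:2056]
    got = [
        (p.left_hit.site.start, p.right_hit.site.start)
        for p in paired_search([("c", seq)], lg, rg, "NNN", "NNN", 3, (13, 18))
    ]
    assert sorted(got) == bf_paired_hits(seq, lg, rg, "NNN", "NNN", 3, 13, 18)
    assert (2000, 2036) in got  # the construction locus itself


def test_planted_offtargets_recovered_by_mismatch_budget():
    seq = random_genome(50_000, seed=4)
    rng = np.random.default_rng(7)
    guide = random_dna(rng, 20)
    seq, truth = simulate_offtargets(seq, guide, [0, 1, 2, 3], pam="NGG", seed=8)
    hits = single_guide_search([("c", seq)], guide, "NGG", max_mm=2)
    keys = {(h.site.start, h.site.strand): h.mismatches for h in hits}
    for t in truth:
        if t["mismatches"] <= 2:
            assert keys.get((t["start"], t["strand"])) == t["mismatches"]
        else:
            assert (t["start"], t["strand"]) not in keys


def test_paired_offtarget_via_planted_pair():
    seq = random_genome(20_000, seed=9)
    rule = ScanRule("NNN", "NNN", 20, (16, 16))
    seq, truth = plant_paired_sites(seq, 1, rule, seed=10)
    t = truth[0]
    hits = paired_search([("c", seq)], t["left_guide"], t["right_guide"], "NNN", "NNN", 0, (13, 18))
    assert len(hits) == 1
    assert hits[0].left_hit.site.start == t["left_start"]
    assert hits[0].right_hit.site.start == t["right_start"]


def test_compare_hit_sets():
    a = [("c", 1, "+"), ("c", 2, "+"), ("c", 3, "-"), ("c", 10, "+"), ("c", 11, "+")]
    b = [("c", 1, "+"), ("c", 2, "+"), ("c", 3, "-"), ("c", 20, "+"), ("c", 21, "+")]
    res = compare_hit_sets(a, b)
    assert (res["shared"], res["a_only"], res["b_only"]) == (3, 2, 2)
    assert res["jaccard"] == pytest.approx(3 / 7)
    assert compare_hit_sets(a, a)["jaccard"] == 1.0
    assert compare_hit_sets(a[:2], b[3:])["jaccard"] == 0.0
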