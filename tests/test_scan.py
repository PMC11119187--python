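"""Single and paired protospacer enumeration against brute-force oracles."""

import math

import numpy as np
import pytest
from helpers_oracle import bf_paired, bf_protospacers, random_dna, rc

from dimerscan.scan import (
    PairedSite,
    ScanRule,
    count_available_loci,
    count_paired_sites,
    find_paired_sites,
    find_protospacers,
    target_ratio,
)


def test_window_too_short_yields_nothing():
    assert find_protospacers("ACGTACGTAC", "NGG", guide_len=20) == []


def test_homopolymer_closed_form():
    """30-bp poly-G with NGG: 8 plus-strand windows, none on the minus strand."""
    sites = find_protospacers("G" * 30, "NGG", guide_len=20)
    assert len(sites) == 8
    assert all(s.strand == "+" for s in sites)
    assert [s.start for s in sites] == list(range(8))


def test_site_geometry_and_sequences():
    seq = "T" * 5 + "CCA" + rc("ACGTACGTACGTACGTACGA") + "G" * 5
    sites = find_protospacers(seq, "NGG", guide_len=20)
    minus = [s for s in sites if s.strand == "-"]
    assert len(minus) == 1
    s = minus[0]
    assert (s.start, s.end) == (8, 28)
    assert s.protospacer == "ACGTACGTACGTACGTACGA"
    assert s.pam == "TGG"  # reverse complement of CCA


@pytest.mark.parametrize("pattern", ["NGG", "NRN", "NYY", "NNN"])
@pytest.mark.parametrize("seed", [0, 1])
def test_protospacers_match_bruteforce(pattern, seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 300)
    got = [(s.start, s.strand) for s in find_protospacers(seq, pattern, 20)]
    assert got == bf_protospacers(seq, pattern, 20)


def test_protospacers_skip_ambiguous_pam_bases():
    seq = "A" * 20 + "NGG"
    assert find_protospacers(seq, "NGG", 20) == []
    # even pattern N rejects a genomic N: no plus-strand site can use this PAM
    assert all(s.strand != "+" for s in find_protospacers(seq, "NNN", 20))


def test_planted_construct_single_pair():
    rng = np.random.default_rng(3)
    lg, rg = random_dna(rng, 20), random_dna(rng, 20)
    seq = "CCT" + rc(lg) + random_dna(rng, 16) + rg + "AGG"
    rule = ScanRule("NGG", "NGG", 20, (16, 16))
    pairs = find_paired_sites(seq, rule)
    assert len(pairs) == 1
    p = pairs[0]
    assert p.spacer_len == 16
    assert p.left.protospacer == lg and p.right.protospacer == rg
    assert p.left.strand == "-" and p.right.strand == "+"
    assert p.spacer_len == p.right.start - p.left.end


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_paired_sites_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 2000)
    rule = ScanRule("NGG", "NGG", 20, (13, 18))
    got = [(p.left.start, p.right.start) for p in find_paired_sites(seq, rule)]
    assert got == bf_paired(seq, "NGG", "NGG", 20, 13, 18)
    assert count_paired_sites(seq, rule) == len(got)


def test_no_pam_matches_no_pairs():
    assert find_paired_sites("AT" * 100, ScanRule("NGG", "NGG")) == []


def test_count_additive_over_contigs():
    rng = np.random.default_rng(7)
    seq = random_dna(rng, 3000)
    rule = ScanRule("NRN", "NRN", 20, (13, 18))
    one = count_available_loci([("c1", seq)], rule)
    two = count_available_loci([("c1", seq), ("c2", seq)], rule)
    assert one > 0 and two == 2 * one


def test_monotonicity_in_spacer_and_pam():
    rng = np.random.default_rng(11)
    seq = random_dna(rng, 5000)
    narrow = count_paired_sites(seq, ScanRule("NGG", "NGG", 20, (15, 16)))
    wide = count_paired_sites(seq, ScanRule("NGG", "NGG", 20, (13, 18)))
    relaxed = count_paired_sites(seq, ScanRule("NNN", "NNN", 20, (13, 18)))
    assert narrow <= wide <= relaxed


def test_strand_symmetry_mirror():
    """Scanning the reverse complement with swapped PAM roles mirrors the pairs."""
    rng = np.random.default_rng(13)
    seq = random_dna(rng, 3000)
    rule = ScanRule("NGG", "NRN", 20, (13, 18))
    fwd = {(p.left.start, p.right.start, p.spacer_len) for p in find_paired_sites(seq, rule)}
    mirror_rule = ScanRule("NRN", "NGG", 20, (13, 18))
    n = len(seq)
    # a pair (ls, rs) maps to (n - rs - 20, n - ls - 20) on the reverse strand
    rev = {
        (n - (p.right.start + 20), n - (p.left.start + 20), p.spacer_len)
        for p in find_paired_sites(rc(seq), mirror_rule)
    }
    assert fwd == rev


def test_target_ratio_identity_and_degenerate():
    rng = np.random.default_rng(17)
    contigs = [("c", random_dna(rng, 2000))]
    rule = ScanRule("NGG", "NGG", 20, (13, 18))
    assert target_ratio(contigs, rule, rule) == 1.0
    empty = [("c", "AT" * 500)]
    r = target_ratio(empty, ScanRule("NNN", "NNN"), rule)
    assert math.isnan(r) or math.isinf(r)
    assert math.isnan(target_ratio(empty, rule, rule))


def test_soft_masked_bases_are_scanned():
    seq = ("G" * 30).lower()
    assert len(find_protospacers(seq, "NGG", 20)) == 8


def test_negative_spacer_range_rejected():
    with pytest.raises(ValueError):
        ScanRule("NGG", "NGG", 20, (-1, 5))
    with pytest.raises(ValueError):
        ScanRule("NGG", "NGG", 20, (5, 3))
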