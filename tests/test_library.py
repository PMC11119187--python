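"""Demultiplexing, per-barcode editing statistics, PAM groups, and PFMs."""

import numpy as np
import pandas as pd
import pytest

from dimerscan.library import (
    BarcodeRecord,
    DEFAULT_LAYOUT,
    build_pfm,
    compute_editing_stats,
    demultiplex,
    pam_context_motifs,
    pam_group_table,
    window_motif,
)
from dimerscan.simulate import make_pam_library, make_window_library, simulate_library_reads


def _tiny_table():
    return [
        BarcodeRecord("AAAAAAAA", "CCCCCCCC", "A" * 84, left_pam6="AGGTAC", right_pam6="TGGCAT"),
        BarcodeRecord("GGGGGGGG", "TTTTTTTT", "C" * 84, left_pam6="ACATAC", right_pam6="TCTCAT"),
    ]


def test_record_requires_exactly_one_variable_region():
    with pytest.raises(ValueError):
        BarcodeRecord("A" * 8, "C" * 8, "A" * 84)
    with pytest.raises(ValueError):
        BarcodeRecord("A" * 8, "C" * 8, "A" * 84, left_pam6="AGGTAC", right_pam6="TGGCAT", window16="T" * 16)


def test_demultiplex_exact_assignment():
    table = _tiny_table()
    reads = [("r1", "AAAAAAAA" + "G" * 68 + "CCCCCCCC"), ("r2", "GGGGGGGG" + "G" * 68 + "TTTTTTTT")]
    assigned, unassigned = demultiplex(reads, table, max_mm=0)
    assert [r[0] for r in assigned[table[0].key]] == ["r1"]
    assert [r[0] for r in assigned[table[1].key]] == ["r2"]
    assert unassigned == []


def test_demultiplex_unassigned_at_zero_mm():
    table = _tiny_table()
    reads = [("r1", "AAAAAAAT" + "G" * 68 + "CCCCCCCC")]
    assigned, unassigned = demultiplex(reads, table, max_mm=0)
    assert len(unassigned) == 1
    assigned, unassigned = demultiplex(reads, table, max_mm=1)
    assert [r[0] for r in assigned[table[0].key]] == ["r1"]


def test_demultiplex_tie_goes_unassigned():
    table = [
        BarcodeRecord("AAAAAAAA", "CCCCCCCC", "A" * 84, left_pam6="AGGTAC", right_pam6="TGGCAT"),
        BarcodeRecord("AAAAAAAT", "CCCCCCCC", "C" * 84, left_pam6="ACATAC", right_pam6="TCTCAT"),
    ]
    # left barcode 1 mm from both records, right barcode exact for both
    reads = [("r1", "AAAAAAAG" + "G" * 68 + "CCCCCCCC")]
    _, unassigned = demultiplex(reads, table, max_mm=1)
    assert len(unassigned) == 1


def test_demultiplex_simulated_exactness():
    """Error-free simulated reads all land on their own record."""
    table = make_pam_library(n_per_class=2, seed=5)
    reads, truth = simulate_library_reads(table, 0.2, n_reads_per_record=30, seq_error_rate=0.0, seed=6)
    assigned, unassigned = demultiplex(reads, table, max_mm=0)
    assert unassigned == []
    for rec in table:
        assert len(assigned[rec.key]) == 30
        assert all(rid.startswith(f"{rec.barcode_left}-{rec.barcode_right}") for rid, _ in assigned[rec.key])


def test_build_pfm_fixed_base():
    pfm = build_pfm(["AAAAAA"])
    assert pfm.freqs[0].tolist() == [1.0] * 6
    assert np.allclose(pfm.ic, 2.0)
    assert np.allclose(pfm.freqs.sum(axis=0), 1.0)


def test_build_pfm_weighting_consistency():
    seqs = ["ACGTAC", "TTTTTT", "ACGTAC"]
    weighted = build_pfm(["ACGTAC", "TTTTTT"], weights=[2.0, 1.0])
    duplicated = build_pfm(seqs)
    assert np.allclose(weighted.freqs, duplicated.freqs)
    assert weighted.total_weight == duplicated.total_weight == 3.0


def test_build_pfm_uniform_random_low_ic():
    rng = np.random.default_rng(0)
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 6)) for _ in range(4000)]
    pfm = build_pfm(seqs)
    assert pfm.ic.max() < 0.02
    assert np.allclose(pfm.freqs.sum(axis=0), 1.0)


def test_build_pfm_validation():
    with pytest.raises(ValueError):
        build_pfm(["ACGT", "ACG"])
    with pytest.raises(ValueError):
        build_pfm(["ACGT"], weights=[0.0])
    with pytest.raises(ValueError):
        build_pfm([])


def test_editing_stats_recover_truth():
    """Estimated per-barcode efficiencies track the realised edit counts."""
    table = make_pam_library(n_per_class=3, seed=1)
    reads, truth = simulate_library_reads(table, 0.3, n_reads_per_record=60, seed=2)
    stats = compute_editing_stats(reads, table, max_mm=1)
    merged = stats.merge(truth.records, on=["barcode_left", "barcode_right"], suffixes=("", "_true"))
    assert (merged["n_reads"] >= 55).all()  # little read loss
    # 3-sigma binomial envelope around the true probability
    sd = np.sqrt(0.3 * 0.7 / merged["n_reads"])
    within = (merged["efficiency"] - 0.3).abs() <= 3 * sd
    assert within.mean() >= 0.95
    assert set(merged["left_class"]).issubset({"NGG", "NRR", "NRY", "NYR", "NYY"})


def test_pam_group_table_zero_efficiency_and_empty_groups():
    stats = pd.DataFrame(
        {
            "left_class": ["NGG", "NRR"],
            "right_class": ["NGG", "NRR"],
            "efficiency": [0.0, 0.0],
            "n_edited": [0, 0],
        }
    )
    table = pam_group_table(stats, n_boot=100)
    ngg = table[(table.side == "left") & (table.pam_class == "NGG")].iloc[0]
    assert ngg["mean"] == 0.0 and ngg["n"] == 1
    nyy = table[(table.side == "left") & (table.pam_class == "NYY")].iloc[0]
    assert nyy["n"] == 0 and np.isnan(nyy["mean"])


def test_pam_context_motifs_empty_signal():
    stats = pd.DataFrame(
        {"left_pam6": ["AGGTAC"], "right_pam6": ["TGGCAT"], "efficiency": [0.0], "n_edited": [0]}
    )
    assert pam_context_motifs(stats) is None


def test_pam_context_motifs_weighting_modes():
    stats = pd.DataFrame(
        {
            "left_pam6": ["AGGTAC", "TGGCAT"],
            "right_pam6": ["ACGTAC", "TCGCAT"],
            "efficiency": [0.5, 0.1],
            "n_edited": [5, 1],
        }
    )
    left_w, _ = pam_context_motifs(stats, weighting="efficiency")
    left_u, _ = pam_context_motifs(stats, weighting="uniform")
    assert left_w.total_weight == pytest.approx(0.6)
    assert left_u.total_weight == 2.0
    assert not np.allclose(left_w.freqs, left_u.freqs)
    with pytest.raises(ValueError):
        pam_context_motifs(stats, weighting="bogus")


def test_window_motif_single_stratum_equals_overall():
    rng = np.random.default_rng(9)
    wins = ["".join("ACGT"[i] for i in rng.integers(0, 4, 16)) for _ in range(20)]
    stats = pd.DataFrame({"window16": wins, "efficiency": [0.3] * 20, "n_edited": [3] * 20})
    res = window_motif(stats, n_strata=1, weighting="uniform")
    assert res is not None
    label, n, pfm = res.strata[0]
    assert n == 20
    assert np.allclose(pfm.freqs, res.overall.freqs)


def test_window_motif_empty_signal():
    stats = pd.DataFrame({"window16": ["A" * 16], "efficiency": [0.0], "n_edited": [0]})
    assert window_motif(stats) is None
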