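"""Seeded generators for every input the pipeline consumes.

Everything is reproducible from (parameters, seed) via numpy's PCG64
streams, and every generator returns a truth record sufficient to score
recall/precision of the downstream stage without re-running generation:

* i.i.d. random genomes with configurable GC;
* genomes with planted paired protospacer sites satisfying a scan rule;
* barcoded library reads with known per-record editing efficiency and an
  NHEJ-style indel spectrum centred on the dimer cut site;
* genomes with planted mismatched off-target half-sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .library import BarcodeRecord, DEFAULT_LAYOUT, LibraryLayout
from .pam import PamPattern, classify_pam
from .scan import ScanRule

_BASES = "ACGT"
_IUPAC_SET = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "N": "ACGT"}


def random_genome(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """An i.i.d. random DNA sequence with P(G) + P(C) = ``gc_fraction``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(_BASES[i] for i in idx)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _sample_pam(rng: np.random.Generator, pattern: PamPattern) -> str:
    return "".join(_IUPAC_SET[c][rng.integers(0, len(_IUPAC_SET[c]))] for c in pattern.pattern)


def _sample_3mer_of_class(rng: np.random.Generator, pam_class: str) -> str:
    members = [s for s in ("".join(p) for p in product(_BASES, repeat=3)) if classify_pam(s) == pam_class]
    return members[rng.integers(0, len(members))]


def _place_nonoverlapping(
    rng: np.random.Generator, genome_len: int, lengths: Sequence[int], min_gap: int = 10
) -> list[int]:
    """Random non-overlapping placements for intervals of the given lengths."""
    placed: list[tuple[int, int]] = []
    starts: list[int] = []
    for L in lengths:
        hi = genome_len - L
        if hi < 0:
            raise ValueError("genome too short for requested plantings")
        for _ in range(2000):
            s = int(rng.integers(0, hi + 1))
            if all(s + L + min_gap <= a or b + min_gap <= s for a, b in placed):
                placed.append((s, s + L))
                starts.append(s)
                break
        else:
            raise ValueError("could not place non-overlapping plantings; genome too crowded")
    return starts


def plant_paired_sites(
    seq: str,
    n: int,
    rule: ScanRule,
    seed: int = 0,
    guides: Sequence[tuple[str, str]] | None = None,
) -> tuple[str, list[dict]]:
    """Overwrite ``n`` non-overlapping loci with paired sites satisfying ``rule``.

    Each planted locus is, on the plus strand,
    rc(left_pam) + rc(left_guide) + spacer + right_guide + right_pam, i.e. a
    PAM-out pair. Guides and PAMs are drawn at random unless ``guides``
    supplies (left_guide, right_guide) pairs. Returns the modified sequence
    and one truth dict per planting (protospacer coordinates, guides, PAMs,
    spacer length). Genome length is unchanged.
    """
    if rule.orientation != "pam-out":
        raise ValueError("planting supports pam-out geometry only")
    if n == 0:
        return seq, []
    rng = np.random.default_rng(seed)
    g = rule.guide_len
    L, R = len(rule.left_pam), len(rule.right_pam)
    spacers = [int(rng.integers(rule.spacer_range[0], rule.spacer_range[1] + 1)) for _ in range(n)]
    lengths = [L + g + sp + g + R for sp in spacers]
    starts = _place_nonoverlapping(rng, len(seq), lengths)
    chars = list(seq)
    truth = []
    for i, (pos, sp) in enumerate(zip(starts, spacers)):
        if guides is not None:
            lg, rg = guides[i]
        else:
            lg, rg = _random_seq(rng, g), _random_seq(rng, g)
        lp = _sample_pam(rng, rule.left_pam)
        rp = _sample_pam(rng, rule.right_pam)
        construct = (
            reverse_complement(lp) + reverse_complement(lg) + _random_seq(rng, sp) + rg + rp
        )
        chars[pos : pos + len(construct)] = construct
        left_start = pos + L
        right_start = left_start + g + sp
        truth.append(
            {
                "left_start": left_start,
                "left_end": left_start + g,
                "right_start": right_start,
                "right_end": right_start + g,
                "spacer_len": sp,
                "left_guide": lg,
                "right_guide": rg,
                "left_pam": lp,
                "right_pam": rp,
            }
        )
    return "".join(chars), truth


@dataclass(frozen=True)
class IndelSpectrum:
    """Distribution of simulated NHEJ outcomes at the dimer cut.

    Deletions (probability ``del_prob``) have truncated-geometric lengths
    1..del_max; insertions take lengths from ``ins_lens`` uniformly. The
    event's left edge is uniform within +/- ``offset_range`` bp of the cut
    centre (mid-spacer).
    """

    del_prob: float = 0.8
    del_geom_p: float = 0.3
    del_max: int = 10
    ins_lens: tuple[int, ...] = (1, 2, 3)
    offset_range: int = 4

    def sample(self, rng: np.random.Generator) -> tuple[str, int, int]:
        offset = int(rng.integers(-self.offset_range, self.offset_range + 1))
        if rng.random() < self.del_prob:
            p = self.del_geom_p
            pmf = np.array([p * (1 - p) ** (k - 1) for k in range(1, self.del_max + 1)])
            length = int(rng.choice(np.arange(1, self.del_max + 1), p=pmf / pmf.sum()))
            return "deletion", length, offset
        return "insertion", int(rng.choice(self.ins_lens)), offset


DEFAULT_SPECTRUM = IndelSpectrum()


@dataclass
class SimTruth:
    """Ground truth of a simulated library run (regenerable from seed)."""

    records: pd.DataFrame  # barcode pair, true_e, n_reads, n_edited_true
    seed: int
    spectrum: IndelSpectrum = field(default_factory=IndelSpectrum)


def _resolve_efficiency(rec: BarcodeRecord, true_efficiency) -> float:
    if callable(true_efficiency):
        return float(true_efficiency(rec))
    if isinstance(true_efficiency, dict):
        return float(true_efficiency[rec.key])
    return float(true_efficiency)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_err, replace=False):
        cur = chars[pos]
        alts = [b for b in _BASES if b != cur]
        chars[pos] = alts[rng.integers(0, 3)]
    return "".join(chars)


def simulate_library_reads(
    table: Sequence[BarcodeRecord],
    true_efficiency,
    n_reads_per_record: int = 200,
    spectrum: IndelSpectrum = DEFAULT_SPECTRUM,
    seq_error_rate: float = 0.001,
    seed: int = 0,
    layout: LibraryLayout = DEFAULT_LAYOUT,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate amplicon reads for a barcoded library with known truth.

    ``true_efficiency`` is a scalar, a dict keyed by barcode pair, or a
    callable(record) -> probability. With probability e a read carries one
    indel drawn from ``spectrum`` positioned about the cut centre
    (mid-insert); all reads then acquire i.i.d. substitution errors at
    ``seq_error_rate``.
    """
    if not table:
        raise ValueError("empty barcode table")
    rng = np.random.default_rng(seed)
    cut_center = (layout.insert_start + layout.insert_end) // 2
    reads: list[tuple[str, str]] = []
    rows = []
    for rec in table:
        e = _resolve_efficiency(rec, true_efficiency)
        if not 0 <= e <= 1:
            raise ValueError(f"efficiency {e} outside [0, 1]")
        n_edited = 0
        for i in range(n_reads_per_record):
            seq = rec.ref_amplicon
            edited = rng.random() < e
            if edited:
                n_edited += 1
                kind, length, offset = spectrum.sample(rng)
                p = cut_center + offset
                if kind == "deletion":
                    seq = seq[:p] + seq[p + length :]
                else:
                    seq = seq[:p] + _random_seq(rng, length) + seq[p:]
            seq = _apply_errors(rng, seq, seq_error_rate)
            reads.append((f"{rec.barcode_left}-{rec.barcode_right}:{i}", seq))
        rows.append(
            {
                "barcode_left": rec.barcode_left,
                "barcode_right": rec.barcode_right,
                "true_e": e,
                "n_reads": n_reads_per_record,
                "n_edited_true": n_edited,
            }
        )
    return reads, SimTruth(records=pd.DataFrame(rows), seed=seed, spectrum=spectrum)


def _unique_barcode_pairs(rng: np.random.Generator, n: int, bc_len: int) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    seen = set()
    while len(pairs) < n:
        pair = (_random_seq(rng, bc_len), _random_seq(rng, bc_len))
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return pairs


def build_amplicon(
    layout: LibraryLayout,
    barcode_left: str,
    barcode_right: str,
    left_guide: str,
    right_guide: str,
    left_pam6: str,
    right_pam6: str,
    insert: str,
) -> str:
    """Assemble the plus-strand amplicon for the fixed library architecture."""
    return (
        barcode_left
        + reverse_complement(left_pam6)
        + reverse_complement(left_guide)
        + insert
        + right_guide
        + right_pam6
        + barcode_right
    )


def make_pam_library(
    n_per_class: int = 40,
    seed: int = 0,
    layout: LibraryLayout = DEFAULT_LAYOUT,
    left_guide: str | None = None,
    right_guide: str | None = None,
    paired_classes: bool = True,
) -> list[BarcodeRecord]:
    """A balanced PAM library: n records per PAM class, both sides.

    For each of the five classes, both proximal 3-mers are drawn from that
    class (plus random downstream context), so left and right groupings are
    each balanced at ``n_per_class``; with ``paired_classes=False`` the two
    3-mers are instead drawn independently and uniformly over all 64, which
    decorrelates the two sides (useful when planting a one-sided bias). One
    fixed guide pair and one fixed spacer sequence are shared by the whole
    library.
    """
    from .pam import PAM_CLASSES

    rng = np.random.default_rng(seed)
    lg = left_guide or _random_seq(rng, layout.guide_len)
    rg = right_guide or _random_seq(rng, layout.guide_len)
    spacer = _random_seq(rng, layout.insert_len)
    pairs = _unique_barcode_pairs(rng, n_per_class * len(PAM_CLASSES), layout.bc_len)
    records = []
    i = 0
    for cls in PAM_CLASSES:
        for _ in range(n_per_class):
            bcl, bcr = pairs[i]
            i += 1
            if paired_classes:
                lp3 = _sample_3mer_of_class(rng, cls)
                rp3 = _sample_3mer_of_class(rng, cls)
            else:
                lp3 = _random_seq(rng, 3)
                rp3 = _random_seq(rng, 3)
            lp6 = lp3 + _random_seq(rng, layout.pam_len - 3)
            rp6 = rp3 + _random_seq(rng, layout.pam_len - 3)
            records.append(
                BarcodeRecord(
                    barcode_left=bcl,
                    barcode_right=bcr,
                    left_pam6=lp6,
                    right_pam6=rp6,
                    ref_amplicon=build_amplicon(layout, bcl, bcr, lg, rg, lp6, rp6, spacer),
                )
            )
    return records


def make_window_library(
    n_records: int = 200,
    seed: int = 0,
    layout: LibraryLayout = DEFAULT_LAYOUT,
    left_guide: str | None = None,
    right_guide: str | None = None,
    windows: Sequence[str] | None = None,
) -> list[BarcodeRecord]:
    """An editing-window library: the 16-nt insert is randomised per record.

    The guide pair and PAM 6-mers are fixed (shared with the PAM-library
    design); ``windows`` overrides the random inserts, e.g. to plant a motif.
    """
    rng = np.random.default_rng(seed)
    lg = left_guide or _random_seq(rng, layout.guide_len)
    rg = right_guide or _random_seq(rng, layout.guide_len)
    lp6 = _random_seq(rng, layout.pam_len)
    rp6 = _random_seq(rng, layout.pam_len)
    pairs = _unique_barcode_pairs(rng, n_records, layout.bc_len)
    records = []
    for i, (bcl, bcr) in enumerate(pairs):
        win = windows[i] if windows is not None else _random_seq(rng, layout.insert_len)
        if len(win) != layout.insert_len:
            raise ValueError("window length must match layout.insert_len")
        records.append(
            BarcodeRecord(
                barcode_left=bcl,
                barcode_right=bcr,
                window16=win,
                ref_amplicon=build_amplicon(layout, bcl, bcr, lg, rg, lp6, rp6, win),
            )
        )
    return records


def _mutate(rng: np.random.Generator, guide: str, n_mm: int) -> str:
    if n_mm > len(guide):
        raise ValueError("mismatch count exceeds guide length")
    chars = list(guide)
    for pos in rng.choice(len(guide), size=n_mm, replace=False):
        alts = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alts[rng.integers(0, 3)]
    return "".join(chars)


def simulate_offtargets(
    seq: str,
    guide: str,
    mismatch_counts: Sequence[int],
    pam: PamPattern | str = "NNN",
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """Plant degenerate half-site copies of ``guide`` at known coordinates.

    One isolated half-site per entry of ``mismatch_counts``, each with
    exactly that Hamming distance to the guide and a PAM sampled from
    ``pam``, planted on a random strand. Returns the modified sequence and
    truth dicts (start, end, strand, mismatches, planted sequence).
    """
    if isinstance(pam, str):
        pam = PamPattern(pam)
    rng = np.random.default_rng(seed)
    g = len(guide)
    L = len(pam)
    site_len = g + L
    starts = _place_nonoverlapping(rng, len(seq), [site_len] * len(mismatch_counts), min_gap=30)
    chars = list(seq)
    truth = []
    for pos, n_mm in zip(starts, mismatch_counts):
        variant = _mutate(rng, guide.upper(), n_mm)
        pam_seq = _sample_pam(rng, pam)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            construct = variant + pam_seq
            proto_start = pos
        else:
            construct = reverse_complement(variant + pam_seq)
            proto_start = pos + L
        chars[pos : pos + site_len] = construct
        truth.append(
            {
                "start": proto_start,
                "end": proto_start + g,
                "strand": strand,
                "mismatches": n_mm,
                "protospacer": variant,
                "pam": pam_seq,
            }
        )
    return "".join(chars), truth
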