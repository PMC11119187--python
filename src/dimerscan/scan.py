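"""Genome-wide enumeration of single and paired protospacer sites.

A dimeric FokI-dCas9 editor cleaves only where two guides bind in PAM-out
orientation: a minus-strand half-site on the left (its PAM genomically
leftmost) and a plus-strand half-site on the right (PAM rightmost), separated
by a dimer spacer — the bp gap between the inner edges of the two
protospacers. Cleavage occurs in that spacer, so the full matched footprint
is guide + spacer + guide (56 bp for two 20-nt guides at the optimal 16-bp
spacer).

Coordinates are 0-based half-open (BED-compatible); the protospacer interval
excludes the PAM. Counting is vectorised over PAM match masks so whole
megabase contigs scan in milliseconds; ``find_*`` functions materialise site
objects and are intended for region-scale inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio.Seq import reverse_complement

from .pam import PamPattern, encode_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProtospacerSite:
    """One genomic half-site: a protospacer plus its adjacent 3' PAM.

    ``start``/``end`` delimit the protospacer (half-open, PAM excluded).
    On '+' the PAM occupies [end, end+len(pam)); on '-' it occupies
    [start-len(pam), start) in reference coordinates. ``protospacer`` and
    ``pam`` are reported 5'->3' on the site's own strand.
    """

    contig: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.protospacer):
            raise ValueError("protospacer length does not match interval")


@dataclass(frozen=True)
class PairedSite:
    """A PAM-out pair: left half-site on '-', right half-site on '+'.

    ``spacer_len`` is the gap between the inner protospacer edges
    (right.start - left.end); FokI dimerises and cuts within it.
    """

    left: ProtospacerSite
    right: ProtospacerSite
    spacer_len: int

    def __post_init__(self) -> None:
        if self.spacer_len < 0:
            raise ValueError("negative dimer spacer")


@dataclass(frozen=True)
class ScanRule:
    """PAM requirements and geometry for a paired-site scan.

    ``spacer_range`` is an inclusive (min, max) interval of allowed dimer
    spacer lengths in bp. ``orientation`` is 'pam-out' (default, the FokI
    dimer geometry) or 'pam-in' (exploratory).
    """

    left_pam: PamPattern
    right_pam: PamPattern
    guide_len: int = 20
    spacer_range: tuple[int, int] = (13, 18)
    orientation: str = "pam-out"

    def __post_init__(self) -> None:
        lp = self.left_pam if isinstance(self.left_pam, PamPattern) else PamPattern(self.left_pam)
        rp = self.right_pam if isinstance(self.right_pam, PamPattern) else PamPattern(self.right_pam)
        object.__setattr__(self, "left_pam", lp)
        object.__setattr__(self, "right_pam", rp)
        lo, hi = self.spacer_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid spacer_range {self.spacer_range}")
        if self.guide_len < 1:
            raise ValueError("guide_len must be >= 1")
        if self.orientation not in ("pam-out", "pam-in"):
            raise ValueError(f"orientation must be 'pam-out' or 'pam-in', got {self.orientation!r}")


def _window_match_mask(bits: np.ndarray, pattern: PamPattern) -> np.ndarray:
    """Boolean mask over window start positions where ``pattern`` matches."""
    L = len(pattern)
    n = bits.size
    if n < L:
        return np.zeros(0, dtype=bool)
    pat = pattern.bits
    mask = (bits[: n - L + 1] & pat[0]) != 0
    for k in range(1, L):
        mask &= (bits[k : n - L + 1 + k] & pat[k]) != 0
    return mask


def _half_site_masks(
    bits: np.ndarray, pam: PamPattern, guide_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Masks over protospacer start positions for '+' and '-' half-sites.

    plus[s]  — protospacer [s, s+g) on '+' with PAM matching at s+g.
    minus[s] — protospacer [s, s+g) on '-' with PAM at [s-L, s); equivalent
    to the reverse-complement pattern matching the forward strand at s-L.
    """
    n = bits.size
    g = guide_len
    L = len(pam)
    plus = np.zeros(n, dtype=bool)
    minus = np.zeros(n, dtype=bool)
    pam_fwd = _window_match_mask(bits, pam)  # index = PAM start on '+'
    pam_rev = _window_match_mask(bits, pam.reverse_complement())
    # '+': need s + g + L <= n and PAM at s+g.
    hi = n - g - L + 1
    if hi > 0:
        plus[:hi] = pam_fwd[g : g + hi]
    # '-': need s >= L and s + g <= n; rev-comp PAM window starts at s-L.
    lo = L
    hi = n - g + 1
    if hi > lo:
        minus[lo:hi] = pam_rev[0 : hi - lo]
    return plus, minus


def find_protospacers(
    seq: str,
    pam: PamPattern | str,
    guide_len: int = 20,
    contig: str = "seq",
) -> list[ProtospacerSite]:
    """All half-sites on both strands of ``seq`` whose PAM matches ``pam``.

    Returns sites sorted by (start, strand). Soft-masked bases are
    uppercased before matching; too-short sequences yield an empty list.
    """
    if isinstance(pam, str):
        pam = PamPattern(pam)
    up = seq.upper()
    bits = encode_sequence(up)
    plus, minus = _half_site_masks(bits, pam, guide_len)
    L = len(pam)
    sites = []
    for s in np.flatnonzero(plus):
        s = int(s)
        sites.append(
            ProtospacerSite(contig, s, s + guide_len, "+", up[s : s + guide_len], up[s + guide_len : s + guide_len + L])
        )
    for s in np.flatnonzero(minus):
        s = int(s)
        sites.append(
            ProtospacerSite(
                contig,
                s,
                s + guide_len,
                "-",
                reverse_complement(up[s : s + guide_len]),
                reverse_complement(up[s - L : s]),
            )
        )
    sites.sort(key=lambda x: (x.start, x.strand))
    return sites


def _pair_masks(bits: np.ndarray, rule: ScanRule) -> tuple[np.ndarray, np.ndarray]:
    """(left-start mask, right-start mask) under the rule's orientation."""
    if rule.orientation == "pam-out":
        _, left = _half_site_masks(bits, rule.left_pam, rule.guide_len)
        right, _ = _half_site_masks(bits, rule.right_pam, rule.guide_len)
    else:  # pam-in: left half-site on '+', right on '-'
        left, _ = _half_site_masks(bits, rule.left_pam, rule.guide_len)
        _, right = _half_site_masks(bits, rule.right_pam, rule.guide_len)
    return left, right


def _spacer_offsets(rule: ScanRule) -> range:
    """Offsets right.start - left.start for each allowed spacer value."""
    lo, hi = rule.spacer_range
    if rule.orientation == "pam-out":
        # spacer = right.start - left.end = right.start - left.start - g
        return range(rule.guide_len + lo, rule.guide_len + hi + 1)
    # pam-in: spacer measured between the two inward-facing PAMs:
    # (right.start - R) - (left.end + L) => offset = g + L + R + spacer
    LR = len(rule.left_pam) + len(rule.right_pam)
    return range(rule.guide_len + lo + LR, rule.guide_len + hi + LR + 1)


def find_paired_sites(seq: str, rule: ScanRule, contig: str = "seq") -> list[PairedSite]:
    """Enumerate all guide pairs satisfying ``rule`` on one contig.

    One PairedSite per (left.start, right.start); overlapping pairs are all
    reported — each is an independent guide-pair design choice.
    """
    up = seq.upper()
    bits = encode_sequence(up)
    left_mask, right_mask = _pair_masks(bits, rule)
    g = rule.guide_len
    lo, _ = rule.spacer_range
    pairs: list[PairedSite] = []
    offsets = _spacer_offsets(rule)
    left_starts = np.flatnonzero(left_mask)
    n = bits.size
    for ls in left_starts:
        ls = int(ls)
        for k, off in enumerate(offsets):
            rs = ls + off
            if rs + g > n or not right_mask[rs]:
                continue
            spacer = lo + k
            if rule.orientation == "pam-out":
                L = len(rule.left_pam)
                left = ProtospacerSite(
                    contig, ls, ls + g, "-",
                    reverse_complement(up[ls : ls + g]),
                    reverse_complement(up[ls - L : ls]),
                )
                R = len(rule.right_pam)
                right = ProtospacerSite(
                    contig, rs, rs + g, "+", up[rs : rs + g], up[rs + g : rs + g + R]
                )
            else:
                L = len(rule.left_pam)
                left = ProtospacerSite(
                    contig, ls, ls + g, "+", up[ls : ls + g], up[ls + g : ls + g + L]
                )
                R = len(rule.right_pam)
                right = ProtospacerSite(
                    contig, rs, rs + g, "-",
                    reverse_complement(up[rs : rs + g]),
                    reverse_complement(up[rs - R : rs]),
                )
            pairs.append(PairedSite(left, right, spacer))
    pairs.sort(key=lambda p: (p.left.start, p.right.start))
    return pairs


def count_paired_sites(seq: str, rule: ScanRule) -> int:
    """Paired-site count on one contig without materialising site objects."""
    bits = encode_sequence(seq.upper())
    left_mask, right_mask = _pair_masks(bits, rule)
    n = bits.size
    g = rule.guide_len
    total = 0
    for off in _spacer_offsets(rule):
        hi = n - g - off  # right start rs = ls + off needs rs + g <= n
        if hi <= 0:
            continue
        total += int(np.count_nonzero(left_mask[:hi] & right_mask[off : off + hi]))
    return total


def count_single_sites(seq: str, pam: PamPattern | str, guide_len: int = 20) -> int:
    """Half-site count (both strands) on one contig."""
    if isinstance(pam, str):
        pam = PamPattern(pam)
    bits = encode_sequence(seq.upper())
    plus, minus = _half_site_masks(bits, pam, guide_len)
    return int(np.count_nonzero(plus)) + int(np.count_nonzero(minus))


def count_available_loci(genome: "str | Iterable[tuple[str, str]]", rule: ScanRule) -> int:
    """Total paired-site count over all contigs of a genome.

    ``genome`` is a FASTA path (plain or gzip) or an iterable of
    (name, sequence) tuples. Contigs are processed independently; pairs never
    span contigs.
    """
    total = 0
    for _, seq in _iter_contigs(genome):
        total += count_paired_sites(seq, rule)
    return total


def target_ratio(
    genome: "str | Iterable[tuple[str, str]]",
    rule_numerator: ScanRule,
    rule_denominator: ScanRule,
) -> float:
    """Ratio of available paired loci between two scan rules.

    A zero denominator yields inf (or nan when both counts are zero) with a
    logged warning rather than an exception: an empty denominator scan is a
    degenerate comparison, not a programming error.
    """
    contigs = list(_iter_contigs(genome))
    num = count_available_loci(contigs, rule_numerator)
    den = count_available_loci(contigs, rule_denominator)
    if den == 0:
        logger.warning("target_ratio: denominator rule matched no loci (numerator=%d)", num)
        return math.nan if num == 0 else math.inf
    return num / den


def _iter_contigs(genome) -> Iterator[tuple[str, str]]:
    if isinstance(genome, str):
        from .io import read_fasta

        yield from read_fasta(genome)
    else:
        yield from genome
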