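"""Mismatch-tolerant off-target search for single and paired guides.

A monomeric Cas9 off-target needs one ~20-nt near-match with a valid PAM; a
dimeric FokI editor additionally needs a second near-match on the opposite
strand at a permissible dimer spacer, in PAM-out orientation. The matched
footprint is guide + spacer + guide (56 bp for 20-nt guides at a 16-bp
spacer), which is the geometric basis of the dimer's specificity: isolated
half-site matches are common, correctly spaced opposite-strand pairs are not.

Distances are Hamming (mismatches only, no bulges); the PAM is a hard
pattern constraint, never counted as a mismatch. Ambiguous genomic bases
mismatch everything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .pam import PamPattern, encode_sequence
from .scan import ProtospacerSite, _half_site_masks, _iter_contigs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OfftargetHit:
    """A half-site within the mismatch budget; PAM validity is implicit."""

    site: ProtospacerSite
    mismatches: int


@dataclass(frozen=True)
class PairedOfftargetHit:
    """Two half-site hits in PAM-out geometry at an allowed dimer spacer."""

    left_hit: OfftargetHit
    right_hit: OfftargetHit
    spacer_len: int
    total_mismatches: int


def _mismatch_profile(bits: np.ndarray, guide_bits: np.ndarray) -> np.ndarray:
    """Hamming distance of every length-g window of ``bits`` to the guide."""
    n, g = bits.size, guide_bits.size
    m = n - g + 1
    if m <= 0:
        return np.zeros(0, dtype=np.int16)
    mm = np.zeros(m, dtype=np.int16)
    for k in range(g):
        mm += (bits[k : k + m] & guide_bits[k]) == 0
    return mm


def _contig_hits(
    contig: str, seq: str, guide: str, pam: PamPattern, max_mm: int
) -> list[OfftargetHit]:
    up = seq.upper()
    bits = encode_sequence(up)
    g = len(guide)
    L = len(pam)
    plus_ok, minus_ok = _half_site_masks(bits, pam, g)
    m = bits.size - g + 1
    hits: list[OfftargetHit] = []
    if m > 0:
        mm_plus = _mismatch_profile(bits, encode_sequence(guide))
        sel = plus_ok[:m] & (mm_plus <= max_mm)
        for s in np.flatnonzero(sel):
            s = int(s)
            site = ProtospacerSite(contig, s, s + g, "+", up[s : s + g], up[s + g : s + g + L])
            hits.append(OfftargetHit(site, int(mm_plus[s])))
        mm_minus = _mismatch_profile(bits, encode_sequence(reverse_complement(guide)))
        sel = minus_ok[:m] & (mm_minus <= max_mm)
        for s in np.flatnonzero(sel):
            s = int(s)
            site = ProtospacerSite(
                contig, s, s + g, "-",
                reverse_complement(up[s : s + g]),
                reverse_complement(up[s - L : s]),
            )
            hits.append(OfftargetHit(site, int(mm_minus[s])))
    hits.sort(key=lambda h: (h.site.contig, h.site.start, h.site.strand))
    return hits


def single_guide_search(
    genome: "str | Iterable[tuple[str, str]]",
    guide: str,
    pam: PamPattern | str = "NGG",
    max_mm: int = 3,
) -> list[OfftargetHit]:
    """All half-sites on both strands within ``max_mm`` of ``guide``.

    ``genome`` is a FASTA path or (name, sequence) iterable. Hits are sorted
    by (contig, start).
    """
    guide = guide.upper()
    if set(guide) - set("ACGT"):
        raise ValueError("guide must be over {A,C,G,T}")
    if isinstance(pam, str):
        pam = PamPattern(pam)
    hits: list[OfftargetHit] = []
    for name, seq in _iter_contigs(genome):
        hits.extend(_contig_hits(name, seq, guide, pam, max_mm))
    hits.sort(key=lambda h: (h.site.contig, h.site.start, h.site.strand))
    return hits


def paired_search(
    genome: "str | Iterable[tuple[str, str]]",
    left_guide: str,
    right_guide: str,
    left_pam: PamPattern | str = "NNN",
    right_pam: PamPattern | str = "NNN",
    max_mm_each: int = 3,
    spacer_range: tuple[int, int] = (13, 18),
) -> list[PairedOfftargetHit]:
    """PAM-out pairs of half-site hits at an allowed dimer spacer.

    The left guide is matched to minus-strand half-sites, the right guide to
    plus-strand half-sites (their designed roles); each qualifying
    (left.start, right.start) pair is reported once.
    """
    if isinstance(left_pam, str):
        left_pam = PamPattern(left_pam)
    if isinstance(right_pam, str):
        right_pam = PamPattern(right_pam)
    g = len(left_guide)
    if len(right_guide) != g:
        raise ValueError("left and right guides must have equal length")
    lo, hi = spacer_range
    pairs: list[PairedOfftargetHit] = []
    for name, seq in _iter_contigs(genome):
        left_hits = [
            h for h in _contig_hits(name, seq, left_guide.upper(), left_pam, max_mm_each)
            if h.site.strand == "-"
        ]
        right_by_start = {
            h.site.start: h
            for h in _contig_hits(name, seq, right_guide.upper(), right_pam, max_mm_each)
            if h.site.strand == "+"
        }
        for lh in left_hits:
            for spacer in range(lo, hi + 1):
                rh = right_by_start.get(lh.site.end + spacer)
                if rh is not None:
                    pairs.append(
                        PairedOfftargetHit(lh, rh, spacer, lh.mismatches + rh.mismatches)
                    )
    pairs.sort(key=lambda p: (p.left_hit.site.contig, p.left_hit.site.start, p.right_hit.site.start))
    return pairs


def footprint_length(guide_len_left: int, guide_len_right: int, spacer_len: int) -> int:
    """Total matched footprint of a dimer: left guide + spacer + right guide."""
    if min(guide_len_left, guide_len_right, spacer_len) < 0:
        raise ValueError("lengths must be nonnegative")
    return guide_len_left + spacer_len + guide_len_right


def _hit_key(h) -> tuple[str, int, str]:
    if isinstance(h, OfftargetHit):
        s = h.site
        return (s.contig, s.start, s.strand)
    if isinstance(h, ProtospacerSite):
        return (h.contig, h.start, h.strand)
    contig, start, strand = h
    return (str(contig), int(start), str(strand))


def compare_hit_sets(a: Sequence, b: Sequence) -> dict:
    """Overlap summary of two hit lists keyed by (contig, start, strand).

    Accepts OfftargetHit objects, ProtospacerSites, or bare key tuples.
    Reports shared/a-only/b-only counts, the key sets, and the Jaccard index
    (1.0 when both sets are empty).
    """
    ka = {_hit_key(h) for h in a}
    kb = {_hit_key(h) for h in b}
    if ka and kb and not {k[0] for k in ka} & {k[0] for k in kb}:
        logger.warning("compare_hit_sets: contig names are disjoint — same genome?")
    shared = ka & kb
    union = ka | kb
    return {
        "shared": len(shared),
        "a_only": len(ka - kb),
        "b_only": len(kb - ka),
        "shared_keys": sorted(shared),
        "a_only_keys": sorted(ka - kb),
        "b_only_keys": sorted(kb - ka),
        "jaccard": len(shared) / len(union) if union else 1.0,
    }
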