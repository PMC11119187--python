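"""Amplicon indel quantification.

Dimeric FokI editors repair through NHEJ, so editing shows up as insertions
and deletions near the cut site, not base substitutions. Editing efficiency
of a read set is therefore the fraction of reads carrying at least one indel
overlapping a quantification window around the expected cut (the dimer
spacer extended a few bp each side).

Alignment is affine-gap global (Needleman-Wunsch) via Bio.Align; indel calls
are left-normalised so coordinates are deterministic regardless of how the
aligner breaks ties among equally scoring gap placements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring. A gap of length L scores open + (L-1)*extend.

    Defaults favour compact indels, the typical NHEJ outcome at a FokI cut.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class Alignment:
    """A gapped global alignment; removing '-' recovers the inputs."""

    aligned_ref: str
    aligned_read: str
    score: float


@dataclass(frozen=True)
class IndelCall:
    """One maximal gap run, left-normalised.

    ``ref_pos`` is the 0-based reference coordinate of the event's left edge:
    a deletion removes ref[ref_pos:ref_pos+length]; an insertion adds
    ``length`` bases immediately before ref_pos.
    """

    kind: str  # "insertion" | "deletion"
    ref_pos: int
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")


@dataclass(frozen=True)
class QuantWindow:
    """Half-open reference interval in which indels count as editing."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid window [{self.start}, {self.end})")


_aligner_cache: dict[AlignParams, Align.PairwiseAligner] = {}
# Alignments are memoised per (ref, read, params): library reads are highly
# duplicated (finite indel spectrum, low error rate), so this collapses most
# of the alignment cost.
_aln_cache: dict[tuple[str, str, AlignParams], Alignment] = {}


def _get_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = _aligner_cache.get(params)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
        aligner.open_gap_score = params.gap_open
        aligner.extend_gap_score = params.gap_extend
        _aligner_cache[params] = aligner
    return aligner


def global_align(read: str, ref: str, params: AlignParams = DEFAULT_PARAMS) -> Alignment:
    """Optimal affine-gap global alignment of ``read`` against ``ref``."""
    if not read or not ref:
        raise ValueError("global_align requires non-empty sequences")
    read = read.upper()
    ref = ref.upper()
    key = (ref, read, params)
    hit = _aln_cache.get(key)
    if hit is not None:
        return hit
    if read == ref:
        aln = Alignment(ref, read, params.match * len(ref))
    else:
        result = _get_aligner(params).align(ref, read)
        best = result[0]
        aln = Alignment(str(best[0]), str(best[1]), float(best.score))
    if len(_aln_cache) < 500_000:
        _aln_cache[key] = aln
    return aln


def call_indels(aln: Alignment) -> list[IndelCall]:
    """Convert maximal gap runs to reference-coordinate indel calls.

    Adjacent insertion and deletion columns stay separate calls (no
    complex-event merging). Calls are left-normalised against the reference
    so repeat-ambiguous placements are deterministic.
    """
    ref = aln.aligned_ref
    read = aln.aligned_read
    calls: list[IndelCall] = []
    ref_seq = ref.replace("-", "")
    ref_pos = 0
    i = 0
    n = len(ref)
    while i < n:
        if read[i] == "-":
            j = i
            while j < n and read[j] == "-":
                j += 1
            calls.append(_left_normalize("deletion", ref_pos, j - i, ref_seq, ref[i:j]))
            ref_pos += j - i
            i = j
        elif ref[i] == "-":
            j = i
            while j < n and ref[j] == "-":
                j += 1
            calls.append(_left_normalize("insertion", ref_pos, j - i, ref_seq, read[i:j]))
            i = j
        else:
            ref_pos += 1
            i += 1
    calls.sort(key=lambda c: (c.ref_pos, c.kind))
    return calls


def _left_normalize(kind: str, pos: int, length: int, ref_seq: str, event_seq: str) -> IndelCall:
    seq = list(event_seq)
    if kind == "deletion":
        while pos > 0 and ref_seq[pos - 1] == ref_seq[pos + length - 1]:
            pos -= 1
    else:
        while pos > 0 and seq and seq[-1] == ref_seq[pos - 1]:
            seq.insert(0, ref_seq[pos - 1])
            seq.pop()
            pos -= 1
    return IndelCall(kind, pos, length)


def is_edited(indels: Sequence[IndelCall], window: QuantWindow) -> bool:
    """True iff any indel overlaps the window.

    Deletions overlap as intervals [ref_pos, ref_pos+length); insertions
    count when their anchor lies in [start, end) — an insertion exactly at
    the window's right edge is outside it.
    """
    for c in indels:
        if c.kind == "deletion":
            if c.ref_pos < window.end and c.ref_pos + c.length > window.start:
                return True
        else:
            if window.start <= c.ref_pos < window.end:
                return True
    return False


@dataclass
class ReadCall:
    """Per-read editing decision (or the filter reason if discarded)."""

    read_id: str
    edited: bool | None
    indels: list[IndelCall] = field(default_factory=list)
    filtered: str | None = None


def classify_reads(
    reads: Iterable[tuple[str, str]],
    ref: str,
    window: QuantWindow,
    params: AlignParams = DEFAULT_PARAMS,
    min_len_frac: float = 0.5,
    min_score_density: float = 0.5,
) -> list[ReadCall]:
    """Align each read to ``ref`` and decide whether it is edited.

    Reads shorter than ``min_len_frac`` of the reference, or whose alignment
    score per read base falls below ``min_score_density``, are filtered out
    (flagged, excluded from any frequency denominator). Substitution-only
    reads are never edited.
    """
    ref = ref.upper()
    out: list[ReadCall] = []
    for rid, seq in reads:
        seq = seq.upper()
        if len(seq) < min_len_frac * len(ref):
            out.append(ReadCall(rid, None, filtered="short"))
            continue
        aln = global_align(seq, ref, params)
        if aln.score / len(seq) < min_score_density:
            out.append(ReadCall(rid, None, filtered="low_score"))
            continue
        calls = call_indels(aln)
        out.append(ReadCall(rid, is_edited(calls, window), calls))
    n_filtered = sum(1 for r in out if r.filtered)
    if n_filtered:
        logger.info("classify_reads: filtered %d/%d reads", n_filtered, len(out))
    return out


def indel_frequency(
    reads: Sequence[tuple[str, str]] | Sequence[str],
    ref: str,
    window: QuantWindow,
    params: AlignParams = DEFAULT_PARAMS,
    **kwargs,
) -> float:
    """Fraction of usable reads with an indel in the window.

    Accepts (read_id, seq) pairs or bare sequences. Raises ValueError on an
    empty read list; returns nan when every read was filtered out (no
    denominator).
    """
    reads = list(reads)
    if not reads:
        raise ValueError("indel_frequency requires at least one read")
    if reads and isinstance(reads[0], str):
        reads = [(f"read{i}", s) for i, s in enumerate(reads)]
    calls = classify_reads(reads, ref, window, params, **kwargs)
    used = [c for c in calls if c.filtered is None]
    if not used:
        return float("nan")
    return sum(c.edited for c in used) / len(used)


def default_quant_window(spacer_start: int, spacer_end: int, ref_len: int, pad: int = 3) -> QuantWindow:
    """The dimer-spacer interval extended ``pad`` bp each side, clipped to the reference."""
    return QuantWindow(max(0, spacer_start - pad), min(ref_len, spacer_end + pad))
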