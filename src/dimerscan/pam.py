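"""IUPAC PAM patterns and the five-way PAM classification.

SpCas9-family editors require a short protospacer-adjacent motif (PAM)
immediately 3' of the protospacer. Wild-type SpCas9 needs NGG; near-PAM-less
variants (SpRY-type) accept NRN/NYN, i.e. essentially any 3-mer. This module
provides degenerate-code matching for such patterns and the five-group
classification of 3-mer PAMs (NGG, NRR, NRY, NYR, NYY) used when stratifying
library editing efficiencies by PAM type.

Matching semantics: a genomic 'N' (ambiguous/assembly-gap base) never
satisfies any pattern position, including pattern 'N' — ambiguous regions
must not inflate site counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Base bitmasks. Genomic 'N' gets 0 so it intersects no pattern set.
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 0}
# Pattern codes and the base sets they accept. R = purine, Y = pyrimidine.
_IUPAC_BITS = {"A": 1, "C": 2, "G": 4, "T": 8, "R": 1 | 4, "Y": 2 | 8, "N": 15}

_COMPLEMENT_CODE = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "N": "N"}

#: The five disjoint PAM groups. NGG takes precedence over NRR even though
#: NGG is a subset of NRR, so the five labels partition all 64 3-mers.
PAM_CLASSES = ("NGG", "NRR", "NRY", "NYR", "NYY")

_PURINES = frozenset("AG")

# 256-entry lookup tables for fast byte-level encoding of sequences.
_SEQ_LUT = np.zeros(256, dtype=np.uint8)
for _b, _v in _BASE_BITS.items():
    _SEQ_LUT[ord(_b)] = _v
    _SEQ_LUT[ord(_b.lower())] = _v


@dataclass(frozen=True)
class PamPattern:
    """A degenerate PAM motif over the IUPAC codes {A, C, G, T, R, Y, N}.

    Stored uppercase; matching is case-insensitive. Typical patterns are
    3 nt (NGG, NRN, NNN) but any length is allowed.
    """

    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", self.pattern.upper())
        if not self.pattern:
            raise ValueError("empty PAM pattern")
        bad = set(self.pattern) - set(_IUPAC_BITS)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in PAM pattern: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pattern)

    def __str__(self) -> str:
        return self.pattern

    @property
    def bits(self) -> np.ndarray:
        """Per-position accepted-base bitmasks (uint8 array)."""
        return np.array([_IUPAC_BITS[c] for c in self.pattern], dtype=np.uint8)

    def reverse_complement(self) -> "PamPattern":
        return PamPattern("".join(_COMPLEMENT_CODE[c] for c in reversed(self.pattern)))

    def matches(self, seq: str) -> bool:
        return iupac_match(self, seq)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to per-base bitmasks (A=1, C=2, G=4, T=8, N=0).

    Case-insensitive; any byte outside {A,C,G,T,N} encodes to 0 and so
    behaves like an ambiguous base.
    """
    return _SEQ_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def iupac_match(pattern: PamPattern | str, seq: str) -> bool:
    """True iff ``seq`` satisfies ``pattern`` position by position.

    ``seq`` must have the same length as the pattern and be over
    {A, C, G, T, N}. A genomic 'N' fails every position.
    """
    if isinstance(pattern, str):
        pattern = PamPattern(pattern)
    if len(seq) != len(pattern):
        raise ValueError(
            f"sequence length {len(seq)} != pattern length {len(pattern)}"
        )
    up = seq.upper()
    bad = set(up) - set(_BASE_BITS)
    if bad:
        raise ValueError(f"invalid base(s) in sequence: {sorted(bad)}")
    return all(_BASE_BITS[b] & _IUPAC_BITS[c] for b, c in zip(up, pattern.pattern))


def classify_pam(seq3: str) -> str:
    """Assign an unambiguous 3-mer PAM to one of the five PAM groups.

    NGG (positions 2-3 both G) is split out first; the remaining 60 3-mers
    are grouped by purine/pyrimidine identity at positions 2 and 3, giving
    class sizes {NGG: 4, NRR: 12, NRY: 16, NYR: 16, NYY: 16}.
    """
    up = seq3.upper()
    if len(up) != 3 or set(up) - set("ACGT"):
        raise ValueError(f"classify_pam needs an unambiguous DNA 3-mer, got {seq3!r}")
    if up[1] == "G" and up[2] == "G":
        return "NGG"
    r2 = up[1] in _PURINES
    r3 = up[2] in _PURINES
    if r2 and r3:
        return "NRR"
    if r2:
        return "NRY"
    if r3:
        return "NYR"
    return "NYY"
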