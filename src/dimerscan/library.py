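"""Barcoded screening-library analysis.

Two library designs are supported, both built around one fixed guide pair:

* PAM library — the 6-nt regions flanking each protospacer (3-nt proximal
  PAM used for classification + 3 context bases) are randomised; barcodes at
  both amplicon ends identify the variant each read came from.
* Editing-window library — the 16-nt region between the two protospacers
  (where the FokI dimer cuts) is randomised.

Per-barcode editing efficiency is the fraction of that barcode's reads
carrying an indel in the quantification window. Efficiencies are then
grouped by PAM class (NGG/NRR/NRY/NYR/NYY) or summarised as position
frequency matrices (PFMs) with per-column information content, the matrix
underlying a sequence logo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .indel import AlignParams, DEFAULT_PARAMS, classify_reads, default_quant_window
from .pam import classify_pam

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class LibraryLayout:
    """Fixed amplicon architecture of a screening library.

    Plus-strand layout (5'->3'):

        BC_L | rc(left_pam6) | rc(left_guide) | insert | right_guide
             | right_pam6 | BC_R

    where ``insert`` is the dimer spacer (fixed in the PAM library,
    randomised 16-mer in the window library), and the left half-site sits on
    the minus strand (PAM-out geometry). PAM 6-mers are stored 5'->3' on
    their own strand, proximal PAM first.
    """

    bc_len: int = 8
    pam_len: int = 6
    guide_len: int = 20
    insert_len: int = 16
    quant_pad: int = 3

    @property
    def insert_start(self) -> int:
        return self.bc_len + self.pam_len + self.guide_len

    @property
    def insert_end(self) -> int:
        return self.insert_start + self.insert_len

    @property
    def amplicon_len(self) -> int:
        return 2 * (self.bc_len + self.pam_len + self.guide_len) + self.insert_len

    def quant_window(self):
        return default_quant_window(self.insert_start, self.insert_end, self.amplicon_len, self.quant_pad)


DEFAULT_LAYOUT = LibraryLayout()


@dataclass(frozen=True)
class BarcodeRecord:
    """One library member: a barcode pair plus its variable region.

    Exactly one of (left_pam6 & right_pam6) or window16 is set, depending on
    the library type. ``ref_amplicon`` is the full expected (unedited)
    sequence.
    """

    barcode_left: str
    barcode_right: str
    ref_amplicon: str
    left_pam6: str | None = None
    right_pam6: str | None = None
    window16: str | None = None

    def __post_init__(self) -> None:
        pam_mode = self.left_pam6 is not None and self.right_pam6 is not None
        win_mode = self.window16 is not None
        if pam_mode == win_mode:
            raise ValueError("record must carry either a PAM 6-mer pair or a window sequence")

    @property
    def key(self) -> tuple[str, str]:
        return (self.barcode_left, self.barcode_right)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[tuple[str, str]],
    table: Sequence[BarcodeRecord],
    max_mm: int = 0,
    bc_len: int | None = None,
) -> tuple[dict[tuple[str, str], list[tuple[str, str]]], list[tuple[str, str]]]:
    """Assign reads to barcode records by the barcodes at the read ends.

    The left barcode is read[:bc_len], the right barcode read[-bc_len:]
    (end-anchored, so internal indels do not shift it). A read is assigned
    to the unique record within ``max_mm`` mismatches at both barcodes; ties
    at the minimal total distance go to the unassigned bin.
    """
    table = list(table)
    if not table:
        raise ValueError("empty barcode table")
    if bc_len is None:
        bc_len = len(table[0].barcode_left)
    exact = {}
    for rec in table:
        if rec.key in exact:
            raise ValueError(f"duplicate barcode pair {rec.key}")
        exact[rec.key] = rec
    assigned: dict[tuple[str, str], list[tuple[str, str]]] = {rec.key: [] for rec in table}
    unassigned: list[tuple[str, str]] = []
    n_reads = 0
    for rid, seq in reads:
        n_reads += 1
        bcl, bcr = seq[:bc_len], seq[-bc_len:]
        rec = exact.get((bcl, bcr))
        if rec is None and max_mm > 0:
            best, best_d, tie = None, None, False
            for cand in table:
                dl = _hamming(bcl, cand.barcode_left)
                if dl > max_mm:
                    continue
                dr = _hamming(bcr, cand.barcode_right)
                if dr > max_mm:
                    continue
                d = dl + dr
                if best_d is None or d < best_d:
                    best, best_d, tie = cand, d, False
                elif d == best_d:
                    tie = True
            if best is not None and not tie:
                rec = best
        if rec is None:
            unassigned.append((rid, seq))
        else:
            assigned[rec.key].append((rid, seq))
    logger.info(
        "demultiplex: %d reads, %d unassigned (max_mm=%d)", n_reads, len(unassigned), max_mm
    )
    return assigned, unassigned


def compute_editing_stats(
    reads: Iterable[tuple[str, str]],
    table: Sequence[BarcodeRecord],
    layout: LibraryLayout = DEFAULT_LAYOUT,
    max_mm: int = 1,
    params: AlignParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Demultiplex, quantify editing per barcode, and classify PAMs.

    Returns one row per barcode record: read counts, edited counts,
    efficiency (nan when the record got no usable reads), and — for PAM
    libraries — the PAM class of each side, assigned from the proximal 3-mer
    of the 6-nt region.
    """
    assigned, _ = demultiplex(reads, table, max_mm=max_mm, bc_len=layout.bc_len)
    window = layout.quant_window()
    rows = []
    for rec in table:
        rec_reads = assigned[rec.key]
        calls = classify_reads(rec_reads, rec.ref_amplicon, window, params)
        used = [c for c in calls if c.filtered is None]
        n_edited = sum(c.edited for c in used)
        row = {
            "barcode_left": rec.barcode_left,
            "barcode_right": rec.barcode_right,
            "n_reads": len(used),
            "n_edited": n_edited,
            "efficiency": n_edited / len(used) if used else float("nan"),
        }
        if rec.window16 is not None:
            row["window16"] = rec.window16
        else:
            row["left_pam6"] = rec.left_pam6
            row["right_pam6"] = rec.right_pam6
            row["left_class"] = classify_pam(rec.left_pam6[:3])
            row["right_class"] = classify_pam(rec.right_pam6[:3])
        rows.append(row)
    return pd.DataFrame(rows)


def pam_group_table(
    stats: pd.DataFrame,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-PAM-class efficiency summary for the left and right sides.

    Reports n, mean, median and a percentile bootstrap CI of the mean for
    each (side, class); empty classes appear with n=0 rather than erroring.
    """
    rng = np.random.default_rng(seed)
    alpha = (1 - ci) / 2
    rows = []
    from .pam import PAM_CLASSES

    for side in ("left", "right"):
        col = f"{side}_class"
        for cls in PAM_CLASSES:
            eff = stats.loc[stats[col] == cls, "efficiency"].dropna().to_numpy()
            if eff.size == 0:
                rows.append(
                    {"side": side, "pam_class": cls, "n": 0, "mean": np.nan,
                     "median": np.nan, "ci_lo": np.nan, "ci_hi": np.nan}
                )
                continue
            boots = rng.choice(eff, size=(n_boot, eff.size), replace=True).mean(axis=1)
            rows.append(
                {
                    "side": side,
                    "pam_class": cls,
                    "n": int(eff.size),
                    "mean": float(eff.mean()),
                    "median": float(np.median(eff)),
                    "ci_lo": float(np.quantile(boots, alpha)),
                    "ci_hi": float(np.quantile(boots, 1 - alpha)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PFM:
    """A position frequency matrix with per-column information content.

    ``freqs`` is 4 x W (rows A, C, G, T); each column sums to 1 where the
    column has weight. ``ic`` is 2 - Shannon entropy per column, in bits
    (0 = no positional bias, 2 = a fixed base).
    """

    freqs: np.ndarray
    ic: np.ndarray
    total_weight: float
    n_sequences: int

    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs, index=list(_BASES))
        df.loc["IC"] = self.ic
        return df


def build_pfm(seqs: Sequence[str], weights: Sequence[float] | None = None) -> PFM:
    """Weighted base frequencies per column over equal-length sequences."""
    if not seqs:
        raise ValueError("build_pfm requires at least one sequence")
    W = len(seqs[0])
    if any(len(s) != W for s in seqs):
        raise ValueError("sequences must have equal length")
    if weights is None:
        w = np.ones(len(seqs))
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(seqs) or (w < 0).any():
            raise ValueError("weights must be nonnegative, one per sequence")
        if w.sum() == 0:
            raise ValueError("weights must not all be zero")
    counts = np.zeros((4, W))
    for s, wi in zip(seqs, w):
        if wi == 0:
            continue
        for j, b in enumerate(s.upper()):
            counts[_BASE_IDX[b], j] += wi
    col = counts.sum(axis=0)
    freqs = counts / np.where(col > 0, col, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return PFM(freqs=freqs, ic=ic, total_weight=float(w.sum()), n_sequences=len(seqs))


def pam_context_motifs(
    stats: pd.DataFrame, weighting: str = "efficiency"
) -> tuple[PFM, PFM] | None:
    """PFMs of the left and right PAM 6-mers over edited records.

    Records with at least one edited read contribute; with
    ``weighting='efficiency'`` each record's 6-mer is weighted by its
    editing efficiency, with ``'uniform'`` all edited records weigh equally.
    Returns None when no record has edited reads (no motif to build).
    """
    if weighting not in ("efficiency", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    edited = stats[stats["n_edited"] > 0]
    if edited.empty:
        logger.warning("pam_context_motifs: no edited records")
        return None
    w = edited["efficiency"].to_numpy() if weighting == "efficiency" else None
    left = build_pfm(edited["left_pam6"].tolist(), w)
    right = build_pfm(edited["right_pam6"].tolist(), w)
    return left, right


@dataclass
class WindowMotifResult:
    """Overall editing-window PFM plus per-efficiency-stratum PFMs."""

    overall: PFM
    strata: list[tuple[str, int, PFM | None]]


def window_motif(
    stats: pd.DataFrame, n_strata: int = 4, weighting: str = "efficiency"
) -> WindowMotifResult | None:
    """Editing-window motif, overall and stratified by efficiency.

    Strata are quantile bins (default quartiles) of the nonzero-efficiency
    records, labelled q1 (lowest) .. qN (highest); a stratum that ends up
    empty is reported with n=0 and no PFM. Returns None when nothing was
    edited.
    """
    if weighting not in ("efficiency", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    edited = stats[stats["n_edited"] > 0]
    if edited.empty:
        logger.warning("window_motif: no edited records")
        return None
    w = edited["efficiency"].to_numpy() if weighting == "efficiency" else None
    overall = build_pfm(edited["window16"].tolist(), w)
    eff = edited["efficiency"].to_numpy()
    edges = np.quantile(eff, np.linspace(0, 1, n_strata + 1))
    strata: list[tuple[str, int, PFM | None]] = []
    for i in range(n_strata):
        lo, hi = edges[i], edges[i + 1]
        if i < n_strata - 1:
            sel = (eff >= lo) & (eff < hi)
        else:
            sel = (eff >= lo) & (eff <= hi)
        seqs = edited.loc[sel, "window16"].tolist()
        label = f"q{i + 1}"
        strata.append((label, len(seqs), build_pfm(seqs) if seqs else None))
    return WindowMotifResult(overall=overall, strata=strata)
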