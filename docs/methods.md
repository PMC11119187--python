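# Methods

## The editor model

A dimeric FokI-dCas9 editor consists of two FokI-dCas9 monomers, each
directed by its own 20-nt guide. Cleavage requires both monomers bound in
**PAM-out** orientation: the left half-site on the minus strand (its PAM
genomically leftmost), the right half-site on the plus strand (PAM
rightmost), with a **dimer spacer** — the gap between the inner protospacer
edges — inside which FokI dimerises and cuts. The matched footprint is
therefore `guide_len + spacer + guide_len`; 56 bp for two 20-nt guides at a
16-bp spacer, versus the 20 bp a monomeric nuclease needs. Throughout the
package "spacer" means this inter-protospacer gap, never the guide sequence
itself.

The near-PAM-less variant is modelled as PAM pattern `NNN` (the union of NRN
and NYN); the classic dual-NGG editor as `NGG` at both half-sites. An
`--nrn-only`-style restriction is available by passing `NRN`, reflecting the
higher activity such variants show on purine-second PAMs.

## Coordinates, matching, and classification

All intervals are 0-based half-open; the protospacer interval excludes the
PAM, which sits at `[end, end+3)` on `+` and `[start-3, start)` on `-`.
IUPAC matching treats a genomic `N` as matching nothing — including pattern
`N` — so assembly gaps cannot inflate site counts. Soft-masked lowercase is
uppercased before matching.

3-mer PAMs are partitioned into five classes by the second and third
positions: NGG first (although NGG ⊂ NRR, it is split out so the five labels
are disjoint: sizes 4/12/16/16/16 over the 64 3-mers), then purine/pyrimidine
identity. Classification of a 6-nt PAM region uses the proximal 3-mer;
positions 4–6 are downstream context carried only in motifs.

## Scanning and counting

Site enumeration is vectorised over per-position PAM-match bitmasks, so
megabase contigs scan in milliseconds; `count_paired_sites` counts left/right
mask coincidences per allowed spacer offset without materialising site
objects. Contigs are independent; pairs never span contigs; every distinct
(left.start, right.start) pair counts once — available loci are guide-pair
design choices, so overlapping pairs are all kept. The default counting
spacer range is 13–18 bp, with (16, 16) as the optimal-design setting. On
i.i.d. uniform sequence the paired-density ratio between `NNN` and `NGG`
rules is the squared PAM-density ratio, 256, which the test suite verifies
within Monte-Carlo error; the corresponding comparison on a real genome is
the editor-to-editor target-space ratio. `target_ratio` with an empty
denominator returns `inf` (or `nan` for 0/0) with a logged warning rather
than raising: it is a degenerate comparison, not a programming error.

A `pam-in` orientation flag exists for exploratory scans; all defaults and
all analyses use PAM-out, the dimer architecture.

## Alignment and indel calling

Reads are aligned globally with affine gaps (match +2, mismatch −1, gap open
−5, gap extend −1; a length-L gap costs open + (L−1)·extend). The scoring
favours compact indels, the typical NHEJ outcome. The aligner is Biopython's
`PairwiseAligner`; determinism across platforms is guaranteed not by the
aligner's tie-break but by **left-normalising** every indel call against the
reference (the VCF-style shift through repeat runs), so equivalent gap
placements collapse to one canonical coordinate. Adjacent insertion and
deletion runs remain separate calls; no complex-event merging.

A read is **edited** iff at least one indel overlaps the quantification
window: deletions as intervals, insertions by their left-edge anchor, with
half-open conventions (an insertion exactly at the window's right edge is
outside). Substitutions never count — the editor's repair signature is
indels. The default window is the dimer-spacer interval padded ±3 bp, since
FokI cuts within the spacer. Reads shorter than 50 % of the reference or
with alignment score density below 0.5 per base are filtered out of both
numerator and denominator (and logged). `indel_frequency` raises on an empty
read list and returns `nan` when every read was filtered. Alignments are
memoised per (reference, read, parameters): library reads are highly
duplicated, which collapses most of the alignment cost.

## Library analysis

The synthetic amplicon architecture (the real construct layout is not
public, so the package defines its own, configurable via `LibraryLayout`) is

```
BC_L(8) | rc(left_pam6) | rc(left_guide) | insert(16) | right_guide | right_pam6 | BC_R(8)
```

with PAM 6-mers stored 5′→3′ on their own strand, proximal PAM first. The
insert is the fixed dimer spacer in the PAM library and the randomised
16-mer in the editing-window library; both libraries share one guide pair.

Demultiplexing reads barcodes at the two read ends (the right barcode
end-anchored, so internal indels do not shift it); a read is assigned to the
unique record within the mismatch budget at both barcodes, with minimal-
distance ties going to the unassigned bin. Efficiencies are per-barcode
proportions of edited reads. Group summaries report mean, median, n, and a
percentile bootstrap 95 % CI of the mean (1000 resamples, seeded) — a
deliberate choice over parametric tests, since the per-barcode efficiency
distribution is bounded and small-n.

PFMs are weighted per-column base frequencies; information content is
2 − Shannon entropy in bits. PAM-context motifs are built over records with
at least one edited read, weighted by efficiency by default (an unweighted
edited-records mode is provided; the two answer slightly different
questions and both are exposed because the choice is genuinely open).
Window motifs are additionally stratified into efficiency quantile bins
(default quartiles) of the edited records; empty strata are reported with
n = 0. No edited records at all yields `None` — an explicit empty-motif
signal.

## Off-target search

Distances are Hamming only — no DNA/RNA bulges — matching the mismatch
model of the standard enumeration tools in this space; the PAM is a hard
pattern constraint and never counted as a mismatch. The paired search keeps
each guide in its designed role (left guide → minus-strand half-site, right
guide → plus-strand half-site); the swapped arrangement is not searched by
default. Both searches are verified against quadratic brute-force oracles in
the test suite.

## Synthetic data

Generators use numpy PCG64 streams keyed by explicit seeds; identical
(parameters, seed) regenerate byte-identical outputs. Defaults:

* genomes: i.i.d. bases, GC 0.5 (the uniform condition under which the
  analytic density calibrations hold); human-like GC is a parameter away.
* indel spectrum: 80 % deletions with truncated-geometric lengths (p = 0.3,
  max 10 bp), 20 % insertions of 1–3 bp, left edge uniform within ±4 bp of
  the mid-spacer cut centre — a generic NHEJ-at-a-FokI-cut shape, fully
  configurable since no empirical spectrum is assumed.
* sequencing error: 0.1 % substitutions, no indel errors, keeping the
  edited/unedited decision crisp.
* planted features (paired sites, off-target half-sites) are non-overlapping
  by construction so recall is exactly countable, and truth records carry
  every coordinate.
* the balanced PAM library draws both proximal 3-mers from the same class
  per record (40 records per class by default); an unpaired mode samples the
  two sides independently, which is what one-sided spike-in experiments
  need — under the paired design a one-sided efficiency bias leaks into the
  other side's motif through the class pairing.
* the window-screen recipe draws per-record efficiencies from Beta(2, 4)
  (mean ⅓, realistic spread) so that efficiency stratification is
  meaningful while remaining sequence-independent.

**What the synthetic data does not emulate:** real genome composition
(repeats, GC structure — so locus counts and ratios on random sequence are
calibrations, not genome predictions), base-quality profiles, PCR
duplicates, chimeric reads, bulge-mediated off-targets, and cell-biology
covariates (chromatin, delivery). Passing tests demonstrate that the
algorithms recover known truth under the stated read model, not that any
particular editor behaves this way in cells.

## Desk-scale run sizes

The acceptance script and test suite use 1-Mb genomes (3 seeds), a
200-barcode × 200-read PAM screen, 2000-record motif screens at 20 reads
per record, and a planted off-target landscape of nine half-sites per guide
plus one genuine pair. These sizes put every statistical check comfortably
inside its tolerance (binomial CIs of ±0.01 on efficiencies; Monte-Carlo
error of ~1 % on density ratios) while the whole suite runs in well under a
minute.

## Known limitations

* Off-target search loads one contig at a time into memory; fine up to
  hundreds of Mb per contig, not tuned for streaming beyond that.
* The paired off-target search reports designed-role pairs only; add the
  swapped-role search by calling it twice with guides exchanged.
* Bootstrap CIs are percentile CIs; for very small groups (n < 10) they are
  anti-conservative, and the group tables report n so users can judge.
* The indel caller is deliberately simple (no quality weighting, no complex
  event merging); it is a quantification tool for amplicons with a known
  cut site, not a general variant caller.
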