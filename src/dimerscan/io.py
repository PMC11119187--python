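"""File I/O helpers: FASTA/FASTQ (plain or gzip), BED, and TSV outputs."""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scan import PairedSite, ProtospacerSite


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) per contig from a FASTA file (gzip ok)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def write_fasta(path: str | Path, contigs: Iterable[tuple[str, str]]) -> None:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs)
    with _open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file (gzip ok)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], quality: int = 37) -> None:
    """Write (read_id, sequence) pairs with a constant per-base quality."""
    with _open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def write_sites_bed(path: str | Path, sites: Iterable[ProtospacerSite]) -> None:
    """BED6 per half-site; name column carries the protospacer sequence."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.protospacer}\t0\t{s.strand}\n")


def write_pairs_tsv(path: str | Path, pairs: Iterable[PairedSite]) -> None:
    cols = "contig\tleft_start\tleft_end\tright_start\tright_end\tspacer_len\tleft_pam\tright_pam\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for p in pairs:
            fh.write(
                f"{p.left.contig}\t{p.left.start}\t{p.left.end}\t{p.right.start}\t"
                f"{p.right.end}\t{p.spacer_len}\t{p.left.pam}\t{p.right.pam}\n"
            )


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_barcode_table(path: str | Path) -> list:
    """Read a barcode table TSV into BarcodeRecords.

    Required columns: barcode_left, barcode_right, ref_amplicon, plus either
    (left_pam6, right_pam6) or window16.
    """
    import pandas as pd

    from .library import BarcodeRecord

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"barcode_left", "barcode_right", "ref_amplicon"}
    if missing := required - set(df.columns):
        raise ValueError(f"barcode table missing column(s): {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs = dict(
            barcode_left=row["barcode_left"],
            barcode_right=row["barcode_right"],
            ref_amplicon=row["ref_amplicon"],
        )
        if "window16" in df.columns and isinstance(row.get("window16"), str):
            kwargs["window16"] = row["window16"]
        else:
            kwargs["left_pam6"] = row["left_pam6"]
            kwargs["right_pam6"] = row["right_pam6"]
        records.append(BarcodeRecord(**kwargs))
    return records


def write_barcode_table(path: str | Path, records) -> None:
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "barcode_left": r.barcode_left,
            "barcode_right": r.barcode_right,
            "ref_amplicon": r.ref_amplicon,
        }
        if r.window16 is not None:
            row["window16"] = r.window16
        else:
            row["left_pam6"] = r.left_pam6
            row["right_pam6"] = r.right_pam6
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_site_keys(path: str | Path) -> list[tuple[str, int, str]]:
    """(contig, start, strand) keys from a BED6 or headered TSV of sites."""
    import pandas as pd

    with open(path) as fh:
        first = fh.readline()
    if "start" in first and "contig" in first or "chrom" in first:
        df = pd.read_csv(path, sep="\t")
        chrom_col = "contig" if "contig" in df.columns else "chrom"
        return [(str(r[chrom_col]), int(r["start"]), str(r.get("strand", "+"))) for _, r in df.iterrows()]
    keys = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            keys.append((f[0], int(f[1]), f[5] if len(f) > 5 else "+"))
    return keys
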