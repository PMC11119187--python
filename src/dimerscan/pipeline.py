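"""End-to-end desk-scale recipes and their run configuration.

Each recipe chains the library: synthetic input generation, the analysis
method, and TSV/JSON outputs plus a manifest echoing the effective
configuration, so a run is regenerable from (config, seeds) alone.

Recipes:

* ``locus_ratio``        — paired-locus counts under two PAM rules and their
                           ratio (near-PAM-less vs dual-NGG).
* ``pam_screen``         — simulated PAM library: per-class efficiency table
                           and PAM-context motifs.
* ``window_screen``      — simulated editing-window library: overall and
                           per-efficiency-stratum window motifs.
* ``paired_offtarget``   — planted off-target landscape: single-guide vs
                           paired-guide hit counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import write_json
from .library import (
    DEFAULT_LAYOUT,
    compute_editing_stats,
    pam_context_motifs,
    pam_group_table,
    window_motif,
)
from .offtarget import paired_search, single_guide_search
from .scan import ScanRule, count_paired_sites, count_single_sites
from .simulate import (
    make_pam_library,
    make_window_library,
    plant_paired_sites,
    random_genome,
    simulate_library_reads,
    simulate_offtargets,
)

RECIPES = ("locus_ratio", "pam_screen", "window_screen", "paired_offtarget")


@dataclass
class RunConfig:
    """Effective parameters of a recipe run; fully serialisable.

    ``genome`` may point at a FASTA; when None a seeded random genome of
    ``genome_len`` bp is generated. PAM rules use IUPAC strings.
    """

    seed: int = 0
    out_dir: str = "dimerscan_out"
    genome: str | None = None
    genome_len: int = 1_000_000
    gc_fraction: float = 0.5
    guide_len: int = 20
    spacer_range: tuple[int, int] = (13, 18)
    pam_a: str = "NNN"  # numerator rule (near-PAM-less dimer)
    pam_b: str = "NGG"  # denominator rule (dual-NGG dimer)
    n_per_class: int = 40
    n_window_records: int = 200
    n_reads_per_record: int = 200
    true_efficiency: float = 0.3
    max_barcode_mm: int = 1
    weighting: str = "efficiency"
    n_strata: int = 4
    max_mm: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.spacer_range = tuple(cfg.spacer_range)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spacer_range"] = list(self.spacer_range)
        return d


def _load_genome(cfg: RunConfig) -> list[tuple[str, str]]:
    if cfg.genome is not None:
        from .io import read_fasta

        return list(read_fasta(cfg.genome))
    return [("synth1", random_genome(cfg.genome_len, cfg.gc_fraction, cfg.seed))]


def _write_manifest(out: Path, name: str, cfg: RunConfig) -> None:
    write_json(out / "manifest.json", {"recipe": name, "version": __version__, "config": cfg.to_dict()})


def recipe_locus_ratio(cfg: RunConfig, out: Path) -> dict:
    genome = _load_genome(cfg)
    rule_a = ScanRule(cfg.pam_a, cfg.pam_a, cfg.guide_len, cfg.spacer_range)
    rule_b = ScanRule(cfg.pam_b, cfg.pam_b, cfg.guide_len, cfg.spacer_range)
    count_a = sum(count_paired_sites(s, rule_a) for _, s in genome)
    count_b = sum(count_paired_sites(s, rule_b) for _, s in genome)
    singles_b = sum(count_single_sites(s, cfg.pam_b, cfg.guide_len) for _, s in genome)
    summary = {
        "genome_bp": sum(len(s) for _, s in genome),
        "paired_count_a": count_a,
        "paired_count_b": count_b,
        "single_count_b": singles_b,
        "paired_ratio_a_over_b": count_a / count_b if count_b else None,
        "single_b_over_paired_b": singles_b / count_b if count_b else None,
        "rule_a": {"pam": cfg.pam_a, "spacer_range": list(cfg.spacer_range)},
        "rule_b": {"pam": cfg.pam_b, "spacer_range": list(cfg.spacer_range)},
    }
    write_json(out / "locus_ratio.json", summary)
    return summary


def _pfm_tsv(pfm, path: Path) -> None:
    pfm.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def recipe_pam_screen(cfg: RunConfig, out: Path) -> dict:
    table = make_pam_library(cfg.n_per_class, seed=cfg.seed)
    reads, truth = simulate_library_reads(
        table, cfg.true_efficiency, cfg.n_reads_per_record, seed=cfg.seed + 1
    )
    stats = compute_editing_stats(reads, table, max_mm=cfg.max_barcode_mm)
    stats.to_csv(out / "editing_stats.tsv", sep="\t", index=False, float_format="%.6f")
    truth.records.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6f")
    groups = pam_group_table(stats, seed=cfg.seed)
    groups.to_csv(out / "pam_groups.tsv", sep="\t", index=False, float_format="%.6f")
    motifs = pam_context_motifs(stats, weighting=cfg.weighting)
    summary = {
        "n_records": len(table),
        "n_reads": len(reads),
        "mean_efficiency": float(stats["efficiency"].mean()),
        "group_means": {
            f"{r.side}_{r.pam_class}": None if np.isnan(r["mean"]) else float(r["mean"])
            for _, r in groups.iterrows()
        },
    }
    if motifs is not None:
        left, right = motifs
        _pfm_tsv(left, out / "pfm_left_pam.tsv")
        _pfm_tsv(right, out / "pfm_right_pam.tsv")
        summary["max_ic_left"] = float(left.ic.max())
        summary["max_ic_right"] = float(right.ic.max())
    write_json(out / "pam_screen.json", summary)
    return summary


def recipe_window_screen(cfg: RunConfig, out: Path) -> dict:
    table = make_window_library(cfg.n_window_records, seed=cfg.seed)
    # Sequence-independent cleavage with realistic barcode-to-barcode spread.
    rng = np.random.default_rng(cfg.seed + 7)
    eff = {rec.key: float(rng.beta(2, 4)) for rec in table}
    reads, truth = simulate_library_reads(table, lambda r: eff[r.key], cfg.n_reads_per_record, seed=cfg.seed + 1)
    stats = compute_editing_stats(reads, table, max_mm=cfg.max_barcode_mm)
    stats.to_csv(out / "editing_stats.tsv", sep="\t", index=False, float_format="%.6f")
    truth.records.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6f")
    result = window_motif(stats, n_strata=cfg.n_strata, weighting=cfg.weighting)
    summary = {"n_records": len(table), "n_reads": len(reads),
               "mean_efficiency": float(stats["efficiency"].mean())}
    if result is not None:
        _pfm_tsv(result.overall, out / "pfm_window.tsv")
        summary["max_ic_window"] = float(result.overall.ic.max())
        strata = {}
        for label, n, pfm in result.strata:
            if pfm is not None:
                _pfm_tsv(pfm, out / f"pfm_window_{label}.tsv")
            strata[label] = {"n": n, "max_ic": float(pfm.ic.max()) if pfm is not None else None}
        summary["strata"] = strata
    write_json(out / "window_screen.json", summary)
    return summary


def recipe_paired_offtarget(cfg: RunConfig, out: Path) -> dict:
    """Emulates a worst-case guide pair: both guides have scattered genomic
    near-copies (1-3 mismatches), but only the on-target locus pairs up."""
    seq = random_genome(cfg.genome_len, cfg.gc_fraction, cfg.seed)
    rule = ScanRule(cfg.pam_a, cfg.pam_a, cfg.guide_len, (16, 16))
    seq, planted = plant_paired_sites(seq, 1, rule, seed=cfg.seed + 1)
    lg, rg = planted[0]["left_guide"], planted[0]["right_guide"]
    mm_counts = [1, 2, 3] * 3
    seq, _ = simulate_offtargets(seq, lg, mm_counts, pam=cfg.pam_a, seed=cfg.seed + 2)
    seq, _ = simulate_offtargets(seq, rg, mm_counts, pam=cfg.pam_a, seed=cfg.seed + 3)
    genome = [("synth1", seq)]
    single_left = single_guide_search(genome, lg, cfg.pam_a, cfg.max_mm)
    single_right = single_guide_search(genome, rg, cfg.pam_a, cfg.max_mm)
    paired = paired_search(genome, lg, rg, cfg.pam_a, cfg.pam_a, cfg.max_mm, cfg.spacer_range)
    summary = {
        "genome_bp": len(seq),
        "single_hits_left": len(single_left),
        "single_hits_right": len(single_right),
        "paired_hits": len(paired),
        "max_mm": cfg.max_mm,
        "spacer_range": list(cfg.spacer_range),
    }
    write_json(out / "paired_offtarget.json", summary)
    return summary


_RECIPE_FUNCS = {
    "locus_ratio": recipe_locus_ratio,
    "pam_screen": recipe_pam_screen,
    "window_screen": recipe_window_screen,
    "paired_offtarget": recipe_paired_offtarget,
}


def run_recipe(name: str, cfg: RunConfig) -> dict:
    """Run one named recipe; outputs land in ``cfg.out_dir``."""
    if name not in _RECIPE_FUNCS:
        raise ValueError(f"unknown recipe {name!r}; choose from {RECIPES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_manifest(out, name, cfg)
    return _RECIPE_FUNCS[name](cfg, out)
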