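"""End-to-end orchestration: scan a cohort VCF, rank windows, annotate.

Every externally visible number — filter thresholds, the computed per-sample
depth ceilings, the window GC cutoff — is logged and written into a
machine-readable run manifest together with input checksums, so a run can be
audited and reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pyfaidx
import yaml

from . import io as sio
from .core_stats import FilterConfig, gc_fraction
from .window_scan import (
    ScanResult,
    apply_gc_filter,
    assign_empirical_p,
    info_diagnostic,
    make_windows,
    scan_records,
)

logger = logging.getLogger("sweepscan")

__all__ = ["RunConfig", "load_run_config", "scan_pipeline", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one scan run (paths + thresholds + window layout)."""

    vcf: str
    focal_samples: list[str]
    divergence_sample: str
    out_dir: str
    reference: Optional[str] = None
    genes: Optional[str] = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    window_bp: int = 100_000
    step_bp: Optional[int] = None
    alpha: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.focal_samples:
            raise ValueError("focal_samples must be non-empty")
        for attr in ("vcf", "reference", "genes"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    filters = FilterConfig.from_dict(raw.pop("filters", {}))
    return RunConfig(filters=filters, **raw)


def window_gc_from_fasta(fasta_path, windows) -> dict:
    """Reference GC fraction per window, via the indexed FASTA."""
    fa = pyfaidx.Fasta(str(fasta_path))
    out = {}
    for w in windows:
        seq = str(fa[w.chrom][w.start:w.end])
        out[w] = gc_fraction(seq)
    return out


def scan_pipeline(config: RunConfig) -> tuple[ScanResult, dict]:
    """Run the windowed theta/D scan on a VCF and rank the windows.

    Returns the scan result (window stats with empirical p-values filled)
    and the run manifest dictionary.  Writes ``windows.tsv`` and
    ``manifest.json`` under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    filt = config.filters
    relevant = list(dict.fromkeys(
        list(config.focal_samples) + [config.divergence_sample]
    ))

    chrom_lengths = sio.vcf_chrom_lengths(config.vcf)
    logger.info("contigs: %s", chrom_lengths)

    ceilings = sio.depth_ceilings_from_vcf(
        config.vcf, relevant, filt.max_depth_quantile
    )
    logger.info(
        "depth ceilings (q=%.2f): %s", filt.max_depth_quantile, ceilings
    )
    logger.info(
        "site filters: min_depth=%d min_site_qual=%g min_GQ=%d "
        "biallelic=%s min_callable_bp=%d",
        filt.min_depth, filt.min_site_qual, filt.min_genotype_quality,
        filt.require_biallelic, filt.min_callable_bp,
    )

    result = scan_records(
        sio.read_all_sites_vcf(config.vcf, relevant),
        config.focal_samples,
        config.divergence_sample,
        filt,
        ceilings,
        chrom_lengths,
        config.window_bp,
        config.step_bp,
    )
    result.depth_ceilings = ceilings
    logger.info("filter tally: %s", dict(result.filter_tally))

    gc_cutoff = None
    n_gc_dropped = 0
    if config.reference is not None:
        gc = window_gc_from_fasta(
            config.reference, [s.window for s in result.stats]
        )
        kept, dropped, gc_cutoff = apply_gc_filter(
            result.stats, gc, filt.max_gc_quantile
        )
        result.stats = kept
        result.gc_cutoff = gc_cutoff
        n_gc_dropped = len(dropped)
        logger.info(
            "GC filter: cutoff=%.4f (q=%.2f), dropped %d windows",
            gc_cutoff, filt.max_gc_quantile, n_gc_dropped,
        )

    assign_empirical_p(result.stats)
    windows_tsv = out_dir / "windows.tsv"
    sio.write_window_table(result.stats, windows_tsv)
    logger.info(
        "retained %d windows (%d discarded for L < %d)",
        len(result.stats), result.n_windows_discarded, filt.min_callable_bp,
    )

    manifest = {
        "inputs": {
            name: {"path": str(p), "md5": sio.file_md5(p)}
            for name, p in (
                ("vcf", config.vcf),
                ("reference", config.reference),
                ("genes", config.genes),
            )
            if p is not None
        },
        "focal_samples": list(config.focal_samples),
        "divergence_sample": config.divergence_sample,
        "filters": dataclasses.asdict(filt),
        "window_bp": config.window_bp,
        "step_bp": config.step_bp or config.window_bp,
        "alpha": config.alpha,
        "seed": config.seed,
        "depth_ceilings": ceilings,
        "gc_cutoff": gc_cutoff,
        "filter_tally": dict(result.filter_tally),
        "n_windows_total": result.n_windows_total,
        "n_windows_discarded_low_L": result.n_windows_discarded,
        "n_windows_dropped_high_gc": n_gc_dropped,
        "n_windows_retained": len(result.stats),
        "outputs": {"windows": str(windows_tsv)},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return result, manifest


def run_pipeline(config: RunConfig) -> dict:
    """scan -> annotate -> diagnose; returns the final manifest."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    result, manifest = scan_pipeline(config)

    if config.genes is not None:
        from .annotate import candidate_gene_table, read_genes_bed, read_genes_gff3

        if str(config.genes).endswith((".gff", ".gff3")):
            genes = read_genes_gff3(config.genes)
        else:
            genes = read_genes_bed(config.genes)
        table = candidate_gene_table(result.stats, genes, config.alpha)
        table.to_csv(out_dir / "candidate_genes.tsv", sep="\t", index=False)
        manifest["n_candidate_genes"] = int(len(table))
        logger.info(
            "%d candidate genes at empirical p < %g", len(table), config.alpha
        )

    try:
        rho, table = info_diagnostic(result.stats)
        table.to_csv(out_dir / "info_diagnostic.tsv", sep="\t", index=False)
        manifest["info_diagnostic_spearman_rho"] = rho
        logger.info("info diagnostic: Spearman rho(ratio, L) = %.4f", rho)
    except ValueError as exc:
        logger.warning("info diagnostic skipped: %s", exc)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
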