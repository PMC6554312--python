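"""Readers and writers for the formats the pipeline touches.

VCF input goes through pysam; only SNV records with GT/DP/GQ FORMAT fields
are consumed (indels and symbolic alleles are skipped with a count).  The
window table is a fixed-header TSV whose first three columns are
BED-compatible; missing values are serialized as "NA".
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam

from .core_stats import FilterConfig, GenotypeCall, SiteRecord, compute_depth_threshold
from .window_scan import WindowSpec, WindowStat

__all__ = [
    "VcfSiteReader",
    "read_all_sites_vcf",
    "read_vcf_with_mask",
    "vcf_chrom_lengths",
    "depth_ceilings_from_vcf",
    "write_window_table",
    "read_window_table",
    "read_bed_intervals",
    "file_md5",
]

WINDOW_TABLE_COLUMNS = (
    "chrom", "start", "end", "L", "theta", "D", "ratio", "empirical_p", "flags",
)


def _is_snv(ref: str, alts: Optional[tuple]) -> bool:
    if len(ref) != 1 or ref == "*":
        return False
    if not alts:
        return True  # monomorphic all-sites record
    for alt in alts:
        if alt is None or len(alt) != 1 or alt in ("*",) or alt.startswith("<"):
            return False
    return True


class VcfSiteReader:
    """Iterate a VCF as :class:`SiteRecord`, with validation.

    Checks that the header declares GT, DP and GQ FORMAT fields, that
    records arrive in coordinate order, and counts skipped indel/symbolic
    records in ``n_skipped``.
    """

    def __init__(self, path, samples: Optional[Sequence[str]] = None):
        self.path = str(path)
        self._vf = pysam.VariantFile(self.path)
        for fmt in ("GT", "DP", "GQ"):
            if fmt not in self._vf.header.formats:
                raise ValueError(
                    f"{self.path}: FORMAT field {fmt} missing from header"
                )
        header_samples = list(self._vf.header.samples)
        if samples is None:
            self.samples = header_samples
        else:
            absent = set(samples) - set(header_samples)
            if absent:
                raise ValueError(
                    f"{self.path}: samples absent from VCF: {sorted(absent)}"
                )
            self.samples = list(samples)
        self.n_skipped = 0

    def __iter__(self) -> Iterator[SiteRecord]:
        last: tuple[Optional[str], int] = (None, 0)
        seen_chroms: set[str] = set()
        for rec in self._vf:
            if rec.chrom != last[0]:
                if rec.chrom in seen_chroms:
                    raise ValueError(
                        f"{self.path}: unsorted input, chromosome "
                        f"{rec.chrom} appears in non-contiguous blocks"
                    )
                seen_chroms.add(rec.chrom)
                last = (rec.chrom, 0)
            if rec.pos <= last[1]:
                raise ValueError(
                    f"{self.path}: unsorted input at {rec.chrom}:{rec.pos}"
                )
            last = (rec.chrom, rec.pos)
            if not _is_snv(rec.ref, rec.alts):
                self.n_skipped += 1
                continue
            calls = {}
            for s in self.samples:
                sd = rec.samples[s]
                gt = sd.get("GT", (None, None))
                if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                    a, b = None, None
                else:
                    a, b = int(gt[0]), int(gt[1])
                dp = sd.get("DP")
                gq = sd.get("GQ")
                calls[s] = GenotypeCall(
                    a, b,
                    int(dp) if dp is not None else 0,
                    int(gq) if gq is not None else 0,
                )
            alts = rec.alts or ()
            yield SiteRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=",".join(alts) if alts else None,
                site_quality=float(rec.qual) if rec.qual is not None else None,
                calls=calls,
                n_alt_alleles=len(alts),
            )


def read_all_sites_vcf(
    path, samples: Optional[Sequence[str]] = None
) -> VcfSiteReader:
    """Open an all-sites VCF as a validated SiteRecord stream."""
    return VcfSiteReader(path, samples)


def read_bed_intervals(path) -> list[tuple[str, int, int, str]]:
    """BED intervals as (chrom, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: need >= 3 columns")
            name = parts[3] if len(parts) > 3 else f"interval{lineno}"
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def read_vcf_with_mask(
    vcf_path, mask_bed, samples: Optional[Sequence[str]] = None
) -> Iterator[SiteRecord]:
    """Variant-only VCF plus a callable-mask BED as an all-sites stream.

    Positions inside the mask without a variant record are synthesized as
    homozygous-reference records marked ``prefiltered`` (the mask asserts
    callability, so the filter stack accepts them without depth/quality
    evidence).  Variant records outside the mask are dropped.
    """
    reader = VcfSiteReader(vcf_path, samples)
    mask: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _ in read_bed_intervals(mask_bed):
        mask.setdefault(chrom, []).append((start, end))
    for ivs in mask.values():
        ivs.sort()
    variants: dict[tuple[str, int], SiteRecord] = {}
    sample_names = reader.samples
    for rec in reader:
        variants[(rec.chrom, rec.pos)] = rec
    for chrom in mask:
        for start, end in mask[chrom]:
            for pos0 in range(start, end):
                rec = variants.get((chrom, pos0 + 1))
                if rec is not None:
                    yield rec
                else:
                    yield SiteRecord(
                        chrom=chrom, pos=pos0 + 1, ref_allele="N",
                        alt_allele=None, site_quality=None,
                        calls={
                            s: GenotypeCall(0, 0, 0, 0) for s in sample_names
                        },
                        n_alt_alleles=0, prefiltered=True,
                    )


def vcf_chrom_lengths(path) -> dict[str, int]:
    """Contig lengths from the VCF header."""
    vf = pysam.VariantFile(str(path))
    lengths = {}
    for name, contig in vf.header.contigs.items():
        if contig.length is None:
            raise ValueError(f"{path}: contig {name} has no declared length")
        lengths[name] = contig.length
    if not lengths:
        raise ValueError(f"{path}: no contigs declared in header")
    return lengths


def depth_ceilings_from_vcf(
    path,
    samples: Sequence[str],
    quantile: float = 0.95,
) -> dict[str, int]:
    """Per-sample nearest-rank depth ceilings from a full pass over the VCF."""
    depths: dict[str, list[int]] = {s: [] for s in samples}
    for rec in VcfSiteReader(path, samples):
        for s in samples:
            depths[s].append(rec.calls[s].depth)
    return {
        s: compute_depth_threshold(vals, quantile)
        for s, vals in depths.items()
    }


def write_window_table(stats: Iterable[WindowStat], path) -> None:
    """Write the window table TSV (BED-compatible first three columns)."""
    with open(path, "w") as fh:
        fh.write("\t".join(WINDOW_TABLE_COLUMNS) + "\n")
        for s in stats:
            ratio = "NA" if s.ratio is None else repr(float(s.ratio))
            p = "NA" if s.empirical_p is None else repr(float(s.empirical_p))
            flags = s.flags if s.flags else "NA"
            fh.write(
                f"{s.window.chrom}\t{s.window.start}\t{s.window.end}\t"
                f"{s.L}\t{float(s.theta)!r}\t{float(s.D)!r}\t{ratio}\t{p}\t"
                f"{flags}\n"
            )


def read_window_table(path) -> list[WindowStat]:
    """Read a window table written by :func:`write_window_table`."""
    stats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != WINDOW_TABLE_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(WINDOW_TABLE_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected "
                    f"{len(WINDOW_TABLE_COLUMNS)} columns, got {len(parts)}"
                )
            chrom, start, end, L, theta, D, ratio, p, flags = parts
            try:
                stats.append(
                    WindowStat(
                        WindowSpec(chrom, int(start), int(end)),
                        int(L), float(theta), float(D),
                        None if ratio == "NA" else float(ratio),
                        None if p == "NA" else float(p),
                        "" if flags == "NA" else flags,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return stats


def file_md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
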