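"""Gene annotation of significant windows and flanking-divergence counts.

Maps the low-theta/D outlier windows (empirical p below a significance
fraction) onto gene intervals, and counts divergent sites in an explicit
flanking region around a candidate gene — the follow-up used to ask whether
a shared protein change could reflect shared ancestry rather than
independent evolution.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core_stats import FilterConfig, SiteRecord, site_passes_filters
from .window_scan import WindowStat

__all__ = [
    "GeneModel",
    "read_genes_bed",
    "read_genes_gff3",
    "candidate_genes",
    "candidate_gene_table",
    "flanking_divergence",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 0-based half-open, matching the window convention."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} !< end {self.end}"
            )


def read_genes_bed(path) -> list[GeneModel]:
    """Genes from a BED file (0-based half-open; name in column 4)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: BED gene rows need >= 4 columns"
                )
            strand = parts[5] if len(parts) > 5 else "."
            genes.append(
                GeneModel(parts[3], parts[0], int(parts[1]), int(parts[2]),
                          strand)
            )
    return genes


def read_genes_gff3(path) -> list[GeneModel]:
    """Gene features from a GFF3 file (1-based inclusive -> half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(gid, feat.seqid, feat.start - 1, feat.end,
                      feat.strand or ".")
        )
    return genes


def _check_chroms(
    windows: Sequence[WindowStat], genes: Sequence[GeneModel]
) -> None:
    win_chroms = {w.window.chrom for w in windows}
    gene_chroms = {g.chrom for g in genes}
    orphans = sorted(gene_chroms - win_chroms)
    if orphans:
        raise ValueError(
            "annotation chromosomes absent from the window table: "
            + ", ".join(orphans)
        )


def _significant(
    windows: Sequence[WindowStat], alpha: float
) -> list[WindowStat]:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return [
        w for w in windows
        if w.empirical_p is not None and w.empirical_p < alpha
    ]


def candidate_genes(
    windows: Sequence[WindowStat],
    genes: Sequence[GeneModel],
    alpha: float = 0.01,
) -> list[str]:
    """Genes overlapping (>= 1 bp, half-open) any window with p < alpha.

    Any-overlap semantics rather than containment: genes frequently exceed
    the window length, so containment would miss them.  Each gene is
    reported once, sorted by id.
    """
    table = candidate_gene_table(windows, genes, alpha)
    return table["gene_id"].tolist()


def candidate_gene_table(
    windows: Sequence[WindowStat],
    genes: Sequence[GeneModel],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-gene overlap summary against significant windows.

    Columns: gene_id, chrom, n_overlapping_significant_windows,
    best_empirical_p (minimum over the overlapping windows).
    """
    _check_chroms(windows, genes)
    sig = _significant(windows, alpha)
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in sig:
        by_chrom.setdefault(w.window.chrom, []).append(w)
    index: dict[str, tuple[list[int], list[WindowStat]]] = {}
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: w.window.start)
        index[chrom] = ([w.window.start for w in ws], ws)

    rows = []
    for g in genes:
        if g.chrom not in index:
            continue
        starts, ws = index[g.chrom]
        hits = [
            w for w in ws[: bisect_right(starts, g.end - 1)]
            if w.window.end > g.start  # overlap: w.start < g.end handled above
        ]
        if hits:
            rows.append(
                (g.gene_id, g.chrom, len(hits),
                 min(w.empirical_p for w in hits))
            )
    rows.sort(key=lambda r: r[0])
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "n_overlapping_significant_windows",
                 "best_empirical_p"],
    )
    return out.drop_duplicates(subset="gene_id")


def flanking_divergence(
    sites: Iterable[SiteRecord],
    sample: str,
    region: tuple[str, int, int],
    config: FilterConfig,
    depth_ceilings: Optional[Mapping[str, int]] = None,
) -> tuple[int, int]:
    """(divergent sites, callable sites) for one sample in a region.

    A divergent site is a callable position at which the sample is
    homozygous for the alternate allele — an integer count of fixed
    differences, without the 0.5 heterozygote weighting of the windowed D
    (the follow-up reports whole divergent sites, and heterozygous positions
    are segregating rather than divergent).  ``region`` is (chrom, start,
    end), 0-based half-open.  Filters are evaluated for ``sample`` alone;
    pass ``depth_ceilings`` to enforce a depth ceiling, otherwise only the
    floor applies.
    """
    chrom, start, end = region
    if not start < end:
        raise ValueError(f"invalid region {region}")
    ceilings = {sample: (depth_ceilings or {}).get(sample, 2**31 - 1)}
    callable_sites = 0
    divergent = 0
    for site in sites:
        if site.chrom != chrom or not (start <= site.pos - 1 < end):
            continue
        if sample not in site.calls:
            raise KeyError(f"sample {sample!r} absent at {chrom}:{site.pos}")
        ok, _ = site_passes_filters(site, config, ceilings)
        if not ok:
            continue
        callable_sites += 1
        if site.calls[sample].is_hom_alt:
            divergent += 1
    if callable_sites == 0:
        warnings.warn(
            f"no callable sites for {sample} in {chrom}:{start}-{end}"
        )
        return 0, 0
    return divergent, callable_sites
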