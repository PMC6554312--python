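"""Site-level estimators and the site filter stack.

The windowed sweep statistic compares nucleotide diversity within a focal
cohort (theta) to divergence of one genome against the reference (D).  Both
are averages over *callable* sites, so the filter stack defined here decides
which positions exist at all for the downstream scan: a site that fails any
filter contributes to neither the numerator nor the denominator of either
quantity, nor to the callable length L.

Genotypes are diploid and unphased; allele index 0 is the reference allele,
which the scan treats as the ancestral state (the focal cohort is mapped to
an outgroup reference, so reference = ancestral is the working polarization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "GenotypeCall",
    "SiteRecord",
    "FilterConfig",
    "site_pi",
    "site_divergence_contrib",
    "allele_frequency",
    "compute_depth_threshold",
    "site_passes_filters",
    "gc_fraction",
]


@dataclass(frozen=True)
class GenotypeCall:
    """One diploid genotype call: two allele indices plus DP and GQ.

    ``allele_a``/``allele_b`` are 0 (reference), >=1 (alternate) or ``None``
    (missing, i.e. "./." in the VCF).
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    depth: int = 0
    genotype_quality: int = 0

    def __post_init__(self) -> None:
        if (self.allele_a is None) != (self.allele_b is None):
            raise ValueError("half-missing genotypes are not supported")
        if self.depth < 0 or self.genotype_quality < 0:
            raise ValueError("depth and genotype_quality must be non-negative")

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.allele_a != self.allele_b

    @property
    def is_hom_alt(self) -> bool:
        return (
            not self.is_missing
            and self.allele_a == self.allele_b
            and self.allele_a != 0
        )

    @property
    def n_alt(self) -> int:
        """Number of non-reference alleles carried (0, 1 or 2)."""
        if self.is_missing:
            raise ValueError("missing genotype has no allele count")
        return int(self.allele_a != 0) + int(self.allele_b != 0)


@dataclass
class SiteRecord:
    """One genomic position with its per-sample calls.

    ``pos`` is 1-based (VCF convention); window arithmetic converts to the
    package-internal 0-based half-open convention at the boundary.
    ``site_quality`` is the VCF QUAL; ``None`` for monomorphic records whose
    QUAL is "." (all-sites VCFs give invariant blocks no meaningful QUAL).
    ``prefiltered`` marks records synthesized from a callable mask, which are
    accepted without re-testing depth/quality.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: Optional[str]
    site_quality: Optional[float]
    calls: Mapping[str, GenotypeCall]
    n_alt_alleles: int = 0
    prefiltered: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.calls:
            raise ValueError("SiteRecord requires at least one genotype call")
        if self.n_alt_alleles < 0:
            raise ValueError("n_alt_alleles must be >= 0")

    @property
    def is_variant(self) -> bool:
        return self.n_alt_alleles >= 1


@dataclass
class FilterConfig:
    """Thresholds of the site/window filter stack.

    Defaults reproduce the scan's published filter set: depth below 3x or
    above the per-sample 95th depth percentile, variant QUAL below 50,
    missing genotypes, non-biallelic records, genotype quality below 20,
    windows with under 10 kb callable, and high-GC windows (above the 95th
    GC quantile across windows).

    ``divergence_mode`` switches how a homozygous-alternate genotype counts
    toward divergence: "sites" (contributes 1; divergence is a per-site
    probability in [0, 1]) or "alleles" (contributes 2).
    """

    min_depth: int = 3
    max_depth_quantile: float = 0.95
    min_site_qual: float = 50.0
    min_genotype_quality: int = 20
    require_biallelic: bool = True
    max_gc_quantile: float = 0.95
    min_callable_bp: int = 10_000
    divergence_mode: str = "sites"

    def __post_init__(self) -> None:
        for name in ("max_depth_quantile", "max_gc_quantile"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {q}")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.min_callable_bp <= 0:
            raise ValueError("min_callable_bp must be > 0")
        if self.divergence_mode not in ("sites", "alleles"):
            raise ValueError("divergence_mode must be 'sites' or 'alleles'")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown FilterConfig keys: {sorted(unknown)}")
        return cls(**dict(d))  # type: ignore[arg-type]


def site_pi(derived_count: int, n_chromosomes: int) -> float:
    """Per-site nucleotide diversity with the small-sample correction.

    For derived-allele count k among n sampled chromosomes this is
    ``2 p (1 - p) * n / (n - 1)`` with p = k/n, i.e. ``2 k (n - k) / (n (n - 1))``
    — the unbiased per-site expected heterozygosity, equal to the mean number
    of pairwise differences among the n chromosomes at the site.
    """
    n, k = int(n_chromosomes), int(derived_count)
    if n < 2:
        raise ValueError(f"need at least 2 chromosomes, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"derived count {k} outside [0, {n}]")
    return 2.0 * k * (n - k) / (n * (n - 1))


def site_divergence_contrib(call: GenotypeCall, mode: str = "sites") -> float:
    """Divergence contribution of one genotype against the reference.

    Heterozygous genotypes contribute 0.5 (one of the two chromosomes carries
    the derived allele).  Homozygous-alternate genotypes contribute 1 in
    "sites" mode (divergent site indicator) or 2 in "alleles" mode (derived
    allele count).
    """
    if call.is_missing:
        raise ValueError("missing genotype must be filtered before divergence")
    if call.is_het:
        return 0.5
    if call.is_hom_alt:
        return 1.0 if mode == "sites" else 2.0
    return 0.0


def allele_frequency(
    site: SiteRecord, focal_samples: Iterable[str]
) -> tuple[int, int]:
    """(derived count, total chromosomes) among the focal diploids.

    All focal genotypes must be non-missing — missing calls are a site
    filter, so reaching here with one is a pipeline error.
    """
    k = 0
    n = 0
    for sample in focal_samples:
        call = site.calls[sample]
        if call.is_missing:
            raise ValueError(
                f"missing genotype for {sample} at {site.chrom}:{site.pos}; "
                "site should have been filtered"
            )
        k += call.n_alt
        n += 2
    if n < 2:
        raise ValueError("need at least one focal sample")
    return k, n


def compute_depth_threshold(depths: Iterable[int], quantile: float) -> int:
    """Nearest-rank percentile of a depth distribution.

    Returns the ``ceil(q * N)``-th order statistic — the smallest observed
    depth whose empirical CDF reaches ``quantile``.  Used as the per-sample
    depth ceiling ("no more than the 95th percentile of the distribution").
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    arr = np.fromiter(depths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty depth stream")
    arr.sort()
    rank = math.ceil(quantile * arr.size)  # 1-based nearest rank
    return int(arr[rank - 1])


def site_passes_filters(
    site: SiteRecord,
    config: FilterConfig,
    depth_ceilings: Mapping[str, int],
) -> tuple[bool, Optional[str]]:
    """Apply the full site filter stack.

    The samples *relevant* to the scan are exactly the keys of
    ``depth_ceilings`` (focal cohort plus divergence sample); other samples
    in the record are ignored.  Returns ``(True, None)`` or ``(False,
    reason)`` where ``reason`` names the first violated rule, checked in the
    order: missing genotype, depth floor, depth ceiling, site quality
    (variant records only), biallelicity, genotype quality.
    """
    if site.prefiltered:
        return True, None
    for sample, ceiling in depth_ceilings.items():
        if site.calls[sample].is_missing:
            return False, "missing_genotype"
    for sample, ceiling in depth_ceilings.items():
        d = site.calls[sample].depth
        if d < config.min_depth:
            return False, "low_depth"
        if d > ceiling:
            return False, "high_depth"
    if site.is_variant:
        if site.site_quality is None or site.site_quality < config.min_site_qual:
            return False, "site_quality"
        if config.require_biallelic and site.n_alt_alleles > 1:
            return False, "multi_allelic"
    for sample in depth_ceilings:
        if site.calls[sample].genotype_quality < config.min_genotype_quality:
            return False, "genotype_quality"
    return True, None


def gc_fraction(sequence: str) -> float:
    """GC fraction of a nucleotide string; N bases are excluded entirely.

    Returns NaN when no A/C/G/T base is present.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return float("nan")
    return gc / acgt
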