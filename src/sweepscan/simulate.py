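"""Synthetic reference-mapped cohort generator.

Emulates the inputs the sweep scan consumes — an all-sites VCF for a small
diploid focal cohort plus a divergence contrast mapped to a reference —
with enough statistical structure that every pipeline stage is testable
without real genomes:

* neutral background polymorphism with derived-allele counts drawn from the
  standard neutral site-frequency spectrum, P(k) proportional to 1/k;
* fixed and heterozygous divergence sites carried by a dedicated divergence
  sample ("outgroup"), disjoint from the polymorphic sites so that windowed
  theta and D have exact closed-form expectations (theta recovers
  ``pi_background``; D recovers ``divergence_rate * (1 - 0.5 * het_fraction)``);
* embedded sweep intervals in which the polymorphic-site density is scaled
  by a diversity factor in [0, 1];
* injected artifact sites (low depth, low GQ, low QUAL, missing genotype,
  multi-allelic) that the default filter stack must remove, and an optional
  high-GC reference tract for the window-level GC filter.

Sites are independent — there is no linkage — because the scan statistic is
a per-site sum, so correctness testing does not need LD and independence
yields closed-form oracles.  A single integer seed fixes every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pyfaidx

from .core_stats import GenotypeCall, SiteRecord

__all__ = [
    "ArtifactRates",
    "SweepSimParams",
    "TruthSet",
    "SimulatedRegion",
    "draw_sfs_count",
    "sfs_weights",
    "expected_pi",
    "expected_divergence",
    "simulate_region",
]

# artifact construction targets the default thresholds of FilterConfig
_CLEAN_DP_MEAN = 20
_CLEAN_DP_MIN = 3
_CLEAN_DP_MAX = 27  # nearest-rank 95th percentile of Poisson(20)
_CLEAN_GQ_RANGE = (60, 100)
_CLEAN_QUAL_RANGE = (55.0, 2000.0)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION = {"A": "C", "G": "T", "C": "A", "T": "G"}

ARTIFACT_CLASSES = ("low_depth", "low_gq", "low_qual", "missing", "multi_allelic")


@dataclass(frozen=True)
class ArtifactRates:
    """Per-site injection probabilities for each artifact class."""

    low_depth: float = 0.0
    low_gq: float = 0.0
    low_qual: float = 0.0
    missing: float = 0.0
    multi_allelic: float = 0.0

    def __post_init__(self) -> None:
        for name in ARTIFACT_CLASSES:
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"artifact rate {name}={r} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ARTIFACT_CLASSES}


@dataclass(frozen=True)
class SweepSimParams:
    """Generative parameters for one simulated chromosome.

    ``pi_background`` is the expected per-site heterozygosity of the focal
    cohort outside sweeps; the per-site probability of a segregating site is
    ``pi_background * H_{n-1}`` (harmonic number of n-1 for n sampled
    chromosomes), which makes windowed theta an unbiased estimator of
    ``pi_background`` under the 1/k frequency spectrum.  ``sweep_intervals``
    are (start, end, diversity_factor) triples, 0-based half-open, with the
    segregating-site density multiplied by the factor inside each interval.
    """

    chrom_length: int
    chrom: str = "chr1"
    n_focal_diploids: int = 4
    pi_background: float = 1e-3
    divergence_rate: float = 2e-3
    het_fraction_of_divergence: float = 0.2
    sweep_intervals: tuple = ()
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    gc_tract: Optional[tuple] = None  # (start, end, gc_level)
    gc_background: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.n_focal_diploids < 1:
            raise ValueError("need at least one focal diploid")
        for name in ("pi_background", "divergence_rate",
                     "het_fraction_of_divergence", "gc_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.seg_density > 1.0:
            raise ValueError("pi_background too high: site density exceeds 1")
        prev_end = -1
        for iv in sorted(self.sweep_intervals):
            start, end, factor = iv
            if not (0 <= start < end <= self.chrom_length):
                raise ValueError(f"sweep interval {iv} outside chromosome")
            if start < prev_end:
                raise ValueError("sweep intervals overlap")
            if not 0.0 <= factor <= 1.0:
                raise ValueError(f"diversity factor {factor} outside [0, 1]")
            prev_end = end
        if self.gc_tract is not None:
            start, end, level = self.gc_tract
            if not (0 <= start < end <= self.chrom_length):
                raise ValueError("gc_tract outside chromosome")
            if not 0.0 <= level <= 1.0:
                raise ValueError("gc_tract level outside [0, 1]")

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_focal_diploids

    @property
    def harmonic(self) -> float:
        n = self.n_chromosomes
        return sum(1.0 / k for k in range(1, n))

    @property
    def seg_density(self) -> float:
        """Per-site probability of a segregating site outside sweeps."""
        return self.pi_background * self.harmonic

    @property
    def focal_samples(self) -> list[str]:
        return [f"focal{i + 1}" for i in range(self.n_focal_diploids)]

    @property
    def divergence_sample(self) -> str:
        return "outgroup"

    @property
    def samples(self) -> list[str]:
        return self.focal_samples + [self.divergence_sample]


def sfs_weights(n_chromosomes: int) -> np.ndarray:
    """Normalized neutral SFS weights P(k) for k = 1..n-1."""
    if n_chromosomes < 2:
        raise ValueError("need >= 2 chromosomes")
    k = np.arange(1, n_chromosomes, dtype=float)
    w = 1.0 / k
    return w / w.sum()


def draw_sfs_count(
    n_chromosomes: int, rng: np.random.Generator, size: Optional[int] = None
):
    """Derived-allele count(s) drawn from the 1/k neutral spectrum."""
    w = sfs_weights(n_chromosomes)
    k = rng.choice(np.arange(1, n_chromosomes), size=size, p=w)
    return int(k) if size is None else k.astype(np.int64)


def expected_pi(params: SweepSimParams) -> float:
    """Analytic expected per-site theta outside sweeps.

    Per segregating site, the mean of the corrected heterozygosity
    2k(n-k)/(n(n-1)) over the 1/k spectrum is exactly 1/H_{n-1}; the
    segregating-site density is pi_background * H_{n-1}, so the product is
    pi_background.
    """
    return params.pi_background


def expected_divergence(params: SweepSimParams) -> float:
    """Analytic expected per-site D of the divergence sample."""
    return params.divergence_rate * (
        1.0 - 0.5 * params.het_fraction_of_divergence
    )


def _bernoulli_positions(
    rng: np.random.Generator, n: int, p: float
) -> np.ndarray:
    """Positions of successes of a Bernoulli(p) process on 0..n-1.

    Drawn as geometric inter-arrival gaps, so runtime scales with the number
    of successes rather than n.
    """
    if p <= 0.0 or n <= 0:
        return np.empty(0, dtype=np.int64)
    if p >= 1.0:
        return np.arange(n, dtype=np.int64)
    chunks: list[np.ndarray] = []
    pos = -1
    while True:
        remaining = n - 1 - pos
        batch = max(1024, int(remaining * p * 1.2) + 16)
        gaps = rng.geometric(p, size=batch)
        cums = pos + np.cumsum(gaps)
        if cums[-1] >= n:
            chunks.append(cums[cums < n])
            break
        chunks.append(cums)
        pos = int(cums[-1])
    return np.concatenate(chunks).astype(np.int64)


@dataclass
class TruthSet:
    """Ground truth accompanying a simulated region."""

    sweep_intervals: tuple
    expected_theta_background: float
    expected_divergence: float
    params: SweepSimParams

    def expected_window_theta(self, start: int, end: int) -> float:
        """Overlap-weighted expected theta of window [start, end)."""
        total = (end - start) * self.expected_theta_background
        for s, e, f in self.sweep_intervals:
            ov = max(0, min(end, e) - max(start, s))
            total -= ov * self.expected_theta_background * (1.0 - f)
        return total / (end - start)


class SimulatedRegion:
    """In-memory realization of one simulated chromosome.

    Site-level draws are materialized eagerly as sparse position arrays
    (0-based); the reference sequence and the per-site depth/quality streams
    are generated lazily from dedicated child seeds, so large regions can be
    scanned through :func:`sweepscan.window_scan.scan_positions` without
    ever constructing per-base data.
    """

    def __init__(self, params: SweepSimParams):
        self.params = params
        ss = np.random.SeedSequence(params.seed)
        (self._sites_ss, self._payload_ss, self._depth_ss,
         self._ref_ss, self._genes_ss) = ss.spawn(5)
        self._reference: Optional[np.ndarray] = None
        self._generate_sites()

    # -- generation -------------------------------------------------------

    def _segments(self) -> list[tuple[int, int, float]]:
        """Chromosome partition into (start, end, diversity_factor)."""
        segs = []
        cursor = 0
        for s, e, f in sorted(self.params.sweep_intervals):
            if cursor < s:
                segs.append((cursor, s, 1.0))
            segs.append((s, e, f))
            cursor = e
        if cursor < self.params.chrom_length:
            segs.append((cursor, self.params.chrom_length, 1.0))
        return segs

    def _generate_sites(self) -> None:
        p = self.params
        rng = np.random.default_rng(self._sites_ss)
        n_chrom = p.n_chromosomes

        parts = []
        for s, e, f in self._segments():
            pos = _bernoulli_positions(rng, e - s, p.seg_density * f)
            parts.append(pos + s)
        self.poly_pos = (
            np.concatenate(parts) if parts else np.empty(0, np.int64)
        )
        n_poly = self.poly_pos.size
        self.poly_k = draw_sfs_count(n_chrom, rng, size=n_poly) \
            if n_poly else np.empty(0, np.int64)
        # uniform assignment of k derived alleles to the 2F chromosomes
        order = np.argsort(rng.random((n_poly, n_chrom)), axis=1)
        mask = np.arange(n_chrom)[None, :] < self.poly_k[:, None]
        self.poly_alleles = np.zeros((n_poly, n_chrom), dtype=np.uint8)
        np.put_along_axis(self.poly_alleles, order, mask, axis=1)
        self.poly_pi = (
            2.0 * self.poly_k * (n_chrom - self.poly_k)
            / (n_chrom * (n_chrom - 1))
        )

        occupied = self.poly_pos
        div = _bernoulli_positions(rng, p.chrom_length, p.divergence_rate)
        self.div_pos = np.setdiff1d(div, occupied, assume_unique=True)
        self.div_is_het = (
            rng.random(self.div_pos.size) < p.het_fraction_of_divergence
        )
        self.div_contrib = np.where(self.div_is_het, 0.5, 1.0)
        occupied = np.union1d(occupied, self.div_pos)

        pay = np.random.default_rng(self._payload_ss)
        self.artifacts: dict[str, dict[str, np.ndarray]] = {}
        for name in ARTIFACT_CLASSES:
            rate = getattr(p.artifact_rates, name)
            pos = _bernoulli_positions(rng, p.chrom_length, rate)
            pos = np.setdiff1d(pos, occupied, assume_unique=True)
            occupied = np.union1d(occupied, pos)
            m = pos.size
            info: dict[str, np.ndarray] = {"pos": pos}
            if name == "low_depth":
                info["sample_idx"] = pay.integers(0, len(p.samples), size=m)
                info["value"] = pay.integers(0, _CLEAN_DP_MIN, size=m)
            elif name == "low_gq":
                info["sample_idx"] = pay.integers(0, len(p.samples), size=m)
                info["value"] = pay.integers(0, 20, size=m)
            elif name == "low_qual":
                info["sample_idx"] = pay.integers(0, p.n_focal_diploids, size=m)
                info["value"] = np.round(pay.uniform(1.0, 49.5, size=m), 1)
            elif name == "missing":
                info["sample_idx"] = pay.integers(0, len(p.samples), size=m)
            elif name == "multi_allelic":
                info["sample_idx"] = pay.integers(0, p.n_focal_diploids, size=m)
            self.artifacts[name] = info
        self.artifact_pos = np.sort(
            np.concatenate([a["pos"] for a in self.artifacts.values()])
        )

    # -- derived views ----------------------------------------------------

    @property
    def truth(self) -> TruthSet:
        return TruthSet(
            sweep_intervals=tuple(sorted(self.params.sweep_intervals)),
            expected_theta_background=expected_pi(self.params),
            expected_divergence=expected_divergence(self.params),
            params=self.params,
        )

    @property
    def reference(self) -> np.ndarray:
        """Reference bases as a uint8 array of ASCII codes (lazy)."""
        if self._reference is None:
            p = self.params
            rng = np.random.default_rng(self._ref_ss)
            u = rng.random(p.chrom_length)
            bases = np.frombuffer(b"ACGT", dtype=np.uint8)

            def compose(gc: float) -> np.ndarray:
                at = (1.0 - gc) / 2.0
                return np.cumsum([at, gc / 2.0, gc / 2.0, at])

            idx = np.searchsorted(compose(p.gc_background), u, side="right")
            idx = np.clip(idx, 0, 3)
            if p.gc_tract is not None:
                s, e, level = p.gc_tract
                t_idx = np.searchsorted(compose(level), u[s:e], side="right")
                idx[s:e] = np.clip(t_idx, 0, 3)
            self._reference = bases[idx]
        return self._reference

    def reference_str(self) -> str:
        return self.reference.tobytes().decode("ascii")

    # -- record stream ----------------------------------------------------

    def iter_sites(self) -> Iterator[SiteRecord]:
        """Yield one SiteRecord per position (all-sites semantics).

        Depth/GQ/QUAL streams come from a dedicated child seed re-created on
        every call, so repeated iteration is byte-identical.
        """
        p = self.params
        samples = p.samples
        n_samp = len(samples)
        rng = np.random.default_rng(self._depth_ss)
        ref = self.reference

        poly_at = {int(pos): i for i, pos in enumerate(self.poly_pos)}
        div_at = {int(pos): i for i, pos in enumerate(self.div_pos)}
        art_at: dict[int, tuple[str, int]] = {}
        for name, info in self.artifacts.items():
            for j, pos in enumerate(info["pos"]):
                art_at[int(pos)] = (name, j)

        block = 65536
        dp_block = gq_block = None
        cursor = block  # force initial refill

        for pos0 in range(p.chrom_length):
            if cursor >= block:
                dp_block = np.clip(
                    rng.poisson(_CLEAN_DP_MEAN, size=(block, n_samp)),
                    _CLEAN_DP_MIN, _CLEAN_DP_MAX,
                )
                gq_block = rng.integers(
                    _CLEAN_GQ_RANGE[0], _CLEAN_GQ_RANGE[1],
                    size=(block, n_samp),
                )
                qual_block = np.round(
                    rng.uniform(*_CLEAN_QUAL_RANGE, size=block), 1
                )
                cursor = 0
            dps = dp_block[cursor]
            gqs = gq_block[cursor]
            clean_qual = float(qual_block[cursor])
            cursor += 1

            ref_base = chr(ref[pos0])
            alt: Optional[str] = None
            qual: Optional[float] = None
            n_alt = 0
            gts: list[tuple[Optional[int], Optional[int]]] = \
                [(0, 0)] * n_samp

            if pos0 in poly_at:
                i = poly_at[pos0]
                row = self.poly_alleles[i]
                gts = [
                    tuple(sorted((int(row[2 * j]), int(row[2 * j + 1]))))
                    for j in range(p.n_focal_diploids)
                ] + [(0, 0)]
                alt, n_alt, qual = _TRANSITION[ref_base], 1, clean_qual
            elif pos0 in div_at:
                i = div_at[pos0]
                og = (0, 1) if self.div_is_het[i] else (1, 1)
                gts = [(0, 0)] * p.n_focal_diploids + [og]
                alt, n_alt, qual = _TRANSITION[ref_base], 1, clean_qual
            elif pos0 in art_at:
                name, j = art_at[pos0]
                info = self.artifacts[name]
                if name == "low_depth":
                    dps = dps.copy()
                    dps[int(info["sample_idx"][j])] = int(info["value"][j])
                elif name == "low_gq":
                    gqs = gqs.copy()
                    gqs[int(info["sample_idx"][j])] = int(info["value"][j])
                elif name == "low_qual":
                    gts = [(0, 0)] * n_samp
                    gts[int(info["sample_idx"][j])] = (0, 1)
                    alt, n_alt = _TRANSITION[ref_base], 1
                    qual = float(info["value"][j])
                elif name == "missing":
                    gts = [(0, 0)] * n_samp
                    gts[int(info["sample_idx"][j])] = (None, None)
                elif name == "multi_allelic":
                    gts = [(0, 0)] * n_samp
                    gts[int(info["sample_idx"][j])] = (1, 2)
                    alt = f"{_TRANSITION[ref_base]},{_TRANSVERSION[ref_base]}"
                    n_alt, qual = 2, clean_qual

            calls = {
                s: GenotypeCall(g[0], g[1], int(dps[k]), int(gqs[k]))
                for k, (s, g) in enumerate(zip(samples, gts))
            }
            yield SiteRecord(
                chrom=p.chrom, pos=pos0 + 1, ref_allele=ref_base,
                alt_allele=alt, site_quality=qual, calls=calls,
                n_alt_alleles=n_alt,
            )

    # -- writers ----------------------------------------------------------

    def write_vcf(self, path) -> None:
        """Write the cohort as an uncompressed all-sites VCF 4.2."""
        p = self.params
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={p.chrom},length={p.chrom_length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(p.samples) + "\n"
            )
            for site in self.iter_sites():
                alt = site.alt_allele if site.alt_allele else "."
                qual = "." if site.site_quality is None \
                    else f"{site.site_quality:g}"
                cols = [
                    site.chrom, str(site.pos), ".", site.ref_allele, alt,
                    qual, ".", ".", "GT:DP:GQ",
                ]
                for s in p.samples:
                    c = site.calls[s]
                    gt = "./." if c.is_missing \
                        else f"{c.allele_a}/{c.allele_b}"
                    cols.append(f"{gt}:{c.depth}:{c.genotype_quality}")
                fh.write("\t".join(cols) + "\n")

    def write_reference(self, path) -> None:
        seq = self.reference_str()
        with open(path, "w") as fh:
            fh.write(f">{self.params.chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
        pyfaidx.Faidx(str(path))  # build .fai alongside

    def write_truth_bed(self, path) -> None:
        with open(path, "w") as fh:
            for s, e, f in sorted(self.params.sweep_intervals):
                fh.write(f"{self.params.chrom}\t{s}\t{e}\tsweep_df={f:g}\n")

    def write_genes_bed(self, path, n_genes: int = 20) -> None:
        """Random non-overlapping gene intervals for annotation tests."""
        p = self.params
        rng = np.random.default_rng(self._genes_ss)
        genes = []
        cursor = 0
        for i in range(n_genes):
            gap = int(rng.integers(1000, max(2000, p.chrom_length // n_genes)))
            length = int(rng.integers(2000, 50_000))
            start = cursor + gap
            end = start + length
            if end > p.chrom_length:
                break
            genes.append((start, end, f"gene{i + 1:04d}"))
            cursor = end
        with open(path, "w") as fh:
            for start, end, gid in genes:
                fh.write(f"{p.chrom}\t{start}\t{end}\t{gid}\t0\t+\n")

    def write_params_json(self, path) -> None:
        d = dataclasses.asdict(self.params)
        d["artifact_rates"] = self.params.artifact_rates.as_dict()
        d["expected_theta_background"] = expected_pi(self.params)
        d["expected_divergence"] = expected_divergence(self.params)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=list)
            fh.write("\n")

    def write_outputs(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": outdir / "reference.fa",
            "vcf": outdir / "cohort.vcf",
            "truth_bed": outdir / "truth.bed",
            "genes_bed": outdir / "genes.bed",
            "params": outdir / "params.json",
        }
        self.write_reference(paths["reference"])
        self.write_vcf(paths["vcf"])
        self.write_truth_bed(paths["truth_bed"])
        self.write_genes_bed(paths["genes_bed"])
        self.write_params_json(paths["params"])
        return paths


def simulate_region(params: SweepSimParams) -> SimulatedRegion:
    """Realize one simulated chromosome from its generative parameters."""
    return SimulatedRegion(params)
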