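"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sweepscan import (
    ArtifactRates,
    FilterConfig,
    GenotypeCall,
    SiteRecord,
    SweepSimParams,
    simulate_region,
)

FOCAL = ["focal1", "focal2", "focal3", "focal4"]
OUTGROUP = "outgroup"
ALL_SAMPLES = FOCAL + [OUTGROUP]


def make_call(a, b, depth=20, gq=80):
    return GenotypeCall(a, b, depth, gq)


def make_site(pos, genotypes, chrom="chr1", qual=None, ref="A", alt=None,
              depth=20, gq=80, n_alt=None):
    """Build a SiteRecord from {sample: (a, b)} genotype pairs."""
    calls = {
        s: make_call(a, b, depth=depth, gq=gq) for s, (a, b) in genotypes.items()
    }
    is_var = any(
        g != (0, 0) and g != (None, None) for g in genotypes.values()
    )
    if n_alt is None:
        n_alt = 1 if is_var else 0
    if alt is None and n_alt:
        alt = "G"
    if qual is None and n_alt:
        qual = 100.0
    return SiteRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        site_quality=qual, calls=calls, n_alt_alleles=n_alt,
    )


def random_window_sites(rng, n_sites, n_focal=4, start_pos=1):
    """Random callable SiteRecords: mixed monomorphic/polymorphic/divergent."""
    sites = []
    for i in range(n_sites):
        gts = {}
        for s in range(n_focal):
            u = rng.random()
            if u < 0.6:
                g = (0, 0)
            elif u < 0.8:
                g = (0, 1)
            else:
                g = (1, 1)
            gts[f"focal{s + 1}"] = g
        u = rng.random()
        gts[OUTGROUP] = (0, 0) if u < 0.5 else ((0, 1) if u < 0.75 else (1, 1))
        sites.append(make_site(start_pos + i, gts))
    return sites


def brute_force_window(sites, focal_samples, divergence_sample,
                       divergence_mode="sites"):
    """Independent re-summation of the windowed statistic.

    Recomputes p from raw genotypes, evaluates 2p(1-p) * n/(n-1) per site
    and X_i + 0.5 Y_i for the divergence sample, and averages over L —
    sharing no code with the scan path.
    """
    L = len(sites)
    theta_sum = 0.0
    d_sum = 0.0
    for site in sites:
        alleles = []
        for s in focal_samples:
            c = site.calls[s]
            alleles.extend([c.allele_a, c.allele_b])
        n = len(alleles)
        p = sum(1 for a in alleles if a != 0) / n
        theta_sum += 2.0 * p * (1.0 - p) * n / (n - 1)
        c = site.calls[divergence_sample]
        if c.allele_a != c.allele_b:
            d_sum += 0.5
        elif c.allele_a != 0:
            d_sum += 1.0 if divergence_mode == "sites" else 2.0
    theta = theta_sum / L
    D = d_sum / L
    return theta, D, (theta / D if D > 0 else None)


@pytest.fixture(scope="session")
def artifact_sim():
    """60 kb cohort with every artifact class injected."""
    params = SweepSimParams(
        chrom_length=60_000,
        seed=3,
        artifact_rates=ArtifactRates(
            low_depth=2e-3, low_gq=2e-3, low_qual=2e-3,
            missing=2e-3, multi_allelic=2e-3,
        ),
    )
    return simulate_region(params)


@pytest.fixture(scope="session")
def clean_sim():
    """50 kb artifact-free cohort."""
    return simulate_region(SweepSimParams(chrom_length=50_000, seed=11))


@pytest.fixture(scope="session")
def artifact_sim_dir(artifact_sim, tmp_path_factory):
    """On-disk outputs (FASTA, VCF, BEDs) of the artifact cohort."""
    out = tmp_path_factory.mktemp("simdata")
    paths = artifact_sim.write_outputs(out)
    return paths


@pytest.fixture()
def loose_config():
    return FilterConfig(min_callable_bp=1_000)


@pytest.fixture()
def default_ceilings():
    return {s: 27 for s in ALL_SAMPLES}
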