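"""Generative model of the synthetic cohort and its closed-form oracles."""

import numpy as np
import pytest

from sweepscan import (
    ArtifactRates,
    FilterConfig,
    SweepSimParams,
    draw_sfs_count,
    expected_divergence,
    expected_pi,
    simulate_region,
    scan_positions,
    site_pi,
)
from sweepscan.core_stats import site_passes_filters
from sweepscan.simulate import sfs_weights, _bernoulli_positions

from conftest import OUTGROUP


class TestSfs:
    def test_singleton_probability_n8(self):
        """P(k=1) = 1/H7 = 140/363 under the 1/k spectrum."""
        w = sfs_weights(8)
        assert w[0] == pytest.approx(140 / 363, rel=1e-12)

    def test_two_chromosomes_always_one(self):
        rng = np.random.default_rng(0)
        assert all(draw_sfs_count(2, rng) == 1 for _ in range(20))

    def test_empirical_frequencies_match(self):
        """1e6 draws match P(k) within 3-sigma multinomial bounds."""
        rng = np.random.default_rng(99)
        n = 8
        draws = draw_sfs_count(n, rng, size=1_000_000)
        w = sfs_weights(n)
        counts = np.bincount(draws, minlength=n)[1:n]
        for k, (c, p) in enumerate(zip(counts, w), start=1):
            sigma = np.sqrt(1_000_000 * p * (1 - p))
            assert abs(c - 1_000_000 * p) < 3 * sigma, f"k={k}"

    def test_mean_site_pi_per_segregating_site(self):
        """E[2k(n-k)/(n(n-1))] over the 1/k spectrum is exactly 1/H_{n-1}."""
        for n in (2, 4, 8, 12):
            w = sfs_weights(n)
            mean_pi = sum(
                wk * site_pi(k, n) for k, wk in enumerate(w, start=1)
            )
            h = sum(1.0 / k for k in range(1, n))
            assert mean_pi == pytest.approx(1.0 / h, rel=1e-12)


class TestBernoulliPositions:
    def test_rate_recovery(self):
        rng = np.random.default_rng(1)
        pos = _bernoulli_positions(rng, 1_000_000, 0.01)
        assert abs(pos.size - 10_000) < 3 * np.sqrt(10_000)
        assert pos.size == np.unique(pos).size
        assert pos.min() >= 0 and pos.max() < 1_000_000

    def test_edge_rates(self):
        rng = np.random.default_rng(1)
        assert _bernoulli_positions(rng, 100, 0.0).size == 0
        assert list(_bernoulli_positions(rng, 5, 1.0)) == [0, 1, 2, 3, 4]


class TestDeterminism:
    def test_same_seed_byte_identical_vcf(self, tmp_path):
        params = SweepSimParams(chrom_length=20_000, seed=17)
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        simulate_region(params).write_vcf(a)
        simulate_region(params).write_vcf(b)
        assert a.read_bytes() == b.read_bytes()

    def test_repeated_iteration_identical(self):
        sim = simulate_region(SweepSimParams(chrom_length=5_000, seed=4))
        first = [(s.pos, s.site_quality,
                  tuple((c.allele_a, c.depth, c.genotype_quality)
                        for c in s.calls.values()))
                 for s in sim.iter_sites()]
        second = [(s.pos, s.site_quality,
                   tuple((c.allele_a, c.depth, c.genotype_quality)
                         for c in s.calls.values()))
                  for s in sim.iter_sites()]
        assert first == second

    def test_different_seeds_differ(self):
        a = simulate_region(SweepSimParams(chrom_length=50_000, seed=1))
        b = simulate_region(SweepSimParams(chrom_length=50_000, seed=2))
        assert not np.array_equal(a.poly_pos, b.poly_pos)


class TestSweepIntervals:
    def test_zero_diversity_factor_silences_interval(self):
        params = SweepSimParams(
            chrom_length=200_000, seed=5,
            sweep_intervals=((80_000, 120_000, 0.0),),
        )
        sim = simulate_region(params)
        inside = (sim.poly_pos >= 80_000) & (sim.poly_pos < 120_000)
        assert inside.sum() == 0
        assert sim.poly_pos.size > 0  # background untouched

    def test_truth_expected_window_theta(self):
        params = SweepSimParams(
            chrom_length=200_000, seed=5,
            sweep_intervals=((100_000, 150_000, 0.1),),
        )
        truth = simulate_region(params).truth
        # window fully inside the sweep
        assert truth.expected_window_theta(100_000, 150_000) == \
            pytest.approx(1e-4)
        # half-overlapping window
        assert truth.expected_window_theta(50_000, 150_000) == \
            pytest.approx(0.5 * 1e-3 + 0.5 * 1e-4)

    def test_overlapping_sweeps_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SweepSimParams(
                chrom_length=100_000,
                sweep_intervals=((0, 50_000, 0.1), (40_000, 80_000, 0.1)),
            )


class TestArtifacts:
    def test_artifact_free_sites_all_pass(self, clean_sim):
        """With zero artifact rates every emitted site passes the stack."""
        cfg = FilterConfig()
        ceilings = {s: 27 for s in clean_sim.params.samples}
        for site in clean_sim.iter_sites():
            ok, reason = site_passes_filters(site, cfg, ceilings)
            assert ok, f"pos {site.pos}: {reason}"

    def test_every_artifact_class_in_failure_tally(self, artifact_sim,
                                                   loose_config,
                                                   default_ceilings):
        from sweepscan import scan_records

        p = artifact_sim.params
        res = scan_records(
            artifact_sim.iter_sites(), p.focal_samples, OUTGROUP,
            loose_config, default_ceilings, {p.chrom: p.chrom_length},
            window_bp=20_000,
        )
        tally = res.filter_tally
        for reason in ("low_depth", "genotype_quality", "site_quality",
                       "missing_genotype", "multi_allelic"):
            assert tally[reason] > 0, reason
        # callable length strictly below the window span
        assert all(s.L < s.window.span for s in res.stats)

    def test_artifact_positions_disjoint_from_signal(self, artifact_sim):
        assert np.intersect1d(
            artifact_sim.artifact_pos, artifact_sim.poly_pos
        ).size == 0
        assert np.intersect1d(
            artifact_sim.artifact_pos, artifact_sim.div_pos
        ).size == 0


class TestParameterRecovery:
    def test_neutral_recovery_pooled_replicates(self):
        """Windowed theta and D recover their analytic expectations
        (pooled over five 2 Mb replicates, 500 windows)."""
        thetas, ds = [], []
        params = None
        for seed in range(5):
            params = SweepSimParams(chrom_length=2_000_000, seed=seed)
            sim = simulate_region(params)
            res = scan_positions(
                params.chrom, params.chrom_length, sim.poly_pos, sim.poly_pi,
                sim.div_pos, sim.div_contrib, sim.artifact_pos,
                FilterConfig(), window_bp=20_000,
            )
            thetas.extend(s.theta for s in res.stats)
            ds.extend(s.D for s in res.stats)
        thetas, ds = np.array(thetas), np.array(ds)
        assert len(thetas) == 500
        se_t = thetas.std(ddof=1) / np.sqrt(len(thetas))
        se_d = ds.std(ddof=1) / np.sqrt(len(ds))
        assert abs(thetas.mean() - expected_pi(params)) < 3 * se_t
        assert abs(ds.mean() - expected_divergence(params)) < 3 * se_d


class TestGcTract:
    def test_high_gc_windows_dropped(self):
        from sweepscan.window_scan import apply_gc_filter, make_windows
        from sweepscan.core_stats import gc_fraction
        from sweepscan.window_scan import WindowStat

        params = SweepSimParams(
            chrom_length=100_000, seed=8,
            gc_tract=(40_000, 60_000, 0.85),
        )
        sim = simulate_region(params)
        seq = sim.reference_str()
        wins = make_windows({params.chrom: params.chrom_length}, 10_000)
        stats = [WindowStat(w, 10_000, 1e-3, 2e-3, 0.5) for w in wins]
        gc = {w: gc_fraction(seq[w.start:w.end]) for w in wins}
        kept, dropped, cutoff = apply_gc_filter(stats, gc, 0.8)
        dropped_starts = {s.window.start for s in dropped}
        assert dropped_starts == {40_000, 50_000}
        assert all("high_gc" in s.flags for s in dropped)

    def test_reference_gc_levels(self):
        params = SweepSimParams(
            chrom_length=100_000, seed=8,
            gc_tract=(40_000, 60_000, 0.85),
        )
        from sweepscan.core_stats import gc_fraction

        seq = simulate_region(params).reference_str()
        assert gc_fraction(seq[40_000:60_000]) == pytest.approx(0.85, abs=0.02)
        assert gc_fraction(seq[:40_000]) == pytest.approx(0.40, abs=0.02)
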