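"""Window construction, the windowed theta/D statistic, and ranking."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan import (
    FilterConfig,
    empirical_p,
    make_windows,
    scan_positions,
    scan_records,
    scan_window,
    assign_empirical_p,
    info_diagnostic,
)
from sweepscan.window_scan import WindowSpec, WindowStat

from conftest import (
    ALL_SAMPLES,
    FOCAL,
    OUTGROUP,
    brute_force_window,
    make_site,
    random_window_sites,
)


class TestMakeWindows:
    def test_non_overlapping_tiling(self):
        wins = make_windows({"chr1": 1_000_000}, 100_000)
        assert len(wins) == 10
        assert wins[0].start == 0 and wins[0].end == 100_000
        assert wins[-1].start == 900_000

    def test_overlapping_step(self):
        wins = make_windows({"chr1": 250_000}, 100_000, 10_000)
        assert len(wins) == (250_000 - 100_000) // 10_000 + 1  # 16

    def test_chromosome_shorter_than_window(self):
        assert make_windows({"chr1": 50_000}, 100_000) == []

    def test_partial_trailing_window_not_emitted(self):
        wins = make_windows({"chr1": 150_000}, 100_000)
        assert len(wins) == 1 and wins[0].end == 100_000

    @pytest.mark.parametrize("window,step", [(0, 1), (100, 0), (-5, 5)])
    def test_invalid_sizes(self, window, step):
        with pytest.raises(ValueError):
            make_windows({"chr1": 1000}, window, step)

    @given(
        length=st.integers(0, 500_000),
        window=st.integers(500, 120_000),
        step_frac=st.integers(1, 4),
    )
    @settings(max_examples=60, deadline=None)
    def test_count_formula(self, length, window, step_frac):
        step = max(1, window // step_frac)
        wins = make_windows({"c": length}, window, step)
        expected = 0 if length < window else (length - window) // step + 1
        assert len(wins) == expected
        assert all(w.end - w.start == window for w in wins)
        assert all(w.end <= length for w in wins)


class TestScanWindow:
    def test_hand_worked_example(self):
        """Five callable sites: theta = 0.2, D = 0.3, ratio = 2/3."""
        mono = {s: (0, 0) for s in ALL_SAMPLES}
        sites = [
            make_site(1, {**mono, **dict(zip(FOCAL, [(1, 1), (1, 1), (0, 0), (0, 0)]))}),  # k=4
            make_site(2, {**mono, **dict(zip(FOCAL, [(0, 1), (0, 1), (0, 0), (0, 0)]))}),  # k=2
            make_site(3, {**mono, OUTGROUP: (1, 1)}),
            make_site(4, {**mono, OUTGROUP: (0, 1)}),
            make_site(5, dict(mono)),
        ]
        cfg = FilterConfig(min_callable_bp=1)
        stat = scan_window(WindowSpec("chr1", 0, 5), sites, FOCAL, OUTGROUP, cfg)
        assert stat.L == 5
        assert stat.theta == pytest.approx(0.2, rel=1e-12)
        assert stat.D == pytest.approx(0.3, rel=1e-12)
        assert stat.ratio == pytest.approx(2 / 3, rel=1e-12)

    def test_all_monomorphic_ratio_undefined(self):
        mono = {s: (0, 0) for s in ALL_SAMPLES}
        sites = [make_site(i + 1, dict(mono)) for i in range(5)]
        cfg = FilterConfig(min_callable_bp=1)
        stat = scan_window(WindowSpec("chr1", 0, 5), sites, FOCAL, OUTGROUP, cfg)
        assert stat.theta == 0.0 and stat.D == 0.0
        assert stat.ratio is None and stat.flags == "zero_divergence"

    def test_window_below_min_callable_discarded(self):
        mono = {s: (0, 0) for s in ALL_SAMPLES}
        sites = [make_site(i + 1, dict(mono)) for i in range(9_999)]
        stat = scan_window(
            WindowSpec("chr1", 0, 100_000), sites, FOCAL, OUTGROUP,
            FilterConfig(min_callable_bp=10_000),
        )
        assert stat is None

    def test_matches_bruteforce_on_random_windows(self):
        rng = np.random.default_rng(42)
        cfg = FilterConfig(min_callable_bp=1)
        for i in range(50):
            sites = random_window_sites(rng, int(rng.integers(5, 60)))
            stat = scan_window(
                WindowSpec("chr1", 0, 100), sites, FOCAL, OUTGROUP, cfg
            )
            theta, D, ratio = brute_force_window(sites, FOCAL, OUTGROUP)
            assert stat.theta == pytest.approx(theta, rel=1e-12)
            assert stat.D == pytest.approx(D, rel=1e-12)

    def test_allele_divergence_mode(self):
        """In 'alleles' mode a hom-alt divergence genotype counts twice."""
        mono = {s: (0, 0) for s in ALL_SAMPLES}
        sites = [
            make_site(1, {**mono, OUTGROUP: (1, 1)}),
            make_site(2, dict(mono)),
        ]
        cfg = FilterConfig(min_callable_bp=1, divergence_mode="alleles")
        stat = scan_window(WindowSpec("chr1", 0, 2), sites, FOCAL, OUTGROUP, cfg)
        assert stat.D == pytest.approx(1.0)


class TestScanRecords:
    def test_agrees_with_per_window_scan(self, artifact_sim, loose_config,
                                         default_ceilings):
        """Streaming accumulation equals filtering + scan_window per window."""
        from sweepscan.core_stats import site_passes_filters

        p = artifact_sim.params
        res = scan_records(
            artifact_sim.iter_sites(), p.focal_samples, OUTGROUP,
            loose_config, default_ceilings, {p.chrom: p.chrom_length},
            window_bp=15_000, step_bp=5_000,
        )
        passing = [
            s for s in artifact_sim.iter_sites()
            if site_passes_filters(s, loose_config, default_ceilings)[0]
        ]
        wins = make_windows({p.chrom: p.chrom_length}, 15_000, 5_000)
        expected = []
        for w in wins:
            in_win = [s for s in passing if w.start <= s.pos - 1 < w.end]
            stat = scan_window(w, in_win, p.focal_samples, OUTGROUP,
                               loose_config)
            if stat is not None:
                expected.append(stat)
        assert len(res.stats) == len(expected)
        for a, b in zip(res.stats, expected):
            assert a.window == b.window and a.L == b.L
            assert a.theta == pytest.approx(b.theta, rel=1e-12)
            assert a.D == pytest.approx(b.D, rel=1e-12)

    def test_vectorized_scan_equals_record_scan(self, artifact_sim,
                                                loose_config,
                                                default_ceilings):
        p = artifact_sim.params
        r_rec = scan_records(
            artifact_sim.iter_sites(), p.focal_samples, OUTGROUP,
            loose_config, default_ceilings, {p.chrom: p.chrom_length},
            window_bp=20_000,
        )
        r_vec = scan_positions(
            p.chrom, p.chrom_length, artifact_sim.poly_pos,
            artifact_sim.poly_pi, artifact_sim.div_pos,
            artifact_sim.div_contrib, artifact_sim.artifact_pos,
            loose_config, window_bp=20_000,
        )
        assert len(r_rec.stats) == len(r_vec.stats)
        for a, b in zip(r_rec.stats, r_vec.stats):
            assert a.L == b.L
            assert a.theta == pytest.approx(b.theta, rel=1e-12)
            assert a.D == pytest.approx(b.D, rel=1e-12)

    def test_chromosome_order_invariance(self, clean_sim, loose_config,
                                         default_ceilings):
        """Retained windows do not depend on chrom_lengths ordering."""
        p = clean_sim.params
        other = [
            make_site(i + 1, {s: (0, 0) for s in ALL_SAMPLES}, chrom="chr2")
            for i in range(3_000)
        ]
        records = list(clean_sim.iter_sites()) + other

        def run(lengths):
            res = scan_records(
                records, p.focal_samples, OUTGROUP, loose_config,
                default_ceilings, lengths, window_bp=10_000,
            )
            return {
                (s.window.chrom, s.window.start, s.L, s.theta, s.D)
                for s in res.stats
            }

        a = run({p.chrom: p.chrom_length, "chr2": 3_000})
        b = run({"chr2": 3_000, p.chrom: p.chrom_length})
        assert a == b

    def test_unknown_chromosome_rejected(self, loose_config,
                                         default_ceilings):
        site = make_site(1, {s: (0, 0) for s in ALL_SAMPLES}, chrom="chrX")
        with pytest.raises(ValueError, match="chrX"):
            scan_records(
                [site], FOCAL, OUTGROUP, loose_config, default_ceilings,
                {"chr1": 50_000}, window_bp=10_000,
            )


class TestEmpiricalP:
    def test_worked_example_with_ties(self):
        ps = empirical_p([0.5, 0.1, 0.3, 0.3, 0.9])
        assert list(ps) == pytest.approx([0.8, 0.2, 0.6, 0.6, 1.0])

    def test_all_equal(self):
        assert list(empirical_p([2.0] * 7)) == [1.0] * 7

    def test_two_values(self):
        assert list(empirical_p([1.0, 2.0])) == [0.5, 1.0]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            empirical_p([])

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1,
                    max_size=60))
    @settings(max_examples=100)
    def test_matches_bruteforce_count(self, ratios):
        ps = empirical_p(ratios)
        n = len(ratios)
        for r, p in zip(ratios, ps):
            assert p == pytest.approx(
                sum(1 for x in ratios if x <= r) / n
            )

    @given(
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=60),
        st.floats(0.01, 0.99),
    )
    @settings(max_examples=100)
    def test_tail_size_bound_and_monotonicity(self, ratios, alpha):
        """p is monotone in ratio; at most ceil(alpha N) windows have p < alpha."""
        ps = empirical_p(ratios)
        order = np.argsort(ratios)
        assert np.all(np.diff(np.asarray(ps)[order]) >= 0)
        assert np.sum(np.asarray(ps) < alpha) <= int(np.ceil(alpha * len(ratios)))

    def test_minimum_attainable_p(self):
        ps = empirical_p(list(range(10)))
        assert min(ps) == pytest.approx(0.1)


def _stat(L, ratio, start=0):
    return WindowStat(
        WindowSpec("chr1", start, start + 100), L, 1e-3,
        1e-3 / ratio if ratio else 0.0, ratio,
    )


class TestInfoDiagnostic:
    def test_monotone_relation_gives_unity(self):
        stats = [_stat(1000 + i, 0.1 * (i + 1), start=i * 100)
                 for i in range(10)]
        rho, table = info_diagnostic(stats)
        assert rho == pytest.approx(1.0)
        assert list(table.columns) == ["L", "ratio"]

    def test_constant_ratio_degenerate(self):
        stats = [_stat(1000 + i, 0.5, start=i * 100) for i in range(5)]
        with pytest.warns(UserWarning, match="degenerate"):
            rho, _ = info_diagnostic(stats)
        assert rho == 0.0

    def test_too_few_windows(self):
        with pytest.raises(ValueError):
            info_diagnostic([_stat(10, 0.5), _stat(11, 0.6, start=100)])

    def test_permutation_null_is_near_zero(self):
        rng = np.random.default_rng(123)
        ratios = rng.random(1000)
        stats = [
            _stat(int(1000 + i), float(r), start=i * 100)
            for i, r in enumerate(rng.permutation(ratios))
        ]
        rho, _ = info_diagnostic(stats)
        assert abs(rho) < 0.1

    def test_zero_divergence_windows_excluded(self):
        stats = [_stat(1000 + i, 0.1 * (i + 1), start=i * 100)
                 for i in range(5)]
        stats.append(
            WindowStat(WindowSpec("chr1", 900, 1000), 50, 0.0, 0.0, None)
        )
        rho, table = info_diagnostic(stats)
        assert len(table) == 5


def test_assign_empirical_p_skips_undefined_ratio():
    stats = [_stat(100, 0.5), _stat(100, 0.2, start=100)]
    stats.append(WindowStat(WindowSpec("chr1", 200, 300), 50, 0.0, 0.0, None))
    assign_empirical_p(stats)
    assert stats[0].empirical_p == pytest.approx(1.0)
    assert stats[1].empirical_p == pytest.approx(0.5)
    assert stats[2].empirical_p is None
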