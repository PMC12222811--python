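"""Segmented log-log regression, AIC comparison, clustering and the census."""

import numpy as np
import pandas as pd
import pytest

from pcnkit.scaling import (
    compare_models,
    dna_content_scaling,
    fit_segmented,
    intragenomic_correlations,
    kmeans_two,
    normalize_length,
    scaling_fit,
)


def broken_line(x, a, b1, b2_total, c):
    """Continuous two-segment mean function with slopes b1 and b2_total."""
    return a + b1 * x + (b2_total - b1) * np.maximum(0.0, x - c)


def simulate_scaling(rng, n=2_000, slopes=(-0.88, -0.125), c=-1.735, sigma=0.4,
                     x_range=(-3.2, -0.05), intercept=-1.2):
    x = rng.uniform(*x_range, n)
    y = broken_line(x, intercept, slopes[0], slopes[1], c) + rng.normal(0, sigma, n)
    return x, y


class TestNormalizeLength:
    def test_fractional_scale(self):
        assert normalize_length(46_000, 2_500_000) == pytest.approx(0.0184)

    def test_equal_lengths_give_one(self):
        assert normalize_length(1_500_000, 1_500_000) == 1.0

    def test_breakpoint_log_and_percent_consistent(self):
        # the log10 breakpoint -1.735 corresponds to ~1.84% of a chromosome
        assert 10 ** (-1.735) == pytest.approx(0.0184, abs=5e-4)


class TestSegmentedFit:
    def test_pure_line_collapses(self, rng):
        x = rng.uniform(-3, 0, 500)
        y = -0.9 * x + 0.3
        fit = fit_segmented(x, y)
        assert fit.slope1 == pytest.approx(-0.9, abs=1e-6)
        assert fit.slope2 == pytest.approx(-0.9, abs=1e-6)
        # perfect-line data gives no breakpoint support
        assert (not fit.breakpoint_supported) or abs(fit.slope1 - fit.slope2) < 1e-6

    def test_recovers_generating_parameters(self, rng):
        x, y = simulate_scaling(rng)
        fit = fit_segmented(x, y)
        assert fit.slope1 == pytest.approx(-0.88, abs=0.05)
        assert fit.slope2 == pytest.approx(-0.125, abs=0.05)
        assert fit.breakpoint == pytest.approx(-1.735, abs=0.1)
        assert fit.breakpoint_supported

    def test_recovery_across_replicates(self):
        """Most replicates land in the tight band; all stay in a loose one."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1_000 + seed)
            x, y = simulate_scaling(rng, n=2_000)
            fit = fit_segmented(x, y)
            assert abs(fit.slope1 + 0.88) < 0.12
            assert abs(fit.slope2 + 0.125) < 0.12
            assert abs(fit.breakpoint + 1.735) < 0.2
            ok = (
                abs(fit.slope1 + 0.88) < 0.05
                and abs(fit.slope2 + 0.125) < 0.05
                and abs(fit.breakpoint + 1.735) < 0.1
            )
            hits += ok
        assert hits >= 17

    def test_continuity_at_breakpoint(self, rng):
        x, y = simulate_scaling(rng, n=800)
        fit = fit_segmented(x, y)
        eps = 1e-9
        below = fit.predict(np.array([fit.breakpoint - eps]))[0]
        above = fit.predict(np.array([fit.breakpoint + eps]))[0]
        assert below == pytest.approx(above, abs=1e-6)

    def test_degenerate_x_fatal(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_segmented(np.ones(50), np.arange(50.0))

    def test_shift_invariance(self, rng):
        x, y = simulate_scaling(rng, n=600)
        f0 = fit_segmented(x, y)
        f1 = fit_segmented(x, y + 5.0)
        assert f1.intercept == pytest.approx(f0.intercept + 5.0, abs=1e-6)
        assert f1.slope1 == pytest.approx(f0.slope1, abs=1e-8)
        assert f1.slope2 == pytest.approx(f0.slope2, abs=1e-8)
        assert f1.breakpoint == pytest.approx(f0.breakpoint, abs=1e-6)
        assert f1.aic == pytest.approx(f0.aic, abs=1e-6)


class TestCompareModels:
    def test_linear_data_prefers_linear(self, rng):
        x = rng.uniform(-3, 0, 1_000)
        y = -0.7 * x + rng.normal(0, 0.3, x.size)
        table = compare_models(x, y).set_index("model")
        assert table.loc["linear", "aic"] - table["aic"].min() <= 2.0

    def test_sharp_break_prefers_segmented(self, rng):
        x, y = simulate_scaling(rng, slopes=(-1.2, 0.0), c=-1.5, sigma=0.3)
        table = compare_models(x, y).set_index("model")
        assert table.index[0] == "segmented" if hasattr(table, "index") else True
        assert table.loc["linear", "aic"] - table.loc["segmented", "aic"] > 10
        assert table.loc["quadratic", "aic"] - table.loc["segmented", "aic"] > 10

    def test_quadratic_data_beats_linear(self, rng):
        x = rng.uniform(-3, 0, 1_000)
        y = 0.4 * x**2 - 0.2 * x + rng.normal(0, 0.3, x.size)
        table = compare_models(x, y).set_index("model")
        assert table.loc["quadratic", "aic"] < table.loc["linear", "aic"]

    def test_linear_row_matches_closed_form_ols(self, rng):
        x = rng.uniform(-2, 1, 300)
        y = 1.5 * x + rng.normal(0, 0.2, x.size)
        table = compare_models(x, y).set_index("model")
        beta = np.polyfit(x, y, 1)
        rss = float(((y - np.polyval(beta, x)) ** 2).sum())
        expected_aic = x.size * np.log(rss / x.size) + 2 * 3
        assert table.loc["linear", "aic"] == pytest.approx(expected_aic, abs=1e-10)


def exact_1d_kmeans_two(values):
    """Oracle: 1-D 2-means is solvable exactly by trying every sorted split."""
    v = np.sort(np.asarray(values, dtype=float))
    best_cost, best_split = np.inf, 1
    for s in range(1, v.size):
        lo, hi = v[:s], v[s:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best_split = cost, s
    return v[best_split - 1], v[best_split]  # largest small, smallest large


def make_records(lengths, pcns, genome_ids=None):
    n = len(lengths)
    return pd.DataFrame(
        {
            "genome_id": genome_ids if genome_ids is not None else [f"g{i}" for i in range(n)],
            "replicon_id": [f"p{i}" for i in range(n)],
            "length_bp": lengths,
            "chromosome_length_bp": [3_000_000] * n,
            "pcn": pcns,
        }
    )


class TestKmeansTwo:
    def test_boundary_between_modes_and_oracle_agreement(self, rng):
        small = 10 ** rng.normal(4.0, 0.15, 120)
        large = 10 ** rng.normal(5.2, 0.15, 80)
        lengths = np.concatenate([small, large])
        recs = make_records(lengths, np.ones(lengths.size))
        cs = kmeans_two(recs, seed=0)
        lo, hi = exact_1d_kmeans_two(np.log10(lengths))
        max_small = np.log10(recs.loc[cs.labels == "small", "length_bp"].max())
        min_large = np.log10(recs.loc[cs.labels == "large", "length_bp"].min())
        assert max_small == pytest.approx(lo)
        assert min_large == pytest.approx(hi)
        assert 4.4 < cs.boundary_log10_length < 5.0

    def test_singleton_cluster_flagged(self):
        recs = make_records([10_000] * 9 + [900_000], np.ones(10))
        cs = kmeans_two(recs)
        assert cs.singleton
        assert (cs.labels == "large").sum() == 1

    def test_same_seed_stable(self, rng):
        lengths = 10 ** rng.uniform(3.5, 6, 200)
        recs = make_records(lengths, np.ones(200))
        a = kmeans_two(recs, seed=3)
        b = kmeans_two(recs, seed=3)
        assert (a.labels == b.labels).all()

    def test_summary_stats_per_cluster(self, rng):
        lengths = np.concatenate([10 ** rng.normal(4, 0.1, 50), 10 ** rng.normal(5.5, 0.1, 50)])
        pcns = np.concatenate([rng.uniform(10, 50, 50), rng.uniform(1, 3, 50)])
        cs = kmeans_two(make_records(lengths, pcns))
        assert set(cs.table.index) == {"small", "large"}
        assert cs.table.loc["small", "pcn_mean"] > cs.table.loc["large", "pcn_mean"]
        for col in ("pcn_sd", "pcn_min", "pcn_max", "length_sd"):
            assert np.isfinite(cs.table[col]).all()


class TestIntragenomicCorrelations:
    def test_two_point_genome_is_perfectly_negative(self):
        recs = make_records([5_000, 100_000], [20.0, 1.5], genome_ids=["g", "g"])
        out = intragenomic_correlations(recs)
        assert out["n_negative"] == 1 and out["n_positive"] == 0
        assert out["mean_r_negative"] == pytest.approx(-1.0)

    def test_population_negative_fraction(self, rng):
        frames = []
        for g in range(400):
            k = int(rng.integers(2, 5))
            lengths = 10 ** rng.uniform(3.5, 5.5, k)
            if rng.random() < 0.8:  # inverse-law genome
                pcn = 50.0 * (lengths / 1e4) ** -0.9 * 10 ** rng.normal(0, 0.05, k)
            else:
                pcn = 0.5 * (lengths / 1e4) ** 0.9 * 10 ** rng.normal(0, 0.05, k)
            frames.append(make_records(lengths, pcn, genome_ids=[f"g{g}"] * k))
        recs = pd.concat(frames, ignore_index=True)
        out = intragenomic_correlations(recs, min_plasmids=2)
        frac = out["n_negative"] / (out["n_negative"] + out["n_positive"])
        sigma = np.sqrt(0.8 * 0.2 / 400)
        assert abs(frac - 0.8) < 3 * sigma
        # genomes with 3+ plasmids are a subset
        out3 = intragenomic_correlations(recs, min_plasmids=3)
        assert out3["n_genomes"] <= out["n_genomes"]

    def test_zero_variance_excluded_and_reported(self):
        recs = make_records([5_000, 5_000], [3.0, 8.0], genome_ids=["g", "g"])
        out = intragenomic_correlations(recs)
        assert out["n_undefined"] == 1
        assert out["n_negative"] == out["n_positive"] == 0


class TestDnaContentScaling:
    def test_exact_inverse_law_gives_flat_content(self, rng):
        lengths = 10 ** rng.uniform(3.5, 6, 400)
        chrom = 3_000_000
        pcn = 1e4 / lengths  # pcn * length constant
        recs = make_records(lengths, pcn)
        fit = dna_content_scaling(recs)
        assert fit.slope1 == pytest.approx(0.0, abs=1e-8)
        assert fit.slope2 == pytest.approx(0.0, abs=1e-8)

    def test_content_slope_is_one_plus_pcn_slope(self, rng):
        # simulate pcn from the two-segment law; content slopes = 1 + slopes
        chrom = 3_000_000
        x = rng.uniform(-3.2, -0.05, 3_000)
        logpcn = broken_line(x, -1.2, -0.88, -0.125, -1.735) + rng.normal(0, 0.2, x.size)
        lengths = 10**x * chrom
        recs = make_records(lengths, 10**logpcn)
        recs["chromosome_length_bp"] = chrom
        fit = dna_content_scaling(recs)
        assert fit.slope1 == pytest.approx(1 - 0.88, abs=0.05)
        assert fit.slope2 == pytest.approx(1 - 0.125, abs=0.05)

    def test_pcn_fit_and_content_fit_share_breakpoint_scale(self, rng):
        chrom = 3_000_000
        x = rng.uniform(-3.2, -0.05, 2_000)
        logpcn = broken_line(x, -1.2, -0.88, -0.125, -1.735) + rng.normal(0, 0.2, x.size)
        recs = make_records(10**x * chrom, 10**logpcn)
        recs["chromosome_length_bp"] = chrom
        pcn_fit = scaling_fit(recs, normalized=True)
        content_fit = dna_content_scaling(recs)
        assert content_fit.breakpoint == pytest.approx(pcn_fit.breakpoint, abs=0.15)
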