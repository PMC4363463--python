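import math

import numpy as np
import pytest
from scipy import stats

from genematch.sampling import (
    RATIO_FLOOR,
    SamplingPlan,
    WeightVector,
    density_ratio_weights,
    kde_1d,
    kde_2d,
    nrd_bandwidth,
    replicate_seed,
    sample_matched_set,
    sample_replicates,
    top_weighted_set,
)
from conftest import gaussian_universe, gene_set, make_universe


def brute_kde_1d(data, bw, x):
    """Independent oracle: direct kernel sum with the standard normal pdf."""
    return sum(stats.norm.pdf((x - d) / bw) for d in data) / (len(data) * bw)


def brute_kde_2d(xs, ys, hx, hy, qx, qy):
    total = 0.0
    for x, y in zip(xs, ys):
        total += stats.norm.pdf((qx - x) / hx) * stats.norm.pdf((qy - y) / hy)
    return total / (len(xs) * hx * hy)


class TestKde1d:
    def test_hand_computed_kernel_sum(self):
        est = kde_1d([0.0, 1.0, 2.0], bandwidth=1.0)
        expected = (stats.norm.pdf(0) + stats.norm.pdf(1) + stats.norm.pdf(2)) / 3
        assert est.evaluate([0.0])[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_at_random_points(self, rng):
        data = rng.normal(size=50)
        est = kde_1d(data)
        queries = rng.uniform(-4, 4, size=20)
        got = est.evaluate(queries)
        for q, g in zip(queries, got):
            assert g == pytest.approx(brute_kde_1d(data, est.bandwidths[0], q), rel=1e-10)

    def test_symmetry(self):
        a = 1.7
        est = kde_1d([-a, a], bandwidth=0.5)
        xs = np.array([0.3, 1.1, 2.9])
        assert est.evaluate(xs) == pytest.approx(est.evaluate(-xs), rel=1e-12)

    def test_monte_carlo_consistency_at_zero(self, rng):
        draws = rng.normal(size=10_000)
        est = kde_1d(draws)
        assert est.evaluate([0.0])[0] == pytest.approx(1 / math.sqrt(2 * math.pi), rel=0.10)

    def test_integrates_to_one(self, rng):
        data = rng.normal(2.0, 1.5, size=200)
        est = kde_1d(data)
        bw = est.bandwidths[0]
        grid = np.linspace(data.min() - 5 * bw, data.max() + 5 * bw, 4000)
        integral = np.trapezoid(est.evaluate(grid), grid)
        assert 0.99 <= integral <= 1.01

    def test_identical_values_error(self):
        with pytest.raises(ValueError):
            kde_1d([3.0, 3.0, 3.0])

    def test_nrd_bandwidth_formula(self):
        vals = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        sd = np.std(vals, ddof=1)
        iqr = np.percentile(vals, 75) - np.percentile(vals, 25)
        expected = 0.9 * min(sd, iqr / 1.34) * 5 ** (-0.2)
        assert nrd_bandwidth(vals) == pytest.approx(expected, rel=1e-12)


class TestKde2d:
    def test_single_point_closed_form(self):
        est = kde_2d([0.0, 0.0], [0.0, 0.0], bandwidths=(1.0, 1.0))
        # both kernels sit at the origin, so value there is 1/(2*pi)
        assert est.evaluate([[0.0, 0.0]])[0] == pytest.approx(1 / (2 * math.pi), rel=1e-12)

    def test_point_symmetry(self):
        est = kde_2d([-1.0, 1.0], [-2.0, 2.0], bandwidths=(0.8, 1.2))
        p = est.evaluate([[0.4, 0.9]])[0]
        q = est.evaluate([[-0.4, -0.9]])[0]
        assert p == pytest.approx(q, rel=1e-12)

    def test_three_point_brute_force(self):
        xs, ys = [0.0, 1.0, -0.5], [2.0, -1.0, 0.25]
        est = kde_2d(xs, ys, bandwidths=(0.7, 1.3))
        q = (0.2, 0.4)
        assert est.evaluate([q])[0] == pytest.approx(brute_kde_2d(xs, ys, 0.7, 1.3, *q), rel=1e-10)

    def test_degenerate_dimension_error(self):
        with pytest.raises(ValueError):
            kde_2d([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


def uniform_weights(universe):
    n = len(universe)
    return WeightVector(
        symbols=universe.symbols,
        raw_ratio=np.ones(n),
        probability=np.full(n, 1.0 / n),
        mode="expression",
    )


def explicit_weights(universe, probs):
    probs = np.asarray(probs, dtype=float)
    return WeightVector(
        symbols=universe.symbols, raw_ratio=probs.copy(), probability=probs, mode="expression"
    )


class TestWeightVector:
    def test_normalization_enforced(self, tiny_universe):
        with pytest.raises(ValueError):
            explicit_weights(tiny_universe, [0.5, 0.5, 0.5, 0.0, 0.0][: len(tiny_universe)])

    def test_negative_rejected(self, tiny_universe):
        with pytest.raises(ValueError):
            explicit_weights(tiny_universe, [1.2, -0.2, 0.0, 0.0, 0.0])

    def test_tsv_round_trip(self, tiny_universe, tmp_path):
        import pandas as pd

        w = uniform_weights(tiny_universe)
        w.write_tsv(tmp_path / "w.tsv")
        df = pd.read_csv(tmp_path / "w.tsv", sep="\t")
        assert list(df["symbol"]) == list(tiny_universe.symbols)
        assert df["probability"].sum() == pytest.approx(1.0, abs=1e-12)


class TestDensityRatioWeights:
    def test_target_equals_universe_gives_uniform(self, rng):
        u = gaussian_universe(300, seed=11)
        w = density_ratio_weights(u, u.symbol_set("all"), mode="expression")
        assert w.probability == pytest.approx(np.full(300, 1 / 300), rel=1e-6)

    def test_bimodal_upper_mode_upweighted(self, rng):
        lower = rng.normal(-3, 0.5, size=200)
        upper = rng.normal(3, 0.5, size=200)
        recs = [(f"L{i}", float(v), None, None, None) for i, v in enumerate(lower)]
        recs += [(f"U{i}", float(v), None, None, None) for i, v in enumerate(upper)]
        u = make_universe(recs)
        target = gene_set("upper", *[f"U{i}" for i in range(0, 200, 4)])
        w = density_ratio_weights(u, target, mode="expression")
        mean_upper = w.probability[200:].mean()
        mean_lower = w.probability[:200].mean()
        assert mean_upper > mean_lower

    def test_importance_weighting_recovers_target_mean(self, rng):
        # 450 base genes at N(0,1), 50 target genes at N(2,1): the weighted
        # mean of expression must land near the target's own mean
        base = rng.normal(0, 1, size=450)
        shifted = rng.normal(2, 1, size=50)
        recs = [(f"B{i}", float(v), None, None, None) for i, v in enumerate(base)]
        recs += [(f"T{i}", float(v), None, None, None) for i, v in enumerate(shifted)]
        u = make_universe(recs)
        target = gene_set("shifted", *[f"T{i}" for i in range(50)])
        w = density_ratio_weights(u, target, mode="expression")
        weighted_mean = float(np.dot(w.probability, u.covariate("log_expr")))
        assert weighted_mean == pytest.approx(shifted.mean(), abs=0.2)

    def test_small_target_error(self):
        u = gaussian_universe(50, seed=1)
        with pytest.raises(ValueError):
            density_ratio_weights(u, gene_set("tiny", "S00001"), mode="expression")

    def test_floor_applied(self, rng):
        # a target far from most of the universe drives ratios to the floor
        base = rng.normal(0, 0.3, size=400)
        far = rng.normal(40, 0.3, size=10)
        recs = [(f"B{i}", float(v), None, None, None) for i, v in enumerate(base)]
        recs += [(f"F{i}", float(v), None, None, None) for i, v in enumerate(far)]
        u = make_universe(recs)
        w = density_ratio_weights(u, gene_set("far", *[f"F{i}" for i in range(10)]))
        assert w.raw_ratio.min() == pytest.approx(RATIO_FLOOR)
        assert np.all(w.probability > 0)

    def test_2d_mode_uses_both_covariates(self, rng):
        n = 400
        expr = rng.normal(5, 2, size=n)
        cds = rng.normal(10, 1, size=n)
        recs = [(f"G{i:03d}", float(expr[i]), float(cds[i]), 11.0, None) for i in range(n)]
        u = make_universe(recs)
        idx = np.argsort(expr + cds)[-60:]
        target = gene_set("big", *[f"G{i:03d}" for i in idx])
        w = density_ratio_weights(u, target, mode="both_2d")
        assert len(w.bandwidths["target"]) == 2
        top = np.argsort(w.probability)[-60:]
        assert (expr[top].mean() > expr.mean()) and (cds[top].mean() > cds.mean())


class TestSampleMatchedSet:
    def test_degenerate_weight_always_first_gene(self, tiny_universe):
        w = explicit_weights(tiny_universe, [1.0, 0.0, 0.0, 0.0, 0.0])
        for seed in range(10):
            assert sample_matched_set(tiny_universe, w, 1, seed=seed).symbols == {"A1"}

    def test_full_pool_returned(self, tiny_universe):
        w = explicit_weights(tiny_universe, [0.9, 0.025, 0.025, 0.025, 0.025])
        got = sample_matched_set(tiny_universe, w, 5, seed=0)
        assert got.symbols == frozenset(tiny_universe.symbols)

    def test_seed_determinism(self, tiny_universe):
        w = uniform_weights(tiny_universe)
        a = sample_matched_set(tiny_universe, w, 3, seed=42)
        b = sample_matched_set(tiny_universe, w, 3, seed=42)
        assert a.symbols == b.symbols

    def test_insufficient_pool_names_shortfall(self, tiny_universe):
        w = uniform_weights(tiny_universe)
        with pytest.raises(ValueError, match="pool"):
            sample_matched_set(tiny_universe, w, 4, exclude=gene_set("x", "A1", "B2"), seed=0)

    def test_exclusion_soundness(self, tiny_universe):
        w = uniform_weights(tiny_universe)
        excl = gene_set("x", "A1", "D4")
        for seed in range(25):
            got = sample_matched_set(tiny_universe, w, 3, exclude=excl, seed=seed)
            assert not (got.symbols & excl.symbols)

    def test_inclusion_frequency_matches_sequential_enumeration(self):
        # Oracle: exhaustive sequential-draw probability that gene 1 appears in
        # a 2-of-3 weighted draw without replacement with weights (.5,.3,.2):
        #   P = w1 + sum_{j != 1} w_j * w1 / (1 - w_j)
        w1, w2, w3 = 0.5, 0.3, 0.2
        p_incl = w1 + w2 * w1 / (1 - w2) + w3 * w1 / (1 - w3)
        u = make_universe([(s, 1.0, None, None, None) for s in ("X1", "X2", "X3")])
        w = explicit_weights(u, [w1, w2, w3])
        reps = 20_000
        hits = sum(
            "X1" in sample_matched_set(u, w, 2, seed=seed).symbols for seed in range(reps)
        )
        se = math.sqrt(p_incl * (1 - p_incl) / reps)
        assert abs(hits / reps - p_incl) < 3 * se


def shifted_universe_and_target(n_base, n_target, seed, shift=1.5, sd=2.0):
    r = np.random.default_rng(seed)
    base = r.normal(0.0, sd, size=n_base)
    shifted = r.normal(shift, sd, size=n_target)
    recs = [(f"B{i:05d}", float(v), 10.0, 11.0, None) for i, v in enumerate(base)]
    recs += [(f"T{i:05d}", float(v), 10.0, 11.0, None) for i, v in enumerate(shifted)]
    u = make_universe(recs)
    target = gene_set("shifted", *[f"T{i:05d}" for i in range(n_target)])
    return u, target, shifted


class TestSampleReplicates:
    def test_determinism_and_sizes(self):
        u, target, _ = shifted_universe_and_target(500, 60, seed=5)
        w = density_ratio_weights(u, target)
        plan = SamplingPlan(mode="expression", n_per_set=40, n_replicates=3, seed=9)
        reps1 = sample_replicates(u, w, plan)
        reps2 = sample_replicates(u, w, plan)
        assert [r.symbols for r in reps1] == [r.symbols for r in reps2]
        assert all(len(r) == 40 for r in reps1)

    def test_replicates_differ_from_each_other(self):
        u, target, _ = shifted_universe_and_target(500, 60, seed=5)
        w = density_ratio_weights(u, target)
        reps = sample_replicates(u, w, SamplingPlan("expression", 40, 5, seed=9))
        assert len({r.symbols for r in reps}) > 1

    def test_replicate_seed_is_order_independent(self):
        u, target, _ = shifted_universe_and_target(500, 60, seed=5)
        w = density_ratio_weights(u, target)
        direct = sample_matched_set(u, w, 40, seed=replicate_seed(9, 2))
        reps = sample_replicates(u, w, SamplingPlan("expression", 40, 3, seed=9))
        assert reps[2].symbols == direct.symbols

    def test_exclusions_respected_in_all_replicates(self):
        u, target, _ = shifted_universe_and_target(500, 60, seed=5)
        w = density_ratio_weights(u, target)
        plan = SamplingPlan("expression", 40, 20, exclude=target, seed=1)
        for rep in sample_replicates(u, w, plan):
            assert not (rep.symbols & target.symbols)

    def test_pooled_replicates_match_target_distribution(self):
        u, target, shifted = shifted_universe_and_target(1800, 200, seed=7)
        w = density_ratio_weights(u, target)
        plan = SamplingPlan("expression", 200, 100, seed=3)
        reps = sample_replicates(u, w, plan)
        pooled = np.concatenate(
            [[u.record(s).log_expr for s in rep.symbols] for rep in reps]
        )
        expr = u.covariate("log_expr")
        ks_matched = stats.ks_2samp(pooled, shifted)
        ks_universe = stats.ks_2samp(expr, shifted)
        assert ks_matched.pvalue > 0.01  # matched draws pass
        assert ks_matched.statistic < ks_universe.statistic  # and beat raw universe


class TestTopWeightedSet:
    def test_top_excluded_pattern(self):
        u, target, _ = shifted_universe_and_target(300, 50, seed=2)
        w = density_ratio_weights(u, target)
        top = top_weighted_set(u, w, 50, exclude=target)
        assert len(top) == 50
        assert not (top.symbols & target.symbols)
        # highest-weight non-target genes: mean expression above universe mean
        mean_top = np.mean([u.record(s).log_expr for s in top.symbols])
        assert mean_top > u.covariate("log_expr").mean()
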