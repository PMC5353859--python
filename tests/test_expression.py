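import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secrepath.expression import (
    ExpressionError,
    ExpressionMatrix,
    GrowthRecord,
    adjust_and_flag_de,
    benjamini_hochberg,
    compute_cpm,
    doubling_time,
    filter_expressed,
    fit_growth_rate,
    specific_productivity,
    tmm_factors,
)


def bh_oracle(p):
    """Brute-force step-up BH: adj_(i) = min_{j>=i} n*p_(j)/j, capped at 1."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = math.inf
    for pos in range(n - 1, -1, -1):
        i = order[pos]
        running = min(running, n * p[i] / (pos + 1))
        adj[i] = min(running, 1.0)
    return adj


class TestComputeCpm:
    def test_single_sample_values(self):
        counts = pd.DataFrame({"s1": [1, 3, 6]}, index=["a", "b", "c"])
        cpm = compute_cpm(counts).values
        assert np.allclose(cpm["s1"], [1e5, 3e5, 6e5])

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)),
                              columns=list("abcd"))
        cpm = compute_cpm(counts).values
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_scale_invariance_of_libsize_cpm(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 100, size=(30, 3)))
        doubled = counts.copy()
        doubled[0] = counts[0] * 2
        a = compute_cpm(counts).values[0]
        b = compute_cpm(doubled).values[0]
        assert np.allclose(a, b)

    def test_all_zero_sample_names_sample(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(ExpressionError, match="empty"):
            compute_cpm(counts)

    def test_no_samples(self):
        with pytest.raises(ExpressionError):
            compute_cpm(pd.DataFrame(index=["g1"]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ExpressionError):
            compute_cpm(pd.DataFrame({"s": [-1, 2]}))

    def test_log2_scale(self):
        counts = pd.DataFrame({"s1": [1, 3, 6]})
        log = compute_cpm(counts, log2=True)
        assert log.scale == "log2cpm"
        assert np.allclose(log.values["s1"], np.log2([1e5 + 1, 3e5 + 1, 6e5 + 1]))


class TestTmm:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 20, 40], "b": [5, 10, 20, 40]})
        factors = tmm_factors(counts)
        assert np.allclose(factors, [1.0, 1.0])

    def test_factors_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.05, size=(200, 5)))
        counts.iloc[:, 0] *= 3
        factors = tmm_factors(counts)
        assert np.isclose(np.exp(np.log(factors).mean()), 1.0)

    def test_pure_depth_difference_factor_near_one(self):
        # doubling depth changes the library size, not the composition
        rng = np.random.default_rng(4)
        base = rng.negative_binomial(5, 0.05, size=(500, 1))
        counts = pd.DataFrame(np.hstack([base, base * 2]))
        factors = tmm_factors(counts)
        assert np.allclose(factors, 1.0, atol=0.05)

    def test_tmm_cpm_runs(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(100, 4)))
        expr = compute_cpm(counts, "tmm")
        assert expr.normalization == "tmm"
        assert expr.scaling_factors is not None


class TestFilterExpressed:
    def make(self, rows):
        return ExpressionMatrix(pd.DataFrame(rows).T)

    def test_kept_with_two_samples(self):
        expr = self.make({"g": [2.0, 0.0, 0.0, 3.0]})
        kept, report = filter_expressed(expr)
        assert list(kept.values.index) == ["g"]
        assert report.n_kept == 1

    def test_removed_with_one_sample(self):
        expr = self.make({"g": [5.0, 0.0, 0.0, 0.0]})
        kept, report = filter_expressed(expr)
        assert len(kept.values) == 0
        assert report.n_removed == 1

    def test_empty_matrix(self):
        expr = ExpressionMatrix(pd.DataFrame())
        kept, _ = filter_expressed(expr)
        assert kept.values.empty

    def test_min_samples_exceeds_columns(self):
        expr = self.make({"g": [2.0, 2.0]})
        with pytest.raises(ExpressionError):
            filter_expressed(expr, min_samples=3)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        expr = ExpressionMatrix(pd.DataFrame(rng.exponential(2, size=(50, 6))))
        once, _ = filter_expressed(expr)
        twice, _ = filter_expressed(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_monotone_in_min_cpm(self):
        rng = np.random.default_rng(7)
        expr = ExpressionMatrix(pd.DataFrame(rng.exponential(2, size=(100, 6))))
        kept_counts = [
            filter_expressed(expr, min_cpm=c)[1].n_kept for c in (0.5, 1, 2, 4)
        ]
        assert kept_counts == sorted(kept_counts, reverse=True)

    def test_requires_cpm_scale(self):
        expr = ExpressionMatrix(pd.DataFrame({"s": [1.0]}), scale="log2cpm")
        with pytest.raises(ExpressionError):
            filter_expressed(expr)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        # p*n/rank: (0.04, 0.04, 0.04, 0.04) after step-up monotonisation
        adjusted = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_matches_oracle_on_grid_vectors(self):
        rng = np.random.default_rng(8)
        grid = np.round(np.arange(0.0, 1.01, 0.01), 2)
        for length in range(1, 7):
            for _ in range(300):
                p = rng.choice(grid, size=length)
                assert np.allclose(
                    benjamini_hochberg(p), bh_oracle(p), atol=1e-12
                )

    def test_exhaustive_length_two(self):
        grid = np.round(np.arange(0.0, 1.01, 0.01), 2)
        for p1 in grid:
            for p2 in grid:
                p = np.array([p1, p2])
                assert np.allclose(benjamini_hochberg(p), bh_oracle(p))

    def test_invalid_p(self):
        with pytest.raises(ExpressionError):
            benjamini_hochberg(np.array([0.5, 1.5]))

    def test_empty(self):
        assert benjamini_hochberg(np.array([])).size == 0

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_property_adjusted_at_least_raw(self, p):
        adjusted = benjamini_hochberg(np.array(p))
        assert (adjusted >= np.array(p) - 1e-12).all()
        assert (adjusted <= 1.0).all()


class TestFlagDe:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2FC", "p"])

    def test_up(self):
        table = self.make([("g", 2.5, 0.001), ("h", 0.0, 0.9)])
        out = adjust_and_flag_de(table)
        assert out.set_index("gene").loc["g", "status"] == "up"

    def test_down(self):
        table = self.make([("g", -2.5, 0.001), ("h", 0.0, 0.9)])
        out = adjust_and_flag_de(table)
        assert out.set_index("gene").loc["g", "status"] == "down"

    def test_de_below_fold(self):
        table = self.make([("g", -1.0, 0.0001), ("h", 0.0, 0.9)])
        out = adjust_and_flag_de(table)
        assert out.set_index("gene").loc["g", "status"] == "de_below_fold"

    def test_not_significant(self):
        table = self.make([("g", 3.0, 0.5)])
        out = adjust_and_flag_de(table)
        assert out.loc[0, "status"] == "not_significant"

    def test_p_out_of_range(self):
        with pytest.raises(ExpressionError):
            adjust_and_flag_de(self.make([("g", 0.0, 2.0)]))

    def test_missing_column(self):
        with pytest.raises(ExpressionError, match="log2FC"):
            adjust_and_flag_de(pd.DataFrame({"gene": ["g"], "p": [0.1]}))


class TestGrowthMetrics:
    def test_ln2_identity(self):
        assert doubling_time(math.log(2)) == pytest.approx(1.0)

    def test_inverse_identity(self):
        for td in (5.0, 19.6, 93.1):
            assert doubling_time(math.log(2) / td) == pytest.approx(td)

    def test_nonpositive_mu(self):
        with pytest.raises(ExpressionError):
            doubling_time(0.0)
        with pytest.raises(ExpressionError):
            doubling_time(-0.01)

    def test_fit_exact_exponential(self):
        t = np.linspace(0, 48, 9)
        record = GrowthRecord(t, 1e5 * np.exp(0.03 * t))
        assert fit_growth_rate(record) == pytest.approx(0.03, abs=1e-12)

    def test_fit_constant_density(self):
        record = GrowthRecord(np.arange(5.0), np.full(5, 2e6))
        assert fit_growth_rate(record) == pytest.approx(0.0, abs=1e-12)

    def test_fit_noisy_recovery(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 70, 8)
        x = 1e5 * np.exp(0.025 * t) * np.exp(rng.normal(0, 0.05, 8))
        record = GrowthRecord(t, x)
        assert fit_growth_rate(record) == pytest.approx(0.025, abs=0.003)

    def test_fit_window(self):
        t = np.linspace(0, 100, 11)
        x = 1e5 * np.exp(0.03 * np.minimum(t, 50))  # plateau after 50 h
        record = GrowthRecord(t, x)
        assert fit_growth_rate(record, window=(0, 50)) == pytest.approx(0.03)

    def test_fit_too_few_points(self):
        record = GrowthRecord([0.0, 1.0], [0.0, 1e5])
        with pytest.raises(ExpressionError):
            fit_growth_rate(record)


class TestSpecificProductivity:
    def test_hand_trapezoid(self):
        record = GrowthRecord(
            time=[0.0, 10.0],
            viable_density=[1e6, 1e6],
            titer=[0.0, 10.0],
        )
        assert specific_productivity(record) == pytest.approx(1.0)

    def test_zero_titer_change(self):
        record = GrowthRecord([0.0, 10.0], [1e6, 1e6], [5.0, 5.0])
        assert specific_productivity(record) == 0.0

    def test_decreasing_titer_warns_negative(self):
        record = GrowthRecord([0.0, 10.0], [1e6, 1e6], [10.0, 5.0])
        with pytest.warns(UserWarning):
            q = specific_productivity(record)
        assert q < 0

    def test_single_timepoint(self):
        record = GrowthRecord([0.0], [1e6], [1.0])
        with pytest.raises(ExpressionError):
            specific_productivity(record)


class TestGrowthRecordInvariants:
    def test_time_must_increase(self):
        with pytest.raises(ExpressionError):
            GrowthRecord([0.0, 0.0], [1.0, 1.0])

    def test_negative_density(self):
        with pytest.raises(ExpressionError):
            GrowthRecord([0.0, 1.0], [1.0, -1.0])
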