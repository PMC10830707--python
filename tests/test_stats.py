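"""Transect summaries, OLS, Kruskal-Wallis/post hoc, t-test and correlations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from isomix.stats import (
    correlate,
    kruskal_wallis,
    posthoc_dunn,
    posthoc_dunnett,
    sex_ttest_log,
    simple_ols,
    summarize_transects,
)


class TestTransects:
    def test_constant_reliefs(self):
        t = summarize_transects("DM", [15, 15, 15, 15, 15])
        assert t.slope_mean == pytest.approx(0.2)
        assert t.slope_sd == pytest.approx(0.0)

    def test_two_transects(self):
        t = summarize_transects("X", [0, 75])
        assert t.slopes == (0.0, 1.0)
        assert t.slope_mean == pytest.approx(0.5)

    def test_hand_computed_mean_sd(self):
        reliefs = [30.0, 22.5, 7.5, 15.0, 37.5]
        t = summarize_transects("Y", reliefs)
        slopes = np.array(reliefs) / 75.0
        assert t.slope_mean == pytest.approx(slopes.mean())
        assert t.slope_sd == pytest.approx(slopes.std(ddof=1))

    def test_order_invariant(self):
        a = summarize_transects("A", [5, 10, 20, 40, 60])
        b = summarize_transects("A", [60, 40, 20, 10, 5])
        assert a.slope_mean == b.slope_mean and a.slope_sd == b.slope_sd

    def test_negative_relief_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            summarize_transects("Z", [5, -1])


class TestOLS:
    def test_exact_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = simple_ols(x, [2 * v + 1 for v in x])
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1.0)

    def test_constant_y(self):
        r = simple_ols([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert r.slope == pytest.approx(0.0)
        assert r.r2 == pytest.approx(0.0)

    def test_constant_x_degenerate(self):
        with pytest.raises(ValueError, match="constant x"):
            simple_ols([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @given(st.integers(min_value=0, max_value=1000))
    def test_f_identity_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        x = rng.standard_normal(n)
        y = 1.5 * x + rng.standard_normal(n)
        r = simple_ols(x, y)
        assert r.f_stat == pytest.approx(r.r2 / (1 - r.r2) * (n - 2), abs=1e-9)
        assert r.df == (1, n - 2)


class TestKruskal:
    def test_all_identical_h_zero(self):
        res = kruskal_wallis({"a": [3, 3, 3], "b": [3, 3], "c": [3, 3, 3]})
        assert res.statistic == pytest.approx(0.0)

    def test_brute_force_rank_oracle(self):
        # ranks 1..9 without ties: H = 12/(N(N+1)) * sum n_i Rbar_i^2 - 3(N+1)
        # group mean ranks 2, 5, 8 -> H = (12/90)*3*(4+25+64) - 30 = 7.2
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_group_order_symmetry(self):
        g = {"a": [1.0, 4.0, 2.0], "b": [5.0, 7.0], "c": [3.0, 9.0, 8.0]}
        rev = {k: g[k] for k in reversed(list(g))}
        assert kruskal_wallis(g).statistic == pytest.approx(kruskal_wallis(rev).statistic)

    @given(st.integers(min_value=0, max_value=200))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        g = {k: rng.standard_normal(int(rng.integers(3, 9))) for k in "abc"}
        h1 = kruskal_wallis(g, posthoc="none").statistic
        h2 = kruskal_wallis({k: np.exp(v) for k, v in g.items()}, posthoc="none").statistic
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0], "b": [2.0, 3.0]})

    def test_dunn_detects_separated_group(self):
        g = {"lo": [1.0, 2.0, 1.5, 2.2, 1.8], "mid": [2.1, 2.4, 1.9, 2.6, 2.3],
             "hi": [9.0, 10.0, 11.0, 9.5, 10.5]}
        pairs = dict(((a, b), p) for a, b, p in posthoc_dunn(g))
        assert pairs[("lo", "hi")] < 0.05
        assert pairs[("lo", "mid")] > 0.05

    def test_dunnett_alternative_runs(self):
        g = {"control": [1.0, 1.2, 0.9, 1.1], "t1": [1.0, 1.1, 1.2, 0.8],
             "t2": [5.0, 5.5, 4.8, 5.2]}
        pairs = dict(((a, b), p) for a, b, p in posthoc_dunnett(g))
        assert pairs[("control", "t2")] < 0.01
        assert pairs[("control", "t1")] > 0.5


class TestTTestAndCorrelation:
    def test_mirrored_groups_t_zero(self):
        a = [10.0, 20.0, 30.0, 40.0]
        res = sex_ttest_log({"F": a, "M": list(a)})
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.df == 6

    def test_nonpositive_percent_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="nonpositive"):
            res = sex_ttest_log({"F": [10.0, 20.0, 0.0], "M": [15.0, 25.0]})
        assert res.n_excluded == 1
        assert res.df == 2  # (3-1) + 2 - 2 after exclusion

    def test_perfect_linear_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = correlate(x, [2 * v for v in x])
        assert res.r == pytest.approx(1.0)
        assert res.df == 3

    def test_pearson_closed_form_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 100, 10)
        y = 0.4 * x + rng.standard_normal(10) * 10
        res = correlate(x, y)
        # independent oracle: covariance over the product of SDs
        r_hand = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        assert res.df == 8
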