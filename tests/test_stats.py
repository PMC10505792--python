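"""ANOVA, Dunnett and Tukey against hand computation, scipy and Monte Carlo."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mpq.stats import (
    dunnett_sf,
    dunnett_test,
    one_way_anova,
    stars,
    summarize,
    tukey_hsd,
)


class TestAnova:
    def test_identical_groups_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0 and res.p == 1.0

    def test_hand_computed_example(self):
        # SSB = 6 (df 2), SSW = 6 (df 6) -> F = 3.0
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.F == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p == pytest.approx(sps.f.sf(3.0, 2, 6))

    def test_location_invariance(self):
        g = [[1.0, 2, 3], [2, 4, 5], [1, 1, 2]]
        shifted = [[x + 17.3 for x in grp] for grp in g]
        assert one_way_anova(g).F == pytest.approx(one_way_anova(shifted).F)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="F undefined"):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_matches_scipy_f_oneway(self, rng):
        g = [rng.normal(i, 1, 12) for i in range(3)]
        res = one_way_anova(g)
        F, p = sps.f_oneway(*g)
        assert res.F == pytest.approx(F) and res.p == pytest.approx(p)


class TestDunnett:
    def test_single_treatment_reduces_to_t_test(self, rng):
        g = {"ctrl": rng.normal(0, 1, 10), "t1": rng.normal(1, 1, 10)}
        res = dunnett_test(g, "ctrl")
        row = res.comparisons.iloc[0]
        assert row["p_adj"] == pytest.approx(row["p_unadj"], abs=2e-4)

    def test_missing_control_raises(self):
        with pytest.raises(ValueError, match="control"):
            dunnett_test({"a": [1, 2, 3], "b": [2, 3, 4]}, "zzz")

    def test_dominance_over_unadjusted(self, rng):
        g = {
            "ctrl": rng.normal(0, 1, 12),
            "a": rng.normal(0.5, 1, 12),
            "b": rng.normal(0, 1, 9),
            "c": rng.normal(-1, 1, 15),
        }
        res = dunnett_test(g, "ctrl")
        assert (res.comparisons["p_adj"] >= res.comparisons["p_unadj"]).all()

    def test_matches_scipy_dunnett(self, rng):
        ctrl = rng.normal(0, 1, 15)
        a = rng.normal(0.7, 1, 15)
        b = rng.normal(-0.2, 1, 12)
        res = dunnett_test({"ctrl": ctrl, "a": a, "b": b}, "ctrl")
        ref = sps.dunnett(a, b, control=ctrl, random_state=0)
        got = res.comparisons.set_index("group")["p_adj"]
        assert got["a"] == pytest.approx(ref.pvalue[0], abs=1e-3)
        assert got["b"] == pytest.approx(ref.pvalue[1], abs=1e-3)

    def test_sf_against_monte_carlo_oracle(self):
        """Balanced 3-treatment design: quadrature within 0.01 of a
        10^6-draw max-|T| Monte Carlo simulation."""
        n, k, n_draws = 10, 3, 1_000_000
        df = (k + 1) * n - (k + 1)
        rng = np.random.default_rng(99)
        means = rng.normal(0, 1 / np.sqrt(n), size=(n_draws, k + 1))
        s2 = rng.chisquare(df, size=n_draws) / df
        t_stats = (means[:, 1:] - means[:, :1]) / np.sqrt(s2[:, None] * (2 / n))
        max_abs = np.abs(t_stats).max(axis=1)
        for t_obs in (1.5, 2.2, 2.8):
            p_mc = (max_abs >= t_obs).mean()
            p_quad = dunnett_sf(t_obs, df, n, np.full(k, n))
            assert abs(p_mc - p_quad) <= 0.01

    def test_familywise_type_i_error_calibrated(self):
        """Null simulation (4 groups, n = 15, 2000 replicates): fraction of
        replicates with any significant comparison near alpha = 0.05."""
        n, reps = 15, 2000
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(reps):
            data = rng.normal(0, 1, size=(4, n))
            m = data.mean(axis=1)
            s2 = data.var(axis=1, ddof=1).mean()
            df = 4 * (n - 1)
            t = (m[1:] - m[0]) / np.sqrt(s2 * 2 / n)
            p = dunnett_sf(np.abs(t).max(), df, n, np.full(3, n))
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07


class TestTukey:
    def test_identical_pair_p_near_one(self):
        g = {
            "a": [1.0, 2.0, 3.0, 2.0],
            "b": [1.0, 2.0, 3.0, 2.0],
            "c": [5.0, 6.0, 7.0, 6.0],
        }
        res = tukey_hsd(g)
        row = res.comparisons.set_index("comparison").loc["a vs b"]
        assert row["p_adj"] > 0.99

    def test_dominance_over_unadjusted(self, rng):
        g = {k: rng.normal(i * 0.4, 1, 10) for i, k in enumerate("abcd")}
        res = tukey_hsd(g)
        assert (res.comparisons["p_adj"] >= res.comparisons["p_unadj"]).all()

    def test_matches_scipy_tukey(self, rng):
        g = [rng.normal(i * 0.5, 1, 9) for i in range(3)]
        res = tukey_hsd({"a": g[0], "b": g[1], "c": g[2]})
        ref = sps.tukey_hsd(*g)
        got = res.comparisons.set_index("comparison")["p_adj"]
        assert got["a vs b"] == pytest.approx(ref.pvalue[0, 1], abs=1e-9)
        assert got["a vs c"] == pytest.approx(ref.pvalue[0, 2], abs=1e-9)
        assert got["b vs c"] == pytest.approx(ref.pvalue[1, 2], abs=1e-9)

    def test_against_studentized_range_monte_carlo(self):
        """Balanced 4-group design: Tukey p within 0.01 of a 10^6-draw
        studentized-range Monte Carlo oracle."""
        n, k, n_draws = 8, 4, 1_000_000
        df = k * (n - 1)
        rng = np.random.default_rng(123)
        means = rng.normal(0, 1 / np.sqrt(n), size=(n_draws, k))
        s2 = rng.chisquare(df, size=n_draws) / df
        q = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(s2 / n)
        for q_obs in (2.5, 3.5, 4.2):
            p_mc = (q >= q_obs).mean()
            p_dist = sps.studentized_range.sf(q_obs, k, df)
            assert abs(p_mc - p_dist) <= 0.01

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1, 2, 3], "b": [2, 3, 4]})


class TestSummaries:
    def test_constant_group(self):
        out = summarize({"g": [2.0, 2.0, 2.0]})
        assert out["mean"].iloc[0] == 2.0 and out["sd"].iloc[0] == 0.0

    def test_two_point_sd(self):
        out = summarize({"g": [1.0, 3.0]})
        assert out["mean"].iloc[0] == 2.0
        assert out["sd"].iloc[0] == pytest.approx(np.sqrt(2))

    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.03, "*"),
            (0.2, "ns"),
            (0.009, "**"),
            (0.0009, "***"),
            (0.00009, "****"),
            (0.05, "ns"),
        ],
    )
    def test_star_mapping(self, p, expected):
        assert stars(p) == expected

    def test_summary_string_renders(self, rng):
        g = {"ctrl": rng.normal(0, 1, 8), "a": rng.normal(2, 1, 8)}
        text = dunnett_test(g, "ctrl").summary()
        assert "ANOVA" in text and "a vs ctrl" in text


@settings(derandomize=True, max_examples=25)
@given(
    st.lists(
        st.lists(st.floats(-50, 50), min_size=4, max_size=8),
        min_size=3,
        max_size=5,
    ),
    st.data(),
)
def test_dunnett_dominance_property(groups, data):
    """Adjusted p >= unadjusted p for arbitrary group data."""
    gd = {f"g{i}": np.array(v) + 1e-3 * i for i, v in enumerate(groups)}
    try:
        res = dunnett_test(gd, "g0")
    except ValueError:
        return  # degenerate variance; precondition violated
    assert (res.comparisons["p_adj"] >= res.comparisons["p_unadj"] - 1e-12).all()
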