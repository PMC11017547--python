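"""Quartile assignment, the ln-scale GLM with sandwich SEs, and reporting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rxaccess.disparity import (
    QuartileDisparityModel,
    assign_quartiles,
    binned_trends,
    fit_quartile_glm,
    quartile_descriptives,
    to_percent_difference,
)

from _oracles import ols_beta, sandwich_cov


def _records(pwmsd, cov, ids=None, **extra):
    n = len(pwmsd)
    df = pd.DataFrame(
        {
            "tract_id": ids if ids is not None else [f"t{i:04d}" for i in range(n)],
            "pwmsd_km": pwmsd,
            "population": 100,
            "cov": cov,
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


class TestAssignQuartiles:
    def test_forced_split_of_eight(self):
        a = assign_quartiles(list(range(1, 9)), [f"t{i}" for i in range(8)])
        assert a.labels.tolist() == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]
        assert a.cut_points == (2.0, 4.0, 6.0)

    def test_all_tied_values_split_by_id(self):
        a = assign_quartiles([5.0] * 8, [f"t{i}" for i in range(8)])
        assert a.counts() == {"Q1": 2, "Q2": 2, "Q3": 2, "Q4": 2}
        assert a.labels["t0"] == "Q1" and a.labels["t7"] == "Q4"

    def test_remainder_goes_to_lowest_quartiles(self):
        a = assign_quartiles(list(range(10)), [f"t{i}" for i in range(10)])
        assert list(a.counts().values()) == [3, 3, 2, 2]

    @given(st.permutations(list(range(12))))
    @settings(deadline=None, derandomize=True)
    def test_invariant_to_input_ordering(self, perm):
        values = [v * 1.5 for v in range(12)]
        ids = [f"t{i}" for i in range(12)]
        ref = assign_quartiles(values, ids)
        shuffled = assign_quartiles([values[i] for i in perm], [ids[i] for i in perm])
        assert shuffled.labels.sort_index().equals(ref.labels.sort_index())

    def test_too_few_or_non_finite_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            assign_quartiles([1, 2, 3], ["a", "b", "c"])
        with pytest.raises(ValueError, match="t1"):
            assign_quartiles([1.0, math.nan, 3.0, 4.0], ["t0", "t1", "t2", "t3"])


class TestQuartileDescriptives:
    def test_two_tracts_per_quartile(self):
        cov = [1, 1, 2, 2, 3, 3, 4, 4]
        pwmsd = [1.0, 3.0] * 4
        df = _records(pwmsd, cov)
        a = assign_quartiles(df["cov"], df["tract_id"])
        tbl = quartile_descriptives(df, a)
        assert tbl["count"].tolist() == [2, 2, 2, 2]
        assert tbl["mean_km"].tolist() == pytest.approx([2.0] * 4)
        assert tbl["median_km"].tolist() == pytest.approx([2.0] * 4)

    def test_uncovered_record_rejected(self):
        df = _records([1.0] * 8, list(range(8)))
        a = assign_quartiles(df["cov"][:8], df["tract_id"][:8])
        df.loc[7, "tract_id"] = "stranger"
        with pytest.raises(ValueError, match="stranger"):
            quartile_descriptives(df, a)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "beta, se, expected",
        [
            (0.0, 0.1, 0.0),
            (math.log(2.0), 0.0, 100.0),
            (-1.2277, 0.0, -70.7),  # ln(1 - 0.707): a 70.7% shorter distance
        ],
    )
    def test_closed_forms(self, beta, se, expected):
        pct, lo, hi = to_percent_difference(beta, se)
        assert pct == pytest.approx(expected, abs=0.05)
        if se == 0:
            assert lo == pytest.approx(pct) and hi == pytest.approx(pct)

    @given(st.floats(min_value=-3, max_value=3), st.floats(min_value=0, max_value=1))
    @settings(deadline=None, derandomize=True)
    def test_round_trip_and_ordering(self, beta, se):
        pct, lo, hi = to_percent_difference(beta, se)
        assert math.log(1 + pct / 100.0) == pytest.approx(beta, abs=1e-9)
        assert lo <= pct <= hi
        # monotone in beta
        pct2, _, _ = to_percent_difference(beta + 0.1, se)
        assert pct2 > pct

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            to_percent_difference(math.nan, 0.1)
        with pytest.raises(ValueError):
            to_percent_difference(0.0, -0.1)


class TestQuartileGlm:
    def test_null_case_all_quartiles_identical(self):
        # same ln-distance distribution in every quartile, zero noise
        pwmsd = [1.0, 2.0, 4.0] * 4
        cov = np.repeat([10, 20, 30, 40], 3)
        df = _records(pwmsd, cov)
        a = assign_quartiles(df["cov"], df["tract_id"])
        res = fit_quartile_glm(df, a)
        for row in res.rows:
            assert row["beta"] == pytest.approx(0.0, abs=1e-12)
            assert row["pct_diff"] == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_quarter_ratio_recovers_log_ratio(self):
        # Q4 distances are exactly 0.25x Q1's: beta_Q4 = ln(0.25) regardless
        # of what Q2/Q3 look like (saturated-dummy OLS = group means)
        q1 = [2.0, 3.0, 5.0]
        df = _records(
            q1 + [1.0, 7.0, 2.0] + [0.3, 0.9, 8.0] + [v * 0.25 for v in q1],
            np.repeat([1, 2, 3, 4], 3),
        )
        a = assign_quartiles(df["cov"], df["tract_id"])
        res = fit_quartile_glm(df, a)
        q4 = [r for r in res.rows if r["level"] == "Q4"][0]
        # group geometric means: ln mean of Q4 minus ln mean of Q1 = ln(0.25)
        assert q4["beta"] == pytest.approx(math.log(0.25), abs=1e-12)
        assert q4["pct_diff"] == pytest.approx(-75.0, abs=1e-9)

    def test_saturated_dummies_recover_group_mean_differences(self, rng):
        df = _records(np.exp(rng.normal(0, 1, size=40)), rng.uniform(0, 100, 40))
        a = assign_quartiles(df["cov"], df["tract_id"])
        res = fit_quartile_glm(df, a)
        y = np.log(df["pwmsd_km"].to_numpy())
        lab = a.labels[df["tract_id"]].to_numpy()
        ref = y[lab == "Q1"].mean()
        for row in res.rows:
            assert row["beta"] == pytest.approx(
                y[lab == row["level"]].mean() - ref, abs=1e-10
            )

    @pytest.mark.parametrize("hc", ["HC0", "HC1", "HC3"])
    def test_sandwich_matches_matrix_oracle_hand_dataset(self, hc):
        # 8-point hand dataset (two per quartile, so every leverage < 1 and
        # HC3 is defined), checked against the explicit
        # (X'X)^-1 X' diag(w e^2) X (X'X)^-1 formula
        df = _records(
            [0.5, 1.1, 0.8, 2.0, 3.5, 0.2, 1.7, 0.9],
            [5.0, 12.0, 20.0, 26.0, 33.0, 47.0, 60.0, 71.0],
        )
        a = assign_quartiles(df["cov"], df["tract_id"])
        res = fit_quartile_glm(df, a, hc_type=hc)
        lab = a.labels[df["tract_id"]].to_numpy()
        X = np.column_stack(
            [np.ones(8)] + [(lab == q).astype(float) for q in ("Q2", "Q3", "Q4")]
        )
        y = np.log(df["pwmsd_km"].to_numpy())
        want_se = np.sqrt(np.diag(sandwich_cov(X, y, hc)))[1:]
        got_se = [r["robust_se"] for r in res.rows]
        np.testing.assert_allclose(got_se, want_se, atol=1e-10, rtol=0)
        np.testing.assert_allclose(
            [r["beta"] for r in res.rows], ols_beta(X, y)[1:], atol=1e-12, rtol=0
        )

    def test_point_estimates_do_not_depend_on_hc_type(self, rng):
        df = _records(np.exp(rng.normal(0, 1, 32)), rng.uniform(0, 100, 32))
        a = assign_quartiles(df["cov"], df["tract_id"])
        betas = {
            hc: [r["beta"] for r in fit_quartile_glm(df, a, hc_type=hc).rows]
            for hc in ("HC0", "HC1", "HC3")
        }
        np.testing.assert_allclose(betas["HC0"], betas["HC1"], rtol=0, atol=0)
        np.testing.assert_allclose(betas["HC0"], betas["HC3"], rtol=0, atol=0)

    def test_ci_is_transformed_beta_pm_1p96_se(self, rng):
        df = _records(np.exp(rng.normal(0, 1, 24)), rng.uniform(0, 100, 24))
        a = assign_quartiles(df["cov"], df["tract_id"])
        for row in fit_quartile_glm(df, a).rows:
            lo = (math.exp(row["beta"] - 1.96 * row["robust_se"]) - 1) * 100
            hi = (math.exp(row["beta"] + 1.96 * row["robust_se"]) - 1) * 100
            assert row["ci_low"] == pytest.approx(lo)
            assert row["ci_high"] == pytest.approx(hi)
            assert row["ci_low"] < row["ci_high"]

    def test_adjustment_covariate_adds_a_term(self, rng):
        df = _records(
            np.exp(rng.normal(0, 1, 24)),
            rng.uniform(0, 100, 24),
            pop_density=rng.uniform(10, 5000, 24),
        )
        a = assign_quartiles(df["cov"], df["tract_id"])
        res = fit_quartile_glm(df, a, adjust_for="pop_density")
        assert [r["level"] for r in res.rows] == ["Q2", "Q3", "Q4", "pop_density"]

    def test_nonpositive_distance_rejected(self):
        df = _records([0.0, 1, 1, 1], [1, 2, 3, 4])
        a = assign_quartiles(df["cov"], df["tract_id"])
        with pytest.raises(ValueError, match="positive"):
            fit_quartile_glm(df, a)


class TestModelResultsApi:
    def _fitted(self, rng):
        n = 40
        df = pd.DataFrame(
            {
                "tract_id": [f"t{i}" for i in range(n)],
                "pwmsd_km": np.exp(rng.normal(0, 0.5, n)),
                "population": 100,
                "pct_poverty": rng.uniform(0, 50, n),
                "pct_higher_ed": rng.uniform(0, 80, n),
                "pct_black_aa": rng.uniform(0, 60, n),
                "pct_hispanic": rng.uniform(0, 60, n),
            }
        )
        return QuartileDisparityModel.from_dataframe(df).fit()

    def test_to_frame_has_contracted_columns(self, rng):
        out = self._fitted(rng).to_frame()
        assert list(out.columns) == [
            "covariate", "level", "beta", "robust_se",
            "pct_diff", "ci_low", "ci_high", "p_value",
        ]
        assert len(out) == 4 * 3  # four covariates, Q2-Q4 rows each
        np.testing.assert_allclose(
            out["pct_diff"], (np.exp(out["beta"]) - 1) * 100, rtol=1e-12
        )

    def test_quartile_table_mirrors_descriptives(self, rng):
        tbl = self._fitted(rng).quartile_table()
        assert set(tbl["covariate"]) == {
            "pct_poverty", "pct_higher_ed", "pct_black_aa", "pct_hispanic"
        }
        assert (tbl["count"] == 10).all()

    def test_summary_mentions_referent_and_hc(self, rng):
        s = self._fitted(rng).summary()
        assert "referent" in s
        assert "HC3" in s

    def test_missing_covariate_column_named(self):
        df = pd.DataFrame({"tract_id": ["a"], "pwmsd_km": [1.0]})
        with pytest.raises(ValueError, match="pct_poverty"):
            QuartileDisparityModel(df)


class TestBinnedTrends:
    def test_income_bin_arithmetic(self):
        df = _records([1.0, 2.0, 3.0, 4.0], [1, 2, 3, 4],
                      median_income=[40200.0, 40900.0, 41500.0, 40100.0])
        out = binned_trends(df, "median_income", 1000.0)
        assert out["bin_lo"].tolist() == [40000.0, 41000.0]
        assert out["n_tracts"].tolist() == [3, 1]
        assert out["bin_hi"].tolist() == [41000.0, 42000.0]

    def test_single_tract_bin_mean_is_that_tract(self):
        df = _records([2.5, 7.0], [1, 2], median_income=[1500.0, 3500.0],
                      ids=["a", "b"])
        out = binned_trends(df, "median_income", 1000.0)
        assert out["mean_pwmsd_km"].tolist() == [2.5, 7.0]

    def test_urban_rural_split_at_75th_density_percentile(self):
        dens = [1.0, 2.0, 3.0, 100.0]
        df = _records([1, 1, 1, 9], [1, 2, 3, 4],
                      median_income=[1000.0] * 4, pop_density=dens)
        urban = binned_trends(df, "median_income", 1000.0, strata="urban")
        rural = binned_trends(df, "median_income", 1000.0, strata="rural")
        assert urban["n_tracts"].sum() == 1   # only the densest tract
        assert rural["n_tracts"].sum() == 3
        assert urban["mean_pwmsd_km"].iloc[0] == pytest.approx(9.0)

    def test_percentile_markers_attached(self):
        df = _records([1.0] * 8, list(range(8)),
                      median_income=np.arange(8, dtype=float) * 1000)
        out = binned_trends(df, "median_income", 1000.0)
        assert out.attrs["p25"] == pytest.approx(np.percentile(df["median_income"], 25))
        assert out.attrs["p75"] == pytest.approx(np.percentile(df["median_income"], 75))

    def test_missing_bin_variable_rejected(self):
        df = _records([1.0] * 4, [1, 2, 3, 4])
        with pytest.raises(ValueError, match="median_income"):
            binned_trends(df, "median_income", 1000.0)
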