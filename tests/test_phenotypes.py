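import numpy as np
import pandas as pd
import pytest

from markertrait.phenotypes import (PhenotypeDataError, clean_height_series,
                                    derive_budburst_metrics, from_long,
                                    nested_anova, to_long, trait_correlations)


def _obs(records):
    return pd.DataFrame(records, columns=["individual_id", "day", "stage"])


class TestBudburst:
    def test_duration_is_stage4_to_stage6_interval(self):
        obs = _obs([("t1", 10, 4), ("t1", 17, 5), ("t1", 24, 6)])
        out = derive_budburst_metrics(obs)
        assert out.loc["t1", "duration"] == pytest.approx(14.0)

    def test_skipped_stage_gets_midpoint_of_assessments(self):
        obs = _obs([("t1", 10, 4), ("t1", 17, 6)])
        out = derive_budburst_metrics(obs)
        # stage 5 never observed but bracketed: midpoint of days 10 and 17
        obs2 = _obs([("t1", 10, 4), ("t1", 17, 6), ("t2", 13.5, 5)])
        out2 = derive_budburst_metrics(obs2)
        assert out2.loc["t1", "timing_stage5"] == out2.loc["t2", "timing_stage5"]
        assert out.loc["t1", "duration"] == pytest.approx(7.0)

    def test_stage_never_reached_is_missing(self):
        obs = _obs([("t1", 10, 4), ("t1", 20, 5)])
        out = derive_budburst_metrics(obs)
        assert np.isnan(out.loc["t1", "timing_stage6"])
        assert np.isnan(out.loc["t1", "duration"])

    def test_decreasing_stage_sequence_names_individual(self):
        obs = _obs([("bad_tree", 10, 5), ("bad_tree", 17, 4)])
        with pytest.raises(PhenotypeDataError, match="bad_tree"):
            derive_budburst_metrics(obs)

    def test_timing_relative_to_first_tree_and_shift_invariant(self):
        obs = _obs([("t1", 10, 4), ("t1", 20, 6),
                    ("t2", 12, 4), ("t2", 26, 6)])
        out = derive_budburst_metrics(obs)
        assert out.loc["t1", "timing_stage4"] == 0.0
        assert out.loc["t2", "timing_stage4"] == 2.0
        shifted = obs.assign(day=obs["day"] + 100)
        out2 = derive_budburst_metrics(shifted)
        pd.testing.assert_frame_equal(out, out2)


class TestHeightCleaning:
    def test_reversal_set_missing_and_gap_increment_undefined(self):
        heights = pd.DataFrame([[100.0, 150.0, 140.0, 200.0]],
                               index=["t1"], columns=[2010, 2011, 2012, 2013])
        cleaned, inc = clean_height_series(heights)
        assert list(cleaned.loc["t1"].values[:2]) == [100.0, 150.0]
        assert np.isnan(cleaned.loc["t1", 2012])
        assert cleaned.loc["t1", 2013] == 200.0
        assert inc.loc["t1", 2011] == 50.0
        assert np.isnan(inc.loc["t1", 2012])
        assert np.isnan(inc.loc["t1", 2013])  # spans a cleaned-away year

    def test_monotone_series_unchanged(self):
        heights = pd.DataFrame([[10.0, 20.0, 30.0]], index=["t1"],
                               columns=[1, 2, 3])
        cleaned, inc = clean_height_series(heights)
        pd.testing.assert_frame_equal(cleaned, heights)
        assert list(inc.loc["t1"]) == [10.0, 10.0]

    def test_all_missing_series_stays_missing(self):
        heights = pd.DataFrame([[np.nan] * 3], index=["t1"], columns=[1, 2, 3])
        cleaned, _ = clean_height_series(heights)
        assert cleaned.isna().all().all()

    def test_output_non_decreasing_over_non_missing(self):
        rng = np.random.default_rng(0)
        heights = pd.DataFrame(rng.normal(100, 30, size=(40, 6)).cumsum(axis=1)
                               + rng.normal(0, 50, size=(40, 6)),
                               columns=range(6))
        cleaned, _ = clean_height_series(heights)
        for _, row in cleaned.iterrows():
            vals = row.dropna().to_numpy()
            assert np.all(np.diff(vals) >= 0)


class TestCorrelations:
    def test_perfect_linearity(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        df["y"] = 2 * df["x"] + 1
        r, p, n = trait_correlations(df)["_all"]
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] < 0.001
        assert n.loc["x", "y"] == 5

    def test_matches_product_moment_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        # explicit sum formula as the oracle
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt((n * (x ** 2).sum() - x.sum() ** 2)
                      * (n * (y ** 2).sum() - y.sum() ** 2))
        expected = num / den
        r, _, _ = trait_correlations(pd.DataFrame({"x": x, "y": y}))["_all"]
        assert r.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_missing_with_warning(self):
        df = pd.DataFrame({"x": [1.0, 2, np.nan, np.nan],
                           "y": [1.0, np.nan, 2, 3]})
        with pytest.warns(UserWarning, match="complete pairs"):
            r, _, _ = trait_correlations(df)["_all"]
        assert np.isnan(r.loc["x", "y"])

    def test_constant_vector_flagged_missing(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning, match="constant"):
            r, _, _ = trait_correlations(df)["_all"]
        assert np.isnan(r.loc["x", "y"])

    def test_pairwise_complete_uses_per_cell_n(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, np.nan],
                           "b": [2.0, 4, 6, 8, 10],
                           "c": [1.0, np.nan, 2, 4, 8]})
        _, _, n = trait_correlations(df)["_all"]
        assert n.loc["a", "b"] == 4
        assert n.loc["a", "c"] == 3
        assert n.loc["b", "c"] == 4


def test_long_wide_round_trip(small_trial):
    _, pheno, _ = small_trial
    back = from_long(to_long(pheno))
    pd.testing.assert_frame_equal(back.sort_index().sort_index(axis=1),
                                  pheno.sort_index().sort_index(axis=1),
                                  check_names=False)


class TestNestedAnova:
    def _balanced(self, sigma_fam, seed=0, n_pop=3, n_fam=6, n_rep=8):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_pop):
            pop_mean = 10.0 * p
            for f in range(n_fam):
                fam_eff = rng.normal(0, sigma_fam)
                for r in range(n_rep):
                    rows.append({"population": f"P{p}",
                                 "family": f"P{p}F{f}",
                                 "block": f"B{r % 2}",
                                 "value": pop_mean + fam_eff + rng.normal()})
        return pd.DataFrame(rows)

    def test_reml_matches_balanced_anova_estimator(self):
        df = self._balanced(sigma_fam=1.5, seed=3)
        df["block"] = "B0"  # single block level -> dropped, balanced nested
        with pytest.warns(UserWarning, match="block"):
            res = nested_anova(df)
        # closed-form EMS estimator on the balanced design
        n_rep = 8
        fam_means = df.groupby("family")["value"].mean()
        pop_of_fam = df.groupby("family")["population"].first()
        pop_means = df.groupby("population")["value"].mean()
        ss_fam = n_rep * sum((fam_means[f] - pop_means[pop_of_fam[f]]) ** 2
                             for f in fam_means.index)
        df_fam = 3 * (6 - 1)
        ms_fam = ss_fam / df_fam
        resid = df["value"] - df["family"].map(fam_means)
        ms_err = (resid ** 2).sum() / (len(df) - 18)
        expected_fam_var = (ms_fam - ms_err) / n_rep
        assert res["variance_components"]["family"] == pytest.approx(
            expected_fam_var, rel=1e-3, abs=1e-3)
        assert res["variance_components"]["residual"] == pytest.approx(
            ms_err, rel=1e-3)

    def test_population_effect_detected(self):
        df = self._balanced(sigma_fam=1.0, seed=1)
        res = nested_anova(df)
        assert res["population_wald"]["p_value"] < 1e-6
        assert res["population_wald"]["df"] == 2

    def test_zero_family_variance_component_near_zero(self):
        shares = []
        for s in range(25):
            df = self._balanced(sigma_fam=0.0, seed=100 + s, n_pop=3,
                                n_fam=6, n_rep=8)
            res = nested_anova(df)
            vc = res["variance_components"]
            total = vc["family"] + vc["block"] + vc["residual"]
            shares.append(vc["family"] / total)
        assert np.mean(shares) <= 0.05

    def test_single_level_factor_rejected(self):
        df = self._balanced(sigma_fam=1.0)
        df["population"] = "P0"
        with pytest.raises(ValueError, match="levels"):
            nested_anova(df)

    def test_family_confounded_with_population_rejected(self):
        df = self._balanced(sigma_fam=1.0, n_fam=1)
        with pytest.raises(ValueError, match="confounded"):
            nested_anova(df)
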