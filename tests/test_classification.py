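"""Climate-vs-geography classifiers, GLMM AIC ranking, delimitations."""

import numpy as np
import pandas as pd
import pytest

from evoregions import (
    SiteCovariates,
    compare_classifiers,
    delimitation_correspondence,
    rank_climate_variables,
)
from evoregions.classification import fit_binomial_random_intercept


def random_covariates(n, seed=0):
    rng = np.random.default_rng(seed)
    lat = rng.uniform(-50, 50, n)
    return SiteCovariates(pd.DataFrame({
        "lat": lat,
        "lon": rng.uniform(-110, -40, n),
        "elevation": rng.uniform(0, 3000, n),
        "MAT": 25 - 0.4 * np.abs(lat) + rng.normal(0, 2, n),
        "MAP": rng.uniform(200, 3000, n),
        "TS": 100 + 10 * np.abs(lat) + rng.normal(0, 30, n),
        "CWD": -rng.uniform(0, 1500, n),
        "continent": np.where(rng.random(n) < 0.5, "South", "NorthCentral"),
        "freezing": (np.abs(lat) > 35).astype(int),
    }, index=[f"s{i}" for i in range(n)]))


class TestCompareClassifiers:
    def test_random_labels_score_near_majority_rate(self):
        cov = random_covariates(300, seed=1)
        rng = np.random.default_rng(12345)
        labels = rng.choice([1, 2], 300, p=[0.6, 0.4])
        clim, geo = compare_classifiers(cov, labels, seed=1, n_trees=200)
        majority = max(np.mean(labels == 1), np.mean(labels == 2))
        for rep in (clim, geo):
            assert abs(rep.mean_accuracy - majority) < 0.12

    def test_climate_driven_labels_favor_climate_model(self):
        cov = random_covariates(300, seed=2)
        labels = np.where(cov.data["MAT"] > cov.data["MAT"].median(), 1, 2)
        clim, geo = compare_classifiers(cov, labels, seed=2, n_trees=200)
        assert clim.mean_accuracy > geo.mean_accuracy
        assert max(clim.importances, key=clim.importances.get) == "MAT"

    def test_continent_driven_labels_favor_geography_model(self):
        cov = random_covariates(300, seed=3)
        labels = np.where(cov.data["continent"] == "South", 1, 2)
        clim, geo = compare_classifiers(cov, labels, seed=3, n_trees=200)
        assert geo.mean_accuracy > clim.mean_accuracy

    def test_seed_reproducible(self):
        cov = random_covariates(120, seed=4)
        labels = np.where(cov.data["MAP"] > 1500, 1, 2)
        a = compare_classifiers(cov, labels, seed=9, n_trees=100)
        b = compare_classifiers(cov, labels, seed=9, n_trees=100)
        assert a[0].mean_accuracy == b[0].mean_accuracy
        assert a[1].importances == b[1].importances

    def test_missing_columns_named(self):
        cov = SiteCovariates(pd.DataFrame(
            {"MAT": [1.0, 2.0]}, index=["a", "b"]))
        with pytest.raises(KeyError, match="CWD"):
            compare_classifiers(cov, np.array([1, 2]), seed=0)

    def test_sites_without_continent_excluded(self):
        cov = random_covariates(100, seed=5)
        cov.data.loc[cov.data.index[:10], "continent"] = np.nan
        labels = np.where(cov.data["MAT"] > 20, 1, 2)
        clim, geo = compare_classifiers(cov, labels, seed=5, n_trees=100)
        assert clim.n_sites == 90
        assert geo.n_sites == 90


class TestBinomialRandomIntercept:
    def test_singleton_groups_fall_back_to_plain_glm(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 80)
        y = (rng.random(80) < 1 / (1 + np.exp(-2 * x))).astype(float)
        groups = np.arange(80)  # one observation per group
        ll, aic, params = fit_binomial_random_intercept(y, x, groups)
        import statsmodels.api as sm

        glm = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Binomial()).fit()
        assert ll == pytest.approx(glm.llf)
        assert params["sigma"] == 0.0

    def test_marginal_likelihood_dominates_glm(self):
        """The varying-intercept model nests the plain GLM at sigma = 0,
        so its maximized log-likelihood can only be higher."""
        rng = np.random.default_rng(1)
        groups = np.repeat(np.arange(20), 5)
        re = rng.normal(0, 1.5, 20)[groups]
        x = rng.normal(0, 1, 100)
        y = (rng.random(100) < 1 / (1 + np.exp(-(x + re)))).astype(float)
        ll, aic, params = fit_binomial_random_intercept(y, x, groups)
        import statsmodels.api as sm

        glm = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Binomial()).fit()
        assert ll >= glm.llf - 1e-6
        assert params["sigma"] > 0.3  # strong planted heterogeneity


class TestRankClimateVariables:
    def test_map_driven_labels_rank_map_first(self):
        cov = random_covariates(250, seed=6)
        rng = np.random.default_rng(6)
        z = ((cov.data["MAP"] - cov.data["MAP"].mean())
             / cov.data["MAP"].std())
        y = (rng.random(250) < 1 / (1 + np.exp(-3 * z))).astype(int) + 1
        tab = rank_climate_variables(cov, y)
        assert tab.iloc[0]["variable"] == "MAP"
        assert tab.iloc[0]["delta_aic"] == 0.0

    def test_collinear_variables_get_identical_aic(self):
        cov = random_covariates(150, seed=7)
        cov.data["MAT2"] = 3.0 * cov.data["MAT"] - 7.0  # affine copy
        rng = np.random.default_rng(7)
        y = (rng.random(150) < 0.5).astype(int)
        tab = rank_climate_variables(cov, y, variables=["MAT", "MAT2"])
        aics = tab.set_index("variable")["aic"]
        assert aics["MAT"] == pytest.approx(aics["MAT2"], abs=1e-3)

    def test_constant_variable_skipped(self):
        cov = random_covariates(100, seed=8)
        cov.data["FLAT"] = 5.0
        rng = np.random.default_rng(8)
        y = (rng.random(100) < 0.5).astype(int)
        tab = rank_climate_variables(cov, y, variables=["MAT", "FLAT"])
        assert list(tab["variable"]) == ["MAT"]

    def test_more_than_two_labels_rejected(self):
        cov = random_covariates(60, seed=9)
        with pytest.raises(ValueError):
            rank_climate_variables(cov, np.arange(60) % 3)


class TestDelimitationCorrespondence:
    def test_exact_flag_match_scores_one(self):
        cov = random_covariates(200, seed=10)
        labels = np.where(cov.data["freezing"] == 1, 2, 1)
        out = delimitation_correspondence(cov, labels,
                                          delimitations=["freezing"])
        assert out[0].match_fraction == 1.0
        assert out[0].mapping[2] == "extratropical"

    def test_independent_flag_scores_near_half(self):
        cov = random_covariates(400, seed=11)
        rng = np.random.default_rng(11)
        cov.data["coinflip"] = (rng.random(400) < 0.5).astype(int)
        labels = rng.choice([1, 2], 400)
        out = delimitation_correspondence(cov, labels,
                                          delimitations=["coinflip"])
        assert 0.5 <= out[0].match_fraction < 0.6

    def test_latitude_band_computed_internally(self):
        cov = random_covariates(200, seed=12)
        labels = np.where(np.abs(cov.data["lat"]) <= 23.4, 1, 2)
        out = delimitation_correspondence(cov, labels,
                                          delimitations=["C1-latitude"])
        assert out[0].match_fraction == 1.0

    def test_match_fraction_at_least_half(self):
        cov = random_covariates(100, seed=13)
        rng = np.random.default_rng(13)
        labels = rng.choice([1, 2], 100)
        for match in delimitation_correspondence(cov, labels):
            assert match.match_fraction >= 0.5

    def test_missing_flag_skipped(self):
        cov = random_covariates(50, seed=14)
        labels = np.array([1, 2] * 25)
        out = delimitation_correspondence(cov, labels,
                                          delimitations=["no_such_flag"])
        assert out == []

    def test_non_binary_labels_rejected(self):
        cov = random_covariates(30, seed=15)
        with pytest.raises(ValueError):
            delimitation_correspondence(cov, np.arange(30) % 3)
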