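import numpy as np
import pandas as pd
import pytest

from benthet import richness_model as rm
from benthet.richness_model import ModelSpec


def simulate_counts(n, rng, beta_x=0.5, theta=None, intercept=1.0):
    """Counts from log mu = intercept + beta_x * x, Poisson or NB(theta)."""
    x = rng.normal(size=n)
    mu = np.exp(intercept + beta_x * x)
    if theta is None:
        y = rng.poisson(mu)
    else:
        y = rng.poisson(rng.gamma(shape=theta, scale=mu / theta))
    return pd.DataFrame({"richness": y, "x": x})


class TestBuildDesign:
    def _data(self, rng, n=60):
        return pd.DataFrame(
            {
                "richness": rng.poisson(10, n),
                "season": rng.choice(["spring", "summer"], n),
                "geoclass": rng.choice(["none", "low", "medium", "high"], n),
                "sediment": rng.choice(["coarse", "fine", "medium", "mud"], n),
                "year": rng.normal(size=n),
            }
        )

    def test_two_level_factor_single_indicator(self, rng):
        X, y, info, _ = rm.build_design(
            ModelSpec("richness", ("season",)), self._data(rng)
        )
        assert list(X.columns) == ["Intercept", "season(summer)"]

    def test_geoclass_reference_high_by_alphabetical_default(self, rng):
        X, _, info, _ = rm.build_design(
            ModelSpec("richness", ("geoclass",)), self._data(rng)
        )
        assert info.factor_levels["geoclass"][0] == "high"
        assert info.term_columns["geoclass"] == [
            "geoclass(low)", "geoclass(medium)", "geoclass(none)"
        ]

    def test_numeric_by_factor_interaction_columns(self, rng):
        X, _, info, _ = rm.build_design(
            ModelSpec("richness", ("year", "sediment", "year:sediment")),
            self._data(rng),
        )
        assert info.term_columns["year:sediment"] == [
            "year:sediment(fine)", "year:sediment(medium)", "year:sediment(mud)"
        ]

    def test_marginality_enforced_at_spec_level(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec("richness", ("year:sediment",))

    def test_single_level_factor_rejected(self, rng):
        data = self._data(rng)
        data["season"] = "summer"
        with pytest.raises(ValueError, match="single observed level"):
            rm.build_design(ModelSpec("richness", ("season",)), data)

    def test_missing_rows_dropped_and_counted(self, rng):
        data = self._data(rng)
        data.loc[:4, "year"] = np.nan
        _, y, _, dropped = rm.build_design(ModelSpec("richness", ("year",)), data)
        assert dropped == 5 and len(y) == len(data) - 5


class TestFitCountGlm:
    def test_intercept_only_poisson_closed_form(self, rng):
        y = pd.Series(rng.poisson(7.0, 500))
        X = pd.DataFrame({"Intercept": np.ones(len(y))})
        fit = rm.fit_count_glm(X, y, "poisson")
        assert fit.table.loc["Intercept", "coef"] == pytest.approx(np.log(y.mean()))
        assert fit.df_resid == len(y) - 1

    def test_nb_slope_recovery_within_3se(self):
        rng = np.random.default_rng(21)
        data = simulate_counts(2000, rng, beta_x=0.5, theta=2.0)
        fit = rm.fit_model(ModelSpec("richness", ("x",), family="negative_binomial"), data)
        row = fit.table.loc["x"]
        assert abs(row["coef"] - 0.5) < 3 * row["se"]
        assert fit.theta == pytest.approx(2.0, rel=0.35)

    def test_poisson_on_nb_data_is_overdispersed(self):
        rng = np.random.default_rng(22)
        data = simulate_counts(1000, rng, theta=1.0)
        fit = rm.fit_model(ModelSpec("richness", ("x",), family="poisson"), data)
        assert rm.pearson_dispersion(fit) > 1.5

    def test_quasipoisson_inflates_se_not_coef(self):
        rng = np.random.default_rng(23)
        data = simulate_counts(500, rng, theta=1.0)
        pois = rm.fit_model(ModelSpec("richness", ("x",), family="poisson"), data)
        quasi = rm.fit_model(ModelSpec("richness", ("x",), family="quasipoisson"), data)
        assert quasi.table["coef"].equals(pois.table["coef"])
        assert (quasi.table["se"] > pois.table["se"]).all()
        assert quasi.aic is None and quasi.phi > 1.5

    def test_rank_deficient_design_names_aliased(self, rng):
        X = pd.DataFrame({"Intercept": np.ones(20), "a": np.arange(20.0)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="rank deficient"):
            rm.fit_count_glm(X, pd.Series(rng.poisson(5, 20)), "poisson")

    def test_non_integer_response_rejected(self):
        X = pd.DataFrame({"Intercept": np.ones(3)})
        with pytest.raises(ValueError, match="non-negative integers"):
            rm.fit_count_glm(X, pd.Series([1.5, 2.0, 3.0]), "poisson")


class TestDispersion:
    def test_equidispersed_poisson_near_one(self):
        rng = np.random.default_rng(30)
        data = simulate_counts(5000, rng, theta=None)
        fit = rm.fit_model(ModelSpec("richness", ("x",), family="poisson"), data)
        assert 0.9 < rm.pearson_dispersion(fit) < 1.1

    def test_bootstrap_detects_overdispersion(self):
        rng = np.random.default_rng(31)
        data = simulate_counts(300, rng, theta=1.0)
        fit = rm.fit_model(ModelSpec("richness", ("x",), family="poisson"), data)
        p = rm.dispersion_bootstrap_test(fit, n_sim=99, rng=1)
        assert p < 0.05

    def test_bootstrap_null_calibrated(self):
        # data generated from the fitted family: rejection should be rare
        rng = np.random.default_rng(32)
        rejections = 0
        for trial in range(20):
            data = simulate_counts(200, rng, theta=None)
            fit = rm.fit_model(ModelSpec("richness", ("x",), family="poisson"), data)
            p = rm.dispersion_bootstrap_test(fit, n_sim=59, rng=100 + trial)
            rejections += p < 0.05
        assert rejections <= 4

    def test_bootstrap_deterministic_under_seed(self):
        rng = np.random.default_rng(33)
        data = simulate_counts(200, rng, theta=1.0)
        fit = rm.fit_model(ModelSpec("richness", ("x",), family="poisson"), data)
        assert rm.dispersion_bootstrap_test(fit, n_sim=39, rng=5) == rm.dispersion_bootstrap_test(
            fit, n_sim=39, rng=5
        )


class TestGvif:
    def test_orthogonal_predictors_give_one(self):
        n = 400
        x = np.arange(n) % 2 - 0.5
        z = np.tile([-0.5, -0.5, 0.5, 0.5], n // 4)
        X = pd.DataFrame({"Intercept": 1.0, "x": x, "z": z})
        rep = rm.gvif(X, {"x": ["x"], "z": ["z"]})
        assert rep.table["gvif"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_single_df_terms_equal_classical_vif(self, rng):
        import statsmodels.api as sm

        n = 500
        x1 = rng.normal(size=n)
        x2 = 0.7 * x1 + rng.normal(size=n)
        x3 = rng.normal(size=n) - 0.3 * x2
        X = pd.DataFrame({"Intercept": 1.0, "x1": x1, "x2": x2, "x3": x3})
        rep = rm.gvif(X, {"x1": ["x1"], "x2": ["x2"], "x3": ["x3"]})
        for name, others in (("x1", [x2, x3]), ("x2", [x1, x3]), ("x3", [x1, x2])):
            r2 = sm.OLS(X[name], sm.add_constant(np.column_stack(others))).fit().rsquared
            assert rep.table.loc[name, "gvif"] == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_duplicated_predictor_is_singular(self, rng):
        x = rng.normal(size=100)
        X = pd.DataFrame({"Intercept": 1.0, "a": x, "b": x})
        with pytest.raises(ValueError, match="singular|constant"):
            rm.gvif(X, {"a": ["a"], "b": ["b"]})

    def test_adjusted_value_invariant_to_rescaling(self, rng):
        n = 300
        x1 = rng.normal(size=n)
        x2 = 0.6 * x1 + rng.normal(size=n)
        X = pd.DataFrame({"Intercept": 1.0, "x1": x1, "x2": x2})
        Xs = X.copy()
        Xs["x1"] = X["x1"] * 1000 + 5
        a = rm.gvif(X, {"x1": ["x1"], "x2": ["x2"]}).table
        b = rm.gvif(Xs, {"x1": ["x1"], "x2": ["x2"]}).table
        assert a["adjusted"].to_numpy() == pytest.approx(b["adjusted"].to_numpy())


class TestBackwardAic:
    def _data(self, rng, n=1000, noise=True):
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        g = rng.choice(["a", "b"], n)
        mu = np.exp(1.5 + 0.4 * x + 0.5 * (g == "b"))
        return pd.DataFrame(
            {"richness": rng.poisson(mu), "x": x, "noise": z, "grp": g}
        )

    def test_pure_noise_predictor_dropped(self):
        # a null term survives only when its chi-square draw exceeds 2
        # (~16% of replicates), so require the drop in most of 12 replicates
        # while the real effects are always retained
        drops = 0
        for s in range(12):
            rng = np.random.default_rng(40 + s)
            data = self._data(rng)
            spec = ModelSpec("richness", ("x", "noise", "grp"), family="poisson")
            reduced, fit, path = rm.backward_aic(spec, data)
            drops += "noise" not in reduced.terms
            assert {"x", "grp"} <= set(reduced.terms)
        assert drops >= 8

    def test_strong_effects_all_kept(self):
        rng = np.random.default_rng(41)
        data = self._data(rng)
        spec = ModelSpec("richness", ("x", "grp"), family="poisson")
        reduced, _, path = rm.backward_aic(spec, data)
        assert reduced.terms == spec.terms and len(path) == 1

    def test_aic_monotone_along_path(self):
        rng = np.random.default_rng(42)
        data = self._data(rng)
        data["noise2"] = rng.normal(size=len(data))
        spec = ModelSpec("richness", ("x", "noise", "noise2", "grp"), family="poisson")
        _, _, path = rm.backward_aic(spec, data)
        aics = [a for _, a in path]
        assert all(b < a for a, b in zip(aics, aics[1:]))

    def test_main_effect_protected_by_interaction(self):
        spec = ModelSpec(
            "richness", ("x", "grp", "x:grp"), family="poisson"
        )
        assert set(spec.droppable) == {"x:grp"}


class TestPosthoc:
    def test_two_level_factor_contrast_equals_coefficient(self, rng):
        data = pd.DataFrame(
            {
                "richness": rng.poisson(10, 200),
                "season": rng.choice(["spring", "summer"], 200),
            }
        )
        fit = rm.fit_model(ModelSpec("richness", ("season",), family="poisson"), data)
        ph = rm.posthoc_pairwise(fit, "season")
        assert len(ph) == 1
        assert abs(ph.loc[0, "estimate"]) == pytest.approx(
            abs(fit.table.loc["season(summer)", "coef"])
        )

    def test_four_level_factor_six_antisymmetric_contrasts(self, rng):
        data = pd.DataFrame(
            {
                "richness": rng.poisson(10, 400),
                "geoclass": rng.choice(["none", "low", "medium", "high"], 400),
            }
        )
        fit = rm.fit_model(ModelSpec("richness", ("geoclass",), family="poisson"), data)
        ph = rm.posthoc_pairwise(fit, "geoclass").set_index("contrast")
        assert len(ph) == 6
        # antisymmetry: reversing a contrast flips its sign; check via the
        # pair (a-b) + (b-c) == (a-c) linearity on the link scale
        est = ph["estimate"]
        assert est["high - low"] + est["low - medium"] == pytest.approx(
            est["high - medium"]
        )

    def test_separated_classes_detected(self):
        # none/low lower than medium/high: those 4 contrasts significant
        rng = np.random.default_rng(50)
        hits = 0
        trials = 30
        for t in range(trials):
            g = rng.choice(["none", "low", "medium", "high"], 500)
            mu = np.where(np.isin(g, ["none", "low"]), 12.0, 24.0)
            data = pd.DataFrame({"richness": rng.poisson(mu), "geoclass": g})
            fit = rm.fit_model(
                ModelSpec("richness", ("geoclass",), family="poisson"), data
            )
            ph = rm.posthoc_pairwise(fit, "geoclass").set_index("contrast")
            crossing = [
                "high - low", "high - none", "low - medium", "medium - none"
            ]
            hits += all(ph.loc[c, "p_adj"] < 0.05 for c in crossing)
        assert hits >= 0.9 * trials

    def test_factor_not_in_model_rejected(self, rng):
        data = pd.DataFrame(
            {"richness": rng.poisson(10, 50), "season": rng.choice(["spring", "summer"], 50)}
        )
        fit = rm.fit_model(ModelSpec("richness", ("season",), family="poisson"), data)
        with pytest.raises(ValueError, match="not a factor"):
            rm.posthoc_pairwise(fit, "sediment")


class TestNonparametricSuite:
    def test_two_groups_kw_equals_mw(self, rng):
        values = pd.Series(rng.normal(size=100))
        groups = pd.Series(["a"] * 50 + ["b"] * 50)
        out = rm.nonparametric_suite(values, groups)
        assert out["kruskal"]["p"] == pytest.approx(
            out["pairwise"].loc[0, "p_raw"], rel=1e-9
        )

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(60)
        rejections = 0
        trials = 200
        for _ in range(trials):
            values = pd.Series(rng.normal(size=60))
            groups = pd.Series(rng.choice(["a", "b", "c"], 60))
            out = rm.nonparametric_suite(values, groups)
            rejections += out["kruskal"]["p"] < 0.05
        assert 0.01 < rejections / trials < 0.10

    def test_shifted_groups_high_power(self):
        rng = np.random.default_rng(61)
        hits = 0
        for _ in range(30):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            out = rm.nonparametric_suite(
                pd.Series(np.concatenate([a, b])),
                pd.Series(["a"] * 50 + ["b"] * 50),
            )
            hits += out["kruskal"]["p"] < 0.05
        assert hits >= 27

    def test_small_group_excluded_with_warning_entry(self, rng):
        values = pd.Series(np.concatenate([rng.normal(size=20), [1.0]]))
        groups = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"])
        out = rm.nonparametric_suite(values, groups)
        assert out["excluded_groups"] == ["c"]

    def test_holm_adjustment_bounds(self, rng):
        values = pd.Series(rng.normal(size=120))
        groups = pd.Series(rng.choice(["a", "b", "c", "d"], 120))
        out = rm.nonparametric_suite(values, groups)
        pw = out["pairwise"]
        assert (pw["p_holm"] >= pw["p_raw"] - 1e-12).all()
        assert (pw["p_holm"] <= 1.0).all()
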