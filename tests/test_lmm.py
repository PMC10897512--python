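import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import citynox as cx
from citynox.lmm import CrossedLMM, Standardizer

from conftest import simulate_crossed


def dense_reml_oracle(y, X, site, week, x0=(0.0, 0.0)):
    """Independent dense-covariance REML maximisation (no Woodbury).

    Builds V0 = I + ts Zs Zs' + tw Zw Zw' explicitly, evaluates the profiled
    REML criterion with dense inverses/determinants, and minimises it with a
    tightly-toleranced Nelder-Mead.  Returns (beta, s2_site, s2_week, s2_resid).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    sites, site_idx = np.unique(site, return_inverse=True)
    weeks, week_idx = np.unique(week, return_inverse=True)
    Zs = np.zeros((n, len(sites)))
    Zs[np.arange(n), site_idx] = 1.0
    Zw = np.zeros((n, len(weeks)))
    Zw[np.arange(n), week_idx] = 1.0
    ZsZs = Zs @ Zs.T
    ZwZw = Zw @ Zw.T

    def crit(lt):
        ts, tw = np.exp(lt)
        V0 = np.eye(n) + ts * ZsZs + tw * ZwZw
        Vi = np.linalg.inv(V0)
        XtVX = X.T @ Vi @ X
        beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
        r = y - X @ beta
        s2 = float(r @ Vi @ r) / (n - p)
        return (
            (n - p) * (1.0 + np.log(2.0 * np.pi * s2))
            + np.linalg.slogdet(V0)[1]
            + np.linalg.slogdet(XtVX)[1]
        )

    res = optimize.minimize(
        crit, x0=np.asarray(x0, float), method="Nelder-Mead",
        options={"xatol": 1e-11, "fatol": 1e-10, "maxiter": 5000},
    )
    ts, tw = np.exp(res.x)
    V0 = np.eye(n) + ts * ZsZs + tw * ZwZw
    Vi = np.linalg.inv(V0)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = float(r @ Vi @ r) / (n - p)
    return beta, ts * s2, tw * s2, s2


def fit_arrays(y, X, site, week, names=None, **kw):
    model = CrossedLMM(y, X, site, week, exog_names=names)
    return model.fit(**kw)


class TestStandardizer:
    def test_three_point_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = Standardizer().fit_transform(df, ["a"])
        assert np.allclose(out["a"], [-1.0, 0.0, 1.0])

    def test_reapplying_training_params_is_idempotent_on_training_data(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(5, 2, 50), "b": rng.normal(-1, 3, 50)})
        std = Standardizer().fit(df, ["a", "b"])
        once = std.transform(df)
        again = std.transform(df)
        assert np.allclose(once[["a", "b"]], again[["a", "b"]])
        assert abs(once["a"].mean()) < 1e-12 and abs(once["a"].std(ddof=1) - 1) < 1e-12

    def test_new_data_uses_training_parameters(self):
        train = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        shifted = pd.DataFrame({"a": [10.0, 11.0, 12.0]})
        std = Standardizer().fit(train, ["a"])
        out = std.transform(shifted)
        # standardized with the training mean/SD, not its own
        assert np.allclose(out["a"], [9.0, 10.0, 11.0])

    def test_zero_sd_column_rejected_by_name(self):
        df = pd.DataFrame({"flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            Standardizer().fit(df, ["flat"])


class TestReml:
    def test_zero_variance_data_matches_ols(self):
        """Data with no site/week/residual structure beyond iid noise at zero
        random-effect variance: beta equals the OLS solution to >= 6 digits."""
        rng = np.random.default_rng(1)
        n_sites, n_weeks = 12, 8
        n = n_sites * n_weeks
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        beta_true = np.array([3.0, 1.5, -2.0])
        y = X @ beta_true  # exactly deterministic response
        site = np.repeat(np.arange(n_sites), n_weeks)
        week = np.tile(np.arange(n_weeks), n_sites)
        res = fit_arrays(y, X, site, week)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(res.params.to_numpy(), ols, rtol=1e-9, atol=1e-9)

    def test_noise_free_city_data_recovers_truth_coefficients(
        self, small_layout, met52, campaign, simulation
    ):
        """Fitting samples generated with zero random-effect SDs recovers the
        generating coefficients to at least 6 significant digits."""
        import dataclasses

        from citynox.simulate import TruthModel, simulate_concentrations

        truth = TruthModel.default()
        nf = TruthModel(
            no2=dataclasses.replace(truth.no2, sd_site=0.0, sd_week=0.0, sd_resid=0.0),
            no=truth.no,
        )
        sim = simulate_concentrations(
            nf, small_layout, campaign, met52, seed=0,
            site_features=simulation.site_features,
        )
        data = sim.samples.copy()
        feats = sim.site_features
        for c in nf.no2.spatial:
            mu, sd = sim.standardization["no2"][c]
            data[c] = (feats.loc[data["site_id"], c].to_numpy() - mu) / sd
        for c in nf.no2.met:
            mu, sd = sim.standardization["no2"][c]
            data[c] = (data[c] - mu) / sd
        cols = list(nf.no2.spatial) + list(nf.no2.met)
        res = CrossedLMM.from_dataframe(data, "no2", cols, standardize=False).fit()
        for c in nf.no2.spatial:
            assert res.params[c] == pytest.approx(nf.no2.spatial[c], rel=1e-6)
        for c in nf.no2.met:
            assert res.params[c] == pytest.approx(nf.no2.met[c], rel=1e-6)

    def test_balanced_design_matches_anova_closed_form(self):
        """On a balanced fully crossed design with intercept-only fixed part,
        REML coincides with the ANOVA method-of-moments estimators:
        s2_resid = MSE, s2_site = (MSA - MSE)/b, s2_week = (MSB - MSE)/a."""
        a, b = 30, 25
        y, X, site, week = simulate_crossed(
            seed=2, n_sites=a, n_weeks=b, beta=[], sd_site=3.0, sd_week=2.0,
            sd_resid=1.5, n_covariates=0,
        )
        y = y + 10.0
        X1 = np.ones((a * b, 1))
        res = fit_arrays(y, X1, site, week)
        ym = y.reshape(a, b)
        grand = ym.mean()
        msa = b * ((ym.mean(axis=1) - grand) ** 2).sum() / (a - 1)
        msb = a * ((ym.mean(axis=0) - grand) ** 2).sum() / (b - 1)
        mse = ((ym - ym.mean(axis=1, keepdims=True) - ym.mean(axis=0, keepdims=True)
                + grand) ** 2).sum() / ((a - 1) * (b - 1))
        assert res.sigma2_resid == pytest.approx(mse, rel=1e-5)
        assert res.sigma2_site == pytest.approx((msa - mse) / b, rel=1e-5)
        assert res.sigma2_week == pytest.approx((msb - mse) / a, rel=1e-5)

    @pytest.mark.parametrize("seed,n_sites,n_weeks", [(3, 20, 10), (4, 15, 12)])
    def test_small_instance_matches_dense_oracle(self, seed, n_sites, n_weeks):
        """n <= 200: estimates agree with a direct dense-covariance REML
        maximisation to 1e-6 relative."""
        y, X, site, week = simulate_crossed(
            seed=seed, n_sites=n_sites, n_weeks=n_weeks, beta=[2.0, -1.0],
            sd_site=1.5, sd_week=1.0, sd_resid=1.0,
        )
        X1 = np.column_stack([np.ones(len(y)), X])
        res = fit_arrays(y, X1, site, week)
        beta_o, s2s_o, s2w_o, s2e_o = dense_reml_oracle(y, X1, site, week)
        assert np.allclose(res.params.to_numpy(), beta_o, rtol=1e-6)
        for mine, oracle in [
            (res.sigma2_site, s2s_o), (res.sigma2_week, s2w_o), (res.sigma2_resid, s2e_o),
        ]:
            assert mine == pytest.approx(oracle, rel=1e-6)

    def test_agrees_with_statsmodels_variance_components(self):
        """Cross-check against statsmodels MixedLM with crossed variance
        components (an entirely independent REML implementation)."""
        import statsmodels.formula.api as smf

        y, X, site, week = simulate_crossed(
            seed=8, n_sites=15, n_weeks=8, beta=[1.0, -2.0], sd_site=1.2,
            sd_week=0.7, sd_resid=1.0,
        )
        X1 = np.column_stack([np.ones(len(y)), X])
        mine = fit_arrays(y, X1, site, week)

        df = pd.DataFrame({"y": y, "x0": X[:, 0], "x1": X[:, 1],
                           "site": site, "week": week, "g": 1})
        sm_fit = smf.mixedlm(
            "y ~ x0 + x1", df, groups="g",
            vc_formula={"site": "0 + C(site)", "week": "0 + C(week)"},
        ).fit(reml=True)
        assert mine.params.iloc[0] == pytest.approx(sm_fit.params["Intercept"], rel=1e-4)
        assert mine.params.iloc[1] == pytest.approx(sm_fit.params["x0"], rel=1e-4)
        assert mine.sigma2_resid == pytest.approx(sm_fit.scale, rel=1e-3)
        assert mine.sigma2_site == pytest.approx(sm_fit.vcomp[0], rel=1e-3)
        assert mine.sigma2_week == pytest.approx(sm_fit.vcomp[1], rel=1e-3)

    def test_local_optimality_probe(self):
        """The REML criterion at the returned variance ratios is no larger
        than at any perturbed point on a surrounding grid."""
        y, X, site, week = simulate_crossed(
            seed=5, n_sites=15, n_weeks=10, beta=[1.0], sd_site=1.0, sd_week=0.8,
            sd_resid=1.0,
        )
        X1 = np.column_stack([np.ones(len(y)), X])
        model = CrossedLMM(y, X1, site, week)
        res = model.fit()
        ts = res.sigma2_site / res.sigma2_resid
        tw = res.sigma2_week / res.sigma2_resid
        at_opt = model.reml_neg2loglik(ts, tw)
        for fs in (0.8, 0.95, 1.05, 1.25):
            for fw in (0.8, 0.95, 1.05, 1.25):
                if fs == 1.0 and fw == 1.0:
                    continue
                assert model.reml_neg2loglik(ts * fs, tw * fw) >= at_opt - 1e-8

    def test_preconditions(self):
        y = np.arange(4.0)
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="2 sites"):
            CrossedLMM(y, X, [0, 0, 0, 0], [0, 1, 0, 1])
        with pytest.raises(ValueError, match="n > p"):
            CrossedLMM(y[:2], np.ones((2, 2)), [0, 1], [0, 1])


class TestFromDataframe:
    def test_month_dummies_reference_and_count(self, analysis_data):
        model = CrossedLMM.from_dataframe(
            analysis_data, "no2", ["major_road_length_100"]
        )
        months = sorted(analysis_data["iso_week"].map(
            lambda w: cx.lmm.month_label(w)).unique())
        dummy_cols = [n for n in model.exog_names if n.startswith("month[")]
        assert len(dummy_cols) == len(months) - 1
        assert model.reference_month == months[0]
        assert f"month[{months[0]}]" not in model.exog_names


class TestR2Decomposition:
    def test_zero_variance_components_give_equal_r2(self):
        rng = np.random.default_rng(6)
        n_sites, n_weeks = 10, 10
        n = n_sites * n_weeks
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 2.0]) + 0.5 * rng.standard_normal(n)
        res = fit_arrays(y, X, np.repeat(np.arange(n_sites), n_weeks),
                         np.tile(np.arange(n_weeks), n_sites))
        r2f, r2m = res.r2()
        # variance components should be ~0, so the two R2s coincide
        assert r2m == pytest.approx(r2f, abs=0.02)
        assert r2f > 0.8

    def test_pure_noise_gives_near_zero_r2(self):
        rng = np.random.default_rng(7)
        n_sites, n_weeks = 40, 25
        n = n_sites * n_weeks
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        res = fit_arrays(y, X, np.repeat(np.arange(n_sites), n_weeks),
                         np.tile(np.arange(n_weeks), n_sites))
        r2f, r2m = res.r2()
        assert r2f < 0.02
        assert r2m < 0.1

    def test_r2_mixed_geq_fixed_and_bounded(self, no2_fit):
        r2f, r2m = no2_fit.r2()
        assert 0.0 <= r2f <= r2m <= 1.0


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self, analysis_data, no2_fit):
        preds = no2_fit.predict(
            analysis_data[no2_fit.model.predictor_cols],
            iso_week=analysis_data["iso_week"].to_numpy(),
            site_id=analysis_data["site_id"].to_numpy(),
        )
        assert np.allclose(preds, no2_fit.fittedvalues, rtol=1e-10, atol=1e-8)

    def test_intercept_path(self, analysis_data, no2_fit):
        """A row at the training predictor means, no week, unknown site:
        the prediction is exactly the fitted intercept."""
        cols = no2_fit.model.predictor_cols
        means = analysis_data[cols].mean().to_frame().T
        pred = no2_fit.predict(means, iso_week=None, site_id=None)
        assert pred[0] == pytest.approx(no2_fit.params["intercept"], rel=1e-10)

    def test_week_blup_additivity(self, analysis_data, no2_fit):
        """Adding the week label changes the prediction by exactly the month
        effect plus that week's BLUP."""
        cols = no2_fit.model.predictor_cols
        row = analysis_data[cols].iloc[[0]]
        week = analysis_data["iso_week"].iloc[0]
        without = no2_fit.predict(row, iso_week=None)
        with_week = no2_fit.predict(row, iso_week=week)
        month_name = f"month[{cx.lmm.month_label(week)}]"
        month_coef = no2_fit.params.get(month_name, 0.0)
        expected = month_coef + no2_fit.blup_week[week]
        assert with_week[0] - without[0] == pytest.approx(expected, rel=1e-10)

    def test_unknown_site_and_week_flagged_zero_contribution(self, no2_fit, analysis_data):
        cols = no2_fit.model.predictor_cols
        row = analysis_data[cols].iloc[[0]]
        known_week = analysis_data["iso_week"].iloc[0]
        p_known_site = no2_fit.predict(
            row, iso_week=known_week, site_id=analysis_data["site_id"].iloc[0]
        )
        p_unknown_site = no2_fit.predict(row, iso_week=known_week, site_id="nowhere")
        diff = p_known_site[0] - p_unknown_site[0]
        assert diff == pytest.approx(
            no2_fit.blup_site[analysis_data["site_id"].iloc[0]], rel=1e-9
        )

    def test_missing_predictor_column_named(self, no2_fit):
        with pytest.raises(KeyError, match="ndvi_50"):
            no2_fit.predict(pd.DataFrame({"major_road_length_100": [0.0]}))


class TestSummary:
    def test_summary_mentions_key_quantities(self, no2_fit):
        text = no2_fit.summary()
        assert "REML" in text
        assert "sd(site)" in text
        assert "intercept" in text
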