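"""Mixed-model machinery: fits, EMMs, contrasts, AICc, bootstrap, screens.

One test cross-checks the adaptive Gauss-Hermite Poisson GLMM against
lme4::glmer (the field's reference implementation) through Rscript.
"""

import subprocess

import numpy as np
import pandas as pd
import pytest

from echogaze.glmm import (LinearMM, PoissonGLMM, collinearity_screen,
                           fit_mixed_model, model_selection_aicc,
                           parametric_bootstrap_null, simulate_poisson_glmm)


def _design(n_bats=7, flights=(1, 12)):
    return pd.DataFrame({
        "bat_id": np.repeat([f"b{i}" for i in range(n_bats)], len(flights)),
        "flight_number": np.tile(flights, n_bats)})


class TestPoissonGLMM:
    def test_constant_response_gives_intercept_only(self):
        data = _design().assign(y=30)
        res = PoissonGLMM.from_dataframe(data, "y", ["flight_number"]).fit()
        assert res.fe_params[0] == pytest.approx(np.log(30.0), abs=1e-4)
        assert abs(res.fe_params[1]) < 1e-4
        assert res.singular  # no between-bat variance in constant data

    def test_matches_lme4_glmer(self, tmp_path):
        rng = np.random.default_rng(7)
        data = _design()
        y = simulate_poisson_glmm(data, ["flight_number"],
                                  [np.log(52.0), np.log(29.0 / 52.0)],
                                  0.15, rng=rng)
        data = data.assign(y=y.astype(int))
        res = PoissonGLMM.from_dataframe(data, "y", ["flight_number"]).fit()
        null = PoissonGLMM.from_dataframe(data, "y", []).fit()
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$flight_number <- factor(d$flight_number)
        m <- glmer(y ~ flight_number + (1|bat_id), data=d, family=poisson, nAGQ=15)
        m0 <- glmer(y ~ 1 + (1|bat_id), data=d, family=poisson, nAGQ=15)
        cat(fixef(m), sqrt(unlist(VarCorr(m))),
            as.numeric(logLik(m)) - as.numeric(logLik(m0)), sep="\\n")
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        b0, b1, sig, dll = map(float, out.stdout.split())
        assert res.fe_params[0] == pytest.approx(b0, abs=1e-3)
        assert res.fe_params[1] == pytest.approx(b1, abs=1e-3)
        assert res.sigma_u == pytest.approx(sig, abs=2e-3)
        assert res.llf - null.llf == pytest.approx(dll, abs=2e-3)

    def test_slope_recovery_within_two_se(self):
        """Standardised-speed slope -1.5 is recovered by the Poisson GLMM."""
        rng = np.random.default_rng(17)
        data = _design(n_bats=14)
        data["speed_z"] = rng.normal(0.0, 1.0, size=len(data))
        y = simulate_poisson_glmm(data, ["speed_z"], [np.log(40.0), -1.5],
                                  0.15, rng=rng)
        data = data.assign(y=y.astype(int))
        res = PoissonGLMM.from_dataframe(data, "y", ["speed_z"]).fit()
        i = res.model.design.column_names.index("speed_z")
        assert abs(res.fe_params[i] - (-1.5)) < 2.0 * res.bse[i]

    def test_overdispersion_near_one_for_poisson_data(self):
        rng = np.random.default_rng(3)
        data = _design(n_bats=20)
        y = simulate_poisson_glmm(data, ["flight_number"],
                                  [np.log(40.0), -0.4], 0.1, rng=rng)
        res = PoissonGLMM.from_dataframe(data.assign(y=y), "y",
                                         ["flight_number"]).fit()
        assert 0.4 < res.overdispersion() < 2.0

    def test_r2_marginal_not_above_conditional(self, permeable_counts):
        res = fit_mixed_model(permeable_counts, "total_pulses",
                              ["flight_number"], family="poisson")
        r2m, r2c = res.r2_nakagawa()
        assert 0.0 <= r2m <= r2c <= 1.0

    def test_wald_type2_table(self, permeable_counts):
        res = fit_mixed_model(permeable_counts, "total_pulses",
                              ["flight_number"], family="poisson")
        tab = res.wald_type2()
        assert set(tab["term"]) == {"flight_number"}
        assert (tab["chi2"] >= 0).all()
        assert tab["p_value"].between(0, 1).all()

    def test_summary_mentions_key_quantities(self, permeable_counts):
        res = fit_mixed_model(permeable_counts, "total_pulses",
                              ["flight_number"], family="poisson")
        text = res.summary()
        for token in ("logLik", "AICc", "sigma_u", "overdispersion"):
            assert token in text


class TestMarginalMeans:
    def test_single_cell_grouping_has_no_contrasts(self, permeable_counts):
        res = fit_mixed_model(permeable_counts.assign(all_one=1),
                              "total_pulses", ["flight_number"],
                              family="poisson")
        mm = res.marginal_means("flight_number")
        assert len(mm) == 2
        contrasts = res.pairwise_contrasts("flight_number")
        assert len(contrasts) == 1  # 2 cells -> 1 pair
        assert contrasts["p_value"].between(0, 1).all()

    def test_balanced_no_effect_emms_equal_grand_mean(self):
        data = _design().assign(y=25)
        res = PoissonGLMM.from_dataframe(data, "y", ["flight_number"]).fit()
        mm = res.marginal_means("flight_number")
        np.testing.assert_allclose(mm["emmean"], 25.0, rtol=1e-3)

    def test_ci_bounds_ordered(self, permeable_counts):
        res = fit_mixed_model(permeable_counts, "multiple_pulses",
                              ["flight_number"], family="poisson")
        mm = res.marginal_means("flight_number")
        assert (mm["ci_lower"] < mm["emmean"]).all()
        assert (mm["emmean"] < mm["ci_upper"]).all()

    def test_bonferroni_style_contrasts_also_available(self, permeable_counts):
        res = fit_mixed_model(permeable_counts, "total_pulses",
                              ["flight_number"], family="poisson")
        tuk = res.pairwise_contrasts("flight_number", adjust="tukey")
        bon = res.pairwise_contrasts("flight_number", adjust="bonferroni")
        assert len(tuk) == len(bon)
        assert (bon["p_value"] <= 1.0).all()


class TestLinearMM:
    def test_recovers_cell_means(self):
        rng = np.random.default_rng(23)
        data = _design(n_bats=30)
        shell = data.assign(y=0.0)
        mod = LinearMM("y", shell, ["flight_number"], "bat_id")
        y = mod.simulate(np.array([2.5, 0.9]), 0.35, rng, scale=0.30)
        res = mod.refit_with_response(y).fit()
        mm = res.marginal_means("flight_number").set_index("flight_number")
        assert mm.loc[1, "emmean"] == pytest.approx(2.5, abs=0.3)
        assert mm.loc[12, "emmean"] == pytest.approx(3.4, abs=0.3)

    def test_boundary_variance_handled(self):
        # zero between-bat variance: fit must still return a usable result
        rng = np.random.default_rng(2)
        data = _design()
        y = 3.0 + rng.normal(0, 0.1, len(data))
        res = LinearMM("y", data.assign(y=y), ["flight_number"], "bat_id").fit()
        assert np.isfinite(res.llf)
        assert res.sigma_u >= 0.0


class TestCollinearityScreen:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        out = collinearity_screen(x, -x)
        assert out["rho"] == pytest.approx(-1.0)
        assert out["split"]

    def test_independent_covariates_no_split(self):
        rng = np.random.default_rng(0)
        out = collinearity_screen(rng.normal(size=28), rng.normal(size=28))
        assert abs(out["rho"]) < 0.35
        assert not out["split"]
        assert out["df"] == 26

    def test_generator_defaults_trigger_split(self, permeable_cohort):
        fl = [f.flight_number for f in permeable_cohort]
        dd = [f.meander_drawn for f in permeable_cohort]
        out = collinearity_screen(fl, dd)
        assert out["rho"] < 0
        assert out["split"]

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            collinearity_screen(np.ones(10), np.arange(10.0))


class TestModelSelection:
    def test_identical_models_tie(self, permeable_counts):
        a = fit_mixed_model(permeable_counts, "total_pulses",
                            ["flight_number"], family="poisson")
        b = fit_mixed_model(permeable_counts, "total_pulses",
                            ["flight_number"], family="poisson")
        tab = model_selection_aicc([a, b], ["a", "b"])
        assert tab["delta_aicc"].max() == pytest.approx(0.0, abs=1e-6)

    def test_true_covariate_beats_noise(self):
        rng = np.random.default_rng(31)
        wins = 0
        reps = 25
        for _ in range(reps):
            data = _design(n_bats=14)
            data["true_x"] = rng.normal(size=len(data))
            data["noise_x"] = rng.normal(size=len(data))
            y = simulate_poisson_glmm(data, ["true_x"], [np.log(30.0), 0.5],
                                      0.1, rng=rng)
            data = data.assign(y=y)
            rt = PoissonGLMM.from_dataframe(data, "y", ["true_x"]).fit()
            rn = PoissonGLMM.from_dataframe(data, "y", ["noise_x"]).fit()
            tab = model_selection_aicc([rt, rn], ["true", "noise"])
            wins += tab.iloc[0]["model"] == "true"
        assert wins / reps >= 0.9

    def test_useless_parameter_penalised_on_null_data(self):
        rng = np.random.default_rng(5)
        data = _design(n_bats=14)
        data["noise_x"] = rng.normal(size=len(data))
        y = simulate_poisson_glmm(data, [], [np.log(30.0)], 0.1, rng=rng)
        data = data.assign(y=y)
        r0 = PoissonGLMM.from_dataframe(data, "y", []).fit()
        r1 = PoissonGLMM.from_dataframe(data, "y", ["noise_x"]).fit()
        tab = model_selection_aicc([r0, r1], ["null", "extra"]).set_index("model")
        assert tab.loc["extra", "delta_aicc"] >= 0.0

    def test_different_data_rejected(self, permeable_counts):
        a = fit_mixed_model(permeable_counts, "total_pulses",
                            ["flight_number"], family="poisson")
        b = fit_mixed_model(permeable_counts, "multiple_pulses",
                            ["flight_number"], family="poisson")
        with pytest.raises(ValueError):
            model_selection_aicc([a, b])


class TestParametricBootstrap:
    def test_full_equals_null_gives_high_p(self, permeable_counts):
        res = fit_mixed_model(permeable_counts, "total_pulses", [],
                              family="poisson")
        boot = parametric_bootstrap_null(res, res, n_sim=39,
                                         rng=np.random.default_rng(0))
        assert boot["stat"] == pytest.approx(0.0, abs=1e-9)
        assert boot["p_value"] > 0.9

    def test_strong_effect_gives_minimal_p(self, permeable_counts):
        full = fit_mixed_model(permeable_counts, "total_pulses",
                               ["flight_number"], family="poisson")
        null = fit_mixed_model(permeable_counts, "total_pulses", [],
                               family="poisson")
        n_sim = 49
        boot = parametric_bootstrap_null(full, null, n_sim=n_sim,
                                         rng=np.random.default_rng(1))
        assert boot["p_value"] <= 1.0 / (boot["n_converged"] + 1) + 1e-12
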