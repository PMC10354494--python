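import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from colonynet import variance_models as vm
from colonynet.synthetic_data import simulate_metric_responses


def dataset(seed=0, n_colonies=10, n_days=12, var_colony=1.5, var_date=0.0,
            var_resid=1.0, with_x=False):
    rng = np.random.default_rng(seed)
    d = simulate_metric_responses(n_colonies, n_days, var_colony, var_date,
                                  var_resid, rng=rng)
    if with_x:
        d["x1"] = rng.normal(size=len(d))
        d["x2"] = rng.normal(size=len(d))
        d["y"] = d["y"] + 0.8 * d["x1"] - 0.5 * d["x2"]
    return d


class TestOnewayReml:
    @pytest.mark.parametrize("seed,fixed", [(1, ()), (2, ("x1",)),
                                            (3, ("x1", "x2"))])
    def test_profiled_solver_matches_statsmodels(self, seed, fixed):
        d = dataset(seed=seed, with_x=bool(fixed))
        spec = vm.ModelSpec(response="y", fixed=fixed, random=("colony_id",))
        a = vm.fit_lmm(d, spec, engine="profile")
        b = vm.fit_lmm(d, spec, engine="statsmodels")
        assert a.var_colony == pytest.approx(b.var_colony, rel=2e-3, abs=1e-6)
        assert a.var_resid == pytest.approx(b.var_resid, rel=2e-3)
        for name in a.beta:
            assert a.beta[name][0] == pytest.approx(b.beta[name][0], abs=1e-4)

    def test_balanced_design_matches_anova_moment_estimator(self):
        # on balanced one-way data, REML equals the classical
        # (MSB - MSW) / n_per_group estimator when it is positive
        d = dataset(seed=5, n_colonies=8, n_days=20)
        vd = vm.fit_lmm(d, vm.uninformed_spec("y"))
        g = d.groupby("colony_id")["y"]
        k, n = g.ngroups, g.size().iloc[0]
        grand = d["y"].mean()
        msb = n * ((g.mean() - grand) ** 2).sum() / (k - 1)
        msw = (g.apply(lambda s: ((s - s.mean()) ** 2).sum()).sum()
               / (k * (n - 1)))
        assert vd.var_colony == pytest.approx((msb - msw) / n, rel=1e-5)
        assert vd.var_resid == pytest.approx(msw, rel=1e-5)

    def test_pure_noise_hits_the_zero_boundary(self):
        d = dataset(seed=11, var_colony=0.0, n_colonies=6, n_days=8)
        vd = vm.fit_lmm(d, vm.uninformed_spec("y"))
        assert vd.var_colony < 0.1

    def test_exact_linear_response_leaves_no_residual_variance(self):
        d = dataset(seed=13, var_colony=0.0, var_resid=1.0, with_x=True)
        rng = np.random.default_rng(99)
        d["y"] = 2.0 + 3.0 * d["x1"] + 1e-8 * rng.normal(size=len(d))
        spec = vm.ModelSpec(response="y", fixed=("x1",), random=("colony_id",))
        vd = vm.fit_lmm(d, spec)
        assert vd.beta["x1"][0] == pytest.approx(3.0, abs=1e-6)
        assert vd.beta["intercept"][0] == pytest.approx(2.0, abs=1e-6)
        assert vd.var_resid < 1e-12


class TestCrossedModel:
    def test_recovers_known_variance_components(self):
        d = dataset(seed=7, n_colonies=12, n_days=30, var_colony=2.0,
                    var_date=1.0, var_resid=1.0)
        spec = vm.ModelSpec(response="y", fixed=(), random=("colony_id", "date"))
        vd = vm.fit_lmm(d, spec)
        # truth R = 2 / (2+1+1) = 0.5; single-study sampling noise is wide
        assert vm.repeatability(vd) == pytest.approx(0.5, abs=0.2)
        assert vd.var_date > 0.2

    def test_agrees_with_lme4(self, tmp_path):
        d = dataset(seed=17, n_colonies=8, n_days=10, var_colony=1.0,
                    var_date=0.5, var_resid=1.0, with_x=True)
        csv = tmp_path / "d.csv"
        d.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ x1 + x2 + (1|colony_id) + (1|date), data=d, REML=TRUE)
            vc <- as.data.frame(VarCorr(m))
            out <- c(vc$vcov[vc$grp=="colony_id"], vc$vcov[vc$grp=="date"],
                     vc$vcov[vc$grp=="Residual"], fixef(m))
            cat(sprintf("%.10f", out), sep="\\n")
        """)
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True, check=True)
        vals = [float(v) for v in proc.stdout.strip().splitlines()]
        vc_colony, vc_date, vc_resid, b0, b1, b2 = vals
        spec = vm.ModelSpec(response="y", fixed=("x1", "x2"),
                            random=("colony_id", "date"))
        vd = vm.fit_lmm(d, spec)
        assert vd.var_colony == pytest.approx(vc_colony, rel=1e-3, abs=1e-5)
        assert vd.var_date == pytest.approx(vc_date, rel=1e-3, abs=1e-5)
        assert vd.var_resid == pytest.approx(vc_resid, rel=1e-3)
        assert vd.beta["intercept"][0] == pytest.approx(b0, abs=1e-5)
        assert vd.beta["x1"][0] == pytest.approx(b1, abs=1e-5)
        assert vd.beta["x2"][0] == pytest.approx(b2, abs=1e-5)


class TestRepeatabilityAndR2:
    def vd(self, vc, vdte, vr, vf=0.0):
        return vm.VarianceDecomposition(
            spec=vm.uninformed_spec("y"), beta={}, var_colony=vc,
            var_date=vdte, var_resid=vr, var_fixed=vf, n_obs=10,
            converged=True, method="test")

    def test_zero_colony_variance_gives_zero_repeatability(self):
        assert vm.repeatability(self.vd(0.0, 0.0, 1.0)) == 0.0

    def test_equal_components_give_half(self):
        assert vm.repeatability(self.vd(1.0, 0.0, 1.0)) == 0.5

    def test_all_zero_components_error(self):
        with pytest.raises(ValueError):
            vm.repeatability(self.vd(0.0, 0.0, 0.0))

    def test_include_fixed_enlarges_the_denominator(self):
        v = self.vd(1.0, 0.0, 1.0, vf=2.0)
        assert vm.repeatability(v, include_fixed=True) == 0.25

    def test_r2_without_fixed_effects(self):
        rm2, rc2 = vm.r2_marginal_conditional(self.vd(1.0, 1.0, 2.0))
        assert rm2 == 0.0 and rc2 == 0.5

    def test_r2_partition_sums_to_one(self):
        v = self.vd(1.0, 0.5, 1.5, vf=2.0)
        rm2, rc2 = vm.r2_marginal_conditional(v)
        resid_share = v.var_resid / (v.var_fixed + v.var_colony + v.var_date
                                     + v.var_resid)
        assert rm2 + (rc2 - rm2) + resid_share == pytest.approx(1.0)

    def test_residual_free_fixed_model_approaches_one(self):
        rm2, _ = vm.r2_marginal_conditional(self.vd(0.0, 0.0, 1e-12, vf=1.0))
        assert rm2 == pytest.approx(1.0, abs=1e-9)


class TestBootstrap:
    def test_single_replicate_gives_degenerate_interval(self):
        d = dataset(seed=21)
        est = vm.bootstrap_repeatability(d, vm.uninformed_spec("y"), B=1,
                                         seed=0)
        assert est.ci_low == est.ci_high == est.samples[0]

    def test_same_seed_is_reproducible(self):
        d = dataset(seed=22)
        spec = vm.uninformed_spec("y")
        a = vm.bootstrap_repeatability(d, spec, B=25, seed=4)
        b = vm.bootstrap_repeatability(d, spec, B=25, seed=4)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_interval_brackets_the_point_estimate_for_wellbehaved_data(self):
        d = dataset(seed=23, n_colonies=12, n_days=20)
        est = vm.bootstrap_repeatability(d, vm.uninformed_spec("y"), B=100,
                                         seed=1)
        assert 0.0 <= est.ci_low <= est.ci_high <= 1.0
        assert est.ci_low <= est.R <= est.ci_high

    def test_row_resampling_method_runs(self):
        d = dataset(seed=24)
        est = vm.bootstrap_repeatability(d, vm.uninformed_spec("y"), B=20,
                                         seed=2, method="rows")
        assert est.method == "rows" and len(est.samples) == 20


class TestVif:
    def spec(self, fixed):
        return vm.ModelSpec(response="y", fixed=fixed, random=("colony_id",))

    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        d = dataset(seed=31, n_colonies=8, n_days=8)
        d["x1"] = np.tile([1.0, -1.0], n // 2)
        d["x2"] = np.repeat([1.0, -1.0], n // 2)
        vifs = vm.compute_vif(d, self.spec(("x1", "x2")))
        assert vifs["x1"] == pytest.approx(1.0)
        assert vifs["x2"] == pytest.approx(1.0)

    def test_near_duplicate_predictor_explodes(self):
        d = dataset(seed=32, with_x=True)
        d["x2"] = d["x1"] + 1e-4 * np.random.default_rng(0).normal(size=len(d))
        vifs = vm.compute_vif(d, self.spec(("x1", "x2")))
        assert vifs["x1"] > 100

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(33)
        d = dataset(seed=33)
        Z = rng.normal(size=(len(d), 3)) @ np.array(
            [[1.0, 0.4, 0.0], [0.0, 1.0, 0.5], [0.2, 0.0, 1.0]])
        d[["x1", "x2", "x3"]] = Z
        vifs = vm.compute_vif(d, self.spec(("x1", "x2", "x3")))
        import statsmodels.api as sm
        for j, name in enumerate(["x1", "x2", "x3"]):
            others = [c for c in ["x1", "x2", "x3"] if c != name]
            r2 = sm.OLS(d[name], sm.add_constant(d[others])).fit().rsquared
            assert vifs[name] == pytest.approx(1.0 / (1.0 - r2))

    def test_perfect_collinearity_names_the_column(self):
        d = dataset(seed=34, with_x=True)
        d["x2"] = 2.0 * d["x1"]
        with pytest.raises(ValueError, match="collinear"):
            vm.compute_vif(d, self.spec(("x1", "x2")))


class TestPartialResiduals:
    def test_only_focal_model_subtracts_random_effects_alone(self):
        d = dataset(seed=41, with_x=True)
        spec = vm.ModelSpec(response="y", fixed=("x1",), random=("colony_id",))
        vd = vm.fit_lmm(d, spec)
        corrected = vm.partial_residuals(d, vd, "x1")
        np.testing.assert_allclose(corrected.to_numpy(),
                                   d["y"].to_numpy() - vd.ranef_rows)

    def test_slope_against_focal_matches_fitted_coefficient(self):
        d = dataset(seed=42, n_colonies=12, n_days=20, with_x=True)
        spec = vm.ModelSpec(response="y", fixed=("x1", "x2"),
                            random=("colony_id",))
        vd = vm.fit_lmm(d, spec)
        corrected = vm.partial_residuals(d, vd, "x1")
        slope = np.polyfit(d["x1"], corrected, 1)[0]
        assert slope == pytest.approx(vd.beta["x1"][0], abs=0.02)

    def test_unknown_focal_driver_is_an_error(self):
        d = dataset(seed=43, with_x=True)
        vd = vm.fit_lmm(d, vm.ModelSpec(response="y", fixed=("x1",),
                                        random=("colony_id",)))
        with pytest.raises(ValueError, match="x2"):
            vm.partial_residuals(d, vd, "x2")
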