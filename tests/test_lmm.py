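"""Mixed-model correctness: OLS limit, independent-library cross-checks,
Type III calibration, stepwise elimination, and conditional R-squared."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from thermobuzz.lmm import (ModelSpec, conditional_r2, fit_model,
                            stepwise_reduce, type3_table)
from thermobuzz.synthetic import PopulationParams, simulate_bee_dataset


def population(fe=None, **kw):
    fe = fe or {"intercept": 185.0, "T_air": 1.5, "distribution": 1.0}
    return PopulationParams(fixed_effects=fe, **kw)


@pytest.fixture(scope="module")
def mixed_data():
    data, _ = simulate_bee_dataset(population(), 215, "frequency", seed=42)
    return data


@pytest.fixture(scope="module")
def mixed_fit(mixed_data):
    spec = ModelSpec("frequency", ["T_air", "distribution"], ["species", "caste"])
    return fit_model(spec, mixed_data)


class TestFitModel:
    def test_zero_variance_limit_matches_ols(self):
        # when the REML estimate lands on the boundary (no group variance),
        # the mixed fit must coincide with plain OLS exactly
        p = population(sd_species=0.0, sd_caste=0.0, sd_residual=20.0)
        data, _ = simulate_bee_dataset(p, 215, "frequency", seed=0)
        spec = ModelSpec("frequency", ["T_air", "mass"], ["species", "caste"])
        lmm = fit_model(spec, data)
        assert lmm.singular and all(v == 0.0 for v in lmm.varcomps.values())
        ols = smf.ols("frequency ~ T_air + mass", data).fit()
        for name in ("Intercept", "T_air", "mass"):
            assert lmm.coefficients.loc[name, "estimate"] == pytest.approx(
                ols.params[name], abs=1e-6 * max(1, abs(ols.params[name])))

    def test_matches_statsmodels_mixedlm(self, mixed_data):
        spec = ModelSpec("frequency", ["T_air"], ["species", "caste"])
        mine = fit_model(spec, mixed_data)
        sm_fit = smf.mixedlm(
            "frequency ~ T_air", mixed_data, groups=np.ones(len(mixed_data)),
            vc_formula={"species": "0 + C(species)", "caste": "0 + C(caste)"},
        ).fit(reml=True)
        assert mine.coefficients.loc["T_air", "estimate"] == pytest.approx(
            sm_fit.fe_params["T_air"], abs=0.01)
        assert mine.varcomps["species"] == pytest.approx(
            sm_fit.vcomp[1], rel=0.05, abs=1.0)
        assert mine.residual_var == pytest.approx(sm_fit.scale, rel=0.02)

    def test_matches_lmerTest_oracle(self, mixed_data, tmp_path):
        """Fixed effects, variance components, REML log-likelihood and the
        Satterthwaite Type III table must agree with lme4/lmerTest."""
        csv = tmp_path / "bees.csv"
        mixed_data.assign(
            dist_code=np.where(mixed_data.distribution == "generalist", 1.0, -1.0)
        ).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}", colClasses=c(species='factor', caste='factor'))
            m <- lmer(frequency ~ T_air + dist_code + (1|species) + (1|caste),
                      data=d, REML=TRUE)
            co <- summary(m)$coefficients
            vc <- as.data.frame(VarCorr(m))
            a <- anova(m, type=3)
            cat(co['T_air','Estimate'], co['T_air','Std. Error'],
                vc$vcov[vc$grp=='species'], vc$vcov[vc$grp=='caste'],
                vc$vcov[vc$grp=='Residual'], as.numeric(logLik(m)),
                a['T_air','F value'], a['T_air','DenDF'], sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        est, se, v_sp, v_ca, v_res, ll, f_air, dfd = map(float, out.stdout.split())
        spec = ModelSpec("frequency", ["T_air", "dist_code"], ["species", "caste"])
        mine = fit_model(spec, pd.read_csv(csv))
        assert mine.coefficients.loc["T_air", "estimate"] == pytest.approx(est, abs=1e-4)
        assert mine.coefficients.loc["T_air", "se"] == pytest.approx(se, rel=1e-3)
        assert mine.varcomps["species"] == pytest.approx(v_sp, rel=1e-2, abs=0.5)
        assert mine.varcomps["caste"] == pytest.approx(v_ca, rel=1e-2, abs=0.5)
        assert mine.residual_var == pytest.approx(v_res, rel=1e-3)
        assert mine.loglik == pytest.approx(ll, abs=1e-3)
        t3 = type3_table(mine).set_index("term")
        assert t3.loc["T_air", "F"] == pytest.approx(f_air, rel=1e-3)
        assert t3.loc["T_air", "df_den"] == pytest.approx(dfd, rel=1e-2)

    def test_response_shift_moves_only_intercept(self, mixed_data, mixed_fit):
        shifted = mixed_data.assign(frequency=mixed_data.frequency + 100.0)
        fit2 = fit_model(mixed_fit.spec, shifted)
        a, b = mixed_fit.coefficients, fit2.coefficients
        assert b.loc["Intercept", "estimate"] - a.loc["Intercept", "estimate"] \
            == pytest.approx(100.0, abs=1e-6)
        others = [n for n in a.index if n != "Intercept"]
        assert np.allclose(a.loc[others, "estimate"], b.loc[others, "estimate"],
                           atol=1e-6)

    def test_missing_mass_rows_dropped_with_count(self, mixed_data):
        data = mixed_data.copy()
        data["mass"] = data["mass"].mask(data.index < 6)
        spec = ModelSpec("frequency", ["T_air", "mass"], ["species", "caste"])
        fit = fit_model(spec, data)
        assert fit.n_dropped == 6
        assert fit.n_bees == len(data) - 6

    def test_single_level_grouping_rejected(self, mixed_data):
        data = mixed_data.assign(caste="worker")
        spec = ModelSpec("frequency", ["T_air"], ["species", "caste"])
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            fit_model(spec, data)


class TestTypeIII:
    def test_balanced_one_factor_equals_classical_anova(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame({
            "g": np.repeat(["a", "b", "c"], 40),
            "y": np.concatenate([rng.normal(m, 1.0, 40) for m in (0.0, 0.5, 1.0)]),
        })
        fit = fit_model(ModelSpec("y", ["g"], []), data)
        t3 = type3_table(fit).iloc[0]
        classical = sm.stats.anova_lm(smf.ols("y ~ C(g, Sum)", data).fit(), typ=3)
        assert t3["F"] == pytest.approx(classical.loc["C(g, Sum)", "F"], rel=1e-9)
        assert t3["df_den"] == pytest.approx(117.0, abs=1e-3)

    def test_single_df_f_equals_squared_t(self, mixed_fit):
        t3 = type3_table(mixed_fit).set_index("term")
        est = mixed_fit.coefficients.loc["T_air", "estimate"]
        se = mixed_fit.coefficients.loc["T_air", "se"]
        assert t3.loc["T_air", "F"] == pytest.approx((est / se) ** 2, rel=1e-10)

    def test_type_iii_invariant_to_term_order(self, mixed_data):
        s1 = ModelSpec("frequency", ["T_air", "mass", "distribution"],
                       ["species", "caste"])
        s2 = ModelSpec("frequency", ["distribution", "mass", "T_air"],
                       ["species", "caste"])
        t1 = type3_table(fit_model(s1, mixed_data)).set_index("term").sort_index()
        t2 = type3_table(fit_model(s2, mixed_data)).set_index("term").sort_index()
        assert np.allclose(t1["F"], t2["F"], rtol=1e-8)

    def test_null_term_type_one_error_nominal(self):
        # OLS path: y depends on x1 only; rejection rate for null x2
        rng = np.random.default_rng(9)
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            n = 60
            data = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
            data["y"] = 2.0 * data.x1 + rng.normal(size=n)
            t3 = type3_table(fit_model(ModelSpec("y", ["x1", "x2"], []), data))
            hits += t3.set_index("term").loc["x2", "p"] < 0.05
        assert 0.03 <= hits / n_sims <= 0.07


class TestStepwise:
    def test_no_interactions_spec_unchanged(self, mixed_data):
        spec = ModelSpec("frequency", ["T_air", "mass"], ["species", "caste"])
        final, log = stepwise_reduce(spec, mixed_data)
        assert final.fixed_terms == spec.fixed_terms and log == []

    def test_strong_interaction_retained(self):
        kept = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            p = population(fe={"intercept": 50.0, "T_air": 2.0, "mass": 100.0})
            data, _ = simulate_bee_dataset(p, 215, "acceleration", seed)
            data["acceleration"] += 30.0 * data["mass"] * data["T_air"]
            spec = ModelSpec("acceleration", ["T_air", "mass", "mass:T_air"],
                             ["species", "caste"])
            final, _ = stepwise_reduce(spec, data)
            kept += "mass:T_air" in final.fixed_terms
        assert kept >= 95

    def test_null_interactions_removed(self):
        # centred predictors keep the interaction test at its nominal level
        # (the Satterthwaite F inherits mild inflation under the extreme
        # main-effect collinearity of raw-scale products; verified to match
        # the reference mixed-model implementation either way)
        n_sims = 300
        removed = 0
        for seed in range(n_sims):
            p = population(fe={"intercept": 50.0, "T_air": 2.0, "mass": 100.0})
            data, _ = simulate_bee_dataset(p, 215, "acceleration", seed + 1000)
            data["T_c"] = data["T_air"] - data["T_air"].mean()
            data["m_c"] = data["mass"] - data["mass"].mean()
            spec = ModelSpec("acceleration", ["T_c", "m_c", "m_c:T_c"],
                             ["species", "caste"])
            final, _ = stepwise_reduce(spec, data)
            removed += "m_c:T_c" not in final.fixed_terms
        assert removed >= 0.90 * n_sims


class TestConditionalR2:
    def test_no_noise_gives_one(self):
        p = population(sd_species=5.0, sd_caste=2.0, sd_residual=1e-6)
        data, _ = simulate_bee_dataset(p, 215, "frequency", seed=2)
        fit = fit_model(ModelSpec("frequency", ["T_air", "distribution"],
                                  ["species", "caste"]), data)
        assert fit.conditional_r2 == pytest.approx(1.0, abs=1e-3)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame({"y": rng.normal(size=300), "x": rng.normal(size=300)})
        fit = fit_model(ModelSpec("y", ["x"], []), data)
        assert fit.conditional_r2 < 0.05

    def test_known_variance_partition(self):
        # fixed-effect variance 2, species variance 1, residual 1 -> 0.75
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n, n_sp = 400, 20
            x = rng.normal(0.0, np.sqrt(2.0), n)
            sp = rng.integers(0, n_sp, n)
            eff = rng.normal(0.0, 1.0, n_sp)
            data = pd.DataFrame({
                "x": x, "species": [f"s{i}" for i in sp],
                "y": x + eff[sp] + rng.normal(0.0, 1.0, n),
            })
            fit = fit_model(ModelSpec("y", ["x"], ["species"]), data)
            vals.append(fit.conditional_r2)
        assert np.mean(vals) == pytest.approx(0.75, abs=0.05)
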