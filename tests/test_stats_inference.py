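"""Mixed-model layer: oracle equivalences, post-hoc behaviour, correlations.

The REML/Satterthwaite engine is validated along two independent routes:
classical fixed-effects ANOVA in the zero-random-variance limit, and
statsmodels MixedLM (plus, where available at development time, R's
lmerTest) on random-intercept data.
"""

import subprocess

import numpy as np
import pandas as pd
import pytest

from soilncycle.mixed import VarCompModel
from soilncycle.stats_inference import (
    ModelSpec,
    TransformDomainError,
    compact_letters,
    fit_mixed_anova,
    inverse_transform,
    pearson_correlations,
    posthoc_contrasts,
    r2_from_variances,
    transform_response,
)
from soilncycle.synthetic_data import simulate_null_anova


class TestTransforms:
    def test_sqrt(self):
        assert transform_response([0, 1, 4, 9], "sqrt").tolist() == [0, 1, 2, 3]

    def test_none_is_identity(self):
        x = [3.2, -1.0, 0.0]
        assert transform_response(x, "none").tolist() == x

    def test_log_of_zero_names_the_row(self):
        with pytest.raises(TransformDomainError, match=r"rows \[1\]"):
            transform_response([1.0, 0.0, 2.0], "log")

    def test_sqrt_of_negative_names_the_row(self):
        with pytest.raises(TransformDomainError, match=r"rows \[2\]"):
            transform_response([1.0, 0.0, -2.0], "sqrt")

    @pytest.mark.parametrize("transform", ["none", "sqrt", "log"])
    def test_inverse_round_trip(self, transform):
        x = np.array([0.5, 1.0, 7.3])
        back = inverse_transform(transform_response(x, transform), transform)
        np.testing.assert_allclose(back, x, rtol=1e-12)


class TestVarianceExplained:
    def test_partition_formula(self):
        r2m, r2c = r2_from_variances(2.0, 1.0, 1.0)
        assert r2m == pytest.approx(0.5)
        assert r2c == pytest.approx(0.75)

    def test_marginal_below_conditional_on_fits(self):
        rng = np.random.default_rng(5)
        df = simulate_null_anova(n_blocks=4, rng=rng)
        df["y"] += np.where(df.season == "late", 1.0, 0.0)
        res = fit_mixed_anova(df, ModelSpec("y"))
        assert 0.0 <= res.r2_marginal <= res.r2_conditional <= 1.0


class TestClassicalAnovaLimit:
    def test_two_group_f_matches_classical(self):
        """With zero random variance the mixed F equals one-way ANOVA F."""
        y = np.array([1, 2, 3, 4, 5, 6], float)
        X = np.column_stack([np.ones(6), [1, 1, 1, -1, -1, -1]])
        # block pairing chosen so the block variance REML estimate is zero
        blocks = np.array([1, 2, 3, 3, 2, 1])
        fit = VarCompModel(y, X, {"block": blocks}).fit()
        F, q, df_den, _ = fit.f_test(np.array([[0.0, 1.0]]))
        assert fit.varcomps["block"] == 0.0
        assert F == pytest.approx(13.5, rel=1e-6)
        assert (q, df_den) == (1, pytest.approx(4.0, abs=1e-4))

    def test_constant_response_gives_zero_f(self):
        df = simulate_null_anova(n_blocks=3)
        df["y"] = 5.0
        res = fit_mixed_anova(df, ModelSpec("y"))
        for t in res.terms.values():
            assert t.F == pytest.approx(0.0, abs=1e-8)


class TestAgainstStatsmodels:
    def test_random_intercept_model_matches_mixedlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        nb, nper = 8, 6
        blocks = np.repeat(np.arange(nb), nper)
        x = rng.normal(size=nb * nper)
        X = np.column_stack([np.ones(nb * nper), x])
        y = (
            1.0
            + 0.5 * x
            + rng.normal(0, 0.7, size=nb)[blocks]
            + rng.normal(0, 1, size=nb * nper)
        )
        sm_fit = sm.MixedLM(y, X, groups=blocks).fit(reml=True)
        vc_fit = VarCompModel(y, X, {"block": blocks}).fit()
        np.testing.assert_allclose(vc_fit.beta, np.asarray(sm_fit.params)[:2], rtol=1e-4)
        assert vc_fit.varcomps["block"] == pytest.approx(
            float(np.asarray(sm_fit.cov_re).ravel()[0]), rel=1e-3
        )
        assert vc_fit.sigma2_resid == pytest.approx(float(sm_fit.scale), rel=1e-3)


class TestAgainstLmerTest:
    def test_nested_model_matches_lmertest(self, tmp_path):
        """Full nested design: F, Satterthwaite df and variance components."""
        rng = np.random.default_rng(123)
        df = simulate_null_anova(
            n_blocks=5,
            species=("s1", "s2", "s3", "s4", "s5", "s6"),
            block_sd=0.4,
            location_sd=0.8,
            rng=rng,
        )
        res = fit_mixed_anova(df, ModelSpec("y"))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        m <- lmer(y ~ season*species + (1|block) + (1|location_id), data=d, REML=TRUE)
        a <- anova(m, type=3)
        v <- as.data.frame(VarCorr(m))
        cat(a["season","F value"], a["season","DenDF"],
            a["species","F value"], a["species","DenDF"],
            v$vcov[v$grp=="block"], v$vcov[v$grp=="location_id"], v$vcov[v$grp=="Residual"], sep=",")
        """
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        f_sea, df_sea, f_sp, df_sp, vb, vl, ve = map(float, proc.stdout.split(","))
        assert res.terms["season"].F == pytest.approx(f_sea, rel=1e-4)
        assert res.terms["season"].df_den == pytest.approx(df_sea, rel=1e-3)
        assert res.terms["species"].F == pytest.approx(f_sp, rel=1e-4)
        assert res.terms["species"].df_den == pytest.approx(df_sp, rel=1e-3)
        assert res.varcomps["block"] == pytest.approx(vb, rel=1e-3, abs=1e-6)
        assert res.varcomps["location_id"] == pytest.approx(vl, rel=1e-3, abs=1e-6)
        assert res.sigma2_resid == pytest.approx(ve, rel=1e-3)


class TestPosthoc:
    def _fitted(self, shift=0.0, species=("s1", "s2", "s3"), seed=5):
        rng = np.random.default_rng(seed)
        df = simulate_null_anova(
            n_blocks=4, species=species, block_sd=0.3, location_sd=0.3, rng=rng
        )
        df.loc[df.species == species[-1], "y"] += shift
        return df, fit_mixed_anova(df, ModelSpec("y"))

    def test_two_level_factor_adjustment_is_identity(self):
        _, res = self._fitted()
        cs = posthoc_contrasts(res, "season")[0]
        row = cs.table.iloc[0]
        from scipy import stats as ss

        p_unadj = 2 * ss.t.sf(abs(row.t), row.df)
        assert row.p_adj == pytest.approx(p_unadj, rel=1e-6)

    def test_no_effect_single_letter_class(self):
        _, res = self._fitted(shift=0.0)
        cs = posthoc_contrasts(res, "species")[0]
        letters = {v for k, v in cs.letters.items()}
        assert letters == {"a"}

    def test_strong_outlier_group_gets_own_letter(self):
        species = ("s1", "s2", "s3", "s4", "s5", "s6")
        _, res = self._fitted(shift=50.0, species=species)
        cs = posthoc_contrasts(res, "species")[0]
        outlier = cs.letters[("all", "s6")]
        others = {cs.letters[("all", s)] for s in species[:-1]}
        assert outlier not in others
        assert len(others) == 1

    def test_adjusted_p_monotone_in_family_size(self):
        """The same t and df yields larger Tukey p with more means."""
        from scipy import stats as ss

        p3 = ss.studentized_range.sf(2.0 * np.sqrt(2), 3, 20)
        p6 = ss.studentized_range.sf(2.0 * np.sqrt(2), 6, 20)
        assert p6 > p3

    def test_interaction_conditioning_produces_strata(self):
        rng = np.random.default_rng(11)
        df = simulate_null_anova(n_blocks=4, rng=rng)
        # strong crossover interaction
        df.loc[(df.season == "late") & (df.species == "sp3"), "y"] += 8.0
        res = fit_mixed_anova(df, ModelSpec("y"))
        assert res.terms["season:species"].p < 0.05
        cs = posthoc_contrasts(res, "species", condition_on="interaction")[0]
        assert cs.conditioning == "within-season"
        assert set(cs.table.stratum) == {"early", "late"}

    def test_single_level_factor_error(self):
        _, res = self._fitted()
        with pytest.raises(ValueError):
            posthoc_contrasts(res, "treatment")


class TestCompactLetters:
    def test_no_significant_pairs_single_letter(self):
        out = compact_letters(["a", "b", "c"], set())
        assert set(out.values()) == {"a"}

    def test_chain_structure(self):
        # x ≠ z, but y indistinguishable from both
        out = compact_letters(["x", "y", "z"], {("x", "z")})
        assert set(out["y"]) == {"a", "b"}
        assert out["x"] != out["z"]

    def test_letters_respect_significance_partition(self):
        out = compact_letters(["g1", "g2", "g3"], {("g1", "g2"), ("g1", "g3")})
        assert set(out["g1"]).isdisjoint(set(out["g2"]))
        assert set(out["g1"]).isdisjoint(set(out["g3"]))
        assert set(out["g2"]) & set(out["g3"])


class TestPearson:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        out = pearson_correlations(df, [("x", "y")])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_negative_relation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [-1.0, -2, -3, -4]})
        out = pearson_correlations(df, [("x", "y")])
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(3)
        n = 4000
        df = pd.DataFrame({"x": rng.normal(size=n), "y": rng.normal(size=n)})
        out = pearson_correlations(df, [("x", "y")])
        assert abs(out.loc[0, "r"]) < 3 / np.sqrt(n)

    def test_zero_variance_error(self):
        df = pd.DataFrame({"x": [1.0, 1, 1], "y": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlations(df, [("x", "y")])

    def test_too_few_pairs_error(self):
        df = pd.DataFrame({"x": [1.0, 2], "y": [1.0, 2]})
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlations(df, [("x", "y")])
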