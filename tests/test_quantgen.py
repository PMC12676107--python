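"""Mixed models, heritability, plasticity and the comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from photoadapt.quantgen import (MixedFitResult, compact_letter_display,
                                 correlations, derive_traits, fit_mixed,
                                 heritability, plasticity,
                                 subpop_anova_tukey, treatment_compare)


def balanced_frame(n_geno=80, reps=3, sg=1.5, se=1.0, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sg, n_geno)
    y = (u[:, None] + rng.normal(0, se, (n_geno, reps))).ravel()
    return pd.DataFrame({
        "accession": np.repeat([f"a{i:03d}" for i in range(n_geno)], reps),
        "year": 2021,
        "replicate": np.tile(np.arange(1, reps + 1), n_geno),
        "block": 1, "column": 1, "dph": 0, "T": y,
    })


class TestDerivedTraits:
    def test_ratio_trait_arithmetic(self):
        rec = pd.DataFrame([{"Asat": 20.0, "gs": 0.4, "leaf_area": 30.0,
                             "leaf_mass": 0.1, "%C": 42.0, "%N": 3.0}])
        out = derive_traits(rec)
        assert out.loc[0, "iWUE"] == pytest.approx(50.0)
        assert out.loc[0, "SLA"] == pytest.approx(300.0)
        assert out.loc[0, "C:N"] == pytest.approx(14.0)

    def test_zero_denominator_leaves_trait_missing(self):
        rec = pd.DataFrame([{"Asat": 20.0, "gs": 0.0}])
        with pytest.warns(UserWarning):
            out = derive_traits(rec)
        assert np.isnan(out.loc[0, "iWUE"])


class TestMixedModel:
    def test_balanced_blups_equal_shrunken_means(self):
        df = balanced_frame()
        fit = fit_mixed(df, "T", model="year2021", genotype_as="random",
                        design_terms=False)
        s2g = fit.variance_components["genotype"]
        s2e = fit.variance_components["residual"]
        ybar = df.groupby("accession")["T"].mean()
        k = s2g / (s2g + s2e / 3)
        expect = k * (ybar - ybar.mean())
        assert np.allclose(fit.blups.reindex(ybar.index), expect, atol=1e-9)

    def test_balanced_blups_sum_to_zero(self):
        fit = fit_mixed(balanced_frame(), "T", model="year2021",
                        genotype_as="random", design_terms=False)
        assert abs(fit.blups.sum()) < 1e-6 * fit.blups.abs().max()

    def test_balanced_blues_equal_centered_means(self):
        df = balanced_frame()
        fit = fit_mixed(df, "T", model="year2021", genotype_as="fixed",
                        design_terms=False)
        ybar = df.groupby("accession")["T"].mean()
        assert np.allclose(fit.blues.reindex(ybar.index), ybar - ybar.mean(),
                           atol=1e-9)
        assert fit.population_mean == pytest.approx(ybar.mean())

    def test_null_genetic_variance_gives_near_zero_blups(self):
        df = balanced_frame(sg=0.0, seed=5)
        fit = fit_mixed(df, "T", model="year2021", genotype_as="random",
                        design_terms=False)
        assert fit.blups.abs().max() < 0.2
        h2 = heritability(fit)
        assert np.isnan(h2.h2_pm) or h2.h2_pm < 0.2

    def test_block_relabeling_leaves_estimates_invariant(self):
        rng = np.random.default_rng(3)
        df = balanced_frame(n_geno=40, reps=2, seed=3)
        df["block"] = rng.integers(1, 5, len(df))
        fit1 = fit_mixed(df, "T", model="year2021", genotype_as="random")
        relabel = {1: 4, 2: 3, 3: 1, 4: 2}
        df2 = df.assign(block=df["block"].map(relabel))
        fit2 = fit_mixed(df2, "T", model="year2021", genotype_as="random")
        assert np.allclose(fit1.blups, fit2.blups, atol=1e-6)
        assert fit1.sigma2_g == pytest.approx(fit2.sigma2_g, abs=1e-6)

    def test_joint_model_partitions_gxe(self):
        rng = np.random.default_rng(8)
        n = 60
        u = rng.normal(0, 1.0, n)
        gy = rng.normal(0, 1.0, (n, 2))  # strong G×E
        rows = []
        for yi, year in enumerate((2021, 2022)):
            for rep in (1, 2):
                for i in range(n):
                    rows.append({"accession": f"a{i:02d}", "year": year,
                                 "replicate": rep, "block": 1, "column": 1,
                                 "dph": 0,
                                 "T": u[i] + gy[i, yi] + rng.normal(0, 0.5)})
        df = pd.DataFrame(rows)
        fit = fit_mixed(df, "T", model="joint", genotype_as="random",
                        design_terms=False)
        vc = fit.variance_components
        assert vc["genotype:year"] > 0.3
        assert vc["genotype"] > 0.3

    def test_singular_fixed_design_names_aliased_terms(self):
        df = balanced_frame(n_geno=10, reps=2)
        df["dph"] = 1.0  # constant covariate aliased with the intercept
        df.loc[0, "dph"] = 1.0
        from photoadapt.mixedmodel import reml_fit, RandomTerm

        x = np.column_stack([np.ones(len(df)), np.ones(len(df))])
        with pytest.raises(ValueError, match="aliased"):
            reml_fit(df["T"].to_numpy(), x, [],
                     fixed_names=["intercept", "dup"])


class TestHeritability:
    def _fit(self, s2g, mean_pev):
        return MixedFitResult(trait="T", model="joint", genotype_as="random",
                              variance_components={}, blues=None, blups=None,
                              pev=None, sigma2_g=s2g, mean_pev=mean_pev,
                              population_mean=0.0, loglik=0.0, converged=True)

    def test_printed_formula_arithmetic(self):
        h = heritability(self._fit(2.0, 1.0))
        assert h.h2_pm == pytest.approx(0.5)
        assert h.h2_cullis == pytest.approx(0.75)

    def test_zero_pev_gives_unity(self):
        h = heritability(self._fit(3.0, 0.0))
        assert h.h2_pm == 1.0 and h.h2_cullis == 1.0

    def test_pev_exceeding_variance_reported_unclamped(self):
        h = heritability(self._fit(1.0, 1.5))
        assert h.h2_pm == pytest.approx(-0.5)
        assert h.out_of_range

    def test_zero_variance_reported_missing(self):
        h = heritability(self._fit(0.0, 1.0))
        assert np.isnan(h.h2_pm) and np.isnan(h.h2_cullis)


class TestPlasticity:
    def test_quoted_formula_value(self):
        res = plasticity(pd.Series({"a": 1.0}), pd.Series({"a": 2.0}),
                         {2021: 10.0, 2022: 8.0})
        assert res.values["a"] == pytest.approx((10 + 1) - (8 + 2))

    def test_identical_years_give_zero(self):
        b = pd.Series({"a": 0.3, "b": -0.1})
        res = plasticity(b, b, {2021: 5.0, 2022: 5.0})
        assert np.allclose(res.values, 0.0)

    def test_missing_year_skipped(self):
        res = plasticity(pd.Series({"a": 1.0, "b": 2.0}),
                         pd.Series({"a": 0.0}), {2021: 0.0, 2022: 0.0})
        assert res.skipped == ["b"]
        assert list(res.values.index) == ["a"]

    @settings(deadline=None, max_examples=20)
    @given(c=st.floats(-50, 50))
    def test_translation_equivariance(self, c):
        b1 = pd.Series({"a": 1.0, "b": -2.0})
        b2 = pd.Series({"a": 0.5, "b": 0.5})
        base = plasticity(b1, b2, {2021: 10.0, 2022: 8.0}).values
        shifted = plasticity(b1, b2 + c, {2021: 10.0, 2022: 8.0}).values
        assert np.allclose(shifted, base - c)


class TestCorrelations:
    def test_perfect_correlations(self, rng):
        x = rng.normal(0, 1, 30)
        r, p = correlations(pd.DataFrame({"x": x, "y": x, "z": -x}))
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)

    def test_p_matches_t_transform(self, rng):
        x, y = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
        r, p = correlations(pd.DataFrame({"x": x, "y": y}))
        rv = r.loc["x", "y"]
        t = rv * np.sqrt(23 / (1 - rv ** 2))
        assert p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(abs(t), 23))

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x, y = rng.normal(0, 1, (2, 20))
            r, p = correlations(pd.DataFrame({"x": x, "y": y}))
            rejections += p.loc["x", "y"] < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.01)

    def test_tiny_sample_reports_r_without_p(self, rng):
        df = pd.DataFrame({"x": [1.0, 2.0, 4.0], "y": [1.0, 3.0, 2.0]})
        r, p = correlations(df)
        assert np.isfinite(r.loc["x", "y"])
        assert np.isnan(p.loc["x", "y"])


class TestAnovaTukey:
    def test_two_group_tukey_equals_t_test(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        F, p, letters, pairs = subpop_anova_tukey(
            np.concatenate([a, b]), ["A"] * 12 + ["B"] * 15)
        t, pt = stats.ttest_ind(a, b)
        assert list(pairs.values())[0] == pytest.approx(pt, abs=1e-6)
        assert F == pytest.approx(t ** 2, abs=1e-9)

    def test_identical_groups_share_one_letter(self, rng):
        y = rng.normal(0, 1, 30)
        _, _, letters, _ = subpop_anova_tukey(
            np.tile(y, 3), ["A"] * 30 + ["B"] * 30 + ["C"] * 30)
        assert set(letters.values()) == {"a"}

    def test_strongly_shifted_group_gets_unique_letter(self, rng):
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                            rng.normal(10, 1, 10)])
        _, _, letters, _ = subpop_anova_tukey(y, ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        assert letters["C"] not in letters["A"] + letters["B"]

    def test_undersized_group_excluded_with_warning(self, rng):
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10), [5.0]])
        with pytest.warns(UserWarning, match="n<2"):
            _, _, letters, _ = subpop_anova_tukey(
                y, ["A"] * 10 + ["B"] * 10 + ["C"])
        assert "C" not in letters

    def test_compact_letter_display_chain(self):
        # A≠C but B indistinguishable from both → B shares letters
        sig = {("A", "B"): False, ("B", "C"): False, ("A", "C"): True}
        letters = compact_letter_display(["A", "B", "C"], sig)
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])


class TestTreatmentCompare:
    @staticmethod
    def _records(effect80=20.0, effect40=10.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for sp, accs in [("steppe", ["g1", "g2", "g3"]),
                         ("desert", ["g4", "g5", "g6"])]:
            for acc in accs:
                for tr, m in [("rswc80", effect80), ("rswc40", effect40)]:
                    for _ in range(5):
                        rows.append({"accession": acc, "subpop": sp,
                                     "treatment": tr,
                                     "leaf_area": rng.normal(m, 1.0)})
        return pd.DataFrame(rows)

    def test_percent_change_arithmetic(self):
        rec = self._records()
        rec["leaf_area"] = np.where(rec["treatment"] == "rswc80", 20.0, 10.0)
        res = treatment_compare(rec, "leaf_area")
        assert np.allclose(res["percent_change_subpop"], 50.0)
        rec["leaf_area"] = 20.0
        res = treatment_compare(rec, "leaf_area")
        assert np.allclose(res["percent_change_subpop"], 0.0)

    def test_anova_detects_treatment_effect(self):
        res = treatment_compare(self._records(), "leaf_area",
                                log_transform=True)
        assert res["anova"].loc["C(treatment)", "PR(>F)"] < 1e-6
        assert res["log_transformed"]

    def test_null_treatment_p_uniform(self):
        pvals = []
        for seed in range(40):
            rec = self._records(effect80=10.0, effect40=10.0, seed=seed)
            res = treatment_compare(rec, "leaf_area")
            pvals.append(res["anova"].loc["C(treatment)", "PR(>F)"])
        # under the null the treatment p-value is Uniform(0,1)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_incomplete_genotype_excluded(self):
        rec = self._records()
        rec = rec[~((rec["accession"] == "g1") & (rec["treatment"] == "rswc40"))]
        with pytest.warns(UserWarning, match="g1"):
            res = treatment_compare(rec, "leaf_area")
        assert res["anova"] is not None
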