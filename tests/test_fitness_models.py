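"""Tests for the trait-model battery: OLS, GLM, LMM, nonparametrics."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from loadfit import fitness_models as fm
from loadfit.datasets import LIFESPAN_MEANS, LRS_MEANS, PAIR_LITTER_MEANS


def records_from(x, y, col="mean_litter_size"):
    return pd.DataFrame({col: y, "x": x})


class TestBoxcox:
    def test_lognormal_sample_advises_log(self):
        rng = np.random.default_rng(123)
        advice = fm.boxcox_advise(np.exp(rng.normal(0, 1, 500)))
        assert abs(advice.lmbda) <= 0.15
        assert advice.transform == "log"

    def test_grid_optimum_matches_mle_oracle(self):
        rng = np.random.default_rng(9)
        for x in (np.exp(rng.normal(0, 1, 400)), rng.normal(5, 1, 400) ** 2):
            advice = fm.boxcox_advise(x)
            oracle = sps.boxcox_normmax(x, method="mle")
            assert advice.lmbda == pytest.approx(oracle, abs=0.011)

    def test_squared_draws_advise_sqrt(self):
        rng = np.random.default_rng(123)
        advice = fm.boxcox_advise(rng.normal(5, 1, 1000) ** 2)
        assert advice.transform == "sqrt"

    def test_constant_data_returns_identity_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            advice = fm.boxcox_advise([3.0] * 10)
        assert advice.transform == "identity"

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fm.boxcox_advise([1.0, 0.0, 2.0])


class TestTraitLm:
    def test_exact_fit(self):
        res = fm.fit_trait_lm(records_from([0, 1, 2, 3], [0, 1, 2, 3]),
                              "litter_size", "x", covariates=())
        assert res.term("x")["estimate"] == pytest.approx(1.0)
        assert res.term("intercept")["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_closed_form_three_points(self):
        # OLS on (0,1),(1,2),(2,2): slope 0.5, intercept 7/6
        res = fm.fit_trait_lm(records_from([0, 1, 2], [1, 2, 2]),
                              "litter_size", "x", covariates=())
        assert res.term("x")["estimate"] == pytest.approx(0.5)
        assert res.term("intercept")["estimate"] == pytest.approx(7 / 6)

    def test_zero_noise_recovery_to_1e8(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        sex = rng.choice(["M", "F"], 60)
        phase = rng.choice(["increase", "decrease"], 60)
        y = (2.0 - 3.0 * x + 0.7 * (sex == "M") + 0.2 * (phase == "increase"))
        df = pd.DataFrame({"mean_litter_size": y, "x": x, "sex": sex,
                           "rodent_phase": phase})
        res = fm.fit_trait_lm(df, "litter_size", "x")
        assert res.term("x")["estimate"] == pytest.approx(-3.0, abs=1e-8)
        assert res.term("sex_M")["estimate"] == pytest.approx(0.7, abs=1e-8)

    def test_transforms_and_guards(self):
        df = pd.DataFrame({"lrs": [0, 1, 4, 9], "x": [0, 1, 2, 3]})
        res = fm.fit_trait_lm(df, "lrs_sqrt", "x", covariates=())
        assert res.transform == "sqrt"
        assert res.term("x")["estimate"] == pytest.approx(1.0)
        bad = pd.DataFrame({"longevity_years": [0.0, 1, 2], "x": [1, 2, 3]})
        with pytest.raises(ValueError, match="positive"):
            fm.fit_trait_lm(bad, "longevity_log", "x", covariates=())

    def test_rank_deficient_design_reports_collinear_terms(self):
        df = pd.DataFrame({"mean_litter_size": [1.0, 2, 3, 4],
                           "x": [1.0, 2, 3, 4], "z": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="collinear"):
            fm.fit_trait_lm(df, "litter_size", "x", covariates=("z",))

    def test_pvalues_invariant_to_row_permutation(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "mean_litter_size": rng.normal(5, 1, 40),
            "x": rng.normal(size=40),
            "sex": rng.choice(["M", "F"], 40),
            "rodent_phase": rng.choice(["increase", "decrease"], 40),
        })
        a = fm.fit_trait_lm(df, "litter_size", "x")
        b = fm.fit_trait_lm(df.sample(frac=1.0, random_state=0), "litter_size", "x")
        np.testing.assert_allclose(a.pvalues, b.pvalues, atol=1e-12)


class TestSurvivalGlm:
    def test_two_group_closed_form(self):
        # survival 8/10 at x=0 and 2/10 at x=1: saturated logit
        x = [0] * 10 + [1] * 10
        y = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        df = pd.DataFrame({"juvenile_survival": y, "x": x})
        res = fm.fit_juvenile_survival_glm(df, "x", covariates=())
        assert res.term("intercept")["estimate"] == pytest.approx(np.log(4), abs=1e-6)
        assert res.term("x")["estimate"] == pytest.approx(np.log(0.25 / 4), abs=1e-6)

    def test_constant_response_rejected(self):
        df = pd.DataFrame({"juvenile_survival": [1, 1, 1], "x": [1, 2, 3]})
        with pytest.raises(ValueError, match="constant"):
            fm.fit_juvenile_survival_glm(df, "x", covariates=())

    def test_complete_separation_raises_advice(self):
        df = pd.DataFrame({"juvenile_survival": [0] * 10 + [1] * 10,
                           "x": list(range(10)) + list(range(20, 30))})
        with pytest.raises(fm.SeparationError, match="penalised"):
            fm.fit_juvenile_survival_glm(df, "x", covariates=())

    def test_score_vanishes_at_optimum(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=300)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        df = pd.DataFrame({"juvenile_survival": rng.binomial(1, p), "x": x})
        res = fm.fit_juvenile_survival_glm(df, "x", covariates=())
        import statsmodels.api as sm
        X = np.column_stack([np.ones(len(df)), x])
        model = sm.GLM(df["juvenile_survival"].to_numpy(), X,
                       family=sm.families.Binomial())
        grad = model.score(res.estimates)
        assert np.linalg.norm(grad) < 1e-6


class TestAncestryLmm:
    def test_reduces_to_ols_when_no_group_variance(self):
        rng = np.random.default_rng(2)
        n = 120
        grp = rng.choice(["native", "F1"], n)
        y = 3 + 0.8 * (grp == "F1") + rng.normal(0, 1, n)
        df = pd.DataFrame({"resp": y, "g": grp,
                           "den": np.tile([f"d{i}" for i in range(20)], 6),
                           "rodent_phase": rng.choice(["increase", "decrease"], n)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fm.fit_ancestry_lmm(df, "resp", "g", fixed=("rodent_phase",),
                                    random="den", reference="native")
        import statsmodels.api as sm
        X = pd.DataFrame({"i": 1.0, "f1": (grp == "F1").astype(float),
                          "ph": (df["rodent_phase"] == "increase").astype(float)})
        ols = sm.OLS(y, X).fit()
        assert m.term("g_F1")["estimate"] == pytest.approx(ols.params["f1"], abs=1e-6)

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(7)
        errs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(25):
                dens = np.repeat(np.arange(50), 4)
                u = rng.normal(0, 1.0, 50)[dens]
                grp = rng.choice(["A", "B"], 200)
                y = 3.0 + 0.5 * (grp == "B") + u + rng.normal(0, 1.0, 200)
                df = pd.DataFrame({"resp": y, "g": grp,
                                   "den": [f"d{d}" for d in dens],
                                   "rodent_phase": rng.choice(
                                       ["increase", "decrease"], 200)})
                m = fm.fit_ancestry_lmm(df, "resp", "g", fixed=("rodent_phase",),
                                        random="den")
                errs.append(abs(m.extra["random_effect_variance"] - 1.0))
        assert np.mean(errs) < 0.3

    def test_f1_litter_boost_detected(self):
        rng = np.random.default_rng(3)
        combos = ["native_x_native", "native_x_immigrant",
                  "native_x_immigrantF1F4", "immigrantF1F4_x_immigrantF1F4"]
        rows = []
        for i in range(160):
            c = combos[i % 4]
            boost = 4.0 if c == "native_x_immigrant" else 0.0
            rows.append({"litter_size": rng.poisson(6) + boost,
                         "pair_combination": c,
                         "den": f"d{rng.integers(20)}",
                         "rodent_phase": str(rng.choice(["increase", "decrease"]))})
        df = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fm.fit_ancestry_lmm(df, "litter_size", "pair_combination",
                                    fixed=("rodent_phase",), random="den",
                                    reference="native_x_native")
        assert m.term("pair_combination_native_x_immigrant")["estimate"] > 0
        assert m.term("pair_combination_native_x_immigrant")["p"] < 0.05


class TestMannWhitney:
    def test_enumerated_extreme_case(self):
        res = fm.mann_whitney_groups([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.pvalue == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_groups(self):
        res = fm.mann_whitney_groups([1, 5, 9, 13], [1, 5, 9, 13])
        assert res.pvalue == pytest.approx(1.0)
        assert res.shift == 0.0

    def test_u_complement_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(size=rng.integers(3, 12))
            ua = fm.mann_whitney_groups(a, b).u
            ub = fm.mann_whitney_groups(b, a).u
            assert ua + ub == len(a) * len(b)

    def test_shift_ci_covers_true_location_difference(self):
        rng = np.random.default_rng(8)
        cover = 0
        for _ in range(200):
            a = rng.normal(0, 1, 25)
            b = rng.normal(1.0, 1, 25)
            r = fm.mann_whitney_groups(a, b)
            cover += r.ci[0] <= 1.0 <= r.ci[1]
        assert 0.90 <= cover / 200 <= 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fm.mann_whitney_groups([], [1.0])


class TestCorrelate:
    def test_perfect_anticorrelation(self):
        res = fm.correlate([1, 2, 3, 4], [-1, -2, -3, -4])
        assert res.r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        res = fm.correlate([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(0.9819805, abs=1e-7)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fm.correlate([1, 1, 1], [1, 2, 3])

    def test_fisher_ci_brackets_r(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = fm.correlate(x, y)
        assert res.ci[0] < res.r < res.ci[1]


class TestGroupContrasts:
    def test_published_ancestry_contrasts(self):
        assert fm.contrast(LRS_MEANS, "F1", "F2+F3") == 5.25
        assert fm.contrast(LIFESPAN_MEANS, "F1", "F2+F3") == 1.6
        assert fm.contrast(PAIR_LITTER_MEANS, "native_x_native",
                           "native_x_immigrantF1F4") == 1.16

    def test_identical_means_give_zero(self):
        assert fm.contrast({"a": 2.5, "b": 2.5}, "a", "b") == 0.0

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            fm.contrast(LRS_MEANS, "nope", "F1")

    def test_all_pairwise(self):
        out = fm.group_mean_contrast({"a": 1.0, "b": 3.0})
        assert out[("b", "a")] == 2.0 and out[("a", "b")] == -2.0
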