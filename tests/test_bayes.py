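import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import gammaln

from glymphdti.bayes import (
    BayesConfig,
    Predictor,
    bf_m,
    design_matrix,
    enumerate_models,
    inclusion_bf,
    model_bf10,
    posterior_model_probs,
    run_bayes_ancova,
    validate_cohort_table,
)
from glymphdti.bayes import _r_squared
from glymphdti.synth import CohortSpec, simulate_cohort

PREDICTORS = [("age", "continuous"), ("EDSS", "continuous"), ("group", "factor")]


def dense_grid_bf_oracle(n, k, r2, r_eff2, n_points=10**6):
    """Independent Bayes-factor oracle: trapezoid rule on a dense log-g grid."""
    u = np.linspace(-40.0, 40.0, n_points)
    g = np.exp(u)
    b = 0.5 * n * r_eff2
    a = 0.5
    logd = (
        a * np.log(b)
        - gammaln(a)
        - (a + 1) * u
        - b / g
        + 0.5 * (n - 1 - k) * np.log1p(g)
        - 0.5 * (n - 1) * np.log1p(g * (1 - r2))
        + u
    )
    mx = logd.max()
    return math.exp(mx) * np.trapezoid(np.exp(logd - mx), u)


def jzs_two_sample_bf_oracle(table, dv, r=0.5):
    """Two-sample JZS Bayes factor via the t-statistic form of the same prior.

    Independent route: integrates over the per-observation g-scale
    (g_tilde = g / N_eff) instead of the design-scaled g, using the
    t-distribution representation of the marginal likelihoods.
    """
    g = table["group"].to_numpy()
    y = table[dv].to_numpy()
    lv = sorted(pd.unique(g))
    y1, y2 = y[g == lv[0]], y[g == lv[1]]
    n1, n2 = len(y1), len(y2)
    n, nu = n1 + n2, n1 + n2 - 2
    sp2 = ((n1 - 1) * y1.var(ddof=1) + (n2 - 1) * y2.var(ddof=1)) / nu
    t = (y2.mean() - y1.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    n_eff = n1 * n2 / n
    b = 0.5 * r**2 * n / n_eff

    def integrand(gt):
        return (
            (1 + n_eff * gt) ** -0.5
            * (1 + t * t / ((1 + n_eff * gt) * nu)) ** (-(nu + 1) / 2)
            * math.sqrt(b) / math.gamma(0.5) * gt**-1.5 * math.exp(-b / gt)
        )

    num, _ = integrate.quad(integrand, 0, np.inf, limit=400)
    return num / (1 + t * t / nu) ** (-(nu + 1) / 2)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortSpec(seed=3))


class TestEnumerateModels:
    def test_three_predictors_give_eight_uniform_models(self):
        space = enumerate_models(PREDICTORS)
        assert len(space.models) == 8
        assert np.allclose(space.priors, 0.125)
        assert () in space.models  # the null

    def test_single_predictor(self):
        space = enumerate_models([("group", "factor")])
        assert len(space.models) == 2
        assert np.allclose(space.priors, 0.5)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_models([("age", "continuous"), ("age", "factor")])


class TestDesignMatrix:
    def test_null_model_has_no_columns(self, cohort):
        space = enumerate_models(PREDICTORS)
        X, y = design_matrix(cohort, (), space.predictors, "FW")
        assert X.shape == (len(cohort), 0)
        assert len(y) == len(cohort)

    def test_covariates_standardised(self, cohort):
        space = enumerate_models(PREDICTORS)
        X, _ = design_matrix(cohort, ("age", "EDSS"), space.predictors, "FW")
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_balanced_factor_column_sums_to_zero(self):
        tab = pd.DataFrame({"group": ["MS"] * 4 + ["NMOSD"] * 4, "FW": np.arange(8.0)})
        X, _ = design_matrix(tab, ("group",), (Predictor("group", "factor"),), "FW")
        assert abs(X.sum()) < 1e-12
        assert set(np.round(np.unique(X), 6)) == {-0.5, 0.5}

    def test_zero_variance_covariate_rejected(self):
        tab = pd.DataFrame({"age": np.ones(10), "FW": np.arange(10.0)})
        with pytest.raises(ValueError, match="zero variance"):
            design_matrix(tab, ("age",), (Predictor("age", "continuous"),), "FW")


class TestModelBF10:
    def test_null_model_is_exactly_one(self, cohort):
        space = enumerate_models(PREDICTORS)
        assert model_bf10(cohort, (), space.predictors, "FW") == 1.0

    @pytest.mark.parametrize("dv", ["FW", "ALPS"])
    def test_every_model_matches_dense_grid_oracle(self, cohort, dv):
        space = enumerate_models(PREDICTORS)
        cfg = BayesConfig()
        kinds = {p.name: p.kind for p in space.predictors}
        for model in space.models:
            if not model:
                continue
            bf = model_bf10(cohort, model, space.predictors, dv, cfg)
            X, y = design_matrix(cohort, model, space.predictors, dv)
            r_eff2 = float(
                np.mean(
                    [
                        (cfg.r_factor if kinds[m] == "factor" else cfg.r_continuous) ** 2
                        for m in model
                    ]
                )
            )
            oracle = dense_grid_bf_oracle(len(y), X.shape[1], _r_squared(X, y), r_eff2)
            assert bf == pytest.approx(oracle, rel=1e-6)

    def test_group_only_matches_two_sample_oracle(self, cohort):
        space = enumerate_models(PREDICTORS)
        bf = model_bf10(cohort, ("group",), space.predictors, "FW")
        oracle = jzs_two_sample_bf_oracle(cohort, "FW")
        assert bf == pytest.approx(oracle, rel=1e-6)

    def test_independent_dv_rarely_beats_null(self):
        # dv unrelated to all predictors: BF10 < 1 for most seeds
        space = enumerate_models(PREDICTORS)
        wins = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)  # independent of the cohort stream
            tab = simulate_cohort(CohortSpec(seed=seed))
            tab = tab.assign(FW=rng.standard_normal(len(tab)))
            bfs = [
                model_bf10(tab, m, space.predictors, "FW") for m in space.models if m
            ]
            wins += all(bf < 1 for bf in bfs)
        assert wins > n_seeds / 2

    def test_saturated_fit_rejected(self):
        tab = pd.DataFrame(
            {"age": [1.0, 2, 3, 4, 5, 6, 7], "FW": [1.0, 2, 3, 4, 5, 6, 7]}
        )
        with pytest.raises(ValueError, match="saturated"):
            model_bf10(tab, ("age",), (Predictor("age", "continuous"),), "FW")

    def test_too_few_rows_rejected(self):
        tab = pd.DataFrame({"age": [1.0, 2, 3], "FW": [0.1, 0.4, 0.2]})
        with pytest.raises(ValueError, match="too small"):
            model_bf10(tab, ("age",), (Predictor("age", "continuous"),), "FW")


class TestModelAveraging:
    def test_equal_bfs_leave_priors_unchanged(self):
        space = enumerate_models(PREDICTORS)
        post = posterior_model_probs(space, np.full(8, 2.5))
        assert np.allclose(post, space.priors, atol=1e-14)

    def test_two_model_arithmetic(self):
        space = enumerate_models([("group", "factor")])
        post = posterior_model_probs(space, np.array([1.0, 3.0]))
        assert post == pytest.approx([0.25, 0.75], abs=1e-12)

    def test_posteriors_sum_to_one_even_for_huge_bfs(self):
        space = enumerate_models(PREDICTORS)
        bfs = np.exp(np.array([0, 650.0, -650.0, 10, 5, 300, 200, 100]))
        post = posterior_model_probs(space, bfs)
        assert post.sum() == pytest.approx(1.0, abs=1e-10)

    def test_bf_m_identity_and_reference_value(self):
        assert bf_m(0.3, 0.3) == pytest.approx(1.0)
        # prior 1/8 and posterior 0.46: the change-of-odds factor ~ 5.963
        assert bf_m(0.125, 0.46) == pytest.approx(5.96296296, rel=1e-8)
        assert bf_m(0.125, 0.50) > bf_m(0.125, 0.46)  # monotone in posterior

    def test_bf_m_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bf_m(0.125, 1.0)


class TestInclusionBF:
    def test_uniform_posteriors_give_unit_inclusion(self):
        space = enumerate_models(PREDICTORS)
        for name in ("age", "EDSS", "group"):
            assert inclusion_bf(space, space.priors.copy(), name) == pytest.approx(1.0)

    def test_single_predictor_space_reduces_to_bf10(self, cohort):
        space = enumerate_models([("group", "factor")])
        bf = model_bf10(cohort, ("group",), space.predictors, "FW")
        post = posterior_model_probs(space, np.array([1.0, bf]))
        for variant in ("all", "matched"):
            assert inclusion_bf(space, post, "group", variant) == pytest.approx(bf, rel=1e-12)

    def test_variants_coincide_on_additive_space(self, cohort):
        res = run_bayes_ancova(cohort, "FW")
        for name, d in res.inclusion.items():
            assert d["all"] == pytest.approx(d["matched"], rel=1e-12)

    def test_unknown_predictor_rejected(self):
        space = enumerate_models(PREDICTORS)
        with pytest.raises(ValueError, match="unknown predictor"):
            inclusion_bf(space, space.priors.copy(), "sex")


class TestRunBayesAncova:
    def test_row_order_invariance(self, cohort):
        res1 = run_bayes_ancova(cohort, "ALPS")
        shuffled = cohort.sample(frac=1.0, random_state=99).reset_index(drop=True)
        res2 = run_bayes_ancova(shuffled, "ALPS")
        assert np.allclose(res1.bf10, res2.bf10, rtol=1e-12)
        assert np.allclose(res1.posteriors, res2.posteriors, rtol=1e-12)

    def test_large_group_effect_detected(self):
        spec = CohortSpec(seed=17)
        spec.alps_model.delta = 3 * spec.alps_model.sd
        tab = simulate_cohort(spec)
        res = run_bayes_ancova(tab, "ALPS")
        assert res.inclusion["group"]["all"] > 3.0

    def test_group_effect_monotone_in_inclusion_bf(self):
        medians = []
        for delta_sd in (0.0, 1.0, 3.0):
            vals = []
            for seed in range(15):
                spec = CohortSpec(seed=seed)
                spec.fw_model.delta = delta_sd * spec.fw_model.sd
                vals.append(
                    run_bayes_ancova(simulate_cohort(spec), "FW").inclusion["group"]["all"]
                )
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]

    def test_missing_rows_dropped_with_count(self, cohort):
        tab = cohort.copy()
        tab.loc[0, "FW"] = np.nan
        tab.loc[5, "age"] = np.nan
        res = run_bayes_ancova(tab, "FW")
        assert res.n_dropped == 2
        assert res.n == len(cohort) - 2

    def test_single_level_factor_rejected(self, cohort):
        tab = cohort.copy()
        tab["group"] = "MS"
        with pytest.raises(ValueError, match="2 levels"):
            validate_cohort_table(tab, ["age", "EDSS", "group", "FW"], "group")
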