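import warnings

import numpy as np
import pytest
from scipy import stats

from prevpool.core import expit, logit, weighted_prevalence
from prevpool.imputation import (
    ImputationConfig,
    assign_strata,
    bayes_logistic_fit,
    cv_auc_misclassification,
    fit_inclusion_ehr,
    fit_inclusion_survey,
    rubin_combine,
    run_imputation,
)
from prevpool.simulator import (
    GenerativeParams,
    attach_poststrat_weights,
    draw_population,
    sample_sources,
)


class TestBayesLogisticFit:
    def test_intercept_only_concentrates_at_mle(self):
        rng = np.random.default_rng(0)
        y = (rng.random(10_000) < 0.3).astype(float)
        fit = bayes_logistic_fit(np.empty((10_000, 0)), y)
        assert fit.mode[0] == pytest.approx(logit(y.mean()), abs=0.05)

    def test_complete_separation_stays_finite(self):
        x = np.linspace(-2, 2, 200)[:, None]
        y = (x[:, 0] > 0).astype(float)
        fit = bayes_logistic_fit(x, y, prior_scale=2.5)
        assert np.all(np.abs(fit.mode) < 50)

    def test_slope_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20_000)[:, None]
        y = (rng.random(20_000) < expit(0.2 + 1.0 * x[:, 0])).astype(float)
        fit = bayes_logistic_fit(x, y)
        se = np.sqrt(fit.cov[1, 1])
        assert abs(fit.mode[1] - 1.0) < 3 * se

    def test_draw_reproducible_and_centred(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)[:, None]
        y = (rng.random(500) < expit(x[:, 0])).astype(float)
        d1 = bayes_logistic_fit(x, y, rng=np.random.default_rng(7)).draw
        d2 = bayes_logistic_fit(x, y, rng=np.random.default_rng(7)).draw
        np.testing.assert_array_equal(d1, d2)
        draws = np.array([bayes_logistic_fit(x, y, rng=np.random.default_rng(s)).draw
                          for s in range(200)])
        fit = bayes_logistic_fit(x, y)
        # draws follow the normal approximation at the mode
        assert np.allclose(draws.mean(axis=0), fit.mode, atol=0.05)

    def test_shape_errors(self):
        with pytest.raises(ValueError, match="rows"):
            bayes_logistic_fit(np.ones((3, 1)), np.ones(4))


def _linear_logit_membership_table(n=50_000, seed=5):
    """All subjects in the EHR; survey membership follows an exactly linear
    logit in the design factors, so the membership model is well-specified."""
    import pandas as pd
    rng = np.random.default_rng(seed)
    u1 = rng.integers(0, 2, n).astype(float)
    u2 = rng.standard_normal(n)
    x1 = rng.integers(0, 2, n).astype(float)
    pi1 = expit(-4.0 + 1.0 * u1 + 1.0 * u2 + 0.187 * x1)
    surv = rng.random(n) < pi1
    df = pd.DataFrame({
        "id": np.arange(n),
        "x1": x1, "x2": rng.standard_normal(n),
        "u1": u1, "u2": u2,
        "y1": np.where(surv, (rng.random(n) < 0.3).astype(float), np.nan),
        "y2": (rng.random(n) < 0.3).astype(float),
        "pi1": np.where(surv, pi1, np.nan),
        "pi2": np.nan,
        "in_survey": surv.astype(int), "in_ehr": 1,
        "linked": surv.astype(int),
        "w1": np.where(surv, 1.0 / pi1, np.nan), "w2": 1.0,
    })
    from prevpool.core import SubjectTable
    return SubjectTable(df)


class TestInclusionModels:
    def test_survey_inclusion_recovery(self):
        t = _linear_logit_membership_table()
        coef, pi1 = fit_inclusion_survey(t, ImputationConfig())
        np.testing.assert_allclose(coef, [-4.0, 1.0, 1.0, 0.187], atol=0.25)
        # known design values survive on survey subjects
        surv = t.in_survey
        np.testing.assert_array_equal(pi1[surv],
                                      t.df.loc[surv, "pi1"].to_numpy())
        assert np.all((pi1 > 0) & (pi1 < 1))

    def test_survey_inclusion_needs_known_pi1(self, small_table):
        df = small_table.df.copy()
        df["pi1"] = np.nan
        from prevpool.core import SubjectTable
        with pytest.raises(ValueError, match="pi1"):
            fit_inclusion_survey(SubjectTable(df), ImputationConfig())

    def test_ehr_inclusion_tracks_true_inclusion(self):
        """Predicted EHR-inclusion probabilities rank subjects like the true
        size measure of the EHR selection (Spearman > 0.5)."""
        params = GenerativeParams(N=50_000, n1=1000, n2=20_000, overlap=0.5,
                                  target_p1=0.3, target_p2=0.32,
                                  seed=5).calibrated()
        rng = np.random.default_rng(5)
        pop = draw_population(params, rng)
        t = attach_poststrat_weights(sample_sources(pop, params, rng), pop)
        coef, pi2 = fit_inclusion_ehr(t, ImputationConfig())
        assert pi2.shape == (len(t),)
        df = t.df
        truth = expit(1.0 + df["u1"] + df["u2"] + 0.187 * df["x1"])
        rho = stats.spearmanr(pi2, truth).statistic
        assert rho > 0.5

    def test_ehr_inclusion_requires_variation(self, medium_table):
        # full overlap: every survey subject is linked
        with pytest.raises(ValueError, match="no variation"):
            fit_inclusion_ehr(medium_table, ImputationConfig())


class TestAssignStrata:
    def test_equally_spaced(self):
        np.testing.assert_array_equal(
            assign_strata(np.linspace(0.1, 0.8, 8)), [1, 1, 2, 2, 3, 3, 4, 4])

    def test_all_equal_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = assign_strata(np.full(20, 0.5))
        assert set(labels) == {1}

    def test_uniform_quartiles(self):
        rng = np.random.default_rng(4)
        labels = assign_strata(rng.random(10_000))
        np.testing.assert_array_equal(np.bincount(labels)[1:], [2500] * 4)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="8"):
            assign_strata(np.linspace(0.1, 0.5, 5))


def _oracle_rubin(phi_m, s_m, nu_com, level=0.95):
    """Textbook combining rules, coded independently of the implementation."""
    phi_m = list(map(float, phi_m))
    M = len(phi_m)
    qbar = sum(phi_m) / M
    W = sum(s**2 for s in s_m) / M
    B = sum((q - qbar) ** 2 for q in phi_m) / (M - 1)
    T = W + (1 + 1 / M) * B
    lam = (1 + 1 / M) * B / T
    if lam == 0:
        df = ((nu_com + 1) / (nu_com + 3)) * nu_com
    else:
        nu_old = (M - 1) / lam**2
        nu_obs = ((nu_com + 1) / (nu_com + 3)) * nu_com * (1 - lam)
        df = nu_old * nu_obs / (nu_old + nu_obs)
    half = stats.t.ppf(0.5 + level / 2, df) * np.sqrt(T)
    return np.sqrt(T), df, (qbar - half, qbar + half)


class TestRubinCombine:
    def test_two_imputation_arithmetic(self):
        se, df, _ = rubin_combine([0.0, 1.0], [1.0, 1.0], nu_com=100)
        assert se == pytest.approx(np.sqrt(1.75), abs=1e-12)

    def test_no_between_variance(self):
        se, df, ci = rubin_combine([0.5] * 5, [0.2] * 5, nu_com=50)
        assert se == pytest.approx(0.2, abs=1e-12)
        # lambda = 0: df equals the observed-data degrees of freedom
        assert df == pytest.approx((51 / 53) * 50, abs=1e-9)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            M = int(rng.integers(2, 40))
            phi = rng.normal(0, 1, M)
            s = rng.random(M) + 0.05
            nu = float(rng.integers(5, 5000))
            got = rubin_combine(phi, s, nu)
            want = _oracle_rubin(phi, s, nu)
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1] == pytest.approx(want[1], abs=1e-10)
            assert got[2] == pytest.approx(want[2], abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="M >= 2"):
            rubin_combine([0.1], [0.1], nu_com=10)
        with pytest.raises(ValueError, match="variance"):
            rubin_combine([0.5, 0.5], [0.0, 0.0], nu_com=10)


class TestRunImputation:
    def test_no_missingness_returns_observed_prevalence(self, small_table):
        """When every subject carries both outcomes there is nothing to impute
        and the estimate equals the weighted observed prevalence exactly."""
        df = small_table.df.copy()
        surv = df["in_survey"] == 1
        df = df[surv].copy()
        df["in_ehr"] = 1
        df["linked"] = 1
        df["y2"] = df["y1"].to_numpy()[::-1]  # any observed values
        df["w2"] = 1.0
        from prevpool.core import SubjectTable
        t = SubjectTable(df)
        res = run_imputation(t, ImputationConfig(M=4, B=2, seed=9))
        expected = weighted_prevalence(df["y1"], df["w2"])
        assert res.P_R == pytest.approx(expected, abs=1e-15)
        assert all(p == res.p_m[0] for p in res.p_m)

    def test_bit_reproducible(self, medium_table):
        cfg = ImputationConfig(M=3, B=3, seed=123)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = run_imputation(medium_table, cfg)
            r2 = run_imputation(medium_table, cfg)
        assert r1.p_m == r2.p_m
        assert r1.s_m == r2.s_m
        assert r1.se_phi == r2.se_phi

    def test_concordance_limit(self):
        """With near-perfect agreement between the two outcomes, the imputed
        gold-standard prevalence tracks the record-based prevalence."""
        params = GenerativeParams(N=50_000, n1=400, n2=5000, overlap=0.5,
                                  target_p1=0.30, target_p2=0.30, phi=12.0,
                                  seed=21).calibrated()
        rng = np.random.default_rng(21)
        pop = draw_population(params, rng)
        t = attach_poststrat_weights(sample_sources(pop, params, rng), pop)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_imputation(t, ImputationConfig(M=4, B=4, seed=3))
        df = t.df
        p2 = weighted_prevalence(df.loc[t.in_ehr, "y2"],
                                 df.loc[t.in_ehr, "w2"])
        assert res.P_R == pytest.approx(p2, abs=0.02)

    def test_empty_linked_set_errors(self, small_table):
        df = small_table.df.copy()
        keep = (df["in_survey"] == 1) ^ (df["in_ehr"] == 1)
        df = df[keep].copy()
        df["linked"] = 0
        from prevpool.core import SubjectTable
        with pytest.raises(ValueError, match="S_c"):
            run_imputation(SubjectTable(df), ImputationConfig(M=2, B=1))

    def test_se_dominates_within_variance(self, medium_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_imputation(medium_table, ImputationConfig(M=4, B=3, seed=5))
        assert res.se_phi >= np.sqrt(res.W)
        assert res.P_R == pytest.approx(np.mean(res.p_m), abs=1e-15)


class TestCvAuc:
    def test_independent_outcome_gives_null_auc(self):
        rng = np.random.default_rng(8)
        n = 2000
        from prevpool.core import SubjectTable
        import pandas as pd
        df = pd.DataFrame({
            "id": np.arange(n),
            "x1": rng.integers(0, 2, n).astype(float),
            "x2": rng.standard_normal(n),
            "u1": rng.integers(0, 2, n).astype(float),
            "u2": rng.standard_normal(n),
            "y1": (rng.random(n) < 0.4).astype(float),
            "y2": (rng.random(n) < 0.4).astype(float),
            "pi1": np.full(n, 0.1),
            "pi2": np.nan,
            "in_survey": 1, "in_ehr": 1, "linked": 1,
            "w1": 1.0, "w2": 1.0,
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aucs = cv_auc_misclassification(SubjectTable(df),
                                            ImputationConfig(seed=1), folds=5)
        for auc in aucs.values():
            assert auc == pytest.approx(0.5, abs=0.05)

    def test_deterministic_outcome_gives_perfect_auc(self):
        rng = np.random.default_rng(9)
        n = 500
        from prevpool.core import SubjectTable
        import pandas as pd
        y = (rng.random(n) < 0.4).astype(float)
        df = pd.DataFrame({
            "id": np.arange(n),
            "x1": rng.integers(0, 2, n).astype(float),
            "x2": rng.standard_normal(n),
            "u1": rng.integers(0, 2, n).astype(float),
            "u2": rng.standard_normal(n),
            "y1": y, "y2": y,
            "pi1": np.full(n, 0.1),
            "pi2": np.nan,
            "in_survey": 1, "in_ehr": 1, "linked": 1,
            "w1": 1.0, "w2": 1.0,
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aucs = cv_auc_misclassification(SubjectTable(df),
                                            ImputationConfig(seed=1), folds=5)
        for auc in aucs.values():
            assert auc > 0.99

    def test_simulated_misclassification_between(self, small_table):
        aucs = cv_auc_misclassification(small_table,
                                        ImputationConfig(seed=2), folds=4)
        again = cv_auc_misclassification(small_table,
                                         ImputationConfig(seed=2), folds=4)
        assert aucs == again  # reproducible under a fixed seed
        finite = [a for a in aucs.values() if np.isfinite(a)]
        assert finite and all(0.5 < a < 1.0 for a in finite)
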