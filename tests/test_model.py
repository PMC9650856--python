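"""Design construction, conditional-logistic fitting, AICc selection."""
import numpy as np
import pandas as pd
import pytest

from stepsel import model as mod
from stepsel.errors import (ConfigurationError, DataError,
                            DegenerateDataError, SeparationError)


class TestStandardize:
    def test_closed_form_small_column(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        out, moments = mod.standardize(df, ["v"])
        np.testing.assert_allclose(out["v"], [-1.0, 0.0, 1.0])  # sample SD = 1
        assert moments["v"] == (2.0, 1.0)

    def test_idempotent_up_to_tolerance(self, rng):
        df = pd.DataFrame({"v": rng.normal(5, 3, 200)})
        once, _ = mod.standardize(df, ["v"])
        twice, _ = mod.standardize(once, ["v"])
        np.testing.assert_allclose(once["v"], twice["v"], atol=1e-12)

    def test_random_column_has_unit_moments(self, rng):
        df = pd.DataFrame({"v": rng.exponential(2, 500)})
        out, _ = mod.standardize(df, ["v"])
        assert out["v"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["v"].std(ddof=1) == pytest.approx(1.0)

    def test_zero_variance_names_column(self):
        with pytest.raises(DegenerateDataError, match="flatcol"):
            mod.standardize(pd.DataFrame({"flatcol": [1.0, 1.0]}), ["flatcol"])


class TestModelColumns:
    def test_dry_m1_manifest(self):
        assert mod.model_columns("dry", "M1") == [
            "sl", "log_sl", "aNDVI", "dNDVI", "elevation", "TRI", "temperature",
            "aNDVI^2", "dNDVI^2", "temperature^2",
        ]

    def test_wet_omits_temperature_terms(self):
        wet4 = mod.model_columns("wet", "M4")
        assert "temperature" in wet4
        assert "temperature^2" not in wet4
        assert "temperature:experience" not in wet4
        assert "temperature:group_size" not in wet4

    @pytest.mark.parametrize("period", ["dry", "wet"])
    def test_m4_is_union_of_m2_and_m3(self, period):
        m2 = set(mod.model_columns(period, "M2"))
        m3 = set(mod.model_columns(period, "M3"))
        m4 = set(mod.model_columns(period, "M4"))
        assert m4 == m2 | m3
        m1 = set(mod.model_columns(period, "M1"))
        assert m1 <= m2 and m1 <= m3

    def test_unknown_period_or_tier(self):
        with pytest.raises(ConfigurationError):
            mod.model_columns("monsoon", "M1")
        with pytest.raises(ConfigurationError):
            mod.model_columns("dry", "M9")


def synthetic_strata(rng, n_strata=40, m=10, n_animals=4):
    """Raw strata with environmental covariates and moderators."""
    rows = []
    for s in range(n_strata):
        animal = f"a{s % n_animals}"
        exp = float(s // n_animals)
        gs = float(1 + (s + 1) % 3)
        for j in range(m):
            rows.append({
                "stratum_id": s, "case": int(j == 0), "animal_id": animal,
                "period": "dry",
                "sl": rng.gamma(2, 300), "log_sl": 0.0,
                "aNDVI": rng.normal(), "dNDVI": rng.normal(),
                "elevation": rng.normal(300, 40), "TRI": rng.gamma(2, 1),
                "temperature": rng.normal(30, 4),
                "experience": exp, "group_size": gs,
            })
    df = pd.DataFrame(rows)
    df["log_sl"] = np.log(df["sl"])
    return df


class TestBuildDesign:
    def test_interaction_is_product_of_standardized_parents(self, rng):
        df = synthetic_strata(rng)
        d = mod.build_design(df, "dry", "M2")
        std, _ = mod.standardize(df, ["aNDVI", "experience"])
        j = d.columns.index("aNDVI:experience")
        np.testing.assert_allclose(
            d.X[:, j], std["aNDVI"].to_numpy() * std["experience"].to_numpy())

    def test_quadratic_is_square_of_standardized_base(self, rng):
        df = synthetic_strata(rng)
        d = mod.build_design(df, "dry", "M1")
        std, _ = mod.standardize(df, ["dNDVI"])
        j = d.columns.index("dNDVI^2")
        np.testing.assert_allclose(d.X[:, j], std["dNDVI"].to_numpy() ** 2)

    def test_stratum_constant_column_rejected(self, rng):
        df = synthetic_strata(rng)
        with pytest.raises(ConfigurationError, match="experience"):
            mod.build_design(df, "dry", columns=["aNDVI", "experience"])

    def test_keep_inestimable_appends_moderator_mains_with_warning(self, rng):
        df = synthetic_strata(rng)
        with pytest.warns(UserWarning, match="not\\s+identifiable"):
            d = mod.build_design(df, "dry", "M2", keep_inestimable=True)
        assert d.columns[-1] == "experience"

    def test_multiple_cases_rejected(self, rng):
        df = synthetic_strata(rng)
        df.loc[1, "case"] = 1
        with pytest.raises(DataError):
            mod.build_design(df, "dry", "M1")


class TestVif:
    def test_orthogonal_columns_are_one(self):
        X = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        out = mod.vif(X)
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_duplicated_column_flagged_infinite(self, rng):
        x = rng.normal(size=50)
        with pytest.warns(UserWarning, match="VIF"):
            out = mod.vif(np.column_stack([x, x, rng.normal(size=50)]))
        assert np.isinf(out.iloc[0])

    def test_matches_statsmodels_regression_oracle(self, rng):
        import statsmodels.api as sm
        z = rng.normal(size=(100, 2))
        X = np.column_stack([z[:, 0], 0.7 * z[:, 0] + 0.5 * z[:, 1],
                             rng.normal(size=100)])
        ours = mod.vif(X)
        for j in range(3):
            others = sm.add_constant(np.delete(X, j, axis=1))
            r2 = sm.OLS(X[:, j], others).fit().rsquared
            assert ours.iloc[j] == pytest.approx(1.0 / (1.0 - r2))


def simulate_clogit(rng, beta, n_strata=200, m=10, n_animals=5):
    """Direct conditional-logit draw: pick the case among m rows by softmax."""
    k = len(beta)
    X = rng.normal(size=(n_strata * m, k))
    eta = (X @ beta).reshape(n_strata, m)
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    case = np.zeros(n_strata * m, dtype=int)
    for s in range(n_strata):
        case[s * m + rng.choice(m, p=p[s])] = 1
    return mod.DesignMatrix(
        X=X, columns=[f"x{j}" for j in range(k)],
        stratum_id=np.repeat(np.arange(n_strata), m), case=case,
        cluster=np.repeat([f"a{s % n_animals}" for s in range(n_strata)], m))


class TestFitClogit:
    def test_symmetric_data_estimate_zero(self):
        # strata of 2 with x_case - x_control summing to zero -> zero score at 0
        X = np.array([[1.0], [0.0], [0.0], [1.0]])
        d = mod.DesignMatrix(X=X, columns=["x"], stratum_id=np.array([0, 0, 1, 1]),
                             case=np.array([1, 0, 1, 0]), cluster=np.array(["a"] * 4))
        fit = mod.fit_clogit(d)
        assert fit.beta["x"] == pytest.approx(0.0, abs=1e-10)

    def test_loglik_at_zero_is_minus_n_log_m(self, rng):
        d = simulate_clogit(rng, np.array([0.5, -0.3]), n_strata=50)
        starts = np.arange(0, 500, 10)
        seg = np.repeat(np.arange(50), 10)
        ll0 = mod.clogit_loglik(np.zeros(2), d.X, starts, seg,
                                np.flatnonzero(d.case == 1))
        assert ll0 == pytest.approx(-50 * np.log(10), abs=1e-12)
        fit = mod.fit_clogit(d)
        assert fit.loglik_null == pytest.approx(-50 * np.log(10), abs=1e-12)

    def test_matches_grid_search_oracle(self, rng):
        beta_true = np.array([0.8, -0.5])
        d = simulate_clogit(rng, beta_true, n_strata=5, m=10)
        starts = np.arange(0, 50, 10)
        seg = np.repeat(np.arange(5), 10)
        case_idx = np.flatnonzero(d.case == 1)

        center, width = np.zeros(2), 3.0
        for _ in range(4):  # successively refined exhaustive grid
            g0 = np.linspace(center[0] - width, center[0] + width, 61)
            g1 = np.linspace(center[1] - width, center[1] + width, 61)
            lls = np.array([[mod.clogit_loglik(np.array([a, b]), d.X, starts, seg,
                                               case_idx) for b in g1] for a in g0])
            i, j = np.unravel_index(np.argmax(lls), lls.shape)
            center, width = np.array([g0[i], g1[j]]), width / 10.0
        fit = mod.fit_clogit(d)
        np.testing.assert_allclose(fit.beta.to_numpy(), center, atol=1e-3)

    def test_matches_statsmodels_conditional_logit(self, rng):
        from statsmodels.discrete.conditional_models import ConditionalLogit
        d = simulate_clogit(rng, np.array([0.6, -0.4, 0.2]), n_strata=150)
        fit = mod.fit_clogit(d)
        sm_fit = ConditionalLogit(d.case, d.X, groups=d.stratum_id).fit(disp=0)
        # statsmodels stops at a looser BFGS gradient tolerance than our Newton
        np.testing.assert_allclose(fit.beta.to_numpy(), sm_fit.params, atol=5e-4)
        np.testing.assert_allclose(fit.se_naive.to_numpy(), sm_fit.bse, rtol=1e-3)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-6)

    def test_invariant_to_within_stratum_recentring(self, rng):
        d = simulate_clogit(rng, np.array([0.5, -0.2]), n_strata=80)
        fit1 = mod.fit_clogit(d)
        shifts = rng.normal(size=80)
        X2 = d.X.copy()
        X2[:, 0] += shifts[d.stratum_id]
        d2 = mod.DesignMatrix(X=X2, columns=d.columns, stratum_id=d.stratum_id,
                              case=d.case, cluster=d.cluster)
        fit2 = mod.fit_clogit(d2)
        np.testing.assert_allclose(fit1.beta.to_numpy(), fit2.beta.to_numpy(),
                                   atol=1e-7)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)

    def test_separation_detected(self):
        # the case row always carries the strictly largest covariate value
        rows, case = [], []
        for s in range(20):
            rows.extend([[10.0 + s], [0.0], [1.0]])
            case.extend([1, 0, 0])
        d = mod.DesignMatrix(X=np.array(rows), columns=["x"],
                             stratum_id=np.repeat(np.arange(20), 3),
                             case=np.array(case), cluster=np.array(["a"] * 60))
        with pytest.raises(SeparationError):
            mod.fit_clogit(d)

    def test_robust_approx_naive_when_clusters_are_strata(self, rng):
        d = simulate_clogit(rng, np.array([0.5, -0.3]), n_strata=2000)
        d.cluster = d.stratum_id.copy()  # one stratum per cluster
        fit = mod.fit_clogit(d)
        np.testing.assert_allclose(np.diag(fit.cov_robust), np.diag(fit.cov_naive),
                                   rtol=0.15)

    def test_covariances_symmetric_psd(self, rng):
        fit = mod.fit_clogit(simulate_clogit(rng, np.array([0.4, 0.1]), n_strata=100))
        for cov in (fit.cov_naive, fit.cov_robust):
            np.testing.assert_allclose(cov, cov.T, atol=1e-12)
            assert np.linalg.eigvalsh(cov).min() >= -1e-12


class TestAicc:
    def make_fit(self, loglik, k, n_strata):
        return mod.FitResult(
            beta=pd.Series(np.zeros(k)), cov_naive=np.eye(k), cov_robust=np.eye(k),
            loglik=loglik, loglik_null=0.0, k=k, n_strata=n_strata, n_clusters=1,
            converged=True, n_iter=1)

    def test_closed_form(self):
        assert mod.aicc(self.make_fit(-100.0, 2, 50)) == pytest.approx(204 + 12 / 47)

    def test_approaches_aic_for_large_n(self):
        fit = self.make_fit(-100.0, 2, 10 ** 9)
        assert mod.aicc(fit) == pytest.approx(204.0, abs=1e-6)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ConfigurationError):
            mod.aicc(self.make_fit(-10.0, 5, 6))

    def test_pure_noise_column_costs_about_two(self, rng):
        d = simulate_clogit(rng, np.array([0.6, 0.0]), n_strata=400)
        full = mod.fit_clogit(d)
        d1 = mod.DesignMatrix(X=d.X[:, :1], columns=["x0"], stratum_id=d.stratum_id,
                              case=d.case, cluster=d.cluster)
        reduced = mod.fit_clogit(d1)
        delta_noise = full.loglik - reduced.loglik  # ~ chi2(1)/2 under the null
        got = mod.aicc(full) - mod.aicc(reduced)
        assert got == pytest.approx(2.0 - 2.0 * delta_noise, abs=0.05)


class TestSelectModel:
    def test_tie_broken_by_smaller_k(self, rng):
        d = simulate_clogit(rng, np.array([0.5]), n_strata=60)
        fit1 = mod.fit_clogit(d)
        fit2 = mod.FitResult(**{**fit1.__dict__})
        fit2.k = fit1.k  # identical fits
        out = mod.select_model({"B": fit2, "A": fit1})
        assert (out["dAICc"] == 0).all()

    def test_ranked_ascending_with_delta(self, rng):
        d = simulate_clogit(rng, np.array([0.9, -0.6]), n_strata=150)
        full = mod.fit_clogit(d)
        d1 = mod.DesignMatrix(X=d.X[:, :1], columns=["x0"], stratum_id=d.stratum_id,
                              case=d.case, cluster=d.cluster)
        reduced = mod.fit_clogit(d1)
        out = mod.select_model({"full": full, "reduced": reduced})
        assert out["dAICc"].iloc[0] == 0.0
        assert out["AICc"].is_monotonic_increasing

    def test_different_strata_not_comparable(self, rng):
        a = mod.fit_clogit(simulate_clogit(rng, np.array([0.5]), n_strata=50))
        b = mod.fit_clogit(simulate_clogit(rng, np.array([0.5]), n_strata=60))
        with pytest.raises(DataError):
            mod.select_model({"a": a, "b": b})
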