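import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.optimize

from locoage import (
    SurvivalSpec,
    assoc_test,
    compare_groups,
    doubling_time,
    fit_cox_gompertz,
    fit_cox_ridge,
    gompertz_loglik,
    predict_log_hazard,
    simulate_survival,
)


def _sim_survival_from_lp(lp, rate, horizon, rng):
    tte = rng.exponential(size=lp.size) / (rate * np.exp(lp - lp.mean()))
    return np.minimum(tte, horizon), (tte <= horizon).astype(int)


class TestCoxRidge:
    def test_huge_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 5))
        t, e = _sim_survival_from_lp(X[:, 0], 0.1, 20.0, rng)
        m = fit_cox_ridge(X, np.zeros(100), t, e, penalty=1e8)
        assert np.abs(m.coef).max() < 1e-4

    def test_single_binary_covariate_sign(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 1000).astype(float)
        t, e = _sim_survival_from_lp(1.0 * x, 0.05, 15.0, rng)
        m = fit_cox_ridge(x.reshape(-1, 1), np.zeros(1000), t, e, penalty=0.01)
        assert m.coef[0] > 0

    def test_matches_brute_force_partial_likelihood(self):
        """Tiny unpenalized fit vs direct maximization of the enumerated
        partial likelihood."""
        X = np.array(
            [[0.5, -1.0], [-0.2, 0.3], [1.0, 0.8], [-0.7, -0.5], [0.1, 1.2],
             [0.9, -0.3]]
        )
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 0, 1, 1, 0, 1])

        def neg_pl(beta):  # naive enumeration, independent of the implementation
            eta = X @ beta
            ll = 0.0
            for i in range(6):
                if events[i]:
                    risk = times >= times[i]
                    ll += eta[i] - np.log(np.exp(eta[risk]).sum())
            return -ll

        brute = scipy.optimize.minimize(neg_pl, np.zeros(2), method="Nelder-Mead",
                                        options={"xatol": 1e-10, "fatol": 1e-12})
        m = fit_cox_ridge(X, np.zeros(6), times, events, penalty=0.0,
                          standardize=False)
        # drop the all-zero gender column from the comparison
        np.testing.assert_allclose(m.coef[:2], brute.x, atol=1e-4)

    def test_matches_lifelines_with_ties(self):
        """Efron tie handling cross-checked against an independent fitter."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 3))
        t, e = _sim_survival_from_lp(X @ [0.5, -0.3, 0.0], 0.1, 10.0, rng)
        t = np.ceil(t)  # yearly resolution forces ties
        m = fit_cox_ridge(X, np.zeros(200), t, e, penalty=0.0, standardize=False)
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        df["T"], df["E"] = t, e
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(
            m.coef[:3], cph.params_.to_numpy(), atol=1e-3
        )

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox_ridge(
                np.random.default_rng(0).standard_normal((10, 2)),
                np.zeros(10), np.ones(10), np.zeros(10),
            )

    def test_recovers_linear_predictor_on_synthetic_descriptors(
        self, default_descriptors
    ):
        """Ridge fit on the 65 covariates reproduces a known linear predictor."""
        d = default_descriptors
        rng = np.random.default_rng(11)
        Xg = np.column_stack([d["X"], d["genders"]])
        beta = rng.standard_normal(65) * 0.3
        lp = (Xg - Xg.mean(axis=0)) @ beta
        lp *= 0.8 / lp.std()
        t, e = _sim_survival_from_lp(lp, 0.04, 9.0, rng)
        m = fit_cox_ridge(d["X"], d["genders"], t, e, penalty=0.01)
        assert m.n_covariates == 65
        pred = predict_log_hazard(m, d["X"], d["genders"])
        assert np.corrcoef(pred, lp)[0, 1] > 0.9


class TestPredictLogHazard:
    def test_training_mean_scores_zero(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 4))
        t, e = _sim_survival_from_lp(X[:, 0], 0.1, 10.0, rng)
        m = fit_cox_ridge(X, rng.integers(0, 2, 200), t, e)
        assert predict_log_hazard(
            m, m.center[:4], np.array([m.center[4]])
        )[0] == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_single_covariate(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((150, 3))
        t, e = _sim_survival_from_lp(X[:, 1], 0.1, 10.0, rng)
        m = fit_cox_ridge(X, np.zeros(150), t, e)
        x1, x2 = X[0].copy(), X[0].copy()
        x2[1] += 2.5
        s = predict_log_hazard(m, np.vstack([x1, x2]), np.zeros(2))
        assert s[1] - s[0] == pytest.approx(2.5 * m.coef[1], abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 3))
        t, e = _sim_survival_from_lp(X[:, 0], 0.2, 10.0, rng)
        m = fit_cox_ridge(X, np.zeros(50), t, e)
        with pytest.raises(ValueError, match="covariates"):
            predict_log_hazard(m, rng.standard_normal((5, 7)), np.zeros(5))


class TestGompertzLoglik:
    def test_hand_evaluated_single_subject(self):
        # (0.01/0.1) e^6 (1 - e^0.1) + (ln 0.01 + 6 + 0.1) = -4.2429 + 1.4948
        ll = gompertz_loglik(
            0.01, 0.1, np.array([60.0]), np.array([1.0]), np.array([1])
        )
        assert ll == pytest.approx(-2.748, abs=5e-4)

    def test_empty_exposure_is_zero(self):
        ll = gompertz_loglik(
            0.01, 0.1, np.array([50.0, 60.0]), np.zeros(2), np.zeros(2)
        )
        assert ll == 0.0

    def test_censored_term_is_log_gompertz_survival(self):
        """For delta=0 the contribution equals minus the integrated hazard,
        cross-checked by quadrature."""
        M0, G, t, dt = 2e-4, 0.09, 55.0, 7.3
        ll = gompertz_loglik(M0, G, np.array([t]), np.array([dt]), np.array([0]))
        integral, _ = scipy.integrate.quad(
            lambda s: M0 * np.exp(G * s), t, t + dt
        )
        assert ll == pytest.approx(-integral, abs=1e-8)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gompertz_loglik(-0.1, 0.1, np.array([50.0]), np.array([1.0]),
                            np.array([1]))
        with pytest.raises(ValueError):
            gompertz_loglik(0.1, 0.0, np.array([50.0]), np.array([1.0]),
                            np.array([1]))


class TestFitCoxGompertz:
    def test_parameter_recovery(self):
        cohort_rng = np.random.default_rng(30)
        ages = cohort_rng.uniform(40, 85, 20000)
        sspec = SurvivalSpec(M0=5e-5, Gamma=0.085, beta_baa=0.0)
        delta, dt = simulate_survival(ages, 0.0, sspec, cohort_rng)
        fit = fit_cox_gompertz(ages, dt, delta)
        assert fit.Gamma == pytest.approx(0.085, abs=0.005)
        assert fit.se_Gamma < 0.005

    def test_baseline_scaling_leaves_gamma(self):
        rng = np.random.default_rng(31)
        ages = rng.uniform(40, 85, 20000)
        f = {}
        for mult in (1.0, 2.0):
            sspec = SurvivalSpec(M0=5e-5 * mult, Gamma=0.085, beta_baa=0.0)
            delta, dt = simulate_survival(ages, 0.0, sspec, np.random.default_rng(32))
            f[mult] = fit_cox_gompertz(ages, dt, delta)
        assert f[2.0].Gamma == pytest.approx(f[1.0].Gamma, abs=3 * f[1.0].se_Gamma)
        assert f[2.0].M0 / f[1.0].M0 == pytest.approx(2.0, rel=0.25)

    def test_multistart_reaches_same_optimum(self):
        rng = np.random.default_rng(33)
        ages = rng.uniform(40, 85, 5000)
        delta, dt = simulate_survival(ages, 0.0, SurvivalSpec(), rng)
        fits = [
            fit_cox_gompertz(ages, dt, delta, starts=((m0, g),))
            for m0, g in [(1e-6, 0.02), (1e-4, 0.08), (5e-3, 0.3)]
        ]
        for f in fits[1:]:
            assert f.Gamma == pytest.approx(fits[0].Gamma, abs=1e-5)
            assert f.loglik == pytest.approx(fits[0].loglik, abs=1e-6)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="unbounded"):
            fit_cox_gompertz(np.array([50.0]), np.array([5.0]), np.array([0]))


class TestDoublingTime:
    def test_empirical_gompertz_constant_gives_eight_years(self):
        assert doubling_time(0.085) == pytest.approx(8.15, abs=0.01)
        assert round(doubling_time(0.085)) == 8

    def test_closed_form_and_scaling(self):
        assert doubling_time(np.log(2.0)) == pytest.approx(1.0)
        assert doubling_time(0.05) == pytest.approx(2 * doubling_time(0.1))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)


class TestAssocTest:
    def test_informative_score_detected(self):
        rng = np.random.default_rng(40)
        n = 5000
        ages = rng.uniform(40, 85, n)
        genders = rng.integers(0, 2, n)
        baa = rng.standard_normal(n) * 3.0
        sspec = SurvivalSpec(beta_baa=0.14)
        delta, dt = simulate_survival(ages, baa, sspec, rng)
        r = assoc_test(baa, ages, genders, dt, delta)
        assert r.hr > 1.0 and r.p < 0.05
        assert r.ci_low < r.hr < r.ci_high
        assert r.events <= r.n

    def test_permuted_score_loses_significance(self):
        rng = np.random.default_rng(41)
        n = 2000
        ages = rng.uniform(40, 85, n)
        genders = rng.integers(0, 2, n)
        baa = rng.standard_normal(n) * 3.0
        delta, dt = simulate_survival(ages, baa, SurvivalSpec(beta_baa=0.2), rng)
        pvals = []
        for k in range(50):
            perm = np.random.default_rng(k).permutation(n)
            pvals.append(assoc_test(baa[perm], ages, genders, dt, delta).p)
        assert np.median(pvals) > 0.1

    def test_zero_variance_score_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            assoc_test(
                np.ones(10), np.linspace(40, 80, 10), np.zeros(10),
                np.ones(10), np.ones(10),
            )


class TestCompareGroups:
    def test_identical_groups_show_no_shift(self):
        rng = np.random.default_rng(50)
        values = rng.standard_normal(1000)
        labels = np.repeat(["a", "b"], 500)
        out = compare_groups(values, labels)
        s = out["summary"].set_index("group")
        pooled_sem = np.hypot(s.loc["a", "sem"], s.loc["b", "sem"])
        assert abs(s.loc["a", "median"] - s.loc["b", "median"]) < 2 * pooled_sem

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(51)
        never = rng.standard_normal(500)
        current = rng.standard_normal(500) + 1.0  # +1 SD shift
        former = rng.standard_normal(500)
        values = np.concatenate([never, current, former])
        labels = np.array(["never"] * 500 + ["current"] * 500 + ["former"] * 500)
        out = compare_groups(values, labels)
        pw = out["pairwise"].set_index(["group_a", "group_b"])
        assert pw.loc[("never", "current"), "p"] < 0.01
        assert pw.loc[("never", "former"), "p"] > 0.01  # reversible: no shift

    def test_permuted_labels_lose_significance(self):
        rng = np.random.default_rng(52)
        values = np.concatenate(
            [rng.standard_normal(200), rng.standard_normal(200) + 1.0]
        )
        labels = np.repeat(["a", "b"], 200)
        pvals = [
            compare_groups(
                values, np.random.default_rng(k).permutation(labels)
            )["pairwise"]["p"].iloc[0]
            for k in range(100)
        ]
        assert np.median(pvals) > 0.1

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(np.arange(4.0), np.array(["a", "a", "a", "b"]))
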