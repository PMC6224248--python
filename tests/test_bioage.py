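import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from locoage import (
    detrend,
    fit_pca,
    project,
    simulate_cohort,
    variance_by_age,
)
from locoage.bioage import BioAgeModel


class TestFitPca:
    def test_rank_one_data_recovers_axis(self):
        rng = np.random.default_rng(0)
        axis = np.zeros(64)
        axis[5] = 1.0
        t = rng.standard_normal(200)
        X = np.outer(t, axis)
        model = fit_pca(X, ages=40 + np.abs(t) * 10)
        assert abs(model.loading @ axis) > 0.999

    def test_duplicated_dataset_gives_identical_model(self, default_descriptors):
        d = default_descriptors
        m1 = fit_pca(d["X"], d["ages"], d["genders"])
        m2 = fit_pca(
            np.vstack([d["X"], d["X"]]),
            np.concatenate([d["ages"], d["ages"]]),
            np.concatenate([d["genders"], d["genders"]]),
        )
        np.testing.assert_allclose(m1.loading, m2.loading, atol=1e-8)
        np.testing.assert_allclose(m1.mean, m2.mean, atol=1e-12)

    def test_score_correlates_with_age_on_synthetic_cohort(
        self, default_descriptors
    ):
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        pc1 = project(model, d["X"])
        assert np.corrcoef(pc1, d["ages"])[0, 1] >= 0.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_pca(np.ones((10, 64)), ages=np.linspace(40, 80, 10))

    def test_sign_oriented_toward_age(self, default_descriptors):
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        scores = project(model, d["X"])
        mask = d["ages"] >= model.training_min_age
        assert np.corrcoef(scores[mask], d["ages"][mask])[0, 1] > 0


class TestProject:
    def test_training_mean_scores_zero(self, default_descriptors):
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        assert project(model, model.mean)[0] == pytest.approx(0.0, abs=1e-10)

    def test_round_trip_on_training_set(self, default_descriptors):
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"], min_age=0.0)
        from sklearn.decomposition import PCA

        pca = PCA(n_components=1).fit(d["X"])
        ref = pca.transform(d["X"])[:, 0]
        got = project(model, d["X"])
        sign = np.sign(np.dot(ref, got))
        np.testing.assert_allclose(got, sign * ref, atol=1e-8)

    def test_dimension_mismatch_rejected(self, default_descriptors):
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        with pytest.raises(ValueError, match="dimension"):
            project(model, np.zeros(10))

    def test_transfer_to_independent_cohort(self, default_descriptors):
        """The loading fit on one cohort scores a second, independently
        simulated cohort with a similar age correlation (the cross-dataset
        projection)."""
        from locoage import markov
        from locoage.pipeline import _descriptor_frame

        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        r_train = np.corrcoef(project(model, d["X"]), d["ages"])[0, 1]

        cohort2, tracks2 = simulate_cohort(600, seed=99)
        df2 = _descriptor_frame(tracks2, markov.DiscretizationScheme())
        X2 = df2[markov.descriptor_names()].to_numpy()
        ages2 = cohort2.set_index("participant_id").loc[
            df2["participant_id"], "age"
        ].to_numpy()
        r_new = np.corrcoef(project(model, X2), ages2)[0, 1]
        assert abs(r_new - r_train) < 0.1

    def test_scale_consistency(self, default_descriptors):
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        c = 3.0
        model_scaled = fit_pca(c * d["X"], d["ages"], d["genders"])
        s1 = project(model, d["X"])
        s2 = project(model_scaled, c * d["X"])
        sign = np.sign(np.dot(s1, s2))
        np.testing.assert_allclose(s2 * sign, c * s1, rtol=1e-6, atol=1e-8)


class TestDetrend:
    def test_residuals_orthogonal_to_age_and_gender(self, default_descriptors):
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        res = detrend(project(model, d["X"]), d["ages"], d["genders"])
        assert abs(np.corrcoef(res.baa, d["ages"])[0, 1]) < 1e-10
        assert abs(np.mean(res.baa)) < 1e-10

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-20.0, 20.0))
    def test_age_shift_invariance(self, shift):
        rng = np.random.default_rng(8)
        ages = rng.uniform(40, 80, 200)
        genders = rng.integers(0, 2, 200)
        scores = 0.5 * ages + genders + rng.standard_normal(200)
        a = detrend(scores, ages, genders).baa
        b = detrend(scores, ages + shift, genders).baa
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_gender_encoding_does_not_change_residuals(self):
        rng = np.random.default_rng(9)
        ages = rng.uniform(40, 80, 300)
        genders = rng.integers(0, 2, 300)
        scores = 0.3 * ages - 2.0 * genders + rng.standard_normal(300)
        a = detrend(scores, ages, genders).baa
        b = detrend(scores, ages, 1 - genders).baa
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_decedents_have_higher_baa(self, default_descriptors):
        """With a positive BAA effect on mortality, participants who die in
        follow-up show higher detrended bioage than survivors."""
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        res = detrend(project(model, d["X"]), d["ages"], d["genders"])
        dead = d["meta"]["delta_death"].to_numpy() == 1
        assert res.baa[dead].mean() > res.baa[~dead].mean()

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant age"):
            detrend(np.arange(10.0), np.full(10, 50.0), np.zeros(10))


class TestVarianceByAge:
    def test_null_scores_have_flat_variance(self):
        rng = np.random.default_rng(10)
        ages = rng.uniform(40, 85, 5000)
        scores = rng.standard_normal(5000)
        out = variance_by_age(scores, ages)
        assert abs(out["slope"]) < 2 * out["slope_se"]

    def test_diffusive_cohort_has_positive_slope(self, default_descriptors):
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        out = variance_by_age(project(model, d["X"]), d["ages"])
        assert out["slope"] > 2 * out["slope_se"]

    def test_bin_width_robustness(self, default_descriptors):
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        pc1 = project(model, d["X"])
        s5 = variance_by_age(pc1, d["ages"], bin_width=5.0)["slope"]
        s10 = variance_by_age(pc1, d["ages"], bin_width=10.0)["slope"]
        assert abs(s10 - s5) / abs(s5) < 0.2

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            variance_by_age(np.ones(20), np.full(20, 50.0))


class TestPersistence:
    def test_json_round_trip(self, tmp_path, default_descriptors):
        d = default_descriptors
        model = fit_pca(d["X"], d["ages"], d["genders"])
        res = detrend(project(model, d["X"]), d["ages"], d["genders"])
        model.detrend_coef = res.coef
        path = tmp_path / "model.json"
        model.to_json(path)
        back = BioAgeModel.from_json(path)
        np.testing.assert_allclose(back.loading, model.loading)
        np.testing.assert_allclose(back.detrend_coef, model.detrend_coef)
        np.testing.assert_allclose(
            project(back, d["X"]), project(model, d["X"])
        )
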