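"""Feature matrix, ICA embedding, kde two-sample test, drug-effect scores."""

import numpy as np
import pandas as pd
import pytest

from swimstates import states, synthetic


def _bout_frame(freq, angle, n, lr, interval):
    return pd.DataFrame({
        "tail_freq_hz": freq, "mean_peak_angle_deg": angle,
        "n_motions": n, "lr_balance": lr, "interval_s": interval})


class TestBuildFeatures:
    @pytest.mark.parametrize("angle,expected", [
        (0.0, 0.0), (1.0, 1.0), (32.0, 4.0)])   # 32^0.4 = 2^2 exactly
    def test_angle_power_transform(self, angle, expected):
        X, _ = states.build_features(
            _bout_frame([20.0], [angle], [4], [0.1], [1.0]))
        assert X[0, 1] == pytest.approx(expected)

    def test_missing_interval_rows_dropped(self):
        X, idx = states.build_features(
            _bout_frame([20, 21.0], [10, 10.0], [4, 4], [0.1, 0.1],
                        [np.nan, 1.0]))
        assert X.shape == (1, 5) and idx.tolist() == [1]

    def test_negative_angle_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            states.build_features(
                _bout_frame([20.0], [-1.0], [4], [0.1], [1.0]))


@pytest.fixture(scope="module")
def embedded_control(control_bouts):
    _, bouts, _ = control_bouts
    X, idx = states.build_features(bouts)
    norm, model = states.fit_embedding(X, seed=0)
    emb = states.project(X, norm, model)
    labels = bouts["state"].to_numpy()[idx]
    epochs = bouts["epoch"].to_numpy()[idx]
    return X, norm, model, emb, labels, epochs


class TestEmbedding:
    def test_ic1_separates_spontaneous_from_omr_scooting(self,
                                                         embedded_control):
        _, _, _, emb, labels, _ = embedded_control
        assert emb[labels == "omr_scoot", 0].mean() > \
            emb[labels == "spont_scoot", 0].mean()

    def test_ic2_separates_turning_from_scooting(self, embedded_control):
        _, _, _, emb, labels, _ = embedded_control
        scoot = np.isin(labels, ["spont_scoot", "omr_scoot"])
        assert emb[labels == "turn_escape", 1].mean() > \
            emb[scoot, 1].mean()

    def test_state_centroids_separated_by_pooled_sd(self, embedded_control):
        _, _, _, emb, labels, _ = embedded_control
        names = np.unique(labels)
        cent = {s: emb[labels == s].mean(axis=0) for s in names}
        pooled_sd = np.linalg.norm(emb.std(axis=0)) / np.sqrt(2)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert np.linalg.norm(cent[a] - cent[b]) > pooled_sd

    def test_same_seed_same_weights(self, embedded_control):
        X = embedded_control[0]
        _, m1 = states.fit_embedding(X, seed=0)
        _, m2 = states.fit_embedding(X, seed=0)
        assert np.allclose(m1.components, m2.components)

    def test_projecting_reference_reproduces_fit_coordinates(
            self, embedded_control):
        X, norm, model, emb, _, _ = embedded_control
        assert np.allclose(states.project(X, norm, model), emb)

    def test_projection_is_row_equivariant(self, embedded_control):
        X, norm, model, emb, _, _ = embedded_control
        perm = np.random.default_rng(0).permutation(len(X))
        assert np.allclose(states.project(X[perm], norm, model), emb[perm])

    def test_zero_variance_feature_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 5))
        X[:, 3] = 0.5
        with pytest.raises(ValueError, match="zero-variance"):
            states.fit_embedding(X)

    def test_dimension_mismatch_rejected(self, embedded_control):
        X, norm, model, _, _, _ = embedded_control
        with pytest.raises(ValueError, match="dimension"):
            states.project(X[:, :4], norm, model)

    def test_model_json_round_trip(self, embedded_control, tmp_path):
        X, norm, model, emb, _, _ = embedded_control
        path = tmp_path / "model.json"
        states.save_model(path, norm, model)
        norm2, model2 = states.load_model(path)
        assert np.allclose(states.project(X, norm2, model2), emb)


class TestKdeTwoSampleTest:
    def test_identical_samples_give_zero_statistic_p_one(self):
        a = np.random.default_rng(0).normal(size=50)
        r = states.kde_two_sample_test(a, a.copy(), n_perm=100, seed=1)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == 1.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 45)
        r1 = states.kde_two_sample_test(a, b, n_perm=50, seed=2)
        r2 = states.kde_two_sample_test(b, a, n_perm=50, seed=2)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_p_value_invariant_under_common_affine_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 40), rng.normal(1, 1, 40)
        r1 = states.kde_two_sample_test(a, b, n_perm=200, seed=3)
        r2 = states.kde_two_sample_test(3.0 * a - 7.0, 3.0 * b - 7.0,
                                        n_perm=200, seed=3)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_power_at_large_separation(self):
        rng = np.random.default_rng(3)
        r = states.kde_two_sample_test(rng.normal(0, 1, 500),
                                       rng.normal(2, 1, 500),
                                       n_perm=300, seed=4)
        assert r.p_value < 0.01

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(4)
        reps, rej = 200, 0
        for i in range(reps):
            a, b = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
            r = states.kde_two_sample_test(a, b, n_perm=199, seed=i)
            rej += r.p_value <= 0.05
        rate = rej / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se

    def test_degenerate_pooled_sample_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            states.kde_two_sample_test(np.ones(30), np.ones(30))

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            states.kde_two_sample_test(np.arange(10), np.arange(30))

    def test_detects_stress_shift_in_generator_ic2(self, control_bouts):
        config, bouts, _ = control_bouts
        X, idx = states.build_features(bouts)
        norm, model = states.fit_embedding(X, seed=0)
        stress_cfg = synthetic.SessionConfig(session_duration_s=240.0,
                                             seed=21)
        pose_s, _ = synthetic.simulate_session(
            stress_cfg, synthetic.condition("stress"))
        from swimstates import kinematics
        bouts_s = kinematics.analyze_session(pose_s, stress_cfg)
        Xs, idx_s = states.build_features(bouts_s)
        spont_c = bouts["epoch"].to_numpy()[idx] == "spont"
        spont_s = bouts_s["epoch"].to_numpy()[idx_s] == "spont"
        ic2_c = states.project(X, norm, model)[spont_c, 1][:300]
        ic2_s = states.project(Xs, norm, model)[spont_s, 1][:300]
        r = states.kde_two_sample_test(ic2_c, ic2_s, n_perm=200, seed=5)
        assert r.p_value < 0.05


class TestDrugScores:
    def test_distance_null_cases(self):
        control = [100.0, 100.0, 100.0]
        stress = [150.0, 150.0]
        s = states.score_distance_effects(
            control, [100.0, 100.0], stress, [150.0, 150.0])
        assert s.stimulatory_distance.mean == pytest.approx(0.0)
        assert s.anxiolytic_distance.mean == pytest.approx(0.0)

    def test_full_stress_reversal_scores_minus_one(self):
        s = states.score_distance_effects(
            [100.0, 100.0], [120.0, 130.0], [150.0, 150.0], [100.0, 100.0])
        assert s.anxiolytic_distance.mean == pytest.approx(-1.0)
        assert s.anxiolytic_magnitude_distance == pytest.approx(1.0)

    def test_distance_scores_scale_free(self):
        rng = np.random.default_rng(0)
        groups = [rng.uniform(50, 150, 6) for _ in range(4)]
        s1 = states.score_distance_effects(*groups)
        s2 = states.score_distance_effects(*[3.7 * g for g in groups])
        assert s1.stimulatory_distance.mean == pytest.approx(
            s2.stimulatory_distance.mean)
        assert s1.anxiolytic_distance.mean == pytest.approx(
            s2.anxiolytic_distance.mean)

    def test_ic_score_worked_cases(self):
        c1s, c1o = [0.0, 0.0], [2.0, 2.0]
        c2, s2 = [0.0, 0.0], [1.0, 1.0]
        s = states.score_ic_effects(c1s, c1o, [2.0, 2.0], c2, s2, [0.0, 0.0])
        # drug fish at the control OMR IC1 mean -> stimulatory = 1
        assert s.stimulatory_ic1.mean == pytest.approx(1.0)
        # drug+stress fish back at the control IC2 mean -> anxiolytic = -1
        assert s.anxiolytic_ic2.mean == pytest.approx(-1.0)

    def test_ic_scores_invariant_under_common_affine_shift(self):
        rng = np.random.default_rng(1)
        g = [rng.normal(0, 1, 5) for _ in range(6)]
        s1 = states.score_ic_effects(*g)
        s2 = states.score_ic_effects(*[2.0 * x + 5.0 for x in g])
        assert s1.stimulatory_ic1.mean == pytest.approx(
            s2.stimulatory_ic1.mean)
        assert s1.anxiolytic_ic2.mean == pytest.approx(s2.anxiolytic_ic2.mean)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            states.score_distance_effects(
                [100.0, 100.0], [110.0, 110.0], [100.0, 100.0],
                [100.0, 100.0])
        with pytest.raises(ValueError, match="contrast is zero"):
            states.score_ic_effects([0.0, 0.0], [0.0, 0.0], [1.0, 1.0],
                                    [0.0, 0.0], [1.0, 1.0], [0.0, 0.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="2 fish"):
            states.score_distance_effects([100.0], [110.0, 120.0],
                                          [150.0, 150.0], [120.0, 130.0])
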