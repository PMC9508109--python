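"""Linear epsilon-SV regression: frame selection, solver, landmark recovery."""

import numpy as np
import pytest

from quailkin.cameras import Observations2D
from quailkin.regression import (AnnotationSet, annotate_from_observations,
                                 evaluate_localization, predict_landmarks,
                                 select_training_frames, svr_objective,
                                 train_epsilon_svr, train_landmark_regressors,
                                 LandmarkRegressor)


class TestSelectTrainingFrames:
    def test_matches_linspace_and_round_oracle(self):
        assert select_training_frames(100, 10) == [
            1, 12, 23, 34, 45, 56, 67, 78, 89, 100]

    @pytest.mark.parametrize("L,M,expected", [
        (5, 5, [1, 2, 3, 4, 5]),
        (10, 1, [1]),
        (10, 2, [1, 10]),
    ])
    def test_degenerate_cases(self, L, M, expected):
        assert select_training_frames(L, M) == expected

    def test_property_first_last_unique(self):
        for L in (7, 31, 200, 571):
            for M in (2, 5, 10, L):
                if M > L:
                    continue
                idx = select_training_frames(L, M)
                assert idx[0] == 1 and idx[-1] == L
                assert len(set(idx)) == M
                assert all(1 <= i <= L for i in idx)

    def test_m_larger_than_l_rejected(self):
        with pytest.raises(ValueError):
            select_training_frames(5, 6)


from oracles import qp_oracle as _qp_oracle  # noqa: E402


class TestEpsilonSVR:
    def test_exact_linear_data(self):
        w, b = train_epsilon_svr(np.array([1.0, 2.0, 3.0]),
                                 np.array([2.0, 4.0, 6.0]),
                                 C=1e6, epsilon=0.0)
        assert w[0] == pytest.approx(2.0, abs=1e-6)
        assert b == pytest.approx(0.0, abs=1e-6)

    def test_constant_targets(self):
        w, b = train_epsilon_svr(np.arange(5.0), np.full(5, 3.25), epsilon=0.0)
        np.testing.assert_allclose(w, 0.0)
        assert b == 3.25

    def test_objective_matches_qp_oracle_on_random_instances(self, rng):
        """libsvm's solution attains the primal optimum of the program."""
        for _ in range(5):
            n, D = 8, 3
            X = rng.normal(size=(n, D))
            y = rng.normal(size=n)
            C, eps = 2.0, 0.1
            w, b = train_epsilon_svr(X, y, C=C, epsilon=eps, tol=1e-10)
            ours = svr_objective(X, y, w, b, C, eps)
            oracle = _qp_oracle(X, y, C, eps)
            assert ours <= oracle + 1e-6

    def test_epsilon_tube_property(self, rng):
        """On feasible data, large C pushes every residual inside the tube."""
        X = rng.normal(size=(10, 4))
        w0, b0 = rng.normal(size=4), 0.7
        eps = 0.3
        y = X @ w0 + b0 + rng.uniform(-eps / 2, eps / 2, size=10)
        w, b = train_epsilon_svr(X, y, C=1e6, epsilon=eps, tol=1e-8)
        resid = np.abs(y - X @ w - b)
        assert np.all(resid <= eps + 1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            train_epsilon_svr(np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            train_epsilon_svr(np.arange(3.0), np.array([1, 2, np.nan]))
        with pytest.raises(ValueError):
            train_epsilon_svr(np.arange(3.0), np.arange(3.0), C=-1.0)


@pytest.fixture(scope="module")
def tracked(noiseless_chain):
    return noiseless_chain


class TestLandmarkRegressors:
    def test_four_scalar_models_per_landmark(self, tracked):
        reg = tracked["track"]["regressor"]
        assert len(reg.landmark_names) == 22
        assert reg.n_models == 22 * 4       # u, v in each of two views

    def test_trained_on_exactly_m_frames(self, tracked):
        assert len(tracked["track"]["annotations"].frames) == 10

    def test_retraining_is_deterministic(self, tracked):
        ann = tracked["track"]["annotations"]
        feats = tracked["sim"]["features"]
        a = train_landmark_regressors(ann, feats, C=1e6, epsilon=0.01)
        b = train_landmark_regressors(ann, feats, C=1e6, epsilon=0.01)
        for key in a.weights:
            np.testing.assert_array_equal(a.weights[key], b.weights[key])

    def test_heldout_rmse_below_half_pixel_on_lowrank_motion(self, rng):
        """Noiseless affine features of low-rank motion are recovered
        almost exactly on held-out frames."""
        # landmarks moving inside a 6-dimensional affine family
        T, N = 120, 5
        basis = np.stack([np.sin(2 * np.pi * k * np.arange(T) / T + k)
                          for k in range(1, 4)] + [np.arange(T) / T], axis=1)
        mix_d = rng.normal(size=(4, 2 * N))
        mix_l = rng.normal(size=(4, 2 * N))
        uv_d = (100 + 40 * basis @ mix_d).reshape(T, N, 2)
        uv_l = (100 + 40 * basis @ mix_l).reshape(T, N, 2)
        names = tuple(f"p{i}" for i in range(N))
        obs_d = Observations2D("ventrodorsal", names, uv_d)
        obs_l = Observations2D("lateral", names, uv_l)
        from quailkin.features import synthesize_features
        feats = synthesize_features(obs_d, obs_l, noise_sd=0.0,
                                    n_distractors=0, seed=2)
        frames = select_training_frames(T, 10)
        ann = annotate_from_observations(obs_d, obs_l, frames)
        reg = train_landmark_regressors(ann, feats, C=1e6, epsilon=0.01)
        pred = predict_landmarks(reg, feats)
        for view, truth in (("ventrodorsal", obs_d), ("lateral", obs_l)):
            tab = evaluate_localization(pred[view], truth)
            pooled = tab[tab.landmark == "__pooled__"].rmse_px.iloc[0]
            assert pooled < 0.5

    def test_training_frame_predictions_inside_tube(self, tracked):
        ann = tracked["track"]["annotations"]
        pred = tracked["track"]["predicted"]
        eps = tracked["track"]["regressor"].epsilon
        for view in ("ventrodorsal", "lateral"):
            p = pred[view]
            for lm in ann.landmarks[:5]:
                j = p.landmark_names.index(lm)
                truth = ann.positions(lm, view)
                got = p.uv[np.array(ann.frames) - 1, j]
                assert np.abs(got - truth).max() <= eps + 1e-3

    def test_zero_features_predict_intercepts(self, tracked):
        reg = tracked["track"]["regressor"]
        X = np.tile(reg.feature_mean, (3, 1))  # standardizes to zero
        pred = reg.predict(X)
        for view in pred:
            for j, lm in enumerate(pred[view].landmark_names):
                for k, coord in enumerate(("u", "v")):
                    b = reg.intercepts[(lm, view, coord)]
                    np.testing.assert_allclose(pred[view].uv[:, j, k], b)

    def test_model_json_round_trip(self, tracked):
        reg = tracked["track"]["regressor"]
        again = LandmarkRegressor.from_json(reg.to_json())
        X = tracked["sim"]["features"].X[:7]
        a, b = reg.predict(X), again.predict(X)
        for view in a:
            np.testing.assert_allclose(a[view].uv, b[view].uv, atol=1e-12)


class TestEvaluateLocalization:
    def _obs(self, uv):
        names = tuple(f"p{i}" for i in range(uv.shape[1]))
        return Observations2D("lateral", names, uv)

    def test_zero_error_and_constant_offset(self, rng):
        uv = rng.normal(size=(10, 3, 2))
        same = evaluate_localization(self._obs(uv), self._obs(uv.copy()))
        assert np.allclose(same.rmse_px, 0.0)
        off = uv.copy()
        off[..., 0] += 1.0
        tab = evaluate_localization(self._obs(off), self._obs(uv))
        np.testing.assert_allclose(tab.rmse_px, 1.0)

    def test_matches_direct_formula(self, rng):
        a, b = rng.normal(size=(6, 2, 2)), rng.normal(size=(6, 2, 2))
        tab = evaluate_localization(self._obs(a), self._obs(b))
        want = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1)))
        assert tab[tab.landmark == "__pooled__"].rmse_px.iloc[0] == \
            pytest.approx(want)


def test_annotation_set_validation():
    import pandas as pd
    table = pd.DataFrame({"frame": [1], "landmark": ["p0"],
                          "view": ["lateral"], "u": [1.0], "v": [2.0]})
    with pytest.raises(ValueError, match="unique"):
        AnnotationSet(sequence_length=5, frames=(1, 1), table=table)
    with pytest.raises(ValueError, match=r"\[1, L\]"):
        AnnotationSet(sequence_length=5, frames=(0, 2), table=table)
    ann = AnnotationSet(sequence_length=5, frames=(1,), table=table)
    with pytest.raises(ValueError, match="missing annotation"):
        ann.positions("p0", "ventrodorsal")
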