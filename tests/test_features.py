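"""Feature front end: windows, PCA and LDA against independent oracles."""

import numpy as np
import pytest

import visparc as vp
from visparc.errors import (
    AlignmentError,
    ClassSizeError,
    DegenerateCovarianceError,
    LengthError,
    ValidationError,
)
from visparc.features import reconstruct_pca
from visparc.types import Recording, Trial


def _rec(responses, trials, frame_rate=10.0):
    responses = np.asarray(responses, dtype=float)
    return Recording(
        responses=responses,
        unit_labels=np.ones(responses.shape[0], dtype=int),
        trials=trials,
        frame_rate=frame_rate,
        mode="twophoton",
    )


class TestTrialAverage:
    def test_identical_trials_return_the_trial(self):
        rec = _rec([[1.0, 2.0, 1.0, 2.0]], [Trial(0, 0, 2), Trial(0, 2, 2)])
        out = vp.trial_average(rec)
        assert np.allclose(out, [[1.0, 2.0]])

    def test_hand_computed_mean(self):
        rec = _rec([[0.0, 2.0, 2.0, 4.0]], [Trial(0, 0, 2), Trial(0, 2, 2)])
        assert np.allclose(vp.trial_average(rec), [[1.0, 3.0]])

    def test_request_order_is_canonicalized(self):
        resp = [[1.0, 2.0, 3.0, 4.0]]
        rec = _rec(resp, [Trial(1, 0, 2), Trial(2, 2, 2)])
        assert np.array_equal(vp.trial_average(rec, {2, 1}), vp.trial_average(rec, {1, 2}))
        # blocks ordered by ascending stimulus id
        assert np.allclose(vp.trial_average(rec, {2, 1}), [[1.0, 2.0, 3.0, 4.0]])

    def test_mismatched_trial_lengths_raise(self):
        rec = _rec([[1.0, 2.0, 3.0, 4.0]], [Trial(0, 0, 2), Trial(0, 2, 1)])
        with pytest.raises(AlignmentError):
            vp.trial_average(rec)

    def test_unknown_stimulus_raises(self):
        rec = _rec([[1.0, 2.0]], [Trial(0, 0, 2)])
        with pytest.raises(ValidationError):
            vp.trial_average(rec, {5})


class TestTakeResting:
    @pytest.mark.parametrize(
        "total_s,trim,dur", [(900, 50, 800), (300, 30, 240)]
    )
    def test_window_lengths(self, total_s, trim, dur):
        fr = 10.0
        rec = _rec(np.zeros((1, int(total_s * fr))), [], frame_rate=fr)
        out = vp.take_resting(rec, trim, trim, dur)
        assert out.shape[1] == int(dur * fr)

    def test_excess_duration_raises(self):
        rec = _rec(np.zeros((1, 100)), [], frame_rate=10.0)
        with pytest.raises(LengthError):
            vp.take_resting(rec, 2, 2, 20)

    def test_window_starts_after_trials_and_trim(self):
        T = 200
        resp = np.arange(T, dtype=float)[None, :]
        rec = _rec(resp, [Trial(0, 0, 50)], frame_rate=10.0)
        out = vp.take_resting(rec, 2.0, 0.0, 5.0)
        assert out[0, 0] == 50 + 20 and out.shape[1] == 50


class TestPCA:
    def test_printed_toy_eigenvalues(self):
        # direct 1/n covariance eigendecomposition of the 4-point toy
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 0.5], [0.0, -0.5]])
        model = vp.fit_pca(X, n_kept=2)
        assert np.allclose(model.eigenvalues[:2], [0.5, 0.125])

    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.standard_normal(20), [1.0, 2.0, -1.0])
        model = vp.fit_pca(X, n_kept=3)
        assert model.eigenvalues[0] > 0
        assert np.all(np.abs(model.eigenvalues[1:]) < 1e-10)

    def test_full_rank_reconstruction_identity(self, rng):
        X = rng.standard_normal((12, 5))
        model = vp.fit_pca(X, n_kept=5)
        scores = vp.project_pca(model, X)
        assert np.allclose(reconstruct_pca(model, scores), X - X.mean(axis=0), atol=1e-8)

    def test_projection_of_mean_and_component(self, rng):
        X = rng.standard_normal((30, 4))
        model = vp.fit_pca(X, n_kept=4)
        assert np.allclose(vp.project_pca(model, model.mean), 0.0, atol=1e-10)
        out = vp.project_pca(model, model.mean + model.components[:, 0])
        expected = np.zeros(4)
        expected[0] = 1.0
        assert np.allclose(out, expected, atol=1e-10)

    def test_reconstruction_error_decreases_with_k(self, rng):
        X = rng.standard_normal((40, 8))
        errs = []
        for k in range(1, 9):
            m = vp.fit_pca(X, n_kept=k)
            rec = reconstruct_pca(m, vp.project_pca(m, X))
            errs.append(np.sum((rec - (X - X.mean(axis=0))) ** 2))
        assert all(e2 <= e1 + 1e-10 for e1, e2 in zip(errs, errs[1:]))

    def test_energy_conservation(self, rng):
        X = rng.standard_normal((25, 6))
        model = vp.fit_pca(X, n_kept=6)
        assert model.eigenvalues.sum() == pytest.approx(model.total_variance, rel=1e-8)

    def test_gram_path_matches_direct_path(self, rng):
        # few units, many timepoints triggers the Gram-matrix route
        X = rng.standard_normal((30, 2000))
        direct = np.linalg.eigvalsh(np.cov(X.T, bias=True))[::-1]
        model = vp.fit_pca(X, n_kept=10)
        assert np.allclose(model.eigenvalues[:10], direct[:10], atol=1e-8)
        assert np.allclose(model.components.T @ model.components, np.eye(10), atol=1e-8)

    def test_variance_fraction_selection(self, rng):
        X = rng.standard_normal((50, 10)) * np.array([5.0] + [0.1] * 9)
        model = vp.fit_pca(X, n_kept=0.9)
        assert model.n_kept == 1

    def test_constant_data_rejected(self):
        with pytest.raises(DegenerateCovarianceError):
            vp.fit_pca(np.ones((5, 5)))


class TestLDA:
    def test_two_class_direction_matches_angle_search_oracle(self, rng):
        # informative axis 0, noise axis 1; brute-force Fisher-ratio maximization
        n = 200
        X = np.vstack(
            [
                rng.normal([-1.0, 0.0], [1.0, 1.0], size=(n, 2)),
                rng.normal([1.0, 0.0], [1.0, 1.0], size=(n, 2)),
            ]
        )
        y = np.repeat([1, 2], n)

        def fisher(w):
            w = w / np.linalg.norm(w)
            p = X @ w
            mu = p.mean()
            between = sum((p[y == c].mean() - mu) ** 2 for c in (1, 2)) / 2
            return between / p.var()

        angles = np.linspace(0, np.pi, 2000, endpoint=False)
        best = max(angles, key=lambda a: fisher(np.array([np.cos(a), np.sin(a)])))
        oracle = np.array([np.cos(best), np.sin(best)])
        model = vp.fit_lda(X, y)
        w = model.projection[:, 0]
        assert abs(abs(oracle @ w) - 1.0) < 1e-2

    def test_identical_class_means_rejected(self):
        X = np.vstack([np.eye(3), np.eye(3)])
        y = np.repeat([1, 2], 3)
        with pytest.raises(DegenerateCovarianceError):
            vp.fit_lda(X, y)

    def test_at_most_c_minus_1_directions(self, rng):
        X = rng.standard_normal((120, 10)) + np.repeat(rng.standard_normal((6, 10)), 20, axis=0)
        y = np.repeat(np.arange(1, 7), 20)
        model = vp.fit_lda(X, y)
        assert model.projection.shape[1] <= 5

    def test_projection_of_global_mean_is_zero(self, rng):
        X = rng.standard_normal((40, 3)) + np.repeat([[0.0], [2.0]], 20, axis=0)
        y = np.repeat([1, 2], 20)
        model = vp.fit_lda(X, y)
        assert np.allclose(vp.project_lda(model, model.global_mean), 0.0, atol=1e-10)
        assert vp.project_lda(model, X).shape == (40, 1)

    def test_first_direction_beats_random_directions(self, rng):
        X = np.vstack(
            [rng.normal(-1.0, 1.0, size=(100, 4)), rng.normal(1.0, 1.0, size=(100, 4))]
        )
        y = np.repeat([1, 2], 100)
        model = vp.fit_lda(X, y)

        def ratio(w):
            p = X @ (w / np.linalg.norm(w))
            mu = p.mean()
            b = sum((p[y == c].mean() - mu) ** 2 for c in (1, 2)) / 2
            return b / p.var()

        w1 = model.projection[:, 0]
        rand = rng.standard_normal((50, 4))
        assert all(ratio(w1) >= ratio(r) - 1e-9 for r in rand)

    def test_small_class_rejected(self):
        X = np.arange(8, dtype=float).reshape(4, 2)
        with pytest.raises(ClassSizeError):
            vp.fit_lda(X, np.array([1, 1, 1, 2]))


class TestPipeline:
    def test_deterministic_given_data(self, in_map_features):
        X, labels = in_map_features
        a, _, _ = vp.fit_transform_pipeline(X, labels)
        b, _, _ = vp.fit_transform_pipeline(X, labels)
        assert np.array_equal(a.features, b.features)

    def test_zscore_rows(self, rng):
        X = rng.standard_normal((5, 100)) * 3 + 7
        Z = vp.zscore_rows(X)
        assert np.allclose(Z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=1), 1, atol=1e-12)
        assert np.allclose(vp.zscore_rows(np.ones((2, 10))), 0.0)
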