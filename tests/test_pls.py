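"""SIMPLS solver and VIP scoring."""

import numpy as np
import pytest

from plsnet import SIMPLS, center, explained_variation, plsfs, simpls_fit, vip_scores
from plsnet.exceptions import DegenerateInputError, DimensionError
from plsnet.pls import PLSModel

from _oracles import nipals_pls1_cov2, simpls_cov2


def random_centered(seed, n, p):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X - X.mean(axis=0), y - y.mean()


class TestCenter:
    def test_subtracts_column_means(self):
        X, y = center([[1.0], [2.0], [3.0]], [5.0, 5.0, 5.0])
        np.testing.assert_allclose(X[:, 0], [-1, 0, 1])
        np.testing.assert_allclose(y, [0, 0, 0])

    def test_idempotent_on_centered_input(self):
        X, y = center([[-1.0], [0.0], [1.0]], [1.0, -1.0, 0.0])
        X2, y2 = center(X, y)
        np.testing.assert_array_equal(X, X2)
        np.testing.assert_array_equal(y, y2)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DimensionError):
            center([[1.0], [2.0], [3.0]], [1.0, 2.0])


class TestSimplsFit:
    def test_first_direction_is_normalized_covariance(self):
        X, y = random_centered(0, 15, 6)
        model = simpls_fit(X, y, 1)
        expected = X.T @ y
        expected /= np.linalg.norm(expected)
        cosine = abs(model.directions[:, 0] @ expected)
        assert cosine >= 1 - 1e-10

    def test_perfect_single_component_fit(self):
        # two orthonormal columns, response equal to the first
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]]) / np.sqrt(2)
        y = X[:, 0].copy()
        model = simpls_fit(X, y, 1)
        np.testing.assert_allclose(np.abs(model.directions[:, 0]), [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(model.explained, [1.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_model_invariants(self, seed):
        X, y = random_centered(seed, 12, 5)
        model = simpls_fit(X, y, 4)
        # unit-norm directions
        norms = np.linalg.norm(model.directions, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)
        # mutually orthogonal score vectors
        P = model.components
        for i in range(model.n_components):
            for j in range(i):
                bound = 1e-8 * np.linalg.norm(P[:, i]) * np.linalg.norm(P[:, j])
                assert abs(P[:, i] @ P[:, j]) <= bound
        # explained variation in [0, 1], cumulative sum non-decreasing
        assert np.all(model.explained >= 0) and np.all(model.explained <= 1)
        assert np.all(np.diff(np.cumsum(model.explained)) >= 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_projection_deflation_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        n = int(rng.integers(8, 21))
        p = int(rng.integers(2, 9))
        m = int(rng.integers(1, min(5, p + 1)))
        X, y = random_centered(seed, n, p)
        model = simpls_fit(X, y, m)
        expected = nipals_pls1_cov2(X, y, m)
        got = simpls_cov2(model, X, y)
        k = min(len(expected), len(got))
        assert k >= 1
        np.testing.assert_allclose(got[:k], expected[:k], atol=1e-8, rtol=1e-8)

    def test_sign_convention_largest_entry_positive(self):
        X, y = random_centered(3, 20, 6)
        model = simpls_fit(X, y, 3)
        for i in range(model.n_components):
            v = model.directions[:, i]
            assert v[np.argmax(np.abs(v))] > 0

    def test_rank_deficient_design_truncates(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 2))
        X = np.column_stack([base, base @ rng.normal(size=(2, 3))])
        X -= X.mean(axis=0)
        y = X @ rng.normal(size=5)
        y -= y.mean()
        model = simpls_fit(X, y, 4)
        assert model.n_components <= 2
        assert model.truncated

    def test_invalid_inputs(self):
        X, y = random_centered(0, 10, 3)
        with pytest.raises(ValueError):
            simpls_fit(X, y, 0)
        with pytest.raises(DegenerateInputError):
            simpls_fit(np.zeros((10, 3)), y, 1)


class TestExplainedVariation:
    def test_response_equal_to_component_gives_one(self):
        X, y = random_centered(4, 12, 4)
        model = simpls_fit(X, y, 1)
        psi = explained_variation(model, model.components[:, 0])
        np.testing.assert_allclose(psi, [1.0], atol=1e-12)

    def test_orthogonal_response_gives_zero(self):
        t = np.array([1.0, -1.0, 1.0, -1.0])
        resp = np.array([1.0, 1.0, -1.0, -1.0])  # centered, orthogonal to t
        model = PLSModel(
            directions=np.ones((1, 1)),
            components=t[:, None],
            explained=np.array([1.0]),
            n_components=1,
        )
        np.testing.assert_allclose(explained_variation(model, resp), [0.0], atol=1e-12)

    def test_noisy_response_matches_direct_correlation(self):
        rng = np.random.default_rng(9)
        t = rng.normal(size=200)
        resp = t + rng.normal(scale=0.5, size=200)
        model = PLSModel(
            directions=np.ones((1, 1)),
            components=t[:, None],
            explained=np.array([1.0]),
            n_components=1,
        )
        expected = np.corrcoef(t, resp)[0, 1] ** 2
        np.testing.assert_allclose(explained_variation(model, resp), [expected], atol=1e-12)


class TestVIP:
    def _model(self, directions, psi):
        p, m = directions.shape
        return PLSModel(
            directions=directions,
            components=np.zeros((2, m)),
            explained=np.asarray(psi, dtype=float),
            n_components=m,
        )

    def test_uniform_weights_give_unit_vip(self):
        p = 4
        model = simpls_fit(*self._uniform_instance(p), 1)
        result = vip_scores(model, self._uniform_instance(p)[1])
        np.testing.assert_allclose(result.scores, np.ones(p), atol=1e-8)

    @staticmethod
    def _uniform_instance(p):
        # response = sum of p orthonormal columns -> direction 1/sqrt(p) each
        X = np.vstack([np.eye(p), -np.eye(p)]) / np.sqrt(2)
        y = X.sum(axis=1)
        return X, y

    def test_one_hot_direction_concentrates_vip(self):
        X = np.vstack([np.eye(3), -np.eye(3)])
        y = X[:, 0].copy()
        model = simpls_fit(X, y, 1)
        result = vip_scores(model, y)
        np.testing.assert_allclose(result.scores, [np.sqrt(3), 0, 0], atol=1e-10)

    def test_two_component_hand_arithmetic(self):
        # psi = (0.8, 0.2) with explicit unit-norm weight vectors
        v1 = np.array([0.6, 0.8, 0.0])
        v2 = np.array([0.0, 0.0, 1.0])
        psi = np.array([0.8, 0.2])
        from plsnet.pls import _vip_from_fit

        scores, degenerate = _vip_from_fit(np.column_stack([v1, v2]), psi)
        assert not degenerate
        expected = np.sqrt(
            3 * np.array([0.8 * 0.36, 0.8 * 0.64, 0.2 * 1.0]) / 1.0
        )
        np.testing.assert_allclose(scores, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_squared_vip_sums_to_feature_count(self, seed):
        X, y = random_centered(seed + 50, 15, 7)
        result = plsfs(X, y, 3)
        assert not result.degenerate
        np.testing.assert_allclose((result.scores**2).sum(), 7.0, atol=1e-8)


class TestPlsfs:
    def test_signal_feature_wins(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 5))
        y = 3.0 * X[:, 2]
        result = plsfs(X, y, 1)
        assert np.argmax(result.scores) == 2
        assert result.scores[2] > np.max(np.delete(result.scores, 2))

    def test_duplicated_features_share_scores(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(30, 3))
        X = np.column_stack([base, base[:, 0]])
        y = base @ [1.0, -0.5, 0.2]
        result = plsfs(X, y, 2)
        np.testing.assert_allclose(result.scores[0], result.scores[3], atol=1e-10)

    def test_constant_response_is_degenerate(self):
        rng = np.random.default_rng(4)
        result = plsfs(rng.normal(size=(10, 4)), np.full(10, 2.5), 2)
        assert result.degenerate
        np.testing.assert_array_equal(result.scores, np.zeros(4))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        perm = rng.permutation(6)
        a = plsfs(X, y, 3).scores
        b = plsfs(X[:, perm], y, 3).scores
        np.testing.assert_allclose(a[perm], b, atol=1e-10)

    def test_pure_noise_has_no_systematic_winner(self):
        # mean VIP across repetitions is flat over features for a noise response
        rng = np.random.default_rng(6)
        p, reps = 5, 200
        totals = np.zeros(p)
        for _ in range(reps):
            X = rng.normal(size=(20, p))
            y = rng.normal(size=20)
            totals += plsfs(X, y, 2).scores
        means = totals / reps
        spread = means.std()
        # no feature's mean deviates from the grand mean by > 3 empirical sd
        assert np.all(np.abs(means - means.mean()) < 3 * spread + 1e-12)
        # and the relative spread itself is small
        assert spread / means.mean() < 0.05


class TestEstimator:
    def test_identifies_informative_feature_and_predicts(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        y = 2.0 * X[:, 1] + rng.normal(scale=0.1, size=60)
        model = SIMPLS(n_components=2).fit(X, y)
        assert int(np.argmax(model.vip_)) == 1
        assert model.score(X, y) > 0.95  # R^2 via RegressorMixin

    def test_get_params_round_trip(self):
        model = SIMPLS(n_components=3, scale=True)
        clone = SIMPLS(**model.get_params())
        assert clone.get_params() == model.get_params()
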