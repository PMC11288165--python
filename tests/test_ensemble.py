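import numpy as np
import pytest
from sklearn.preprocessing import StandardScaler

from gramclass._cnn import CNNConfig, Conv1DClassifier
from gramclass.ensemble import (
    MEMBER_NAMES,
    derive_member_params,
    fit_ensemble,
    mode_vote,
    tune_hyperparameter,
    variance_gate,
)
from gramclass.ngram_features import FeatureMatrix, build_feature_matrix
from gramclass.selection import GAConfig
from gramclass.synthetic import SyntheticSpec, generate_dataset


def make_fm(X, y):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        X=X,
        y=np.asarray(y),
        feature_names=[f"f{i}" for i in range(X.shape[1])],
        class_names=[f"c{i}" for i in range(int(np.max(y)) + 1)],
    )


@pytest.fixture(scope="module")
def strong_fm():
    spec = SyntheticSpec(n_classes=3, n_per_class=25, length=300, planting_rate=25.0, seed=4)
    sset, _ = generate_dataset(spec)
    return build_feature_matrix(sset, 1, 3)


class TestDeriveMemberParams:
    def test_formula_arithmetic(self):
        rng = np.random.default_rng(0)
        fm = make_fm(rng.poisson(4, size=(30, 30)), np.repeat([0, 1, 2], 10))
        p = derive_member_params(fm, GAConfig())
        assert p.features_per_class == 10
        assert p.rf_trees == 30 and p.rf_depth == 3
        assert p.mlp_hidden == 30
        assert p.rf_max_features == 4  # floor(log2(30))

    def test_constant_matrix_falls_back_to_empirical_priors(self):
        fm = make_fm(np.ones((12, 5)), np.repeat([0, 1, 2], [6, 3, 3]))
        p = derive_member_params(fm, GAConfig())
        assert p.largest_feature_variance == 0.0
        assert p.nb_priors_fallback
        assert p.nb_priors == pytest.approx([0.5, 0.25, 0.25])

    def test_lvf_matches_independent_recompute(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 8)) * rng.uniform(0.5, 3, size=8)
        fm = make_fm(np.abs(X), np.repeat([0, 1], 20))
        p = derive_member_params(fm, GAConfig())
        expected = max(np.var(np.abs(X)[:, j]) for j in range(8))
        assert p.largest_feature_variance == pytest.approx(expected)
        assert p.total_feature_variance == pytest.approx(np.abs(X).var(axis=0).sum())

    def test_priors_sum_to_one(self, strong_fm):
        p = derive_member_params(strong_fm, GAConfig())
        assert sum(p.nb_priors) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        fm = FeatureMatrix(
            X=np.ones((4, 3)), y=np.zeros(4, dtype=int),
            feature_names=["a", "b", "c"], class_names=["only"],
        )
        with pytest.raises(ValueError):
            derive_member_params(fm, GAConfig())


class TestVarianceGate:
    def test_equal_variance_boundary_gates_everything(self):
        x = np.vstack([np.tile([0.0, 1.0], 5) for _ in range(4)])  # equal variances
        assert np.all(variance_gate(x, v_h=1.0) == 0)

    def test_single_live_channel_survives(self):
        x = np.ones((4, 10))
        x[2] = np.linspace(0, 5, 10)
        gated = variance_gate(x, v_h=1.0)
        assert np.all(gated[2] == x[2])
        assert np.all(gated[[0, 1, 3]] == 0)

    def test_matches_brute_force_thresholding(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 20)) * rng.uniform(0.2, 2.0, size=(8, 1))
        gated = variance_gate(x, v_h=0.5)
        variances = [np.var(x[c]) for c in range(8)]
        threshold = 0.5 * np.mean(variances)
        for c in range(8):
            if variances[c] > threshold:
                np.testing.assert_array_equal(gated[c], x[c])
            else:
                assert np.all(gated[c] == 0)

    def test_batched_input_gates_per_sample(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 6, 12))
        batched = variance_gate(x, v_h=0.8)
        for b in range(3):
            np.testing.assert_array_equal(batched[b], variance_gate(x[b], v_h=0.8))


class TestTuneHyperparameter:
    def test_fixed_point_when_accuracy_unchanged(self):
        assert tune_hyperparameter(2.5, 0.8, 0.8, 0.5) == 2.5

    def test_improvement_scales_value(self):
        assert tune_hyperparameter(1.0, 0.7, 0.8, 0.5) == pytest.approx(1.05)

    def test_clamped_to_bounds(self):
        assert tune_hyperparameter(1.0, 0.0, 1.0, 1.0, bounds=(0.5, 1.5)) == 1.5
        assert tune_hyperparameter(1.0, 1.0, 0.0, 1.0, bounds=(0.999, 2.0)) == 0.999


class TestCNN:
    def test_separable_data_learned(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 40))
        y = (rng.random(120) < 0.5).astype(int)
        X[y == 1, :5] += 2.0
        Xs = StandardScaler().fit_transform(X)
        clf = Conv1DClassifier(CNNConfig(epochs=30, seed=1)).fit(Xs, y)
        assert clf.score(Xs, y) >= 0.95

    def test_probability_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 30))
        y = rng.integers(0, 3, size=40)
        clf = Conv1DClassifier(CNNConfig(epochs=2, seed=0)).fit(X, y)
        probs = clf.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_deterministic_refit(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 25))
        y = rng.integers(0, 2, size=50)
        p1 = Conv1DClassifier(CNNConfig(epochs=4, seed=9)).fit(X, y).predict_proba(X)
        p2 = Conv1DClassifier(CNNConfig(epochs=4, seed=9)).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_feature_length_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            Conv1DClassifier(CNNConfig(epochs=1)).fit(np.ones((10, 2)), np.arange(10) % 2)

    def test_config_ranges_enforced(self):
        with pytest.raises(ValueError):
            CNNConfig(channels=(32, 128)).validate()
        with pytest.raises(ValueError):
            CNNConfig(kernels=(3, 7)).validate()


class TestModeVote:
    def vote_oracle(self, votes, probs):
        """Exhaustive counting oracle, independent of the implementation."""
        n_classes = probs.shape[2]
        counts = [sum(1 for v in votes if v == c) for c in range(n_classes)]
        top = max(counts)
        tied = [c for c in range(n_classes) if counts[c] == top]
        if len(tied) == 1:
            return tied[0]
        sums = {c: sum(probs[m, 0, c] for m in range(len(votes))) for c in tied}
        best = max(sums.values())
        return min(c for c in tied if sums[c] == best)

    def test_strict_majority(self):
        labels = np.array([[0], [0], [0], [1], [1], [2]])
        probs = np.full((6, 1, 3), 1 / 3)
        assert mode_vote(labels, probs)[0] == 0

    def test_tie_broken_by_summed_probability(self):
        labels = np.array([[0], [0], [1], [1], [2], [2]])
        probs = np.zeros((6, 1, 3))
        for m, weights in enumerate(
            [(0.9, 0.05, 0.05), (0.6, 0.3, 0.1), (0.1, 0.8, 0.1),
             (0.2, 0.7, 0.1), (0.1, 0.2, 0.7), (0.0, 0.15, 0.85)]
        ):
            probs[m, 0] = weights
        # summed: A=1.9, B=2.2, C=1.85 -> B wins
        assert mode_vote(labels, probs)[0] == 1

    def test_exhaustive_patterns_match_oracle(self):
        rng = np.random.default_rng(6)
        probs = rng.dirichlet(np.ones(3), size=6)[:, None, :]  # fixed member probs
        for pattern in range(3**6):
            votes = [(pattern // 3**m) % 3 for m in range(6)]
            labels = np.array(votes)[:, None]
            expected = self.vote_oracle(votes, probs)
            assert mode_vote(labels, probs)[0] == expected

    def test_unanimity(self):
        labels = np.tile(np.array([2, 0, 1]), (6, 1))
        probs = np.full((6, 3, 3), 1 / 3)
        np.testing.assert_array_equal(mode_vote(labels, probs), [2, 0, 1])

    def test_member_permutation_invariance(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, size=(6, 10))
        probs = rng.dirichlet(np.ones(3), size=(6, 10))
        perm = rng.permutation(6)
        np.testing.assert_array_equal(
            mode_vote(labels, probs), mode_vote(labels[perm], probs[perm])
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mode_vote(np.zeros((6, 4), dtype=int), np.zeros((6, 5, 3)))


class TestEnsembleFit:
    def test_members_beat_chance_on_strong_signal(self, strong_fm):
        model = fit_ensemble(strong_fm, GAConfig(), CNNConfig(epochs=10, seed=0), seed=3)
        labels, probs = model.predict_members(strong_fm.X)
        chance = 1 / strong_fm.n_classes
        for m, name in enumerate(MEMBER_NAMES):
            acc = np.mean(labels[m] == strong_fm.y)
            assert acc > chance + 0.15, f"{name} at {acc:.2f}"
        np.testing.assert_allclose(
            probs.reshape(-1, strong_fm.n_classes).sum(axis=1), 1.0, atol=1e-6
        )

    def test_fitted_flag_and_class_order(self, strong_fm):
        model = fit_ensemble(strong_fm, GAConfig(), CNNConfig(epochs=2, seed=0), seed=3)
        assert model.fitted
        assert model.class_names == strong_fm.class_names

    def test_refit_reproduces_predictions(self, strong_fm):
        kw = dict(ga=GAConfig(), seed=5)
        m1 = fit_ensemble(strong_fm, kw["ga"], CNNConfig(epochs=3, seed=2), seed=kw["seed"])
        m2 = fit_ensemble(strong_fm, kw["ga"], CNNConfig(epochs=3, seed=2), seed=kw["seed"])
        l1, p1 = m1.predict_members(strong_fm.X)
        l2, p2 = m2.predict_members(strong_fm.X)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(p1, p2)

    def test_predict_before_fit_rejected(self, strong_fm):
        from gramclass.ensemble import EnsembleModel, derive_member_params

        model = EnsembleModel(
            class_names=strong_fm.class_names,
            params=derive_member_params(strong_fm, GAConfig()),
            cnn_config=CNNConfig(),
        )
        with pytest.raises(RuntimeError):
            model.predict(strong_fm.X)
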