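import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from somnoscore.core import N_STAGES, stage_codes
from somnoscore.simulate import (DEFAULT_FEATURE_PARAMS, GeneratorConfig,
                                 simulate_dataset)
from somnoscore.staging import (SleepStager, backward_pass, build_composite,
                                forward_pass, leaf_class_probs)


def _single_leaf_forest(n_trees, y):
    """Forest whose trees cannot split (constant features): one leaf each."""
    X = np.zeros((len(y), 3))
    return RandomForestClassifier(n_estimators=n_trees, bootstrap=False,
                                  random_state=0).fit(X, y)


class TestLeafClassProbs:
    def test_single_leaf_returns_class_fractions(self):
        rf = _single_leaf_forest(1, [0, 0, 2])  # W, W, N2
        np.testing.assert_allclose(leaf_class_probs(rf, [[0, 0, 0]]),
                                   [[2 / 3, 0, 1 / 3, 0, 0]])

    def test_averaging_identical_trees_is_idempotent(self):
        one = leaf_class_probs(_single_leaf_forest(1, [0, 0, 2]), [[0, 0, 0]])
        two = leaf_class_probs(_single_leaf_forest(2, [0, 0, 2]), [[0, 0, 0]])
        np.testing.assert_allclose(one, two)

    def test_distributions_sum_to_one(self, rng):
        rf = RandomForestClassifier(n_estimators=10, random_state=0).fit(
            rng.normal(size=(100, 4)), rng.integers(0, 5, 100))
        probs = leaf_class_probs(rf, rng.normal(size=(20, 4)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_untrained_ensemble_rejected(self):
        with pytest.raises(ValueError, match="untrained"):
            leaf_class_probs(RandomForestClassifier(), [[0.0]])


class TestRecursions:
    E3 = np.zeros((3, 10))  # emissions are ignored by table transitions

    def test_identity_table_is_absorbing(self):
        alpha = forward_pass(self.E3, np.eye(5), [1, 0, 0, 0, 0])
        np.testing.assert_allclose(alpha, np.tile([1, 0, 0, 0, 0], (4, 1)))

    def test_uniform_table_gives_uniform_distributions(self):
        T = np.full((5, 5), 0.2)
        alpha = forward_pass(self.E3, T, [0.5, 0.5, 0, 0, 0])
        np.testing.assert_allclose(alpha[1:], 0.2)
        beta = backward_pass(self.E3, T, [0.2] * 5)
        np.testing.assert_allclose(beta[:-1], 0.2)

    def test_forward_matches_explicit_markov_propagation(self, rng):
        T = rng.random((5, 5))
        T /= T.sum(axis=1, keepdims=True)
        alpha0 = rng.random(5)
        alpha0 /= alpha0.sum()
        alpha = forward_pass(self.E3, T, alpha0)
        # independent oracle: explicit double loop over stages
        expected = alpha0.copy()
        for t in range(3):
            nxt = np.zeros(5)
            for s in range(5):
                for k in range(5):
                    nxt[s] += T[k, s] * expected[k]
            expected = nxt
            np.testing.assert_allclose(alpha[t + 1], expected, atol=1e-12)

    def test_backward_is_forward_on_reversed_sequence(self, rng):
        T = rng.random((5, 5))
        T /= T.sum(axis=1, keepdims=True)
        init = rng.random(5)
        init /= init.sum()
        E = np.zeros((6, 10))
        beta = backward_pass(E, T, init)
        alpha = forward_pass(E[::-1], T, init)
        np.testing.assert_allclose(beta[::-1], alpha, atol=1e-12)

    def test_distributions_always_sum_to_one(self, rng):
        T = rng.random((5, 5))
        T /= T.sum(axis=1, keepdims=True)
        alpha = forward_pass(np.zeros((20, 5)), T, [1, 0, 0, 0, 0])
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-12)


class TestComposite:
    def test_layout_for_thirteen_groups(self):
        x = build_composite(np.full(5, 0.2), np.full(65, 0.2), np.full(5, 0.2))
        assert x.shape == (75,)

    def test_first_epoch_uses_alpha0(self, small_stager, small_dataset):
        _, features, _ = small_dataset
        E = small_stager.emissions_.transform(features[5])
        X = small_stager._composite_matrix(E)
        np.testing.assert_allclose(X[0, :5], small_stager.alpha0_)
        np.testing.assert_allclose(X[-1, -5:], small_stager.beta_end_)

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_composite(np.zeros(4), np.zeros(65), np.zeros(5))
        with pytest.raises(ValueError):
            build_composite(np.zeros(5), np.zeros(63), np.zeros(5))


class TestSleepStager:
    def test_training_set_accuracy_bar(self, small_stager, small_dataset):
        _, features, stages = small_dataset
        assert small_stager.score(features[:5], stages[:5]) > 0.85

    def test_same_seed_is_bit_identical(self, small_dataset):
        _, features, stages = small_dataset
        runs = []
        for _ in range(2):
            m = SleepStager(n_estimators=15, random_state=3).fit(
                features[:3], stages[:3])
            runs.append(m.predict_proba_sequence(features[3]))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_missing_stage_in_labels_rejected(self, small_dataset):
        _, features, _ = small_dataset
        with pytest.raises(ValueError, match="N3"):
            SleepStager().fit(features[:2],
                              [["W", "N1", "N2", "R"] * 50] * 2)

    def test_prediction_rows_sum_to_one(self, small_stager, small_dataset):
        _, features, _ = small_dataset
        probs = small_stager.predict_proba_sequence(features[5])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_schema_mismatch_rejected(self, small_stager, small_dataset):
        _, features, _ = small_dataset
        crippled = SleepStager.__new__(SleepStager)
        crippled.__dict__.update(small_stager.__dict__)
        crippled.n_groups_ = 12
        with pytest.raises(ValueError, match="schema"):
            crippled.predict_proba_sequence(features[5])

    def test_temporal_context_beats_baselines(self, small_stager,
                                              small_dataset):
        """The architectural claim: alpha/beta context helps beyond both the
        majority stage and an emissions-only classifier."""
        _, features, stages = small_dataset
        full_acc = small_stager.score(features[5], stages[5])
        ablation = SleepStager(n_estimators=30, temporal_context=False,
                               random_state=5).fit(features[:5], stages[:5])
        abl_acc = ablation.score(features[5], stages[5])
        codes = np.concatenate([stage_codes(s) for s in stages[:5]])
        majority = np.bincount(codes, minlength=5).max() / codes.size
        assert full_acc > abl_acc
        assert full_acc > majority

    def test_grouped_importance_sums_to_one(self, small_stager):
        imp = small_stager.grouped_feature_importance()
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(imp) == {"alpha", "beta"} | set(
            small_stager.emissions_.group_names_)

    def test_emg_only_signal_dominates_importance(self):
        """When only the EMG family separates stages, its block should carry
        the largest importance among emission groups."""
        params = {k: v for k, v in DEFAULT_FEATURE_PARAMS.items()}
        params["orp"] = {"mu_match": 0.5, "mu_other": 0.5, "sd": 0.15}
        params["spindles"] = [DEFAULT_FEATURE_PARAMS["spindles"][2]] * 5
        params["rems"] = [DEFAULT_FEATURE_PARAMS["rems"][0]] * 5
        params["sems"] = [DEFAULT_FEATURE_PARAMS["sems"][0]] * 5
        params["hr"] = {"q_mean": [0.5] * 5, "q_sd": 0.15, "change_sd": 2.0}
        params["sao2"] = {"mean": [95.0] * 5, "mean_sd": 1.0,
                          "var_scale": [0.5] * 5}
        params["position_change"] = [0.05] * 5
        params["snores"] = [0.5] * 5
        config = GeneratorConfig(n_psgs=4, n_epochs=150, seed=21,
                                 feature_params=params)
        features, stages = simulate_dataset(config)
        m = SleepStager(n_estimators=25, random_state=2).fit(features, stages)
        imp = m.grouped_feature_importance()
        emission_groups = {k: v for k, v in imp.items()
                           if k not in ("alpha", "beta")}
        assert max(emission_groups, key=emission_groups.get) == "emg"

    def test_too_few_recordings_rejected(self, small_dataset):
        _, features, stages = small_dataset
        with pytest.raises(ValueError, match="at least 2"):
            SleepStager().fit(features[:1], stages[:1])
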