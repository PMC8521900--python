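"""The staging model: emissions + classifier-driven forward/backward recursions.

A random forest predicts the stage of epoch ``t`` from the composite vector

    x_t = [alpha_{t-1}, e_t, beta_{t+1}]

where ``e_t`` is the epoch's emission vector, ``alpha_{t-1}`` is the stage
distribution of the previous epoch given all emissions up to it, and
``beta_{t+1}`` is the next epoch's distribution given all emissions from it
onward.  Both context vectors are produced by recursions whose transition
kernels are themselves random forests over (conditioning stage one-hot,
emission vector):

    alpha_t(s) = sum_k P(s_t = s | s_{t-1} = k, e_t) * alpha_{t-1}(k)
    beta_t(s)  = sum_k P(s_t = s | s_{t+1} = k, e_t) * beta_{t+1}(k)

The sums are computed exactly: the transition forest is evaluated once per
conditioning stage (five one-hot inputs per epoch) and mixed by the incoming
distribution.  Class probabilities are leaf-fraction estimates — per tree,
the fraction of training instances of each class in the leaf containing the
input, averaged over the forest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .core import Hypnogram, N_STAGES, STAGES, stage_codes
from .emissions import EmissionModelSet


def leaf_class_probs(ensemble, X) -> np.ndarray:
    """Leaf-fraction class probabilities, expanded to the 5 canonical stages.

    This is the forest's ``predict_proba`` (per-tree leaf class fractions
    averaged over trees) with columns re-indexed so absent classes get
    probability zero.
    """
    try:
        raw = ensemble.predict_proba(np.asarray(X, dtype=float))
    except AttributeError as exc:
        raise ValueError("untrained ensemble") from exc
    out = np.zeros((raw.shape[0], N_STAGES))
    out[:, np.asarray(ensemble.classes_, dtype=np.intp)] = raw
    return out


def transition_tensor(transition_model, E: np.ndarray) -> np.ndarray:
    """Evaluate P(stage | conditioning stage, e_t) for every epoch.

    Returns a tensor of shape ``(n, 5, 5)`` indexed ``[epoch, conditioning
    stage, output stage]``.  ``transition_model`` may be a fitted forest over
    ``[one-hot(5), emissions]`` or a plain 5x5 row-stochastic array (an
    emission-independent transition table, mainly for testing against exact
    Markov-chain propagation).
    """
    E = np.asarray(E, dtype=float)
    n = E.shape[0]
    if isinstance(transition_model, np.ndarray):
        if transition_model.shape != (N_STAGES, N_STAGES):
            raise ValueError("transition table must be 5x5")
        return np.broadcast_to(transition_model, (n, N_STAGES, N_STAGES)).copy()
    X = np.zeros((N_STAGES * n, N_STAGES + E.shape[1]))
    for k in range(N_STAGES):
        X[k * n:(k + 1) * n, k] = 1.0
        X[k * n:(k + 1) * n, N_STAGES:] = E
    P = leaf_class_probs(transition_model, X)
    return P.reshape(N_STAGES, n, N_STAGES).transpose(1, 0, 2)


def forward_pass(E, transition_model, alpha0) -> np.ndarray:
    """Forward stage distributions ``alpha_0 .. alpha_n`` (shape (n+1, 5))."""
    T = transition_tensor(transition_model, E)
    n = T.shape[0]
    alpha = np.empty((n + 1, N_STAGES))
    alpha[0] = np.asarray(alpha0, dtype=float)
    for t in range(1, n + 1):
        a = T[t - 1].T @ alpha[t - 1]
        alpha[t] = a / a.sum()
    return alpha


def backward_pass(E, transition_model, beta_end) -> np.ndarray:
    """Backward stage distributions ``beta_1 .. beta_{n+1}`` (shape (n+1, 5)).

    Row ``i`` holds ``beta_{i+1}``; the last row is the boundary ``beta_{n+1}``.
    """
    T = transition_tensor(transition_model, E)
    n = T.shape[0]
    beta = np.empty((n + 1, N_STAGES))
    beta[n] = np.asarray(beta_end, dtype=float)
    for t in range(n, 0, -1):
        b = T[t - 1].T @ beta[t]
        beta[t - 1] = b / b.sum()
    return beta


def build_composite(alpha_prev, e_t, beta_next) -> np.ndarray:
    """Concatenate ``[alpha_{t-1}, e_t, beta_{t+1}]`` with validation."""
    alpha_prev = np.asarray(alpha_prev, dtype=float)
    beta_next = np.asarray(beta_next, dtype=float)
    e_t = np.asarray(e_t, dtype=float)
    if alpha_prev.shape != (N_STAGES,) or beta_next.shape != (N_STAGES,):
        raise ValueError("context vectors must have length 5")
    if e_t.size % N_STAGES != 0:
        raise ValueError("emission vector length must be a multiple of 5")
    return np.concatenate([alpha_prev, e_t, beta_next])


class SleepStager(BaseEstimator, ClassifierMixin):
    """Sequence classifier for 30-s sleep epochs.

    Parameters
    ----------
    n_estimators, min_samples_leaf, max_features
        Random-forest hyperparameters shared by the two transition forests
        and the final forest.
    emission_groups
        Optional explicit emission-group list (name, estimator) pairs;
        defaults to the 13-group layout of :mod:`somnoscore.emissions`.
    beta_end
        Boundary for the backward recursion: ``"last"`` (empirical last-epoch
        stage frequencies, symmetric to alpha_0) or ``"uniform"``.
    temporal_context
        If False, the final forest sees only the emission vector (an
        ablation without the alpha/beta context).
    random_state
        Seed controlling every source of randomness; identical seeds yield
        bit-identical fitted models and predictions.

    Fitted attributes carry trailing underscores: ``emissions_``,
    ``forward_rf_``, ``backward_rf_``, ``final_rf_``, ``alpha0_``,
    ``beta_end_``, ``n_groups_``.
    """

    def __init__(self, n_estimators: int = 100, min_samples_leaf: int = 5,
                 max_features="sqrt", emission_groups=None,
                 beta_end: str = "last", temporal_context: bool = True,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.emission_groups = emission_groups
        self.beta_end = beta_end
        self.temporal_context = temporal_context
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _rf(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features, random_state=seed, n_jobs=1)

    def fit(self, features_list: list[pd.DataFrame], stages_list) -> "SleepStager":
        """Fit emissions, transition forests and the final forest.

        ``features_list`` holds one per-epoch feature table per recording,
        ``stages_list`` the matching expert stage sequences.  Every stage
        must occur somewhere in the training labels.
        """
        if len(features_list) < 2:
            raise ValueError("need at least 2 recordings to train")
        codes_list = [stage_codes(s) for s in stages_list]
        present = np.unique(np.concatenate(codes_list))
        absent = [STAGES[i] for i in range(N_STAGES) if i not in present]
        if absent:
            raise ValueError(f"stage(s) absent from training labels: {absent}")

        seeds = np.random.SeedSequence(self.random_state).generate_state(4)
        all_df = pd.concat(features_list, ignore_index=True)
        all_codes = np.concatenate(codes_list)
        self.emissions_ = EmissionModelSet(
            groups=self.emission_groups, seed=int(seeds[0]) % (2**31)
        ).fit(all_df, all_codes)
        self.n_groups_ = len(self.emissions_.groups_)
        E_list = [self.emissions_.transform(df) for df in features_list]

        # boundary distributions
        firsts = np.array([c[0] for c in codes_list])
        lasts = np.array([c[-1] for c in codes_list])
        self.alpha0_ = (np.bincount(firsts, minlength=N_STAGES) + 1e-9)
        self.alpha0_ /= self.alpha0_.sum()
        if self.beta_end == "uniform":
            self.beta_end_ = np.full(N_STAGES, 1.0 / N_STAGES)
        else:
            self.beta_end_ = (np.bincount(lasts, minlength=N_STAGES) + 1e-9)
            self.beta_end_ /= self.beta_end_.sum()

        if self.temporal_context:
            # transition forests on (conditioning one-hot, e_t) -> s_t
            fX, fy, bX, by = [], [], [], []
            for E, c in zip(E_list, codes_list):
                eye = np.eye(N_STAGES)
                fX.append(np.hstack([eye[c[:-1]], E[1:]]))
                fy.append(c[1:])
                bX.append(np.hstack([eye[c[1:]], E[:-1]]))
                by.append(c[:-1])
            self.forward_rf_ = self._rf(int(seeds[1]) % (2**31)).fit(
                np.vstack(fX), np.concatenate(fy))
            self.backward_rf_ = self._rf(int(seeds[2]) % (2**31)).fit(
                np.vstack(bX), np.concatenate(by))
            # composite features with the same recursions used at inference
            X_final = np.vstack([self._composite_matrix(E) for E in E_list])
        else:
            self.forward_rf_ = self.backward_rf_ = None
            X_final = np.vstack(E_list)
        self.final_rf_ = self._rf(int(seeds[3]) % (2**31)).fit(
            X_final, all_codes)
        return self

    # ------------------------------------------------------------------
    def _composite_matrix(self, E: np.ndarray) -> np.ndarray:
        n = E.shape[0]
        alpha = forward_pass(E, self.forward_rf_, self.alpha0_)
        beta = backward_pass(E, self.backward_rf_, self.beta_end_)
        # epoch i (0-based): alpha_{t-1} = alpha[i], beta_{t+1} = beta[i+1]
        return np.hstack([alpha[:n], E, beta[1:n + 1]])

    def _check_schema(self, E: np.ndarray) -> None:
        if E.shape[1] != N_STAGES * self.n_groups_:
            raise ValueError(
                f"emission schema mismatch: expected {N_STAGES * self.n_groups_}"
                f" values, got {E.shape[1]}")

    def predict_proba_sequence(self, features: pd.DataFrame) -> np.ndarray:
        """Per-epoch stage distributions p_s(x_t) for one recording."""
        if not hasattr(self, "final_rf_"):
            raise ValueError("SleepStager is not fitted")
        E = self.emissions_.transform(features)
        self._check_schema(E)
        X = self._composite_matrix(E) if self.temporal_context else E
        probs = leaf_class_probs(self.final_rf_, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        return probs

    def predict_hypnogram(self, features: pd.DataFrame) -> Hypnogram:
        """Predict one recording's hypnogram with per-stage probabilities.

        The predicted stage is the argmax of the leaf-fraction probabilities;
        exact ties break by canonical stage order (W first).
        """
        return Hypnogram.from_probabilities(
            self.predict_proba_sequence(features))

    # sklearn-flavoured aliases over lists of recordings ----------------
    def predict(self, features_list) -> list[Hypnogram]:
        if isinstance(features_list, pd.DataFrame):
            return [self.predict_hypnogram(features_list)]
        return [self.predict_hypnogram(df) for df in features_list]

    def score(self, features_list, stages_list) -> float:
        """Mean per-epoch accuracy over recordings' pooled epochs."""
        hyps = self.predict(features_list)
        if isinstance(features_list, pd.DataFrame):
            stages_list = [stages_list]
        correct = total = 0
        for h, s in zip(hyps, stages_list):
            correct += int(np.sum(h.codes == stage_codes(s)))
            total += len(h)
        return correct / total

    def grouped_feature_importance(self) -> dict[str, float]:
        """Mean-decrease-impurity importance summed per feature block.

        Blocks: the alpha context, each emission group, the beta context.
        Fractions sum to 1.
        """
        imp = self.final_rf_.feature_importances_
        out: dict[str, float] = {}
        offset = 0
        if self.temporal_context:
            out["alpha"] = float(imp[:N_STAGES].sum())
            offset = N_STAGES
        for k, name in enumerate(self.emissions_.group_names_):
            lo = offset + k * N_STAGES
            out[name] = float(imp[lo:lo + N_STAGES].sum())
        if self.temporal_context:
            out["beta"] = float(imp[-N_STAGES:].sum())
        return out
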