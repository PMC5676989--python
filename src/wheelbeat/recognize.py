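"""Identity scoring and decisions.

Four enrolment model families produce, for any feature vector, a score per
enrolled identity, normalised to [0, 1] and summing to one so that scores
are comparable across frames:

- ``svm``  — RBF support vector machine with logistic (Platt) probability
  calibration fitted on training scores (per-frame min-max rescaling is
  deliberately not used: it would destroy cross-frame comparability);
- ``knn``  — k-nearest neighbours, vote fractions;
- ``mlp``  — one-hidden-layer perceptron, softmax outputs;
- ``gmmubm`` — a universal background model (diagonal Gaussian mixture over
  all enrolment data) MAP-adapted per subject (means only, relevance-factor
  rule); identity scores are softmax-normalised log-likelihood ratios of
  adapted model vs background.

Two continuous-operation refinements sit on top: *user-tuned thresholds*
(per-identity acceptance threshold, set at each identity's equal-error
point on validation scores) and *past-score weighting* — the current score
vector is replaced by a recency-weighted average of the last N vectors,
with half-Gaussian weights ``w = exp(-(t_n - t_0)^2 / (2 sigma^2))``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from wheelbeat.features import FeatureVector

__all__ = [
    "EnrollmentModel",
    "UbmModel",
    "ThresholdProfile",
    "DecisionState",
    "train",
    "score",
    "score_matrix",
    "weight_scores",
    "identify",
    "authenticate",
    "tune_thresholds",
    "MODEL_KINDS",
]

MODEL_KINDS = ("svm", "knn", "mlp", "gmmubm")


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features.astype(float))
    rows = [f.values if isinstance(f, FeatureVector) else np.asarray(f, float)
            for f in features]
    return np.stack(rows)


class UbmModel:
    """Universal background model with per-subject MAP mean adaptation.

    The background mixture (diagonal covariances) is fitted on the pooled
    enrolment data; each subject's model shares its weights and covariances
    but moves component means toward the subject's data with the standard
    relevance-factor rule ``alpha_k = n_k / (n_k + r)``.
    """

    def __init__(self, n_components: int = 16, relevance: float = 16.0,
                 seed: int = 0, reg_covar: float = 1e-3):
        self.n_components = n_components
        self.relevance = relevance
        self.seed = seed
        self.reg_covar = reg_covar
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "UbmModel":
        self.classes_ = np.unique(y)
        k = min(self.n_components, max(2, X.shape[0] // 4))
        self.ubm_ = GaussianMixture(
            n_components=k, covariance_type="diag", reg_covar=self.reg_covar,
            random_state=self.seed, n_init=1, max_iter=200).fit(X)
        self.adapted_means_ = {}
        for label in self.classes_:
            Xs = X[y == label]
            gamma = self.ubm_.predict_proba(Xs)          # (n, k)
            n_k = gamma.sum(axis=0)                      # (k,)
            safe = np.maximum(n_k, 1e-12)[:, None]
            xbar = gamma.T @ Xs / safe
            alpha = (n_k / (n_k + self.relevance))[:, None]
            self.adapted_means_[label] = (alpha * xbar
                                          + (1 - alpha) * self.ubm_.means_)
        return self

    def _loglik(self, X: np.ndarray, means: np.ndarray) -> np.ndarray:
        gm = GaussianMixture(n_components=self.ubm_.n_components,
                             covariance_type="diag")
        gm.weights_ = self.ubm_.weights_
        gm.means_ = means
        gm.covariances_ = self.ubm_.covariances_
        gm.precisions_cholesky_ = 1.0 / np.sqrt(self.ubm_.covariances_)
        return gm.score_samples(X)

    def llr(self, X: np.ndarray) -> np.ndarray:
        """Per-sample log-likelihood ratio (adapted vs UBM) per identity."""
        base = self._loglik(X, self.ubm_.means_)
        cols = [self._loglik(X, self.adapted_means_[c]) - base
                for c in self.classes_]
        return np.stack(cols, axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        llr = self.llr(X)
        llr = llr - llr.max(axis=1, keepdims=True)
        e = np.exp(llr)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class EnrollmentModel:
    """A trained recognizer: standardiser + classifier + identity list."""

    kind: str
    classes: np.ndarray
    scaler: StandardScaler
    estimator: object
    meta: dict = field(default_factory=dict)


def train(features, labels: Sequence[str], kind: str = "svm",
          config: dict | None = None, seed: int = 0,
          meta: dict | None = None) -> EnrollmentModel:
    """Fit an enrolment model on (features, identity labels).

    ``features`` may be a list of :class:`FeatureVector` or a 2-D array.
    Standardisation is fitted on the training data only and stored with the
    model.  ``config`` overrides the model-family defaults (e.g. ``{"k": 1}``
    for kNN, ``{"C": 1.0}`` for SVM).  Deterministic for a fixed seed.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    cfg = dict(config or {})
    X = _as_matrix(features)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least two enrolled identities")
    if X.shape[0] != y.size:
        raise ValueError("features and labels must align")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    if kind == "svm":
        base = SVC(C=cfg.get("C", 10.0), kernel="rbf",
                   gamma=cfg.get("gamma", "auto"), random_state=seed)
        est = CalibratedClassifierCV(base, method="sigmoid",
                                     cv=cfg.get("calibration_cv", 3),
                                     ensemble=False)
    elif kind == "knn":
        est = KNeighborsClassifier(n_neighbors=cfg.get("k", 3),
                                   metric="euclidean")
    elif kind == "mlp":
        # early stopping needs a meaningful validation split; on tiny
        # enrolment sets it halts before the network has learnt anything
        est = MLPClassifier(hidden_layer_sizes=cfg.get("hidden", (64,)),
                            early_stopping=cfg.get("early_stopping",
                                                   X.shape[0] >= 100),
                            max_iter=cfg.get("max_iter", 500),
                            random_state=seed)
    else:  # gmmubm
        est = UbmModel(n_components=cfg.get("n_components", 16),
                       relevance=cfg.get("relevance", 16.0), seed=seed)
    est.fit(Xs, y)

    model_meta = {"seed": seed, "n_train": int(X.shape[0])}
    model_meta.update(meta or {})
    return EnrollmentModel(kind=kind, classes=np.asarray(est.classes_),
                           scaler=scaler, estimator=est, meta=model_meta)


def score_matrix(model: EnrollmentModel, features) -> np.ndarray:
    """Score many feature vectors at once; rows sum to one."""
    X = model.scaler.transform(_as_matrix(features))
    return model.estimator.predict_proba(X)


def score(model: EnrollmentModel, f) -> np.ndarray:
    """Score one feature vector over all enrolled identities."""
    vec = f.values if isinstance(f, FeatureVector) else np.asarray(f, float)
    return score_matrix(model, vec[None, :])[0]


@dataclass
class DecisionState:
    """Ring buffer of past score vectors for recency weighting.

    ``n_history`` is the number N of past vectors to keep (default 4 — one
    per second of the 4 s frame overlap); ``sigma_s`` the half-Gaussian
    width in seconds.
    """

    n_history: int = 4
    sigma_s: float = 2.0
    _buffer: deque = field(default_factory=deque, repr=False)

    def push(self, t: float, scores: np.ndarray) -> None:
        if self._buffer and t <= self._buffer[-1][0]:
            raise ValueError("timestamps must be strictly increasing")
        self._buffer.append((float(t), np.asarray(scores, dtype=float)))
        while len(self._buffer) > self.n_history:
            self._buffer.popleft()

    def history(self) -> list[tuple[float, np.ndarray]]:
        return list(self._buffer)


def weight_scores(state: DecisionState, current: np.ndarray,
                  t_now: float = 0.0) -> np.ndarray:
    """Recency-weighted score vector.

    ``p_w = sum_n w_n p(x_{t_n}) / sum_n w_n`` over the current vector
    (weight 1) and the buffered past vectors, with half-Gaussian weights
    ``w_n = exp(-(t_n - t_0)^2 / (2 sigma^2))``.  A convex combination: for
    normalised inputs the output stays in [0, 1] and sums to one.  With an
    empty history the current vector is returned unchanged.
    """
    current = np.asarray(current, dtype=float)
    entries = state.history() + [(float(t_now), current)]
    times = np.array([t for t, _ in entries])
    vecs = np.stack([v for _, v in entries])
    w = np.exp(-((times - float(t_now)) ** 2) / (2.0 * state.sigma_s**2))
    return (w[:, None] * vecs).sum(axis=0) / w.sum()


def identify(model: EnrollmentModel, f, state: DecisionState | None = None,
             t_now: float = 0.0) -> str:
    """Closed-set identification: argmax of (optionally weighted) scores.

    Ties resolve to the earlier enrolled identity.
    """
    s = score(model, f)
    if state is not None:
        s = weight_scores(state, s, t_now)
    return str(model.classes[int(np.argmax(s))])


@dataclass
class ThresholdProfile:
    """Per-identity acceptance thresholds (user-tuned authentication)."""

    thresholds: dict

    def __getitem__(self, identity: str) -> float:
        return self.thresholds[identity]


def authenticate(model: EnrollmentModel, f, claimed: str,
                 thresholds: ThresholdProfile,
                 state: DecisionState | None = None,
                 t_now: float = 0.0) -> bool:
    """Accept the claimed identity iff its score meets that user's threshold."""
    if claimed not in model.classes:
        raise ValueError(f"identity {claimed!r} is not enrolled")
    s = score(model, f)
    if state is not None:
        s = weight_scores(state, s, t_now)
    idx = int(np.nonzero(model.classes == claimed)[0][0])
    return bool(s[idx] >= thresholds[claimed])


def tune_thresholds(model: EnrollmentModel, features, labels
                    ) -> ThresholdProfile:
    """Per-identity threshold at that identity's equal-error point.

    For each enrolled identity, genuine scores (that identity's score on its
    own validation samples) and impostor scores (its score on everyone
    else's) define a small verification problem; the threshold is the
    equal-error operating point.
    """
    from wheelbeat.evaluate import compute_eer  # local: avoids module cycle

    y = np.asarray(labels)
    S = score_matrix(model, features)
    profile = {}
    for i, identity in enumerate(model.classes):
        genuine = S[y == identity, i]
        impostor = S[y != identity, i]
        if genuine.size == 0 or impostor.size == 0:
            profile[str(identity)] = 0.5
            continue
        _, thr = compute_eer(genuine, impostor)
        profile[str(identity)] = float(thr)
    return ThresholdProfile(profile)
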