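"""The three injury classifiers, class weighting and centroid undersampling.

All three models emit a continuous score strictly inside (0, 1):

* ``svm`` — RBF-kernel support vector classifier with Platt-scaled
  probabilities; class weights scale the per-class penalty.
* ``fnn`` — a small feedforward net (10 tanh hidden units, dropout 0.6,
  sigmoid output) trained for 20 epochs with Adam (lr 0.001) on
  class-weighted binary cross-entropy with an L2 penalty.  Implemented in
  NumPy so the weighted loss and dropout schedule are exactly as specified
  and fully seed-deterministic.
* ``adaboost`` — AdaBoost over one-level decision stumps, at most 50;
  class weights enter as initial sample weights.

Cost-sensitive learning sets each class's weight inversely proportional to
its frequency; traditional learning uses unit weights.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cluster import KMeans
from sklearn.ensemble import AdaBoostClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

_PROB_EPS = 1e-9

DEFAULT_HYPERPARAMS: Mapping[str, dict] = {
    "svm": {"C": 1.0, "kernel": "rbf"},
    "fnn": {
        "hidden_units": 10,
        "dropout": 0.6,
        "epochs": 20,
        "learning_rate": 0.001,
        "batch_size": 32,
        "l2": 1e-4,
        "loss": "bce",  # "wse" = class-weighted squared error variant
    },
    "adaboost": {"n_estimators": 50},
}


@dataclass(frozen=True)
class ClassWeights:
    w0: float
    w1: float

    def as_dict(self) -> dict[int, float]:
        return {0: self.w0, 1: self.w1}


def compute_class_weights(y, cost_sensitive: bool) -> ClassWeights:
    """Unit weights, or weights inversely proportional to class frequency.

    Cost-sensitive: ``w_c = N / (2 * n_c)`` (balanced-heuristic scaling, so
    a 50/50 sample still gets unit weights).
    """
    if not cost_sensitive:
        return ClassWeights(1.0, 1.0)
    y = np.asarray(y)
    n = len(y)
    n1 = int(np.sum(y == 1))
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("cost-sensitive weights need both classes present")
    return ClassWeights(n / (2.0 * n0), n / (2.0 * n1))


@dataclass(frozen=True)
class UndersampleConfig:
    """Centroid-undersampling settings.

    ``ratio`` is the injured:noninjured ratio after resampling — 0.40 means
    noninjured rows are replaced by round(n_injured / 0.40) k-means
    centroids.  ``k`` is retained as configuration metadata; with
    ``exact_k=True`` exactly ``k`` centroids are produced instead.
    """

    ratio: float = 0.40
    k: int = 8
    exact_k: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.ratio <= 1.0):
            raise ValueError("ratio must lie in (0, 1]")


def kmeans_undersample(
    X: pd.DataFrame, y, cfg: UndersampleConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Replace noninjured rows by k-means centroids; keep injured verbatim.

    Returns (features, labels) with injured rows first, bit-identical to
    their originals, followed by the centroid rows labelled 0.  If the
    requested centroid count is not below the available noninjured count,
    the data pass through unchanged (with a warning).
    """
    y = np.asarray(y)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("undersampling needs both classes present")
    m = cfg.k if cfg.exact_k else int(round(n1 / cfg.ratio))
    if m >= n0:
        logger.warning(
            "requested %d centroids but only %d noninjured rows; passing through",
            m,
            n0,
        )
        return X.copy(), y.copy()
    X0 = X.loc[y == 0]
    km = KMeans(n_clusters=m, n_init=10, random_state=cfg.seed)
    km.fit(X0.to_numpy(dtype=float))
    centroids = pd.DataFrame(km.cluster_centers_, columns=X.columns)
    X1 = X.loc[y == 1]
    X_out = pd.concat([X1, centroids], ignore_index=True)
    y_out = np.concatenate([np.ones(n1, dtype=int), np.zeros(m, dtype=int)])
    return X_out, y_out


@dataclass(frozen=True)
class ModelSpec:
    """Classifier kind + learning mode + (overridable) hyperparameters."""

    kind: str  # "svm" | "fnn" | "adaboost"
    cost_sensitive: bool = True
    seed: int = 0
    overrides: Mapping[str, object] = field(default_factory=dict)

    def hyperparams(self) -> dict:
        if self.kind not in DEFAULT_HYPERPARAMS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        hp = dict(DEFAULT_HYPERPARAMS[self.kind])
        for k, v in self.overrides.items():
            if k not in hp:
                raise ValueError(f"unknown hyperparameter {k!r} for {self.kind}")
            logger.info("hyperparameter override %s=%r for %s", k, v, self.kind)
            hp[k] = v
        return hp

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class _NumpyFNN:
    """Minimal 1-hidden-layer net: tanh hidden, dropout, sigmoid output."""

    def __init__(self, n_in: int, hp: dict, seed: int):
        self.hp = hp
        rng = np.random.default_rng(seed)
        h = hp["hidden_units"]
        # uniform fan-in initialisation
        lim1 = 1.0 / np.sqrt(n_in)
        lim2 = 1.0 / np.sqrt(h)
        self.W1 = rng.uniform(-lim1, lim1, size=(n_in, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.uniform(-lim2, lim2, size=(h, 1))
        self.b2 = np.zeros(1)
        self._rng = rng
        self.loss_history: list[float] = []

    @staticmethod
    def _sigmoid(z):
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def _forward(self, X, train: bool):
        h = np.tanh(X @ self.W1 + self.b1)  # pre-dropout hidden activation
        if train and self.hp["dropout"] > 0:
            keep = 1.0 - self.hp["dropout"]
            mask = (self._rng.random(h.shape) < keep) / keep
            a1 = h * mask
        else:
            mask = None
            a1 = h
        p = self._sigmoid(a1 @ self.W2 + self.b2).ravel()
        return h, a1, mask, p

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray):
        hp = self.hp
        params = [self.W1, self.b1, self.W2, self.b2]
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(X)
        for _ in range(hp["epochs"]):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, hp["batch_size"]):
                idx = order[start : start + hp["batch_size"]]
                xb, yb, wb = X[idx], y[idx], sample_weight[idx]
                h, a1, mask, p = self._forward(xb, train=True)
                p = np.clip(p, _PROB_EPS, 1 - _PROB_EPS)
                if hp["loss"] == "bce":
                    loss = -np.mean(wb * (yb * np.log(p) + (1 - yb) * np.log(1 - p)))
                    dz = wb * (p - yb) / len(idx)  # d loss / d preactivation
                else:  # weighted squared error
                    loss = np.mean(wb * (p - yb) ** 2)
                    dz = 2 * wb * (p - yb) * p * (1 - p) / len(idx)
                epoch_loss += loss * len(idx)
                dW2 = a1.T @ dz[:, None] + hp["l2"] * self.W2
                db2 = dz.sum(keepdims=True)
                da1 = dz[:, None] @ self.W2.T
                if mask is not None:
                    da1 = da1 * mask
                dz1 = da1 * (1 - h**2)  # tanh' on the pre-dropout activation
                dW1 = xb.T @ dz1 + hp["l2"] * self.W1
                db1 = dz1.sum(axis=0)
                grads = [dW1, db1, dW2, db2.ravel()]
                t += 1
                for p_, g, m_, v_ in zip(params, grads, m_t, v_t):
                    m_ *= beta1
                    m_ += (1 - beta1) * g
                    v_ *= beta2
                    v_ += (1 - beta2) * g**2
                    mhat = m_ / (1 - beta1**t)
                    vhat = v_ / (1 - beta2**t)
                    p_ -= hp["learning_rate"] * mhat / (np.sqrt(vhat) + eps)
            self.loss_history.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, _, _, p = self._forward(X, train=False)
        return p


@dataclass
class TrainedClassifier:
    """Fitted predictor with its spec and training feature schema."""

    spec: ModelSpec
    feature_names: list[str]
    _impl: object

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Scores strictly inside (0, 1), one per row of ``X``."""
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.feature_names:
                raise ValueError("feature schema mismatch with training data")
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.shape[1] != len(self.feature_names):
                raise ValueError("feature schema mismatch with training data")
        if self.spec.kind == "fnn":
            p = self._impl.predict_proba(Xv)
        else:
            p = self._impl.predict_proba(Xv)[:, 1]
        return np.clip(p, _PROB_EPS, 1 - _PROB_EPS)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train(
    spec: ModelSpec,
    X: pd.DataFrame | np.ndarray,
    y,
    weights: ClassWeights | None = None,
) -> TrainedClassifier:
    """Fit one classifier on standardized features.

    ``weights`` defaults to the spec's learning mode applied to ``y``.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        feature_names = [f"f{i}" for i in range(Xv.shape[1])]
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    if weights is None:
        weights = compute_class_weights(y, spec.cost_sensitive)

    hp = spec.hyperparams()
    if spec.kind == "svm":
        base = SVC(
            C=hp["C"],
            kernel=hp["kernel"],
            class_weight=weights.as_dict(),
            random_state=spec.seed,
        )
        # Platt scaling: sigmoid calibration fitted on internal 5-fold scores
        n1 = int(np.sum(y == 1))
        cv = min(5, n1, len(y) - n1)
        impl = CalibratedClassifierCV(base, method="sigmoid", cv=max(cv, 2), ensemble=False)
        impl.fit(Xv, y)
    elif spec.kind == "adaboost":
        stump = DecisionTreeClassifier(max_depth=1, random_state=spec.seed)
        impl = AdaBoostClassifier(
            estimator=stump,
            n_estimators=hp["n_estimators"],
            random_state=spec.seed,
        )
        sw = np.where(y == 1, weights.w1, weights.w0)
        impl.fit(Xv, y, sample_weight=sw / sw.sum())
    elif spec.kind == "fnn":
        impl = _NumpyFNN(Xv.shape[1], hp, spec.seed)
        sw = np.where(y == 1, weights.w1, weights.w0)
        impl.fit(Xv, y.astype(float), sw)
    else:
        raise ValueError(f"unknown model kind {spec.kind!r}")
    return TrainedClassifier(spec=spec, feature_names=feature_names, _impl=impl)
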