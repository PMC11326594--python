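"""Classical classifiers over region feature vectors.

Three classifiers mirror the comparison usually run on hand-crafted
ultrasound texture features:

* **k-star** — an entropic instance-based learner.  The affinity of a
  query to each stored instance is the probability of "transforming" the
  query into that instance, modelled per real-valued attribute as an
  exponential kernel P(d) ~ exp(-d / x0).  The kernel width x0 is chosen
  per attribute (and per query) so that the *effective* number of
  neighbours interpolates, via the blend parameter b in (0, 1], between
  the nearest instance(s) (b -> 0) and the whole training set (b = 1).
  Class scores are the summed transformation probabilities of same-class
  instances, normalized; the classic score of a class is the negative log
  of that probability.  Implemented from scratch — no scikit-learn
  analogue exists.

* **linear SGD** — a hinge-loss linear model trained by per-sample
  stochastic gradient descent (scikit-learn's ``SGDClassifier``) on
  internally standardized features, learning rate 0.001 held constant
  for 100 epochs by default.

* **random forest** — a bagged decision-tree ensemble
  (scikit-learn's ``RandomForestClassifier``), bootstrap resampling on,
  100 trees by default.

The positive class throughout is ``"PCOS"``.  Vote ties resolve toward
the lower-indexed class in sorted label order ("PCOS" < "normal").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import train_test_split

from .evaluate import ConfusionMatrix, confusion

__all__ = [
    "Prediction",
    "KStarModel",
    "LinearSGDModel",
    "ForestModel",
    "kstar_fit",
    "kstar_predict",
    "sgd_fit",
    "sgd_predict",
    "rf_fit",
    "rf_predict",
    "cross_validate",
    "CVResult",
]


@dataclass
class Prediction:
    """A predicted label with per-class probabilities or scores."""

    label: str
    probabilities: dict[str, float] | None = None
    score: float | None = None  # signed decision value toward the positive class


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be 2-D with one row per label")
    if not np.isfinite(x).all():
        raise ValueError("features contain missing or non-finite values")
    return x, y


# --------------------------------------------------------------------------
# k-star
# --------------------------------------------------------------------------


@dataclass
class KStarModel:
    X: np.ndarray
    y: np.ndarray
    blend: float
    classes: tuple[str, ...]
    scales: np.ndarray  # per-attribute SD used only for bracketing x0


def kstar_fit(features: np.ndarray, labels: np.ndarray, blend: float = 0.2) -> KStarModel:
    """Store the training instances; k-star is lazy."""
    x, y = _check_xy(features, labels)
    if not 0 < blend <= 1:
        raise ValueError("blend must lie in (0, 1]")
    classes = tuple(sorted(set(map(str, y))))
    if len(classes) < 1:
        raise ValueError("need at least one training instance")
    scales = x.std(axis=0)
    return KStarModel(X=x, y=y.astype(str), blend=blend, classes=classes, scales=scales)


def _effective_count(p: np.ndarray) -> float:
    s = p.sum()
    return float(s * s / (p * p).sum())


def _attribute_probs(dist: np.ndarray, blend: float) -> np.ndarray:
    """Per-instance transformation probabilities for one attribute.

    Solves for the kernel width x0 such that the effective instance count
    (sum p)^2 / sum p^2 equals n0 + blend * (N - n0), where n0 is the
    number of instances at the minimum distance.  Monotone in x0, so
    bisection on log(x0) suffices.
    """
    n = len(dist)
    d = dist - dist.min()
    if d.max() <= 0:  # all instances equidistant: uniform
        return np.full(n, 1.0 / n)
    n0 = int((d <= 1e-12).sum())
    target = n0 + blend * (n - n0)

    pos = d[d > 0]
    lo = np.log(pos.min() * 1e-8)
    hi = np.log(d.max() * 1e8)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = np.exp(-d / np.exp(mid))
        if _effective_count(p) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    p = np.exp(-d / np.exp(0.5 * (lo + hi)))
    return p / p.sum()


def kstar_predict(model: KStarModel, query: np.ndarray) -> Prediction:
    """Class probabilities of one query instance."""
    q = np.asarray(query, dtype=float).ravel()
    if q.shape[0] != model.X.shape[1]:
        raise ValueError(
            f"query has {q.shape[0]} attributes, model expects {model.X.shape[1]}"
        )
    # joint transformation probability = product over attributes
    logp = np.zeros(len(model.X))
    for a in range(model.X.shape[1]):
        pa = _attribute_probs(np.abs(model.X[:, a] - q[a]), model.blend)
        logp += np.log(np.maximum(pa, 1e-300))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    probs = {c: float(p[model.y == c].sum()) for c in model.classes}
    label = max(model.classes, key=lambda c: probs[c])
    score = probs.get("PCOS", probs[label])
    return Prediction(label=label, probabilities=probs, score=score)


# --------------------------------------------------------------------------
# linear SGD
# --------------------------------------------------------------------------


@dataclass
class LinearSGDModel:
    estimator: SGDClassifier
    feature_mean: np.ndarray
    feature_std: np.ndarray
    classes: tuple[str, ...]

    @property
    def weights(self) -> np.ndarray:
        return self.estimator.coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.estimator.intercept_[0])


def sgd_fit(
    features: np.ndarray,
    labels: np.ndarray,
    lr: float = 0.001,
    epochs: int = 100,
    seed: int = 0,
) -> LinearSGDModel:
    """Hinge-loss linear model, per-sample SGD in seeded shuffled order.

    Features are standardized internally (train statistics stored on the
    model); the learning rate is held constant at ``lr``.
    """
    x, y = _check_xy(features, labels)
    classes = tuple(sorted(set(map(str, y))))
    if len(classes) < 2:
        raise ValueError("SGD training requires at least two classes")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    est = SGDClassifier(
        loss="hinge",
        penalty=None,
        learning_rate="constant",
        eta0=lr,
        max_iter=epochs,
        tol=None,
        shuffle=True,
        random_state=seed,
    )
    est.fit((x - mu) / sd, y.astype(str))
    return LinearSGDModel(estimator=est, feature_mean=mu, feature_std=sd, classes=classes)


def sgd_predict(model: LinearSGDModel, query: np.ndarray) -> Prediction:
    x = np.atleast_2d(np.asarray(query, dtype=float))
    z = (x - model.feature_mean) / model.feature_std
    label = str(model.estimator.predict(z)[0])
    d = float(model.estimator.decision_function(z)[0])
    # sklearn's decision value is positive toward classes_[1]
    pos = str(model.estimator.classes_[1])
    score = d if pos == "PCOS" else -d
    return Prediction(label=label, score=score)


# --------------------------------------------------------------------------
# random forest
# --------------------------------------------------------------------------


@dataclass
class ForestModel:
    estimator: RandomForestClassifier
    classes: tuple[str, ...]
    n_trees: int
    bootstrap: bool
    seed: int


def rf_fit(
    features: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 100,
    bootstrap: bool = True,
    seed: int = 0,
) -> ForestModel:
    """Bagged decision-tree ensemble with random feature subsetting."""
    x, y = _check_xy(features, labels)
    if len(x) < 1:
        raise ValueError("need at least one sample")
    est = RandomForestClassifier(
        n_estimators=n_trees, bootstrap=bootstrap, random_state=seed
    )
    est.fit(x, y.astype(str))
    return ForestModel(
        estimator=est,
        classes=tuple(est.classes_),
        n_trees=n_trees,
        bootstrap=bootstrap,
        seed=seed,
    )


def rf_predict(model: ForestModel, query: np.ndarray) -> Prediction:
    x = np.atleast_2d(np.asarray(query, dtype=float))
    proba = model.estimator.predict_proba(x)[0]
    probs = dict(zip(model.classes, map(float, proba)))
    # majority vote; ties resolve to the lower class index (sorted order)
    label = model.classes[int(np.argmax(proba))]
    return Prediction(label=label, probabilities=probs, score=probs.get("PCOS"))


# --------------------------------------------------------------------------
# evaluation split
# --------------------------------------------------------------------------

_FITTERS = {"kstar": kstar_fit, "sgd": sgd_fit, "rf": rf_fit}
_PREDICTORS = {"kstar": kstar_predict, "sgd": sgd_predict, "rf": rf_predict}


@dataclass
class CVResult:
    """Held-out evaluation of one classifier on one stratified split."""

    confusion: ConfusionMatrix
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # decision scores toward PCOS
    classifier: str

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy


def cross_validate(
    classifier: str,
    features: np.ndarray,
    labels: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
    **fit_kwargs,
) -> CVResult:
    """Stratified train/test split (default 80/20), fit, evaluate.

    ``classifier`` is one of ``"kstar"``, ``"sgd"`` or ``"rf"``.
    """
    if classifier not in _FITTERS:
        raise ValueError(f"unknown classifier {classifier!r}; choose from {sorted(_FITTERS)}")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    x, y = _check_xy(features, labels)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    if len(set(y_tr)) < 2 or len(set(y_te)) < 2:
        raise ValueError("split left a class empty; use more samples or a different fraction")
    if classifier in ("sgd", "rf"):
        fit_kwargs.setdefault("seed", seed)
    model = _FITTERS[classifier](x_tr, y_tr, **fit_kwargs)
    preds = [_PREDICTORS[classifier](model, row) for row in x_te]
    y_pred = np.array([p.label for p in preds])
    scores = np.array([p.score if p.score is not None else 0.0 for p in preds])
    return CVResult(
        confusion=confusion(y_te, y_pred),
        y_true=y_te.astype(str),
        y_pred=y_pred,
        scores=scores,
        classifier=classifier,
    )
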