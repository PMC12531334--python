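"""S- and T-learner prescriptive inference over pluggable classifiers.

The CATE tau(x) = P(Y=1 | W=A, x) - P(Y=1 | W=B, x) is estimated either by
one classifier given the treatment indicator as a feature (S-learner) or by
one classifier per arm (T-learner); the prescription is the arm with the
greater predicted probability of a favourable outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression

ALGORITHMS = (
    "extremely_randomized_trees",
    "random_forest",
    "gradient_boosted_trees",
    "logistic_regression",
    "gaussian_process",
)

GP_MAX_N = 2000     # GP fits are subsampled (seeded) beyond this size


class DegenerateDataError(ValueError):
    """The training data cannot support the requested fit."""


@dataclass(frozen=True)
class BaseLearnerSpec:
    algorithm: str
    seed: int = 0
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; roster: {ALGORITHMS}"
            )


def _instantiate(base):
    """Build a fresh classifier from a spec or clone a given estimator."""
    if isinstance(base, BaseLearnerSpec):
        kw = dict(base.settings)
        if base.algorithm == "extremely_randomized_trees":
            return ExtraTreesClassifier(random_state=base.seed, **kw)
        if base.algorithm == "random_forest":
            return RandomForestClassifier(random_state=base.seed, **kw)
        if base.algorithm == "gradient_boosted_trees":
            return GradientBoostingClassifier(random_state=base.seed, **kw)
        if base.algorithm == "logistic_regression":
            kw.setdefault("max_iter", 1000)
            return LogisticRegression(**kw)
        if base.algorithm == "gaussian_process":
            return GaussianProcessClassifier(random_state=base.seed, **kw)
    return clone(base)


class FrequencyTableClassifier(BaseEstimator, ClassifierMixin):
    """Saturated lookup table: P(y=1 | x) = empirical mean of y at x.

    Only defined for finite discrete feature vectors; unseen rows fall back
    to the overall training mean.
    """

    def fit(self, X, y):
        X, y = np.asarray(X), np.asarray(y)
        self.table_ = {}
        for row, yi in zip(X, y):
            self.table_.setdefault(tuple(row), []).append(int(yi))
        self.table_ = {k: float(np.mean(v)) for k, v in self.table_.items()}
        self.default_ = float(np.mean(y))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p1 = np.array(
            [self.table_.get(tuple(row), self.default_) for row in np.asarray(X)]
        )
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class MetaLearner:
    kind: str                       # 'S' | 'T'
    components: dict                # {'model': clf} or {'A': clf, 'B': clf}
    base: object


@dataclass
class CateEstimate:
    tau_hat: np.ndarray
    p_A: np.ndarray
    p_B: np.ndarray


def _delta_a(w) -> np.ndarray:
    return (np.asarray(w) == "A").astype(float)


def _maybe_subsample(base, X, y, n_max=GP_MAX_N):
    alg = base.algorithm if isinstance(base, BaseLearnerSpec) else ""
    if alg == "gaussian_process" and len(y) > n_max:
        rng = np.random.default_rng(getattr(base, "seed", 0))
        idx = rng.choice(len(y), n_max, replace=False)
        return X[idx], y[idx]
    return X, y


def fit_s_learner(X, w, y, base) -> MetaLearner:
    """Single outcome classifier on features [x, delta_w^A] (A encoded 1)."""
    X, y = np.asarray(X, float), np.asarray(y)
    if len(X) < 2:
        raise DegenerateDataError("need at least two observations")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("outcome is single-class; S-learner cannot fit")
    feats = np.column_stack([X, _delta_a(w)])
    feats, y = _maybe_subsample(base, feats, y)
    clf = _instantiate(base).fit(feats, y)
    return MetaLearner("S", {"model": clf}, base)


def fit_t_learner(X, w, y, base) -> MetaLearner:
    """One outcome classifier per treatment arm."""
    X, w, y = np.asarray(X, float), np.asarray(w), np.asarray(y)
    components = {}
    for arm in ("A", "B"):
        sel = w == arm
        if not sel.any():
            raise DegenerateDataError(f"arm {arm} is empty")
        if len(np.unique(y[sel])) < 2:
            raise DegenerateDataError(f"arm {arm} outcome is single-class")
        Xa, ya = _maybe_subsample(base, X[sel], y[sel])
        components[arm] = _instantiate(base).fit(Xa, ya)
    return MetaLearner("T", components, base)


def _prob_one(clf, X) -> np.ndarray:
    proba = clf.predict_proba(np.asarray(X, float))
    classes = list(clf.classes_)
    if 1 not in classes:
        return np.zeros(len(proba))
    return proba[:, classes.index(1)]


def outcome_prob(model: MetaLearner, x, w: str) -> np.ndarray:
    """P(Y=1 | W=w, X=x); x may be one phenotype or a stack."""
    x = np.atleast_2d(np.asarray(x, float))
    if model.kind == "S":
        delta = np.full(len(x), 1.0 if w == "A" else 0.0)
        return _prob_one(model.components["model"], np.column_stack([x, delta]))
    return _prob_one(model.components[w], x)


def estimate_cate(model: MetaLearner, x) -> CateEstimate:
    """tau_hat(x) = P(Y=1 | A, x) - P(Y=1 | B, x), bounded in [-1, 1]."""
    p_a = outcome_prob(model, x, "A")
    p_b = outcome_prob(model, x, "B")
    return CateEstimate(p_a - p_b, p_a, p_b)


def prescribe(model: MetaLearner, x) -> np.ndarray:
    """Arm with the greater predicted favourable-outcome probability;
    exact ties go to A for reproducibility."""
    est = estimate_cate(model, x)
    return np.where(est.p_A >= est.p_B, "A", "B")
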