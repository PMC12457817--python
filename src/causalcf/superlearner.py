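"""From-scratch Super Learner: cross-validated convex stacking of a
configurable library of base learners.

The Super Learner fits every base learner on each fold-complement of a
V-fold split, assembles the out-of-fold prediction matrix, and chooses
non-negative weights summing to one that minimize the cross-validated
loss (squared error for regression, mean negative Bernoulli
log-likelihood for classification) over the probability simplex.  Base
learners are then refitted on the full data.  By construction the
ensemble's CV loss is never worse than that of the best single learner
(the simplex vertices are candidate solutions).

Two shipped library presets mirror a reduced (parametric) and a full
(parametric + flexible non-parametric) candidate set; custom libraries
can be declared in YAML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import minimize, nnls
from sklearn.base import clone
from sklearn import config_context
from sklearn.linear_model import (
    Lasso,
    LassoCV,
    LassoLarsCV,
    LinearRegression,
    LogisticRegression,
    Ridge,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "LearnerSpec",
    "EnsembleModel",
    "SuperLearnerError",
    "fit_super_learner",
    "predict_ensemble",
    "truncate_ps",
    "get_library",
    "library_from_yaml",
    "REDUCED_LIBRARY",
    "FULL_LIBRARY",
]

FAMILIES = (
    "glm",
    "glm-pairwise-interactions",
    "ridge-bayes-glm",
    "gam",
    "lasso-elasticnet",
    "random-forest",
    "gradient-boosting",
    "neural-net",
    "mars-like",
)


class SuperLearnerError(RuntimeError):
    """All base learners failed, or the inputs violate the contract."""


@dataclass(frozen=True)
class LearnerSpec:
    """One base learner: a family with fixed default hyperparameters."""

    name: str
    family: str
    task: str  # "regression" | "classification"
    hyperparameters: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SuperLearnerError(f"unknown learner family '{self.family}'")
        if self.task not in ("regression", "classification"):
            raise SuperLearnerError(f"unknown task '{self.task}'")

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)


class _HingeFeatures:
    """Piecewise-linear hinge basis, max(x-t, 0) and max(t-x, 0), with
    knots at the per-feature 25/50/75% quantiles of the training data.
    Combined with an L1-penalized fit this yields an adaptive-spline
    learner in the spirit of multivariate adaptive regression splines."""

    def __init__(self):
        self.knots_ = None

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.knots_ = np.quantile(X, [0.25, 0.5, 0.75], axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        feats = [X]
        for row in self.knots_:
            feats.append(np.maximum(X - row, 0.0))
            feats.append(np.maximum(row - X, 0.0))
        return np.column_stack(feats)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self


def build_estimator(spec: LearnerSpec, seed: int):
    """Instantiate the scikit-learn estimator behind a learner spec."""
    hp = spec.hp
    reg = spec.task == "regression"
    if spec.family == "glm":
        return LinearRegression() if reg else LogisticRegression(
            penalty=None, max_iter=1000)
    if spec.family == "glm-pairwise-interactions":
        expand = PolynomialFeatures(degree=2, interaction_only=True, include_bias=False)
        base = Ridge(alpha=1e-6) if reg else LogisticRegression(C=1e6, max_iter=1000)
        return make_pipeline(expand, base)
    if spec.family == "ridge-bayes-glm":
        # ridge-penalized GLM with a small fixed penalty: a shrinkage
        # analogue of a weakly informative Bayesian GLM
        return Ridge(alpha=hp.get("alpha", 1.0)) if reg else LogisticRegression(
            C=hp.get("C", 1.0), max_iter=1000)
    if spec.family == "gam":
        splines = SplineTransformer(n_knots=hp.get("n_knots", 5), degree=3)
        base = Ridge(alpha=1.0) if reg else LogisticRegression(C=1.0, max_iter=1000)
        return make_pipeline(splines, base)
    if spec.family == "lasso-elasticnet":
        if reg:
            # LARS path with CV-chosen penalty: exact lasso path, cheap at
            # moderate p; falls back to coordinate descent for wide designs
            if hp.get("wide", False):
                return LassoCV(alphas=hp.get("n_alphas", 30),
                               cv=hp.get("cv", 5), max_iter=5000)
            return LassoLarsCV(cv=hp.get("cv", 5))
        return LogisticRegression(penalty="l1", C=hp.get("C", 1.0),
                                  solver="liblinear", max_iter=1000,
                                  random_state=seed)
    if spec.family == "random-forest":
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

        kw = dict(n_estimators=hp.get("n_estimators", 100), random_state=seed,
                  min_samples_leaf=hp.get("min_samples_leaf", 5), n_jobs=1)
        return RandomForestRegressor(**kw) if reg else RandomForestClassifier(**kw)
    if spec.family == "gradient-boosting":
        from sklearn.ensemble import (
            HistGradientBoostingClassifier,
            HistGradientBoostingRegressor,
        )

        kw = dict(random_state=seed, max_iter=hp.get("max_iter", 100))
        return (HistGradientBoostingRegressor(**kw) if reg
                else HistGradientBoostingClassifier(**kw))
    if spec.family == "neural-net":
        from sklearn.neural_network import MLPClassifier, MLPRegressor

        kw = dict(hidden_layer_sizes=hp.get("hidden_layer_sizes", (16,)),
                  max_iter=hp.get("max_iter", 500), random_state=seed)
        net = MLPRegressor(**kw) if reg else MLPClassifier(**kw)
        return make_pipeline(StandardScaler(), net)
    if spec.family == "mars-like":
        base = (Lasso(alpha=hp.get("alpha", 0.01), max_iter=5000) if reg
                else LogisticRegression(penalty="l1", C=1.0, solver="liblinear",
                                        max_iter=1000, random_state=seed))
        return make_pipeline(_HingeFeatures(), base)
    raise SuperLearnerError(f"unhandled family '{spec.family}'")  # pragma: no cover


# ---------------------------------------------------------------------------
# libraries

_REDUCED_FAMILIES = ("glm", "glm-pairwise-interactions", "ridge-bayes-glm",
                     "gam", "lasso-elasticnet")
_FULL_EXTRA_FAMILIES = ("random-forest", "gradient-boosting", "neural-net",
                        "mars-like")


def _specs(families, task):
    return tuple(LearnerSpec(name=f, family=f, task=task) for f in families)


REDUCED_LIBRARY = {t: _specs(_REDUCED_FAMILIES, t)
                   for t in ("regression", "classification")}
FULL_LIBRARY = {t: _specs(_REDUCED_FAMILIES + _FULL_EXTRA_FAMILIES, t)
                for t in ("regression", "classification")}

#: Named presets. "glm" and "glm-lasso" are small parametric libraries
#: used for fast, correctly-specified simulation runs.
LIBRARY_PRESETS = {
    "reduced": _REDUCED_FAMILIES,
    "full": _REDUCED_FAMILIES + _FULL_EXTRA_FAMILIES,
    "glm": ("glm",),
    "glm-lasso": ("glm", "lasso-elasticnet"),
}


def get_library(name: str, task: str) -> tuple[LearnerSpec, ...]:
    """Return a shipped library preset for the given prediction task."""
    if name not in LIBRARY_PRESETS:
        raise SuperLearnerError(
            f"unknown library preset '{name}'; available: {sorted(LIBRARY_PRESETS)}")
    return _specs(LIBRARY_PRESETS[name], task)


def library_from_yaml(path, task: str) -> tuple[LearnerSpec, ...]:
    """Load a custom library definition (YAML list of {name, family,
    hyperparameters}) for the given task."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    specs = []
    for e in entries:
        specs.append(LearnerSpec(
            name=e.get("name", e["family"]), family=e["family"], task=task,
            hyperparameters=tuple(sorted((e.get("hyperparameters") or {}).items())),
        ))
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SuperLearnerError("learner names must be unique within a library")
    return tuple(specs)


# ---------------------------------------------------------------------------
# stacking


@dataclass
class EnsembleModel:
    """A fitted Super Learner ensemble."""

    specs: tuple[LearnerSpec, ...]
    learners: list
    meta_weights: np.ndarray
    cv_risks: np.ndarray
    v_folds: int
    loss: str  # "squared_error" | "log_loss"
    n_features: int = 0
    dropped: tuple[str, ...] = field(default=())
    oof_predictions: np.ndarray | None = None  # n x L out-of-fold matrix
    oof_target: np.ndarray | None = None

    @property
    def task(self) -> str:
        return "regression" if self.loss == "squared_error" else "classification"


def _predict_one(est, X, task):
    if task == "classification":
        return np.clip(est.predict_proba(X)[:, 1], 0.0, 1.0)
    return est.predict(X)


def _loss_value(pred, y, loss):
    if loss == "squared_error":
        return float(np.mean((pred - y) ** 2))
    p = np.clip(pred, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _solve_weights(Z: np.ndarray, y: np.ndarray, loss: str) -> np.ndarray:
    """Minimize the CV loss over the probability simplex.

    Regression: non-negative least squares (renormalized) warm-starts an
    SLSQP polish under the simplex constraints.  Classification: SLSQP on
    the Bernoulli log-loss from a uniform start.  If the polished point
    is ever worse than the best vertex, the vertex wins, so the returned
    weights never lose to any single learner.
    """
    L = Z.shape[1]
    if L == 1:
        return np.array([1.0])

    def obj(w):
        return _loss_value(Z @ w, y, loss)

    if loss == "squared_error":
        w0, _ = nnls(Z, y)
        w0 = w0 / w0.sum() if w0.sum() > 0 else np.full(L, 1.0 / L)
    else:
        w0 = np.full(L, 1.0 / L)
    res = minimize(
        obj, w0, method="SLSQP",
        bounds=[(0.0, 1.0)] * L,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum() if w.sum() > 0 else np.full(L, 1.0 / L)
    vertex_losses = [obj(np.eye(L)[k]) for k in range(L)]
    best_vertex = int(np.argmin(vertex_losses))
    if obj(w) > vertex_losses[best_vertex]:
        w = np.eye(L)[best_vertex]
    return w


def fit_super_learner(features, target, library, v_folds: int = 10,
                      loss: str | None = None, seed: int = 0) -> EnsembleModel:
    """Fit the Super Learner ensemble.

    Parameters
    ----------
    features, target
        Training data; the target must be binary 0/1 for classification.
    library
        Sequence of :class:`LearnerSpec`, all with the same task.
    v_folds
        Internal cross-validation folds (stratified by the target for
        classification, so exposed counts are preserved per fold).
    loss
        ``"squared_error"`` or ``"log_loss"``; inferred from the task if
        omitted.
    seed
        Controls fold shuffling and any stochastic base learner.

    A base learner that raises during any fold is dropped with a logged
    warning and the remaining weights renormalized; if every learner
    fails a :class:`SuperLearnerError` is raised.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    library = tuple(library)
    if not library:
        raise SuperLearnerError("empty learner library")
    task = library[0].task
    if any(s.task != task for s in library):
        raise SuperLearnerError("mixed tasks within one library")
    if loss is None:
        loss = "squared_error" if task == "regression" else "log_loss"
    if X.shape[0] < 2 * v_folds:
        raise SuperLearnerError(
            f"need at least {2 * v_folds} records for {v_folds}-fold stacking, "
            f"got {X.shape[0]}")
    if task == "classification" and not np.all(np.isin(y, (0.0, 1.0))):
        raise SuperLearnerError("classification target must be binary 0/1")

    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31 - 1))
    if task == "classification":
        splitter = StratifiedKFold(n_splits=v_folds, shuffle=True,
                                   random_state=fold_seed)
        split_iter = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=v_folds, shuffle=True, random_state=fold_seed)
        split_iter = splitter.split(X)
    folds = list(split_iter)

    L = len(library)
    Z = np.full((X.shape[0], L), np.nan)
    alive = np.ones(L, dtype=bool)
    learner_seeds = [int(rng.integers(2**31 - 1)) for _ in range(L)]
    prototypes = [build_estimator(s, learner_seeds[k]) for k, s in enumerate(library)]
    with warnings.catch_warnings(), config_context(assume_finite=True):
        warnings.simplefilter("ignore")
        for train_idx, test_idx in folds:
            for k, spec in enumerate(library):
                if not alive[k]:
                    continue
                try:
                    est = clone(prototypes[k])
                    est.fit(X[train_idx], y[train_idx])
                    Z[test_idx, k] = _predict_one(est, X[test_idx], task)
                except Exception as exc:  # noqa: BLE001 - learner robustness
                    alive[k] = False
                    logger.warning("learner '%s' failed and was dropped: %s",
                                   spec.name, exc)
        if not alive.any():
            raise SuperLearnerError("all base learners failed")

        kept = np.flatnonzero(alive)
        Zk = Z[:, kept]
        if np.isnan(Zk).any():  # pragma: no cover - defensive
            raise SuperLearnerError("incomplete out-of-fold predictions")
        cv_risks = np.array([_loss_value(Zk[:, j], y, loss)
                             for j in range(len(kept))])
        weights = _solve_weights(Zk, y, loss)

        fitted = []
        for k in kept:
            est = clone(prototypes[k])
            est.fit(X, y)
            fitted.append(est)

    return EnsembleModel(
        specs=tuple(library[k] for k in kept),
        learners=fitted,
        meta_weights=weights,
        cv_risks=cv_risks,
        v_folds=v_folds,
        loss=loss,
        n_features=X.shape[1],
        dropped=tuple(library[k].name for k in np.flatnonzero(~alive)),
        oof_predictions=Zk,
        oof_target=y,
    )


def predict_ensemble(model: EnsembleModel, features) -> np.ndarray:
    """Weighted combination of base-learner predictions; classification
    outputs are probabilities in [0, 1]."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise SuperLearnerError(
            f"feature schema mismatch: model expects {model.n_features} columns, "
            f"got {X.shape[1] if X.ndim == 2 else 'non-2d input'}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        preds = np.column_stack(
            [_predict_one(est, X, model.task) for est in model.learners])
    out = preds @ model.meta_weights
    if model.task == "classification":
        out = np.clip(out, 0.0, 1.0)
    return out


def truncate_ps(ps) -> np.ndarray:
    """Truncate propensity scores at their empirical 5th and 95th
    percentiles (linear-interpolation quantiles of the input vector)."""
    ps = np.asarray(ps, dtype=float).ravel()
    if ps.size == 0:
        raise ValueError("cannot truncate an empty propensity-score vector")
    lo, hi = np.quantile(ps, [0.05, 0.95])
    return np.clip(ps, lo, hi)
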