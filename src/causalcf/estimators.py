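"""Doubly robust estimation of the average causal effect.

Two estimators are provided, both built on the same nuisance inputs
(per-record outcome predictions under exposure and non-exposure, and the
propensity score):

* **AIPW** — the one-step estimator: the g-computation plug-in plus an
  inverse-probability-weighted residual correction.  Its variance is the
  empirical variance of the per-record influence terms divided by n.
* **TMLE** — a substitution estimator: the outcome is mapped to [0, 1]
  using the observed outcome range, the initial outcome predictions are
  fluctuated along an intercept-free logistic submodel in the "clever
  covariate" H(X, W) = X/g - (1-X)/(1-g), and the targeted predictions
  are averaged and back-transformed.  The fluctuation solves the
  efficient-influence-function score equation, so the mean EIF at the
  targeted fit is zero and the estimate respects the outcome bounds.

K-fold cross-fitting fits both nuisance models on each fold-complement
and evaluates on the held-out fold; TMLE targeting is likewise performed
within the held-out data.  Standard errors always come from the
(pooled, out-of-fold) EIF.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.special import expit

from .data import DataValidationError, ObservedData
from .superlearner import (
    LearnerSpec,
    fit_super_learner,
    get_library,
    predict_ensemble,
    truncate_ps,
)

__all__ = [
    "NuisanceEstimates",
    "TargetedFit",
    "EffectEstimate",
    "FoldAssignment",
    "PositivityError",
    "TargetingError",
    "SparseExposureError",
    "aipw",
    "tmle",
    "make_folds",
    "crossfit",
    "estimate_ace",
    "analyze",
    "SuperLearnerNuisance",
    "ParametricNuisance",
    "OracleNuisance",
]

Z_95 = 1.96  # Wald multiplier for 95% intervals


class PositivityError(ValueError):
    """Propensity scores of exactly 0 or 1 (positivity violation)."""


class TargetingError(RuntimeError):
    """The TMLE fluctuation failed to solve the score equation."""


class SparseExposureError(RuntimeError):
    """A cross-fitting fold complement lacks exposed or unexposed records."""


@dataclass
class NuisanceEstimates:
    """Per-record nuisance predictions: Ê[Y|X=1,W], Ê[Y|X=0,W] and the
    (post-truncation) propensity score ĝ = P̂(X=1|W)."""

    e1: np.ndarray
    e0: np.ndarray
    g: np.ndarray
    out_of_fold: bool = False

    def __post_init__(self) -> None:
        self.e1 = np.asarray(self.e1, dtype=float).ravel()
        self.e0 = np.asarray(self.e0, dtype=float).ravel()
        self.g = np.asarray(self.g, dtype=float).ravel()
        if not (self.e1.shape == self.e0.shape == self.g.shape):
            raise DataValidationError("nuisance vectors must share one length")
        bad = np.flatnonzero((self.g <= 0.0) | (self.g >= 1.0))
        if bad.size:
            raise PositivityError(
                f"propensity scores at or beyond 0/1 for records {bad[:10].tolist()}"
                f"{'...' if bad.size > 10 else ''} (positivity violation)")


@dataclass
class TargetedFit:
    """TMLE targeting diagnostics: clever covariate, fluctuation
    coefficient and targeted predictions on the original outcome scale."""

    H: np.ndarray
    epsilon: float
    e1_star: np.ndarray
    e0_star: np.ndarray
    bounds: tuple[float, float]
    n_clipped: int = 0


@dataclass
class EffectEstimate:
    """Point estimate of the ACE with EIF-based Wald inference."""

    psi: float
    se: float
    ci_low: float
    ci_high: float
    eif: np.ndarray
    method: str
    folds: int | None = None
    library: str | None = None
    seed: int | None = None
    n: int = 0
    diagnostics: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "method": self.method, "folds": self.folds, "library": self.library,
            "psi": self.psi, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n": self.n, "seed": self.seed,
        }


@dataclass
class FoldAssignment:
    """Random partition into K folds of sizes differing by at most one."""

    K: int
    fold: np.ndarray
    seed: int


def _wald(psi: float, se: float) -> tuple[float, float]:
    return psi - Z_95 * se, psi + Z_95 * se


def _if_se(values: np.ndarray, center: float) -> tuple[float, np.ndarray]:
    """EIF-based standard error: sqrt of the sample variance of the
    per-record influence terms (centred at the estimate) divided by n."""
    n = values.size
    eif = values - center
    se = float(np.sqrt(np.sum(eif**2) / (n * (n - 1))))
    return se, eif


def _aipw_terms(data: ObservedData, nuis: NuisanceEstimates) -> np.ndarray:
    X, Y = data.X, data.Y
    return (
        nuis.e1 - nuis.e0
        + X * (Y - nuis.e1) / nuis.g
        - (1 - X) * (Y - nuis.e0) / (1 - nuis.g)
    )


def aipw(data: ObservedData, nuis: NuisanceEstimates, **meta) -> EffectEstimate:
    """One-step (AIPW) estimate of the ACE with EIF-based inference."""
    if nuis.e1.shape[0] != data.n:
        raise DataValidationError("nuisance estimates not aligned with data")
    terms = _aipw_terms(data, nuis)
    psi = float(terms.mean())
    se, eif = _if_se(terms, psi)
    lo, hi = _wald(psi, se)
    return EffectEstimate(psi=psi, se=se, ci_low=lo, ci_high=hi, eif=eif,
                          method="aipw", n=data.n, **meta)


# ---------------------------------------------------------------------------
# TMLE

_LOGIT_GUARD = 1e-12  # numerical guard for logits of scaled predictions
_RANGE_CLIP = 1e-4    # spec'd clip for scaled predictions outside [0, 1]


def _scale_predictions(pred_s: np.ndarray) -> tuple[np.ndarray, int]:
    """Clip scaled predictions that fall outside [0, 1] to the working
    range [1e-4, 1-1e-4]; values inside [0, 1] are preserved up to a tiny
    logit guard so that boundary predictions stay effectively unchanged."""
    n_out = int(np.sum((pred_s < 0) | (pred_s > 1)))
    out = np.where(pred_s < 0, _RANGE_CLIP, pred_s)
    out = np.where(pred_s > 1, 1 - _RANGE_CLIP, out)
    return np.clip(out, _LOGIT_GUARD, 1 - _LOGIT_GUARD), n_out


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _solve_fluctuation(y_s: np.ndarray, offset: np.ndarray, H: np.ndarray,
                       tol: float = 1e-11, max_iter: int = 100) -> float:
    """Newton solve of the intercept-free logistic fluctuation score
    (1/n) sum H_i (y_i - expit(offset_i + eps H_i)) = 0."""
    n = y_s.size
    eps = 0.0
    for _ in range(max_iter):
        p = expit(offset + eps * H)
        score = float(np.sum(H * (y_s - p))) / n
        if abs(score) < tol:
            return eps
        info = float(np.sum(H**2 * p * (1 - p))) / n
        if info <= 0:
            break
        step = score / info
        eps += np.clip(step, -5.0, 5.0)
    p = expit(offset + eps * H)
    score = float(np.sum(H * (y_s - p))) / n
    if abs(score) < 1e-9:
        return eps
    raise TargetingError(f"fluctuation failed to converge (score {score:.3g})")


def tmle(data: ObservedData, nuis: NuisanceEstimates, **meta) -> EffectEstimate:
    """Targeted maximum likelihood estimate of the ACE.

    Uses the bounded continuous-outcome recipe: scale Y and the initial
    predictions to [0, 1] by the observed outcome range, fluctuate with a
    single epsilon along the clever covariate, back-transform.  The
    targeted predictions (and hence the estimate) stay within the
    observed outcome range.
    """
    if nuis.e1.shape[0] != data.n:
        raise DataValidationError("nuisance estimates not aligned with data")
    a, b = float(data.Y.min()), float(data.Y.max())
    if b - a <= 0:
        raise TargetingError("degenerate outcome: all values identical")
    return _tmle_on_bounds(data, nuis, (a, b), **meta)


def _tmle_on_bounds(data: ObservedData, nuis: NuisanceEstimates,
                    bounds: tuple[float, float], **meta) -> EffectEstimate:
    a, b = bounds
    span = b - a
    X, Y = data.X, data.Y
    y_s = np.clip((Y - a) / span, 0.0, 1.0)
    e1_s, c1 = _scale_predictions((nuis.e1 - a) / span)
    e0_s, c0 = _scale_predictions((nuis.e0 - a) / span)
    ex_s = np.where(X == 1, e1_s, e0_s)
    H = X / nuis.g - (1 - X) / (1 - nuis.g)
    eps = _solve_fluctuation(y_s, _logit(ex_s), H)
    e1_star_s = expit(_logit(e1_s) + eps / nuis.g)
    e0_star_s = expit(_logit(e0_s) - eps / (1 - nuis.g))
    e1_star = a + span * e1_star_s
    e0_star = a + span * e0_star_s
    psi = float(np.mean(e1_star - e0_star))
    ex_star = np.where(X == 1, e1_star, e0_star)
    values = H * (Y - ex_star) + (e1_star - e0_star)
    se, eif = _if_se(values, psi)
    lo, hi = _wald(psi, se)
    fit = TargetedFit(H=H, epsilon=eps, e1_star=e1_star, e0_star=e0_star,
                      bounds=(a, b), n_clipped=c1 + c0)
    est = EffectEstimate(psi=psi, se=se, ci_low=lo, ci_high=hi, eif=eif,
                         method="tmle", n=data.n, **meta)
    est.diagnostics["targeting"] = fit
    return est


# ---------------------------------------------------------------------------
# cross-fitting


def make_folds(n: int, K: int, seed: int, strata=None) -> FoldAssignment:
    """Random partition of n records into K folds of near-equal size,
    optionally stratified (records are shuffled within strata, then dealt
    cyclically, keeping both global and per-stratum balance)."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < 2 * K:
        raise ValueError(f"n={n} too small for K={K} folds (need n >= 2K)")
    rng = np.random.default_rng(seed)
    if strata is None:
        order = rng.permutation(n)
    else:
        strata = np.asarray(strata)
        order = np.concatenate([
            rng.permutation(np.flatnonzero(strata == s))
            for s in np.unique(strata)
        ])
    fold = np.empty(n, dtype=int)
    fold[order] = np.arange(n) % K
    # rotate fold labels randomly so no fold is systematically largest
    shift = int(rng.integers(K))
    fold = (fold + shift) % K
    return FoldAssignment(K=K, fold=fold, seed=seed)


@runtime_checkable
class NuisanceFitter(Protocol):
    """Fits both nuisance models on training data and predicts Ê1, Ê0, ĝ
    for test records.  Implementations must be pure functions of their
    inputs and the seed."""

    def fit_predict(self, train: ObservedData, test: ObservedData,
                    seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ...  # pragma: no cover


@dataclass
class SuperLearnerNuisance:
    """Super Learner nuisances: an ensemble regression of Y on (X, W) for
    the outcome model and an ensemble classification of X on W for the
    propensity score."""

    library: str | Sequence[LearnerSpec] = "reduced"
    v_folds: int = 10

    def _libs(self):
        if isinstance(self.library, str):
            return (get_library(self.library, "regression"),
                    get_library(self.library, "classification"))
        reg = tuple(s for s in self.library if s.task == "regression")
        clf = tuple(s for s in self.library if s.task == "classification")
        if not reg or not clf:
            reg = tuple(dataclasses.replace(s, task="regression") for s in self.library)
            clf = tuple(dataclasses.replace(s, task="classification") for s in self.library)
        return reg, clf

    def fit_predict(self, train, test, seed):
        reg_lib, clf_lib = self._libs()
        s_out, s_ps = np.random.SeedSequence(seed).spawn(2)
        s_out = int(s_out.generate_state(1)[0] % (2**31 - 1))
        s_ps = int(s_ps.generate_state(1)[0] % (2**31 - 1))
        feats = np.column_stack([train.X, train.W])
        out_model = fit_super_learner(feats, train.Y, reg_lib,
                                      v_folds=self.v_folds, seed=s_out)
        ps_model = fit_super_learner(train.W, train.X, clf_lib,
                                     v_folds=self.v_folds, seed=s_ps)
        ones = np.ones(test.n)
        e1 = predict_ensemble(out_model, np.column_stack([ones, test.W]))
        e0 = predict_ensemble(out_model, np.column_stack([0 * ones, test.W]))
        g = predict_ensemble(ps_model, test.W)
        return e1, e0, g


@dataclass
class ParametricNuisance:
    """Plain main-effects GLM nuisances (OLS outcome, logistic exposure),
    with optional feature transforms to deliberately misspecify one model
    (used in double-robustness checks)."""

    outcome_features: Callable[[np.ndarray], np.ndarray] | None = None
    ps_features: Callable[[np.ndarray], np.ndarray] | None = None

    def fit_predict(self, train, test, seed):
        del seed  # deterministic fits
        fo = self.outcome_features or (lambda W: W)
        fp = self.ps_features or (lambda W: W)
        D = np.column_stack([np.ones(train.n), train.X, fo(train.W)])
        coef, *_ = np.linalg.lstsq(D, train.Y, rcond=None)
        ones = np.ones(test.n)
        e1 = np.column_stack([ones, ones, fo(test.W)]) @ coef
        e0 = np.column_stack([ones, 0 * ones, fo(test.W)]) @ coef
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e4, max_iter=2000, tol=1e-8)
        clf.fit(fp(train.W), train.X.astype(int))
        g = np.clip(clf.predict_proba(fp(test.W))[:, 1], 1e-6, 1 - 1e-6)
        return e1, e0, g


@dataclass
class OracleNuisance:
    """True data-generating nuisance functions, injectable for testing."""

    params: object  # DGMParams

    def fit_predict(self, train, test, seed):
        del train, seed
        from .dgm import conditional_outcome_mean, exposure_linpred

        e1 = conditional_outcome_mean(test.W, np.ones(test.n), self.params)
        e0 = conditional_outcome_mean(test.W, np.zeros(test.n), self.params)
        g = np.clip(expit(exposure_linpred(test.W, self.params)), 1e-6, 1 - 1e-6)
        return e1, e0, g


def _resolve_fitter(library) -> tuple[NuisanceFitter, str]:
    if isinstance(library, str):
        return SuperLearnerNuisance(library=library), library
    if isinstance(library, NuisanceFitter):
        return library, type(library).__name__
    return SuperLearnerNuisance(library=tuple(library)), "custom"


def crossfit(data: ObservedData, K: int, method: str, library,
             seed: int = 0, truncate: bool = True,
             pooled_truncation: bool = False) -> EffectEstimate:
    """K-fold cross-fitted estimate of the ACE.

    For each fold, both nuisance models are fitted on the complement and
    evaluated on the held-out fold; propensity scores are truncated
    within each held-out prediction vector (or pooled across folds with
    ``pooled_truncation``).  AIPW pools the out-of-fold influence terms;
    TMLE performs targeting within each held-out fold and averages the
    fold estimates weighted by fold size.  Standard errors use the pooled
    out-of-fold EIF centred at the overall estimate.
    """
    if method not in ("aipw", "tmle"):
        raise ValueError(f"unknown method '{method}'")
    fitter, lib_name = _resolve_fitter(library)
    folds = make_folds(data.n, K, seed, strata=data.X)
    n = data.n
    e1 = np.empty(n)
    e0 = np.empty(n)
    g = np.empty(n)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                  for s in np.random.SeedSequence((seed, 13)).spawn(K)]
    for k in range(K):
        test_idx = np.flatnonzero(folds.fold == k)
        train_idx = np.flatnonzero(folds.fold != k)
        x_train = data.X[train_idx]
        if x_train.sum() == 0 or x_train.sum() == x_train.size:
            raise SparseExposureError(
                f"fold {k}: complement has no "
                f"{'exposed' if x_train.sum() == 0 else 'unexposed'} records; "
                "use fewer folds")
        e1_k, e0_k, g_k = fitter.fit_predict(
            data.subset(train_idx), data.subset(test_idx), fold_seeds[k])
        if truncate and not pooled_truncation:
            g_k = truncate_ps(g_k)
        e1[test_idx], e0[test_idx], g[test_idx] = e1_k, e0_k, g_k
    if truncate and pooled_truncation:
        g = truncate_ps(g)
    nuis = NuisanceEstimates(e1=e1, e0=e0, g=g, out_of_fold=True)
    meta = dict(folds=K, library=lib_name, seed=seed)

    if method == "aipw":
        return aipw(data, nuis, **meta)

    # TMLE: fold-wise targeting on a common outcome range, fold-size
    # weighted pooling of the substitution estimates, pooled EIF variance
    a, b = float(data.Y.min()), float(data.Y.max())
    if b - a <= 0:
        raise TargetingError("degenerate outcome: all values identical")
    values = np.empty(n)
    psi_folds = np.empty(K)
    weights = np.empty(K)
    total_clipped = 0
    for k in range(K):
        idx = np.flatnonzero(folds.fold == k)
        sub = data.subset(idx)
        sub_nuis = NuisanceEstimates(e1=e1[idx], e0=e0[idx], g=g[idx],
                                     out_of_fold=True)
        est_k = _tmle_on_bounds(sub, sub_nuis, (a, b))
        fitk: TargetedFit = est_k.diagnostics["targeting"]
        values[idx] = fitk.H * (sub.Y - np.where(sub.X == 1, fitk.e1_star,
                                                 fitk.e0_star)) \
            + (fitk.e1_star - fitk.e0_star)
        psi_folds[k] = est_k.psi
        weights[k] = idx.size / n
        total_clipped += fitk.n_clipped
    psi = float(np.sum(weights * psi_folds))
    se, eif = _if_se(values, psi)
    lo, hi = _wald(psi, se)
    est = EffectEstimate(psi=psi, se=se, ci_low=lo, ci_high=hi, eif=eif,
                         method="tmle", n=n, **meta)
    est.diagnostics.update(fold_estimates=psi_folds.tolist(),
                           n_clipped=total_clipped)
    return est


def estimate_ace(data: ObservedData, method: str = "tmle",
                 folds: int | None = None, library="reduced",
                 seed: int = 0, truncate: bool = True) -> EffectEstimate:
    """Estimate the ACE with or without cross-fitting.

    Without cross-fitting, nuisance models are fitted on the full sample
    and evaluated in-sample; the propensity scores are truncated at
    their 5th/95th percentiles before estimation.
    """
    if folds is not None:
        return crossfit(data, folds, method, library, seed=seed,
                        truncate=truncate)
    if method not in ("aipw", "tmle"):
        raise ValueError(f"unknown method '{method}'")
    fitter, lib_name = _resolve_fitter(library)
    e1, e0, g = fitter.fit_predict(data, data, seed)
    if truncate:
        g = truncate_ps(g)
    nuis = NuisanceEstimates(e1=e1, e0=e0, g=g, out_of_fold=False)
    fn = aipw if method == "aipw" else tmle
    return fn(data, nuis, folds=None, library=lib_name, seed=seed)


def analyze(data, method: str = "tmle", folds: int | None = None,
            library="reduced", seed: int = 0) -> tuple[EffectEstimate, dict]:
    """Applied-analysis entry point: run the full pipeline on a user
    dataset (``ObservedData``, data frame, or CSV path with columns
    ``y, x, w*``) and report the estimate together with a
    propensity-score overlap summary by exposure group."""
    import pandas as pd

    if isinstance(data, (str, bytes)) or hasattr(data, "read"):
        data = ObservedData.from_frame(pd.read_csv(data))
    elif isinstance(data, pd.DataFrame):
        data = ObservedData.from_frame(data)
    if data.X.sum() == 0 or data.X.sum() == data.n:
        raise DataValidationError("exposure must have both levels present")
    est = estimate_ace(data, method=method, folds=folds, library=library,
                       seed=seed)
    # overlap diagnostics from a full-sample propensity fit
    fitter, _ = _resolve_fitter(library)
    _, _, g = fitter.fit_predict(data, data, seed)
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    diag = {
        "ps_summary": {
            "exposed": dict(zip(("min", "q1", "median", "q3", "max"),
                                np.quantile(g[data.X == 1], qs).round(4).tolist())),
            "unexposed": dict(zip(("min", "q1", "median", "q3", "max"),
                                  np.quantile(g[data.X == 0], qs).round(4).tolist())),
        },
        "n_exposed": int(data.X.sum()),
        "n_unexposed": int(data.n - data.X.sum()),
    }
    return est, diag
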