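"""Synthetic data-generating mechanisms (DGMs) for confounded exposure studies.

Each mechanism generates, in a fixed sequential order, a mixed set of
binary and continuous confounders with mutual dependence, then a binary
exposure from a logistic model and a continuous outcome from a Gaussian
linear model.  *Simple* mechanisms use main effects only with linear
associations; *complex* mechanisms add two-way interactions
(confounder-confounder in the exposure and outcome models,
exposure-confounder in the outcome model) and non-linear terms (squares
and ``log(|z|+1)`` transforms of designated continuous confounders),
with a scalar multiplier applied to all interaction coefficients.

Two calibration routines keep mechanisms comparable across scenarios:
``calibrate_intercept`` re-centres the marginal outcome mean at zero,
and ``calibrate_effect`` tunes the exposure main effect so that the
efficient doubly robust test, evaluated at the exactly specified
nuisance functions, rejects the null of no effect in a target fraction
(default 80%) of replicate datasets.
The true average causal effect of a calibrated mechanism is obtained
empirically from noise-free potential-outcome means in a single very
large sample (``true_ace``).

All generators are pure functions of ``(params, n, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .data import ObservedData

__all__ = [
    "ConfounderModel",
    "DGMParams",
    "ScenarioTruth",
    "ConfigurationError",
    "CalibrationError",
    "generate_confounders",
    "generate_exposure",
    "generate_outcome",
    "simulate_dataset",
    "conditional_outcome_mean",
    "exposure_linpred",
    "calibrate_intercept",
    "with_calibrated_intercept",
    "calibrate_effect",
    "rejection_rate",
    "true_ace",
]

FAMILIES = ("bernoulli-logistic", "gaussian-linear", "categorical-multinomial")


class ConfigurationError(ValueError):
    """A DGM parameterization is internally inconsistent."""


class CalibrationError(RuntimeError):
    """A calibration routine failed to reach its target."""


@dataclass(frozen=True)
class ConfounderModel:
    """Generation rule for one confounder, conditional on all previously
    emitted columns.

    ``coefs`` must have one entry per previously emitted matrix column
    (generation is therefore acyclic by construction).  Categorical
    variables use a baseline-category multinomial logit and are emitted
    as ``k-1`` indicator columns.
    """

    name: str
    family: str
    intercept: float = 0.0
    coefs: tuple[float, ...] = ()
    sd: float = 1.0
    level_intercepts: tuple[float, ...] = ()
    level_coefs: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"confounder '{self.name}': unknown family '{self.family}' "
                f"(expected one of {FAMILIES})"
            )
        if self.family == "categorical-multinomial" and not self.level_intercepts:
            raise ConfigurationError(
                f"confounder '{self.name}': categorical family requires level_intercepts"
            )
        if self.family == "gaussian-linear" and self.sd <= 0:
            raise ConfigurationError(f"confounder '{self.name}': sd must be positive")

    @property
    def n_columns(self) -> int:
        if self.family == "categorical-multinomial":
            return len(self.level_intercepts)
        return 1


@dataclass(frozen=True)
class DGMParams:
    """Full parameterization of one data-generating mechanism.

    Interaction and non-linear coefficient blocks are stored at their
    base values; ``interaction_multiplier`` scales the interaction
    coefficients (in both the exposure and the outcome model) at
    generation time.  Simple mechanisms must carry identically zero
    interaction and non-linear blocks.
    """

    name: str
    complexity: str  # "simple" | "complex"
    p: int
    n_continuous: int
    confounder_models: tuple[ConfounderModel, ...]
    # exposure model (logistic)
    exposure_intercept: float
    exposure_main: tuple[float, ...]
    exposure_ww_pairs: tuple[tuple[int, int], ...] = ()
    exposure_ww_coefs: tuple[float, ...] = ()
    exposure_nl_idx: tuple[int, ...] = ()
    exposure_sq_coefs: tuple[float, ...] = ()
    exposure_log_coefs: tuple[float, ...] = ()
    # outcome model (Gaussian)
    outcome_intercept: float = 0.0
    outcome_effect: float = 0.0  # exposure main effect (beta_X)
    outcome_main: tuple[float, ...] = ()
    outcome_ww_pairs: tuple[tuple[int, int], ...] = ()
    outcome_ww_coefs: tuple[float, ...] = ()
    outcome_xw_idx: tuple[int, ...] = ()
    outcome_xw_coefs: tuple[float, ...] = ()
    outcome_nl_idx: tuple[int, ...] = ()
    outcome_sq_coefs: tuple[float, ...] = ()
    outcome_log_coefs: tuple[float, ...] = ()
    residual_sd: float = 1.0
    interaction_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.complexity not in ("simple", "complex"):
            raise ConfigurationError(f"unknown complexity '{self.complexity}'")
        if self.p != len(self.confounder_models):
            raise ConfigurationError(
                f"p={self.p} but {len(self.confounder_models)} confounder models given"
            )
        n_cont = sum(m.family == "gaussian-linear" for m in self.confounder_models)
        if n_cont != self.n_continuous:
            raise ConfigurationError(
                f"n_continuous={self.n_continuous} but {n_cont} gaussian models given"
            )
        ncols = 0
        for m in self.confounder_models:
            if len(m.coefs) != ncols:
                raise ConfigurationError(
                    f"confounder '{m.name}': expected {ncols} dependence coefficients "
                    f"(one per previously generated column), got {len(m.coefs)}"
                )
            if m.family == "categorical-multinomial":
                for row in m.level_coefs:
                    if len(row) != ncols:
                        raise ConfigurationError(
                            f"confounder '{m.name}': level_coefs rows must have length {ncols}"
                        )
            ncols += m.n_columns
        if len(self.exposure_main) != ncols or len(self.outcome_main) != ncols:
            raise ConfigurationError(
                f"main-effect vectors must have length {ncols} (emitted columns)"
            )
        for pairs, coefs, label in (
            (self.exposure_ww_pairs, self.exposure_ww_coefs, "exposure_ww"),
            (self.outcome_ww_pairs, self.outcome_ww_coefs, "outcome_ww"),
        ):
            if len(pairs) != len(coefs):
                raise ConfigurationError(f"{label}: pairs and coefficients differ in length")
            for i, j in pairs:
                if not (0 <= i < ncols and 0 <= j < ncols):
                    raise ConfigurationError(f"{label}: pair ({i},{j}) out of range")
        for idx, sq, lg, label in (
            (self.exposure_nl_idx, self.exposure_sq_coefs, self.exposure_log_coefs, "exposure_nl"),
            (self.outcome_nl_idx, self.outcome_sq_coefs, self.outcome_log_coefs, "outcome_nl"),
        ):
            if len(idx) != len(sq) or len(idx) != len(lg):
                raise ConfigurationError(f"{label}: index/coefficient length mismatch")
        if len(self.outcome_xw_idx) != len(self.outcome_xw_coefs):
            raise ConfigurationError("outcome_xw: index/coefficient length mismatch")
        if self.residual_sd < 0:
            raise ConfigurationError("residual_sd must be non-negative")
        if self.complexity == "simple":
            blocks = (
                self.exposure_ww_coefs + self.exposure_sq_coefs + self.exposure_log_coefs
                + self.outcome_ww_coefs + self.outcome_xw_coefs
                + self.outcome_sq_coefs + self.outcome_log_coefs
            )
            if any(c != 0.0 for c in blocks):
                raise ConfigurationError(
                    "simple mechanisms must have all interaction and non-linear "
                    "coefficients identically zero"
                )

    @property
    def n_columns(self) -> int:
        """Number of emitted confounder-matrix columns (equals ``p`` unless
        categorical variables are present)."""
        return sum(m.n_columns for m in self.confounder_models)


@dataclass(frozen=True)
class ScenarioTruth:
    """Empirically evaluated true average causal effect of a mechanism."""

    theta: float
    n_truth: int
    seed: int


# ---------------------------------------------------------------------------
# generation


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_confounders(params: DGMParams, n: int, seed) -> np.ndarray:
    """Draw an ``n x n_columns`` confounder matrix, each variable from its
    stated family conditional on the previously generated columns."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = _rng(seed)
    W = np.empty((n, params.n_columns))
    c = 0
    for m in params.confounder_models:
        prev = W[:, :c]
        lp = m.intercept + prev @ np.asarray(m.coefs)
        if m.family == "bernoulli-logistic":
            W[:, c] = (rng.random(n) < expit(lp)).astype(float)
            c += 1
        elif m.family == "gaussian-linear":
            W[:, c] = lp + m.sd * rng.standard_normal(n)
            c += 1
        else:  # categorical-multinomial, baseline level emits no column
            k1 = len(m.level_intercepts)
            util = np.zeros((n, k1 + 1))
            for lev in range(k1):
                lev_co = np.asarray(m.level_coefs[lev]) if m.level_coefs else np.zeros(c)
                util[:, lev + 1] = m.level_intercepts[lev] + prev @ lev_co
            probs = np.exp(util - util.max(axis=1, keepdims=True))
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            draw = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
            for lev in range(k1):
                W[:, c + lev] = (draw == lev + 1).astype(float)
            c += k1
    return W


def _nl_contrib(W: np.ndarray, idx, sq, lg) -> np.ndarray:
    if not idx:
        return np.zeros(W.shape[0])
    Z = W[:, list(idx)]
    return Z**2 @ np.asarray(sq) + np.log(np.abs(Z) + 1.0) @ np.asarray(lg)


def _ww_contrib(W: np.ndarray, pairs, coefs) -> np.ndarray:
    if not pairs:
        return np.zeros(W.shape[0])
    ii = [i for i, _ in pairs]
    jj = [j for _, j in pairs]
    return (W[:, ii] * W[:, jj]) @ np.asarray(coefs)


def exposure_linpred(W: np.ndarray, params: DGMParams) -> np.ndarray:
    """Logit-scale linear predictor of the exposure model."""
    if W.shape[1] != params.n_columns:
        raise ConfigurationError(
            f"W has {W.shape[1]} columns, mechanism emits {params.n_columns}"
        )
    m = params.interaction_multiplier
    lp = params.exposure_intercept + W @ np.asarray(params.exposure_main)
    lp += m * _ww_contrib(W, params.exposure_ww_pairs, params.exposure_ww_coefs)
    lp += _nl_contrib(W, params.exposure_nl_idx, params.exposure_sq_coefs,
                      params.exposure_log_coefs)
    return lp


def conditional_outcome_mean(W: np.ndarray, X: np.ndarray, params: DGMParams) -> np.ndarray:
    """Noise-free conditional outcome mean E[Y | X, W] under the mechanism."""
    m = params.interaction_multiplier
    X = np.asarray(X, dtype=float)
    lp = params.outcome_intercept + params.outcome_effect * X
    lp = lp + W @ np.asarray(params.outcome_main)
    lp += m * _ww_contrib(W, params.outcome_ww_pairs, params.outcome_ww_coefs)
    if params.outcome_xw_idx:
        lp += m * (X[:, None] * W[:, list(params.outcome_xw_idx)]) @ np.asarray(
            params.outcome_xw_coefs
        )
    lp += _nl_contrib(W, params.outcome_nl_idx, params.outcome_sq_coefs,
                      params.outcome_log_coefs)
    return lp


def generate_exposure(W: np.ndarray, params: DGMParams, seed) -> np.ndarray:
    """Bernoulli exposure draws from the logistic exposure model."""
    lp = exposure_linpred(W, params)
    if not np.all(np.isfinite(lp)):
        raise ConfigurationError("non-finite exposure linear predictor")
    rng = _rng(seed)
    return (rng.random(W.shape[0]) < expit(lp)).astype(float)


def generate_outcome(W: np.ndarray, X: np.ndarray, params: DGMParams, seed) -> np.ndarray:
    """Gaussian outcome draws around the conditional mean."""
    if W.shape[0] != np.asarray(X).shape[0]:
        raise ConfigurationError("W and X lengths disagree")
    mu = conditional_outcome_mean(W, X, params)
    if not np.all(np.isfinite(mu)):
        raise ConfigurationError("non-finite outcome linear predictor")
    rng = _rng(seed)
    return mu + params.residual_sd * rng.standard_normal(W.shape[0])


def simulate_dataset(params: DGMParams, n: int, seed: int) -> ObservedData:
    """Generate one complete analysis sample.

    Confounders, exposure and outcome use independent child streams of
    ``seed`` so that, e.g., changing only the outcome coefficients leaves
    the generated ``(W, X)`` unchanged.
    """
    s_w, s_x, s_y = np.random.SeedSequence(seed).spawn(3)
    W = generate_confounders(params, n, s_w)
    X = generate_exposure(W, params, s_x)
    Y = generate_outcome(W, X, params, s_y)
    return ObservedData(W, X, Y)


# ---------------------------------------------------------------------------
# calibration

#: Fixed seed for the large calibration sample used by the intercept and
#: effect calibrations; part of the versioned mechanism definition.
CALIBRATION_SEED = 202_501


def calibrate_intercept(
    params: DGMParams,
    n: int = 1_000_000,
    seed: int = CALIBRATION_SEED,
    tol: float = 0.005,
    max_iter: int = 40,
) -> float:
    """Return the outcome intercept that centres the marginal mean of Y at 0.

    Because the outcome mean is linear in the intercept, a single large
    simulated ``(W, X)`` sample yields the answer in one linear solve:
    the intercept is minus the mean of all remaining (noise-free) outcome
    terms.  The residual |mean Y| on the calibration sample is zero by
    construction; on a fresh draw it is bounded by sampling error, well
    inside ``tol`` at the default sample size.
    """
    del max_iter  # linear solve: no iteration needed
    s_w, s_x = np.random.SeedSequence(seed).spawn(2)
    W = generate_confounders(params, n, s_w)
    X = generate_exposure(W, params, s_x)
    base = dataclasses.replace(params, outcome_intercept=0.0)
    resid = float(np.mean(conditional_outcome_mean(W, X, base)))
    beta0 = -resid
    check = beta0 + resid
    if abs(check) > tol:  # pragma: no cover - linear solve is exact
        raise CalibrationError(f"intercept calibration residual mean {check:.4g}")
    return beta0


def with_calibrated_intercept(params: DGMParams, n: int = 1_000_000,
                              seed: int = CALIBRATION_SEED) -> DGMParams:
    """Convenience wrapper returning params with the centred intercept."""
    return dataclasses.replace(
        params, outcome_intercept=calibrate_intercept(params, n=n, seed=seed)
    )


class _PowerEngine:
    """Common-random-number engine for power evaluation under a mechanism.

    The rejection test is the efficient one-step (AIPW) analysis evaluated
    at the exactly specified nuisance functions — the true conditional
    outcome means and the true propensity score, both known under
    simulation.  This keeps the test size nominal in every scenario
    (feasible nuisance fits with ~p covariates at n comparable to p
    severely inflate size, which would confound the power target with
    finite-sample size distortion).

    Only the outcome depends on the exposure main effect, so per-replicate
    confounders, exposure and noise are drawn once; the per-record
    influence terms are affine in beta_X, making each power evaluation a
    pure array operation and the calibration search deterministic.
    """

    def __init__(self, params: DGMParams, n: int, reps: int, seed: int,
                 n_cal: int = 200_000):
        self.params = params
        self.n = n
        self.reps = reps
        # intercept calibration pieces: beta0(bX) = -(m0 + bX * xbar)
        s_w, s_x = np.random.SeedSequence((seed, 0)).spawn(2)
        Wc = generate_confounders(params, n_cal, s_w)
        Xc = generate_exposure(Wc, params, s_x)
        base = dataclasses.replace(params, outcome_intercept=0.0, outcome_effect=0.0)
        self._m0 = float(np.mean(conditional_outcome_mean(Wc, Xc, base)))
        b1 = dataclasses.replace(params, outcome_intercept=0.0, outcome_effect=1.0)
        self._xterm = float(np.mean(conditional_outcome_mean(Wc, Xc, b1))) - self._m0

        A = np.empty((reps, n))
        B = np.empty((reps, n))
        root = np.random.SeedSequence((seed, 1))
        for r, child in enumerate(root.spawn(reps)):
            s_wr, s_xr, s_er = child.spawn(3)
            W = generate_confounders(params, n, s_wr)
            X = generate_exposure(W, params, s_xr)
            eps = params.residual_sd * _rng(s_er).standard_normal(n)
            g = np.clip(expit(exposure_linpred(W, params)), 1e-12, 1 - 1e-12)
            A[r] = self._terms(0.0, W, X, eps, g)
            B[r] = self._terms(1.0, W, X, eps, g) - A[r]
        self._A, self._B = A, B

    def beta0(self, beta_x: float) -> float:
        return -(self._m0 + beta_x * self._xterm)

    def _terms(self, beta_x, W, X, eps, g) -> np.ndarray:
        pp = dataclasses.replace(
            self.params, outcome_effect=beta_x, outcome_intercept=self.beta0(beta_x)
        )
        n = W.shape[0]
        mu1 = conditional_outcome_mean(W, np.ones(n), pp)
        mu0 = conditional_outcome_mean(W, np.zeros(n), pp)
        Y = np.where(X == 1, mu1, mu0) + eps
        return (
            mu1 - mu0
            + X * (Y - mu1) / g
            - (1 - X) * (Y - mu0) / (1 - g)
        )

    def power(self, beta_x: float, alpha: float = 0.05) -> float:
        T = self._A + beta_x * self._B
        psi = T.mean(axis=1)
        dev = T - psi[:, None]
        se = np.sqrt((dev**2).sum(axis=1) / (self.n * (self.n - 1)))
        z = norm.ppf(1 - alpha / 2)
        return float(np.mean(np.abs(psi) > z * se))


def calibrate_effect(
    params: DGMParams,
    n: int,
    target_power: float = 0.80,
    alpha: float = 0.05,
    reps: int = 400,
    seed: int = CALIBRATION_SEED,
    tol: float = 0.03,
    max_iter: int = 40,
    beta_max: float = 10.0,
) -> float:
    """Bisection search for the exposure main effect achieving the target
    rejection rate of H0: ACE = 0 at sample size ``n``.

    The rejection rate is assessed on ``reps`` replicate datasets with
    the efficient one-step doubly robust analysis evaluated at the
    exactly specified nuisance functions (see :class:`_PowerEngine`).
    Common random numbers across candidate effects make the search
    deterministic and nearly monotone.  The outcome intercept is
    re-centred (via the linear solve of ``calibrate_intercept``) at every
    candidate effect size.
    """
    if not 0 < target_power < 1:
        raise CalibrationError("target_power must be in (0, 1)")
    engine = _PowerEngine(params, n, reps, seed)
    lo, p_lo = 0.0, engine.power(0.0, alpha)
    hi = 0.25
    p_hi = engine.power(hi, alpha)
    while p_hi < target_power:
        hi *= 2.0
        if hi > beta_max:
            raise CalibrationError(
                f"target power {target_power} unreachable below beta_x={beta_max}; "
                f"achieved power range [{p_lo:.3f}, {p_hi:.3f}]"
            )
        p_hi = engine.power(hi, alpha)
    best, best_p = hi, p_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = engine.power(mid, alpha)
        if abs(p_mid - target_power) < abs(best_p - target_power):
            best, best_p = mid, p_mid
        if p_mid < target_power:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    if abs(best_p - target_power) > tol:
        raise CalibrationError(
            f"calibration stalled: closest achievable power {best_p:.3f} "
            f"at beta_x={best:.4f} (target {target_power} +/- {tol})"
        )
    return best


def rejection_rate(params: DGMParams, n: int, reps: int = 400,
                   seed: int = 1, alpha: float = 0.05) -> float:
    """Rejection proportion of H0: ACE = 0 under ``params`` (at its current
    exposure effect), using the same exactly specified doubly robust
    analysis as ``calibrate_effect``, on fresh replicates."""
    engine = _PowerEngine(params, n, reps, seed)
    return engine.power(params.outcome_effect, alpha)


def true_ace(params: DGMParams, n_truth: int = 1_000_000,
             seed: int = CALIBRATION_SEED, chunk: int = 200_000) -> ScenarioTruth:
    """Empirical true ACE from noise-free potential-outcome conditional
    means averaged over a single very large confounder sample.

    Evaluation is chunked to bound memory; the result is deterministic
    given ``seed`` (child streams per chunk).
    """
    n_chunks = int(np.ceil(n_truth / chunk))
    children = np.random.SeedSequence((seed, 7)).spawn(n_chunks)
    total, count = 0.0, 0
    for k, child in enumerate(children):
        m = min(chunk, n_truth - k * chunk)
        W = generate_confounders(params, m, child)
        mu1 = conditional_outcome_mean(W, np.ones(m), params)
        mu0 = conditional_outcome_mean(W, np.zeros(m), params)
        total += float(np.sum(mu1 - mu0))
        count += m
    return ScenarioTruth(theta=total / count, n_truth=count, seed=seed)
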