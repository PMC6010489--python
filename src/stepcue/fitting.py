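"""Maximum-likelihood fitting of step-length families and AICc model selection.

`StepLengthModel` is a scikit-learn style density estimator (fit /
score_samples / sample, `get_params` / `set_params`) over the truncated
families in :mod:`stepcue.families`.  Module-level functions provide the
comparison machinery: AICc, pairwise and multi-model Akaike weights, the
across-individuals exact binomial sign test, pooled fits and
rank-frequency (complementary cumulative) curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils.validation import check_is_fitted, column_or_1d

from .families import (
    FAMILIES,
    ModelSpec,
    SupportBounds,
    log_normalization,
    sample as family_sample,
)

__all__ = [
    "StepSample",
    "FitResult",
    "ModelComparison",
    "StepLengthModel",
    "InsufficientStepsError",
    "fit",
    "aicc",
    "pairwise_weight",
    "multi_model_weights",
    "sign_test",
    "pooled_fit",
    "rank_frequency",
]


class InsufficientStepsError(ValueError):
    """Too few steps to fit the requested family (n < k + 2)."""


@dataclass
class StepSample:
    """Ordered positive step lengths (m) for one individual or a pool."""

    lengths: np.ndarray
    individual: str | None = None
    condition: str | None = None
    bounds: SupportBounds | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.size == 0:
            raise ValueError("StepSample must be non-empty")
        if np.any(~np.isfinite(self.lengths)) or np.any(self.lengths <= 0):
            raise ValueError("step lengths must be finite and positive")
        if self.bounds is not None and not np.all(self.bounds.contains(self.lengths)):
            raise ValueError("step lengths outside the declared bounds")

    @property
    def n(self) -> int:
        return int(self.lengths.size)


@dataclass(frozen=True)
class FitResult:
    """A fitted family on a sample: parameters, log-likelihood and AICc."""

    model: ModelSpec
    log_likelihood: float
    n: int
    bounds: SupportBounds
    converged: bool = True
    sample_id: str | None = None

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def aicc(self) -> float:
        return aicc(self.log_likelihood, self.k, self.n)


@dataclass(frozen=True)
class ModelComparison:
    """Fits of several families on one sample, with Akaike weights."""

    fits: tuple[FitResult, ...]
    weights: np.ndarray

    @property
    def best(self) -> FitResult:
        return self.fits[int(np.argmax(self.weights))]

    def weight_of(self, family: str) -> float:
        for f, w in zip(self.fits, self.weights):
            if f.model.family == family:
                return float(w)
        raise KeyError(family)


# ---------------------------------------------------------------------------
# information criteria and weights
# ---------------------------------------------------------------------------

def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion 2k - 2 lnL + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return 2.0 * k - 2.0 * log_likelihood + 2.0 * k * (k + 1) / (n - k - 1)


def _akaike_weights(aiccs: np.ndarray) -> np.ndarray:
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def pairwise_weight(fit_a: FitResult, fit_b: FitResult) -> float:
    """Akaike weight of model A in the two-model set {A, B} (same sample)."""
    if fit_a.n != fit_b.n:
        raise ValueError("pairwise weights require fits on the same sample")
    return float(_akaike_weights(np.array([fit_a.aicc, fit_b.aicc]))[0])


def multi_model_weights(fits: list[FitResult]) -> ModelComparison:
    """Akaike weights over a model set; softmax of -AICc/2 after min-shift."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError("all fits must be on the same sample")
    w = _akaike_weights(np.array([f.aicc for f in fits]))
    return ModelComparison(fits=tuple(fits), weights=w)


def sign_test(successes: int, trials: int) -> float:
    """Exact two-tailed binomial sign test against p = 1/2.

    Doubles the smaller tail probability and caps at 1; no normal
    approximation.
    """
    if not (0 <= successes <= trials):
        raise ValueError("require 0 <= successes <= trials")
    lo = stats.binom.cdf(successes, trials, 0.5)
    hi = stats.binom.sf(successes - 1, trials, 0.5)
    return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

# optimizer search box, shared across families
_LOGLAM_BOX = (-4.0, 4.0)      # log10 lambda in m^-1
_D_BOX = (0.5 + 1e-6, 3.0)     # the data may sit on either side of D = 2
_GAMMA_BOX = (0.05, 3.0)
_MU_BOX = (-3.0, 3.0)
_W_BOX = (0.01, 0.99)

# per-family free-parameter layout in optimizer space
_LAYOUT: dict[str, tuple[tuple[str, tuple[float, float]], ...]] = {
    "EXP": (("loglam", _LOGLAM_BOX),),
    "BIEXP": (("w", _W_BOX), ("loglam1", _LOGLAM_BOX), ("loglam2", _LOGLAM_BOX)),
    "STRETCHED": (("loglam", _LOGLAM_BOX), ("gamma", _GAMMA_BOX)),
    "GSE_CONSTRAINED": (("loglam", _LOGLAM_BOX), ("D", _D_BOX)),
    "GSE_FREE": (("loglam", _LOGLAM_BOX), ("gamma", _GAMMA_BOX), ("mu", _MU_BOX)),
    "POWER": (("mu", (_MU_BOX[0], -1e-6)),),
}


def _theta_to_params(family: str, theta: np.ndarray) -> dict:
    names = [n for n, _ in _LAYOUT[family]]
    raw = dict(zip(names, theta))
    if family == "BIEXP":
        l1, l2 = 10.0 ** raw["loglam1"], 10.0 ** raw["loglam2"]
        w = raw["w"]
        if l1 > l2:  # identifiability tie-break: report lam1 < lam2
            l1, l2 = l2, l1
            w = 1.0 - w
        if l1 == l2:
            l2 = l1 * (1.0 + 1e-9)
        return {"w": w, "lam1": l1, "lam2": l2}
    params = {}
    for name, val in raw.items():
        params["lam" if name == "loglam" else name] = (
            10.0**val if name == "loglam" else val
        )
    return params


def _neg_log_likelihood(family: str, theta: np.ndarray, x: np.ndarray,
                        bounds: SupportBounds) -> float:
    params = _theta_to_params(family, theta)
    try:
        spec = ModelSpec(family, params)
        logZ = log_normalization(spec, bounds)
        ll = float(np.sum(spec.log_kernel(x))) - x.size * logZ
    except (ValueError, OverflowError, FloatingPointError):
        return 1e12
    if not math.isfinite(ll):
        return 1e12
    return -ll


def _starts(family: str, x: np.ndarray, nested: dict[str, "FitResult"]) -> list[np.ndarray]:
    """Multi-start list: 8 log-spaced rates cycled with shape values, plus
    starts seeded from fitted nested (simpler) families."""
    lam0 = 1.0 / float(np.mean(x))
    loglams = np.log10(lam0) + np.linspace(-1.5, 1.5, 8)
    loglams = np.clip(loglams, *_LOGLAM_BOX)
    shapes = {
        "D": [1.1, 1.5, 1.9, 2.3],
        "gamma": [0.3, 0.7, 1.0, 1.5],
        "mu": [-1.5, -0.5, 0.0, 0.5],
        "w": [0.2, 0.4, 0.6, 0.8],
    }
    starts: list[np.ndarray] = []
    for i, ll in enumerate(loglams):
        theta = []
        for name, box in _LAYOUT[family]:
            if name == "loglam":
                theta.append(ll)
            elif name == "loglam1":
                theta.append(ll - 0.4)
            elif name == "loglam2":
                theta.append(ll + 0.4)
            else:
                theta.append(np.clip(shapes[name][i % 4], *box))
        starts.append(np.array(theta, dtype=float))
    # seeds from nested optima guarantee logL monotonicity under nesting
    if family in ("GSE_CONSTRAINED", "STRETCHED", "GSE_FREE", "BIEXP") and "EXP" in nested:
        lam = nested["EXP"].model.params["lam"]
        ll = math.log10(max(lam, 1e-12))
        if family == "GSE_CONSTRAINED":
            starts.append(np.array([ll, 2.0]))
        elif family == "STRETCHED":
            starts.append(np.array([ll, 1.0]))
        elif family == "GSE_FREE":
            starts.append(np.array([ll, 1.0, 0.0]))
        elif family == "BIEXP":
            starts.append(np.array([0.5, ll - 1e-3, ll + 1e-3]))
    if family == "GSE_FREE" and "GSE_CONSTRAINED" in nested:
        p = nested["GSE_CONSTRAINED"].model.params
        starts.append(
            np.array([
                math.log10(p["lam"]),
                np.clip(p["D"] - 1.0, *_GAMMA_BOX),
                np.clip(p["D"] - 2.0, *_MU_BOX),
            ])
        )
    return starts


class StepLengthModel(DensityMixin, BaseEstimator):
    """Truncated step-length distribution fitted by maximum likelihood.

    Parameters
    ----------
    family : str, default="GSE_CONSTRAINED"
        One of EXP, BIEXP, STRETCHED, GSE_CONSTRAINED, GSE_FREE, POWER.
    bounds : SupportBounds or None
        Truncation bounds; if None, [min(X), max(X)] of the fitted data.
    tol : float
        Optimizer tolerance on the log-likelihood.

    Attributes
    ----------
    params_ : dict
        Fitted natural parameters of the family.
    log_likelihood_ : float
    aicc_ : float
    bounds_ : SupportBounds
    n_ : int
    converged_ : bool
    """

    def __init__(self, family: str = "GSE_CONSTRAINED",
                 bounds: SupportBounds | None = None, tol: float = 1e-8):
        self.family = family
        self.bounds = bounds
        self.tol = tol

    # -- sklearn plumbing ---------------------------------------------------
    def _validate_input(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        x = column_or_1d(X)
        if np.any(~np.isfinite(x)) or np.any(x <= 0):
            raise ValueError("step lengths must be finite and positive")
        return x

    def fit(self, X, y=None):
        """Fit by bounded multi-start local optimization of the likelihood."""
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        x = self._validate_input(X)
        k = FAMILIES[self.family].k
        n = x.size
        if n < k + 2:
            raise InsufficientStepsError(
                f"insufficient steps: n={n} < k+2={k + 2} for {self.family}"
            )
        bounds = self.bounds or SupportBounds(float(x.min()), float(x.max()))
        if not np.all(bounds.contains(x)):
            raise ValueError("data fall outside the supplied bounds")

        nested: dict[str, FitResult] = {}
        if self.family in ("GSE_CONSTRAINED", "STRETCHED", "BIEXP", "GSE_FREE"):
            nested["EXP"] = _fit_family(x, "EXP", bounds, self.tol, {})
        if self.family == "GSE_FREE":
            nested["GSE_CONSTRAINED"] = _fit_family(
                x, "GSE_CONSTRAINED", bounds, self.tol, nested
            )
        res = _fit_family(x, self.family, bounds, self.tol, nested)

        self.params_ = dict(res.model.params)
        self.log_likelihood_ = res.log_likelihood
        self.bounds_ = bounds
        self.n_ = n
        self.k_ = k
        self.converged_ = res.converged
        self.aicc_ = res.aicc if n > k + 1 else math.nan
        return self

    def score_samples(self, X):
        """Log-density of each length under the fitted model."""
        check_is_fitted(self, "params_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        from .families import log_pdf

        return log_pdf(ModelSpec(self.family, self.params_), self.bounds_, x)

    def score(self, X, y=None):
        """Total log-likelihood of X."""
        return float(np.sum(self.score_samples(X)))

    def sample(self, n_samples: int = 1, random_state=None):
        check_is_fitted(self, "params_")
        return family_sample(
            ModelSpec(self.family, self.params_), self.bounds_, n_samples,
            seed=random_state,
        )

    def to_result(self, sample_id: str | None = None) -> FitResult:
        check_is_fitted(self, "params_")
        return FitResult(
            model=ModelSpec(self.family, self.params_),
            log_likelihood=self.log_likelihood_,
            n=self.n_,
            bounds=self.bounds_,
            converged=self.converged_,
            sample_id=sample_id,
        )


def _fit_family(x: np.ndarray, family: str, bounds: SupportBounds, tol: float,
                nested: dict[str, FitResult]) -> FitResult:
    boxes = [box for _, box in _LAYOUT[family]]
    best_theta, best_nll = None, np.inf
    for theta0 in _starts(family, x, nested):
        res = optimize.minimize(
            lambda th: _neg_log_likelihood(family, th, x, bounds),
            theta0,
            method="L-BFGS-B",
            bounds=boxes,
            options={"ftol": tol, "maxiter": 500},
        )
        if res.fun < best_nll:
            best_nll, best_theta = res.fun, res.x
    converged = best_theta is not None and best_nll < 1e11
    if not converged:
        raise RuntimeError(f"likelihood optimization failed for {family}")
    params = _theta_to_params(family, best_theta)
    return FitResult(
        model=ModelSpec(family, params),
        log_likelihood=-best_nll,
        n=x.size,
        bounds=bounds,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# module-level wrappers
# ---------------------------------------------------------------------------

def fit(sample: StepSample, family: str,
        bounds: SupportBounds | None = None) -> FitResult:
    """Fit one family to a step sample (thin wrapper over StepLengthModel)."""
    est = StepLengthModel(family=family, bounds=bounds or sample.bounds)
    est.fit(sample.lengths)
    return est.to_result(sample_id=sample.individual)


def pooled_fit(samples: list[StepSample], family: str) -> FitResult:
    """Concatenate individuals, recompute bounds over the pool, and fit."""
    if not samples:
        raise ValueError("no samples to pool")
    lengths = np.concatenate([s.lengths for s in samples])
    pooled = StepSample(lengths, individual="pooled")
    return fit(pooled, family)


def rank_frequency(sample: StepSample) -> tuple[np.ndarray, np.ndarray]:
    """Rank-frequency curve: fraction of steps >= each observed length.

    Complement of the empirical CDF; 1 at the minimum length, 1/n (times
    the multiplicity of the maximum) at the maximum; ties collapse.
    """
    x = np.sort(sample.lengths)
    uniq, first_idx = np.unique(x, return_index=True)
    frac = 1.0 - first_idx / x.size
    return uniq, frac
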