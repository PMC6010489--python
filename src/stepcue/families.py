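"""Truncated step-length distribution families and micro-cue encounter theory.

The central object is a family of probability densities on a truncated
support [a, b],

    p(l) = N * exp(-(lambda * l)**gamma) * l**mu,

the *generalized stretched exponential* (GSE).  The constrained variant ties
both exponents to a single fractal dimension D of the substrate micro-cue
pattern, gamma = D - 1 and mu = D - 2, so that D = 2 (uniform random cues)
gives a simple exponential and D = 1 a pure power law.  Alongside the GSE
sit the standard competitors used in movement-ecology model selection:
simple exponential, bi-exponential mixture, bare stretched exponential and
power law, all truncated to the same support.

The second half of the module implements the two-dimensional encounter
theory for a walker that travels in straight lines and turns on contact
with cues whose number within radius r scales as n(r) = (r/delta)**D:
the per-length encounter probability q(r), the free-path survival
function, and the resulting free-path density, which is the predicted
step-length distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "FAMILIES",
    "SupportBounds",
    "ModelSpec",
    "CueGeometry",
    "normalization",
    "log_normalization",
    "log_pdf",
    "pdf",
    "cdf",
    "survival",
    "sample",
    "cue_count",
    "encounter_rate",
    "free_path_survival",
    "free_path_pdf",
    "mean_free_path_uniform",
]

#: number of nodes of the log-spaced grid used for CDF tabulation/sampling
_GRID_N = 4096

#: sentinel meaning "effectively infinite" upper bound
INF = math.inf


class NonNormalizableError(ValueError):
    """The kernel does not have a finite integral on the given bounds."""


@dataclass(frozen=True)
class SupportBounds:
    """Truncated support [lower, upper] in meters, 0 < lower < upper <= inf."""

    lower: float
    upper: float = INF

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper):
            raise ValueError(
                f"require 0 < lower < upper, got [{self.lower}, {self.upper}]"
            )

    @property
    def finite(self) -> bool:
        return math.isfinite(self.upper)

    def contains(self, l) -> np.ndarray:
        l = np.asarray(l, dtype=float)
        return (l >= self.lower) & (l <= self.upper)


# ---------------------------------------------------------------------------
# family definitions
# ---------------------------------------------------------------------------

def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


class _Family:
    """A distribution family: named parameters plus a log-kernel."""

    name: str
    param_names: tuple[str, ...]
    k: int  # free-parameter count for information criteria

    def validate(self, params: dict) -> None:
        missing = set(self.param_names) - set(params)
        _require(not missing, f"{self.name}: missing parameters {sorted(missing)}")

    def log_kernel(self, l: np.ndarray, params: dict) -> np.ndarray:
        raise NotImplementedError

    def effective_exponents(self, params: dict) -> tuple[float, float]:
        """Return (gamma, mu) of the equivalent GSE kernel, for integrability checks."""
        raise NotImplementedError


class _Exponential(_Family):
    name = "EXP"
    param_names = ("lam",)
    k = 1

    def validate(self, params):
        super().validate(params)
        _require(params["lam"] > 0, "EXP: lam > 0 required")

    def log_kernel(self, l, params):
        return -params["lam"] * l

    def effective_exponents(self, params):
        return 1.0, 0.0


class _BiExponential(_Family):
    """Mixture w*lam1*exp(-lam1 l) + (1-w)*lam2*exp(-lam2 l), renormalized."""

    name = "BIEXP"
    param_names = ("w", "lam1", "lam2")
    k = 3

    def validate(self, params):
        super().validate(params)
        w, l1, l2 = params["w"], params["lam1"], params["lam2"]
        _require(0.0 < w < 1.0, "BIEXP: w in (0,1) required")
        _require(l1 > 0 and l2 > 0, "BIEXP: rates must be positive")
        _require(l1 != l2, "BIEXP: lam1 != lam2 required (else use EXP)")

    def log_kernel(self, l, params):
        w, l1, l2 = params["w"], params["lam1"], params["lam2"]
        a = np.log(w * l1) - l1 * l
        b = np.log((1.0 - w) * l2) - l2 * l
        hi = np.maximum(a, b)
        return hi + np.log(np.exp(a - hi) + np.exp(b - hi))

    def effective_exponents(self, params):
        return 1.0, 0.0


class _Stretched(_Family):
    """Bare stretched-exponential kernel exp(-(lam l)**gamma) (no power prefactor)."""

    name = "STRETCHED"
    param_names = ("lam", "gamma")
    k = 2

    def validate(self, params):
        super().validate(params)
        _require(params["lam"] > 0, "STRETCHED: lam > 0 required")
        _require(params["gamma"] > 0, "STRETCHED: gamma > 0 required")

    def log_kernel(self, l, params):
        return -np.power(params["lam"] * l, params["gamma"])

    def effective_exponents(self, params):
        return params["gamma"], 0.0


class _GSEConstrained(_Family):
    """GSE with gamma = D - 1 and mu = D - 2 tied to the fractal dimension D."""

    name = "GSE_CONSTRAINED"
    param_names = ("lam", "D")
    k = 2

    def validate(self, params):
        super().validate(params)
        _require(params["lam"] > 0, "GSE_CONSTRAINED: lam > 0 required")
        _require(params["D"] > 0, "GSE_CONSTRAINED: D > 0 required")

    def log_kernel(self, l, params):
        lam, D = params["lam"], params["D"]
        gamma, mu = D - 1.0, D - 2.0
        if gamma == 0.0:  # D = 1: stretch factor constant, pure power law l**-1
            return -1.0 + mu * np.log(l)
        return -np.power(lam * l, gamma) + mu * np.log(l)

    def effective_exponents(self, params):
        return params["D"] - 1.0, params["D"] - 2.0


class _GSEFree(_Family):
    name = "GSE_FREE"
    param_names = ("lam", "gamma", "mu")
    k = 3

    def validate(self, params):
        super().validate(params)
        _require(params["lam"] > 0, "GSE_FREE: lam > 0 required")
        _require(params["gamma"] > 0, "GSE_FREE: gamma > 0 required")

    def log_kernel(self, l, params):
        return -np.power(params["lam"] * l, params["gamma"]) + params["mu"] * np.log(l)

    def effective_exponents(self, params):
        return params["gamma"], params["mu"]


class _PowerLaw(_Family):
    """Pure power law l**mu with mu < 0 (Levy-walk hallmark), truncated."""

    name = "POWER"
    param_names = ("mu",)
    k = 1

    def validate(self, params):
        super().validate(params)
        _require(params["mu"] < 0, "POWER: mu < 0 required")

    def log_kernel(self, l, params):
        return params["mu"] * np.log(l)

    def effective_exponents(self, params):
        return 0.0, params["mu"]


FAMILIES: dict[str, _Family] = {
    f.name: f
    for f in (
        _Exponential(),
        _BiExponential(),
        _Stretched(),
        _GSEConstrained(),
        _GSEFree(),
        _PowerLaw(),
    )
}


@dataclass(frozen=True)
class ModelSpec:
    """A candidate family with concrete parameter values."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {sorted(FAMILIES)}"
            )
        FAMILIES[self.family].validate(self.params)

    @property
    def k(self) -> int:
        return FAMILIES[self.family].k

    def log_kernel(self, l) -> np.ndarray:
        l = np.asarray(l, dtype=float)
        return FAMILIES[self.family].log_kernel(l, self.params)


# ---------------------------------------------------------------------------
# normalization, pdf, cdf, sampling
# ---------------------------------------------------------------------------

def _check_integrable(model: ModelSpec, bounds: SupportBounds) -> None:
    gamma, mu = FAMILIES[model.family].effective_exponents(model.params)
    if not bounds.finite:
        # with no exponential decay (gamma <= 0 in effect) the tail must fall
        # faster than 1/l
        if gamma <= 0.0 and mu >= -1.0:
            raise NonNormalizableError(
                f"{model.family} kernel is non-normalizable on "
                f"[{bounds.lower}, inf) (gamma<=0 and mu>=-1)"
            )


def log_normalization(model: ModelSpec, bounds: SupportBounds) -> float:
    """log of the kernel integral Z on [a, b]; N = 1/Z normalizes the pdf.

    Adaptive quadrature on the log-kernel with an overflow shift; absolute
    tolerance 1e-9 on the shifted integrand.
    """
    _check_integrable(model, bounds)
    a, b = bounds.lower, bounds.upper
    # shift by the max log-kernel over a probe grid to keep exp() in range
    probe_hi = b if bounds.finite else max(10.0 / _char_rate(model), 10.0 * a)
    probe = np.geomspace(a, probe_hi, 256)
    shift = float(np.max(model.log_kernel(probe)))

    def f(l):
        return math.exp(float(model.log_kernel(l)) - shift)

    val, _ = integrate.quad(f, a, b, epsabs=1e-9, epsrel=1e-10, limit=200)
    if not (val > 0.0 and math.isfinite(val)):
        raise NonNormalizableError(
            f"kernel integral not finite/positive for {model.family} on [{a}, {b}]"
        )
    return shift + math.log(val)


def _char_rate(model: ModelSpec) -> float:
    """Rough inverse length-scale, used only to size probe grids."""
    return float(
        model.params.get("lam")
        or model.params.get("lam1")
        or 1.0
    )


def normalization(model: ModelSpec, bounds: SupportBounds) -> float:
    """Normalization factor N such that the pdf integrates to one."""
    return math.exp(-log_normalization(model, bounds))


def log_pdf(model: ModelSpec, bounds: SupportBounds, l) -> np.ndarray:
    """Log-density at l; -inf outside [a, b] by convention."""
    l = np.asarray(l, dtype=float)
    logZ = log_normalization(model, bounds)
    out = np.full(l.shape, -np.inf)
    inside = bounds.contains(l)
    if np.any(inside):
        out[inside] = model.log_kernel(l[inside]) - logZ
    if l.ndim == 0:
        return float(out)
    return out


def pdf(model: ModelSpec, bounds: SupportBounds, l) -> np.ndarray:
    return np.exp(log_pdf(model, bounds, l))


def _cdf_grid(model: ModelSpec, bounds: SupportBounds) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced node grid and normalized CDF values on it (trapezoid)."""
    a = bounds.lower
    b = bounds.upper if bounds.finite else max(50.0 / _char_rate(model), 50.0 * a)
    grid = np.geomspace(a, b, _GRID_N)
    logk = model.log_kernel(grid)
    shift = logk.max()
    dens = np.exp(logk - shift)
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))]
    )
    if cum[-1] <= 0:
        raise NonNormalizableError(f"degenerate kernel mass for {model.family}")
    return grid, cum / cum[-1]


def cdf(model: ModelSpec, bounds: SupportBounds, l) -> np.ndarray:
    """CDF by tabulated quadrature; 0 below a, 1 above b."""
    grid, cum = _cdf_grid(model, bounds)
    l = np.asarray(l, dtype=float)
    out = np.interp(l, grid, cum, left=0.0, right=1.0)
    return float(out) if l.ndim == 0 else out


def survival(model: ModelSpec, bounds: SupportBounds, l) -> np.ndarray:
    """Fraction of probability mass at lengths >= l (monotone 1 -> 0)."""
    return 1.0 - cdf(model, bounds, l)


def sample(model: ModelSpec, bounds: SupportBounds, n: int, seed=None) -> np.ndarray:
    """Draw n step lengths by numeric inversion of the tabulated CDF.

    Inversion uses monotone (piecewise-linear) interpolation on a
    log-spaced grid of 4096 nodes, which handles every family uniformly.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    _check_integrable(model, bounds)
    grid, cum = _cdf_grid(model, bounds)
    # make the CDF strictly increasing so inversion is well defined
    cum = np.maximum.accumulate(cum + np.arange(cum.size) * 1e-15)
    rng = np.random.default_rng(seed)
    u = rng.uniform(cum[0], cum[-1], size=n)
    return np.interp(u, cum, grid)


# ---------------------------------------------------------------------------
# 2-D micro-cue encounter theory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CueGeometry:
    """Geometry of a fractal micro-cue pattern.

    rho: cue detection radius (m); delta: characteristic cue spacing and
    inner cutoff of the fractal scaling (m); D: fractal dimension in (0, 2].
    Cues must not overlap: rho <= delta / 2.
    """

    rho: float
    delta: float
    D: float

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.delta > 0):
            raise ValueError("rho and delta must be positive")
        if not (0.0 < self.D <= 2.0):
            raise ValueError(f"D must lie in (0, 2], got {self.D}")
        if self.rho > self.delta / 2.0:
            raise ValueError(
                f"cues overlap: rho={self.rho} > delta/2={self.delta / 2.0}"
            )


def cue_count(geom: CueGeometry, r) -> np.ndarray:
    """Expected number of cues within distance r of a point: (r/delta)**D."""
    return np.power(np.asarray(r, dtype=float) / geom.delta, geom.D)


def encounter_rate(geom: CueGeometry, r) -> np.ndarray:
    """Per-length encounter probability q(r) = rho*D/(pi*delta^2)*(r/delta)**(D-2).

    Constant in r for D = 2 (uniform cues); decreasing for D < 2.
    """
    r = np.asarray(r, dtype=float)
    q = geom.rho * geom.D / (math.pi * geom.delta**2) * np.power(
        r / geom.delta, geom.D - 2.0
    )
    return float(q) if r.ndim == 0 else q


def free_path_survival(geom: CueGeometry, r) -> np.ndarray:
    """Probability of travelling at least r >= delta without an encounter.

    exp(-int_delta^r q); the D = 1 limit integrates to a log and gives a
    pure power law (r/delta)**(-rho/(pi*delta)).
    """
    r = np.asarray(r, dtype=float)
    rho, d, D = geom.rho, geom.delta, geom.D
    rr = np.maximum(r, d)  # hazard starts at the inner cutoff
    if abs(D - 1.0) < 1e-12:
        out = np.power(rr / d, -rho / (math.pi * d))
    else:
        integral = rho * D / (math.pi * d**D) * (rr ** (D - 1.0) - d ** (D - 1.0)) / (
            D - 1.0
        )
        out = np.exp(-integral)
    return float(out) if r.ndim == 0 else out


def free_path_pdf(geom: CueGeometry, r) -> np.ndarray:
    """Free-path density p(r) = survival(r) * q(r): the predicted step-length law.

    For D = 2 the tail is a simple exponential; for 1 < D < 2 it is the
    constrained GSE with gamma = D - 1 and mu = D - 2.
    """
    r = np.asarray(r, dtype=float)
    out = free_path_survival(geom, r) * encounter_rate(geom, r)
    return float(out) if r.ndim == 0 else out


def mean_free_path_uniform(geom: CueGeometry) -> float:
    """Classical 2-D mean free path pi*delta^2/(2*rho) for a uniform field (D=2)."""
    return math.pi * geom.delta**2 / (2.0 * geom.rho)
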