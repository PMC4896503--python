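"""Candidate density-dependence functions and their maximum-likelihood fits.

Six mean functions describe how the expected number (or rate) of immigrants
``I`` responds to the post-removal density ``D``:

========  =======================  ==========================================
name      formula                  pattern
========  =======================  ==========================================
``DI``    ``I = b``                density independence
``LDD``   ``I = a*D + b``          linear (negative or positive) dependence
``EDD``   ``I = a*exp(-b*D)``      exponential (negative or positive)
``SDD``   ``I = a*(1-exp(-b*D))``  saturating positive dependence
``PDD``   ``I = -a*D**2 + b*D``    quadratic through the origin (hump)
``RDD``   ``I = a*D*exp(-b*D)``    Ricker (hump)
========  =======================  ==========================================

Counts (per-site scaling) are fit with a negative-binomial likelihood
parameterised by mean ``mu`` and dispersion ``k`` (variance ``mu + mu**2/k``);
rates (per-new-vacancy and per-capita scalings) are fit with a Gamma
likelihood in mean/shape form, with 0.001 added to both responses and means
so that zero rates keep finite density.  Wherever a candidate formula yields
a non-positive mean (PDD beyond its root, extreme EDD) the mean is floored at
a small epsilon so log-densities stay finite.

Fitting is a deterministic multi-start bounded quasi-Newton minimisation of
the negative log-likelihood followed by a simplex polish; the nuisance
parameter is log-transformed for positivity.  Sign constraints keep each
function identifiable while still letting LDD and EDD cover both directions
of density dependence: ``a >= 0`` for EDD, SDD, PDD, RDD and ``b >= 0`` for
DI, SDD, RDD.

The model-comparison score is AICc, ``-2 logL + 2K + 2K(K+1)/(n-K-1)``, with
``K`` counting the nuisance parameter, so a fit needs ``n > K + 1`` points.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.special import gammaln
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .scaling import ScaledSeries

__all__ = [
    "CANONICAL_ORDER",
    "N_MEAN_PARAMS",
    "FAMILIES",
    "mean_function",
    "nb_negloglik",
    "gamma_negloglik",
    "FitResult",
    "FitError",
    "TooFewEventsError",
    "fit_mle",
    "CandidateModelRegressor",
]

CANONICAL_ORDER = ("DI", "LDD", "EDD", "SDD", "PDD", "RDD")
N_MEAN_PARAMS = {"DI": 1, "LDD": 2, "EDD": 2, "SDD": 2, "PDD": 2, "RDD": 2}
FAMILIES = ("negative_binomial", "gamma")

MEAN_FLOOR = 1e-6
GAMMA_OFFSET = 1e-3


class FitError(RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class TooFewEventsError(ValueError):
    """n <= K + 1, so the AICc small-sample correction is undefined."""


# ---------------------------------------------------------------------------
# mean functions
# ---------------------------------------------------------------------------

def _check_name(name: str) -> str:
    if name not in CANONICAL_ORDER:
        raise ValueError(f"unknown function {name!r}; expected one of {CANONICAL_ORDER}")
    return name


def _raw_mean(name: str, a: float | None, b: float, D: np.ndarray) -> np.ndarray:
    if name == "DI":
        return np.full_like(D, b, dtype=float)
    if name == "LDD":
        return a * D + b
    if name == "EDD":
        return a * np.exp(-b * D)
    if name == "SDD":
        return a * (1.0 - np.exp(-b * D))
    if name == "PDD":
        return -a * D**2 + b * D
    if name == "RDD":
        return a * D * np.exp(-b * D)
    raise AssertionError(name)


def mean_function(name: str, a: float | None, b: float, density) -> np.ndarray | float:
    """Evaluate a candidate mean function, floored at zero for prediction.

    ``a`` is ignored for DI (its single mean parameter is ``b``).  PDD and
    RDD are exactly zero at density 0; PDD is clipped to zero beyond the
    density at which the parabola goes negative.
    """
    _check_name(name)
    D = np.asarray(density, dtype=float)
    if np.any(D < 0):
        raise ValueError("density must be non-negative")
    out = np.maximum(_raw_mean(name, a, b, D), 0.0)
    return float(out) if np.isscalar(density) or out.ndim == 0 else out


def _floored_mean(name: str, a: float | None, b: float, D: np.ndarray,
                  floor: float = MEAN_FLOOR) -> np.ndarray:
    return np.maximum(_raw_mean(name, a, b, D), floor)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _split_params(name: str, params: Sequence[float]) -> tuple[float | None, float, float]:
    """Split ``params`` into (a, b, nuisance) for the named function."""
    params = list(params)
    expected = N_MEAN_PARAMS[name] + 1
    if len(params) != expected:
        raise ValueError(f"{name} expects {expected} parameters (mean + nuisance), got {len(params)}")
    if name == "DI":
        return None, float(params[0]), float(params[1])
    return float(params[0]), float(params[1]), float(params[2])


def _nb_logpmf_exact(y: np.ndarray, mu: np.ndarray, k: float) -> np.ndarray:
    """Stable NB log-pmf for integer counts, accurate even for huge k.

    Uses log Gamma(y+k) - log Gamma(k) = sum_{i<y} log(k+i), which avoids
    cancellation between two enormous gammaln values in the Poisson limit.
    """
    ymax = int(y.max()) if len(y) else 0
    cum = np.concatenate(([0.0], np.cumsum(np.log(k + np.arange(ymax)))))
    rising = cum[y.astype(int)]
    return (
        rising
        - gammaln(y + 1.0)
        - k * np.log1p(mu / k)
        + y * (np.log(mu) - np.log(k + mu))
    )


def nb_negloglik(params: Sequence[float], points: ScaledSeries | tuple, function: str) -> float:
    """Negative log-likelihood of integer counts under NB(mean, dispersion).

    ``params`` are the mean parameters followed by the dispersion ``k``
    (variance ``mu + mu**2/k``).  The mean is ``mean_function`` floored at a
    small epsilon.
    """
    _check_name(function)
    D, y = _extract_xy(points)
    if np.any(y != np.round(y)):
        raise ValueError("negative-binomial responses must be non-negative integers")
    a, b, k = _split_params(function, params)
    if k <= 0:
        raise ValueError("dispersion k must be positive")
    mu = _floored_mean(function, a, b, D)
    return float(-_nb_logpmf_exact(y, mu, k).sum())


def _gamma_logpdf(x: np.ndarray, mu: np.ndarray, shape: float) -> np.ndarray:
    # mean/shape parameterisation: scale = mu / shape
    scale = mu / shape
    return (shape - 1.0) * np.log(x) - x / scale - gammaln(shape) - shape * np.log(scale)


def gamma_negloglik(params: Sequence[float], points: ScaledSeries | tuple, function: str) -> float:
    """Negative log-likelihood of rates under a Gamma(mean, shape) model.

    Both responses and means are offset by +0.001 so that exact-zero rates
    contribute a finite term.
    """
    _check_name(function)
    D, y = _extract_xy(points)
    a, b, s = _split_params(function, params)
    if s <= 0:
        raise ValueError("Gamma shape must be positive")
    mu = _floored_mean(function, a, b, D) + GAMMA_OFFSET
    return float(-_gamma_logpdf(y + GAMMA_OFFSET, mu, s).sum())


def _extract_xy(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, ScaledSeries):
        D, y = points.densities, points.responses
    else:
        D, y = points
        D = np.asarray(D, dtype=float)
        y = np.asarray(y, dtype=float)
    if D.shape != y.shape:
        raise ValueError("densities and responses must have equal length")
    if np.any(D < 0) or np.any(y < 0):
        raise ValueError("densities and responses must be non-negative")
    return D, y


# ---------------------------------------------------------------------------
# fit result container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """One maximum-likelihood fit of a candidate function."""

    function: str
    family: str
    a: float | None
    b: float
    nuisance: float
    loglik: float
    k_params: int
    n: int
    aicc: float
    converged: bool
    provenance: dict = field(default_factory=dict)

    def predict(self, density) -> np.ndarray | float:
        return mean_function(self.function, self.a, self.b, density)

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        return json.dumps(d, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# multi-start MLE
# ---------------------------------------------------------------------------

_BIG = 1e30


def _smoothed_argmax(D: np.ndarray, y: np.ndarray) -> float:
    """Centre of the best of three equal-width density bins (moment heuristic)."""
    dmax = D.max()
    if dmax <= 0:
        return 1.0
    edges = np.linspace(0.0, dmax * (1 + 1e-9), 4)
    best_c, best_m = dmax / 2.0, -np.inf
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (D >= lo) & (D < hi)
        if sel.any() and y[sel].mean() > best_m:
            best_m = y[sel].mean()
            best_c = (lo + hi) / 2.0
    return max(best_c, dmax / 20.0)


def _mean_starts(name: str, D: np.ndarray, y: np.ndarray) -> list[tuple[float, ...]]:
    """Deterministic grid of mean-parameter starting points."""
    eps = 1e-3
    m = max(float(y.mean()), eps)
    M = max(float(y.max()), eps)
    dmax = max(float(D.max()), 1.0)
    dstar = _smoothed_argmax(D, y)
    if name == "DI":
        return [(m,), (M / 2.0,), (2.0 * m,), (eps,)]
    if name == "LDD":
        # least-squares line as the anchor start
        A = np.vstack([D, np.ones_like(D)]).T
        slope, intercept = np.linalg.lstsq(A, y, rcond=None)[0]
        return [
            (float(slope), float(max(intercept, 0.0))),
            (0.0, m),
            (-m / dmax, M),
            (m / dmax, eps),
        ]
    if name == "EDD":
        return [(M, 2.0 / dmax), (m, 0.5 / dmax), (M, -0.5 / dmax), (m, 0.0)]
    if name == "SDD":
        return [(M, 2.0 / dmax), (m, 0.5 / dmax), (2.0 * m, 5.0 / dmax), (M, 0.2 / dmax)]
    if name == "PDD":
        starts = []
        for ds in (dstar, dmax / 3.0, dmax / 2.0, 0.75 * dmax):
            a0 = M / ds**2  # vertex height M at D = ds
            starts.append((a0, 2.0 * a0 * ds))
        return starts
    if name == "RDD":
        starts = []
        for ds in (dstar, dmax / 4.0, dmax / 2.0, dmax):
            b0 = 1.0 / ds
            starts.append((M * math.e * b0, b0))
        return starts
    raise AssertionError(name)


def _bounds(name: str) -> list[tuple[float | None, float | None]]:
    none = (None, None)
    nonneg = (0.0, None)
    if name == "DI":
        return [nonneg]
    return {
        "LDD": [none, none],
        "EDD": [nonneg, none],
        "SDD": [nonneg, nonneg],
        "PDD": [nonneg, none],
        "RDD": [nonneg, nonneg],
    }[name]


_LOG_NU_BOUNDS = (math.log(1e-4), math.log(5e8))


def fit_mle(
    function: str,
    points: ScaledSeries | tuple,
    family: str,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FitResult:
    """Fit one candidate function by deterministic multi-start ML.

    Parameters
    ----------
    function : str
        One of ``DI, LDD, EDD, SDD, PDD, RDD``.
    points : ScaledSeries or (densities, responses)
        The data under one scaling.  Counts for the negative-binomial
        family, rates for the Gamma family.
    family : str
        ``"negative_binomial"`` or ``"gamma"``.
    tol : float
        Objective tolerance passed to the quasi-Newton stage.
    max_iter : int
        Iteration cap per start.

    Returns
    -------
    FitResult
        Parameter estimates, log-likelihood, AICc and optimizer provenance.

    Raises
    ------
    TooFewEventsError
        If ``n <= K + 1`` so AICc is undefined.
    FitError
        If every start fails to produce a finite optimum.
    """
    _check_name(function)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    D, y = _extract_xy(points)
    n = len(y)
    K = N_MEAN_PARAMS[function] + 1
    if n - K - 1 <= 0:
        raise TooFewEventsError(
            f"too few events for AICc: n={n} with K={K} requires n > {K + 1}"
        )
    nll = nb_negloglik if family == "negative_binomial" else gamma_negloglik
    if family == "negative_binomial" and np.any(y != np.round(y)):
        raise ValueError("negative-binomial responses must be non-negative integers")

    mean_bounds = _bounds(function)

    def objective(theta: np.ndarray) -> float:
        if theta[-1] > _LOG_NU_BOUNDS[1] or theta[-1] < _LOG_NU_BOUNDS[0]:
            return _BIG
        for t, (lo, hi) in zip(theta, mean_bounds):
            if (lo is not None and t < lo) or (hi is not None and t > hi):
                return _BIG
        try:
            params = list(theta[:-1]) + [math.exp(theta[-1])]
            with np.errstate(all="ignore"):
                val = nll(params, (D, y), function)
        except (ValueError, FloatingPointError, OverflowError):
            return _BIG
        return val if np.isfinite(val) else _BIG

    nu_starts = (1.0, 10.0) if family == "negative_binomial" else (0.5, 2.0)
    bounds = _bounds(function) + [_LOG_NU_BOUNDS]
    diagnostics, candidates = [], []
    for mean_start in _mean_starts(function, D, y):
        for nu0 in nu_starts:
            x0 = np.array(list(mean_start) + [math.log(nu0)])
            res = optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": tol * 1e-4, "gtol": 1e-10, "maxiter": max_iter},
            )
            diagnostics.append(
                {"x0": x0.tolist(), "fun": float(res.fun), "success": bool(res.success)}
            )
            if np.isfinite(res.fun) and res.fun < _BIG:
                candidates.append((float(res.fun), res.x, bool(res.success)))
    if not candidates:
        raise FitError(f"all starts failed for {function} ({family})", diagnostics)
    candidates.sort(key=lambda c: c[0])
    best_fun, best_x, best_ok = candidates[0]
    # simplex polish for tight parameter accuracy
    polish = optimize.minimize(
        objective,
        best_x,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000},
    )
    if np.isfinite(polish.fun) and polish.fun <= best_fun:
        best_fun, best_x = float(polish.fun), polish.x
        best_ok = best_ok or bool(polish.success)
    theta = np.asarray(best_x, dtype=float)
    # clip against bounds (Nelder-Mead is unconstrained)
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None:
            theta[i] = max(theta[i], lo)
        if hi is not None:
            theta[i] = min(theta[i], hi)
    params = list(theta[:-1]) + [math.exp(theta[-1])]
    final_nll = nll(params, (D, y), function)
    a, b, nuisance = _split_params(function, params)
    logL = -final_nll
    aicc_val = -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1.0) / (n - K - 1.0)
    return FitResult(
        function=function,
        family=family,
        a=a,
        b=b,
        nuisance=nuisance,
        loglik=logL,
        k_params=K,
        n=n,
        aicc=aicc_val,
        converged=bool(best_ok and np.isfinite(final_nll)),
        provenance={
            "starts": diagnostics,
            "chosen": theta.tolist(),
            "tol": tol,
            "polished": bool(np.isfinite(polish.fun) and polish.fun <= candidates[0][0]),
        },
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class CandidateModelRegressor(BaseEstimator, RegressorMixin):
    """Sklearn-style wrapper around :func:`fit_mle` for one candidate function.

    Parameters
    ----------
    function : str, default "RDD"
        Candidate mean function to fit.
    family : str, default "negative_binomial"
        Error family: NB for counts, Gamma for rates.
    tol : float, default 1e-8
        Optimizer objective tolerance.

    Attributes
    ----------
    a_, b_ : float
        Fitted mean parameters (``a_`` is None for DI).
    dispersion_ : float
        NB dispersion ``k`` or Gamma shape.
    loglik_, aicc_ : float
        Maximised log-likelihood and its small-sample information score.
    converged_ : bool
    result_ : FitResult

    Examples
    --------
    >>> import numpy as np
    >>> D = np.arange(1, 13, dtype=float)
    >>> y = np.round(1.5 * D * np.exp(-0.2 * D)).astype(float)
    >>> reg = CandidateModelRegressor(function="RDD").fit(D, y)
    >>> reg.predict([5.0]).round(2)  # doctest: +SKIP
    array([2.76])
    """

    def __init__(self, function: str = "RDD", family: str = "negative_binomial",
                 tol: float = 1e-8, max_iter: int = 500):
        self.function = function
        self.family = family
        self.tol = tol
        self.max_iter = max_iter

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expected a single density column")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-d densities or a (n, 1) column")
        return X

    def fit(self, X, y):
        D = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        result = fit_mle(self.function, (D, y), self.family,
                         tol=self.tol, max_iter=self.max_iter)
        self.result_ = result
        self.a_ = result.a
        self.b_ = result.b
        self.dispersion_ = result.nuisance
        self.loglik_ = result.loglik
        self.aicc_ = result.aicc
        self.n_ = result.n
        self.converged_ = result.converged
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        D = self._validate_X(X)
        return mean_function(self.function, self.a_, self.b_, D)
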