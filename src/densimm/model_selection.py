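"""AICc multimodel inference across the candidate functions.

For each site, the six candidate fits are compared on Akaike's information
criterion with the small-sample correction,

    AICc = -2 logL + 2K + 2K(K+1) / (n - K - 1),

from which differences to the best model (``delta``) give normalised Akaike
weights ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)``, interpreted as the
probability that function ``i`` is the best of the set.  Evidence ratios
``w_i / w_j`` compare two named functions, and are averaged arithmetically
across sites for an overall verdict.  Peak diagnostics locate the interior
maximum of the hump-shaped functions, and a binned summary reproduces the
combined-data presentation (mean +/- 1 SE per 0.1-wide proportion bin, with
zero density kept as its own bin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .candidate_models import (
    CANONICAL_ORDER,
    FitResult,
    FitError,
    TooFewEventsError,
    fit_mle,
    mean_function,
)
from .experiment_io import SiteSeries
from .scaling import ScaledSeries

__all__ = [
    "aicc",
    "akaike_weights",
    "evidence_ratio",
    "ComparisonRow",
    "ComparisonTable",
    "CrossSiteSummary",
    "compare_site",
    "fit_site",
    "family_for_scaling",
    "cross_site_summary",
    "PeakLocation",
    "peak_location",
    "BinStat",
    "bin_summary",
    "vacancy_fill_summary",
    "DensityDependenceSelector",
]


def aicc(logL: float, K: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    Raises a domain error when ``n - K - 1 <= 0``.
    """
    if n - K - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n}, K={K} requires n > K + 1")
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1.0) / (n - K - 1.0)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Normalised Akaike weights from a set of AICc scores.

    Invariant to adding a constant to every score; sums to 1.
    """
    scores = np.asarray(aiccs, dtype=float)
    if scores.size == 0:
        raise ValueError("empty AICc list")
    if not np.all(np.isfinite(scores)):
        raise ValueError("AICc scores must be finite")
    rel = np.exp(-(scores - scores.min()) / 2.0)
    return rel / rel.sum()


def evidence_ratio(w_i: float, w_j: float) -> float:
    """Relative likelihood ``w_i / w_j`` of function i over function j.

    A zero denominator (a weight that rounds to 0) yields ``inf`` rather
    than an exception.
    """
    if w_j < 0 or w_i < 0:
        raise ValueError("weights must be non-negative")
    if w_j == 0:
        return float("inf")
    return w_i / w_j


@dataclass
class ComparisonRow:
    function: str
    aicc: float
    delta_aicc: float
    weight: float
    converged: bool = True


@dataclass
class ComparisonTable:
    """Per-site AICc comparison across the six candidate functions."""

    site_id: str
    scaling: str
    rows: list[ComparisonRow]
    best: str
    fits: dict[str, FitResult | None] = field(default_factory=dict)

    def row(self, function: str) -> ComparisonRow:
        for r in self.rows:
            if r.function == function:
                return r
        raise KeyError(function)

    def weight(self, function: str) -> float:
        return self.row(function).weight

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_id,
                "scaling": self.scaling,
                "function": [r.function for r in self.rows],
                "aicc": [r.aicc for r in self.rows],
                "delta_aicc": [r.delta_aicc for r in self.rows],
                "weight": [r.weight for r in self.rows],
                "converged": [r.converged for r in self.rows],
                "best": [r.function == self.best for r in self.rows],
            }
        )


def compare_site(fits: Mapping[str, FitResult | None] | Iterable[FitResult],
                 site_id: str | None = None,
                 scaling: str | None = None) -> ComparisonTable:
    """Build the per-site comparison table from the six candidate fits.

    Rows appear in the canonical order DI, LDD, EDD, SDD, PDD, RDD.  A
    missing or non-converged fit is kept as a flagged row but excluded from
    best-function selection.  Ties on AICc break toward fewer parameters,
    then canonical order.
    """
    if not isinstance(fits, Mapping):
        fits = {f.function: f for f in fits}
    missing = [name for name in CANONICAL_ORDER if name not in fits]
    if missing:
        fits = dict(fits)
        for name in missing:
            fits[name] = None
    usable: dict[str, FitResult] = {}
    for name in CANONICAL_ORDER:
        f = fits.get(name)
        if f is None or not f.converged:
            warnings.warn(f"function {name} missing or non-converged; excluded from best-selection")
        else:
            usable[name] = f
    if not usable:
        raise ValueError("no converged fits to compare")
    weights = akaike_weights([usable[n].aicc for n in usable])
    wmap = dict(zip(usable, weights))
    best_aicc = min(f.aicc for f in usable.values())
    best = min(
        (f for f in usable.values() if f.aicc == best_aicc),
        key=lambda f: (f.k_params, CANONICAL_ORDER.index(f.function)),
    ).function
    rows = []
    for name in CANONICAL_ORDER:
        f = fits.get(name)
        if name in usable:
            rows.append(ComparisonRow(name, f.aicc, f.aicc - best_aicc, wmap[name], True))
        else:
            rows.append(ComparisonRow(name, float("nan"), float("nan"), 0.0, False))
    some = next(iter(usable.values()))
    return ComparisonTable(
        site_id=site_id if site_id is not None else "",
        scaling=scaling if scaling is not None else some.family,
        rows=rows,
        best=best,
        fits=dict(fits),
    )


def family_for_scaling(scaling: str) -> str:
    """Error family matched to a scaling: NB for counts, Gamma for rates."""
    return "negative_binomial" if scaling == "per_site" else "gamma"


def fit_site(series: ScaledSeries, family: str | None = None, **fit_options) -> ComparisonTable:
    """Fit all six candidate functions to one scaled series and compare them.

    Fit failures (too few events never reach here; non-convergence does) are
    recorded as missing rows rather than raised.
    """
    if family is None:
        family = family_for_scaling(series.scaling)
    fits: dict[str, FitResult | None] = {}
    for name in CANONICAL_ORDER:
        try:
            fits[name] = fit_mle(name, series, family, **fit_options)
        except (FitError, TooFewEventsError) as exc:
            warnings.warn(f"site {series.site_id}: {name} fit failed: {exc}")
            fits[name] = None
    return compare_site(fits, site_id=series.site_id, scaling=series.scaling)


@dataclass
class CrossSiteSummary:
    """Evidence ratios of one function over another, across sites."""

    numerator: str
    denominator: str
    mean: float
    sd: float
    min: float
    max: float
    per_site: list[tuple[str, float]]
    n_infinite: int = 0


def cross_site_summary(tables: Sequence[ComparisonTable], numerator: str,
                       denominator: str) -> CrossSiteSummary:
    """Average the per-site evidence ratios ``w_num / w_den``.

    Infinite ratios (zero denominator weights) are flagged and excluded from
    the mean/SD, with a warning.
    """
    if not tables:
        raise ValueError("need at least one comparison table")
    per_site = [
        (t.site_id, evidence_ratio(t.weight(numerator), t.weight(denominator)))
        for t in tables
    ]
    ratios = np.array([r for _, r in per_site])
    finite = ratios[np.isfinite(ratios)]
    n_inf = int(np.sum(~np.isfinite(ratios)))
    if n_inf:
        warnings.warn(f"{n_inf} site(s) had an infinite evidence ratio; mean over finite sites")
    if finite.size == 0:
        raise ValueError("all evidence ratios are infinite")
    sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    return CrossSiteSummary(
        numerator=numerator,
        denominator=denominator,
        mean=float(finite.mean()),
        sd=sd,
        min=float(finite.min()),
        max=float(finite.max()),
        per_site=per_site,
        n_infinite=n_inf,
    )


class PeakLocation(NamedTuple):
    density: float | None
    value: float | None
    proportion: float | None


def peak_location(fit: FitResult, n_initial: int) -> PeakLocation:
    """Interior maximum of a fitted hump-shaped function.

    RDD peaks at ``D* = 1/b`` with height ``a/(b e)``; PDD at ``D* = b/(2a)``
    with height ``b**2/(4a)``.  Monotone or constant functions (and
    degenerate hump fits with non-positive curvature parameters) have no
    interior peak and return ``(None, None, None)``.
    """
    if n_initial <= 0:
        raise ValueError("n_initial must be positive")
    none = PeakLocation(None, None, None)
    if fit.function == "RDD":
        if fit.b is None or fit.b <= 0 or fit.a is None or fit.a <= 0:
            return none
        d = 1.0 / fit.b
        v = fit.a / (fit.b * np.e)
    elif fit.function == "PDD":
        if fit.a is None or fit.a <= 0 or fit.b <= 0:
            return none
        d = fit.b / (2.0 * fit.a)
        v = fit.b**2 / (4.0 * fit.a)
    else:
        return none
    return PeakLocation(float(d), float(v), float(d / n_initial))


class BinStat(NamedTuple):
    center: float
    mean: float
    se: float
    n: int


def bin_summary(points: ScaledSeries, bin_width: float = 0.1) -> list[BinStat]:
    """Mean +/- 1 SE of responses per half-open density bin.

    Densities are expected in proportion-of-initial units.  Points at
    exactly zero density form their own bin (reported first, centre 0);
    other points fall into ``[k*w, (k+1)*w)``.  SE is the sample SD over
    ``sqrt(n)``, reported as 0 for singleton bins.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    D, y = points.densities, points.responses
    if len(D) == 0:
        return []
    out: list[BinStat] = []

    def stat(center: float, vals: np.ndarray) -> BinStat:
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        return BinStat(center, float(vals.mean()), se, len(vals))

    zero = y[D == 0]
    if zero.size:
        out.append(stat(0.0, zero))
    pos_D, pos_y = D[D > 0], y[D > 0]
    if pos_D.size:
        idx = np.floor(pos_D / bin_width).astype(int)
        for k in sorted(set(idx)):
            out.append(stat((k + 0.5) * bin_width, pos_y[idx == k]))
    return out


def vacancy_fill_summary(series_list: Sequence[SiteSeries], bootstrap_reps: int = 10_000,
                         seed: int = 0) -> tuple[float, float, float, int]:
    """Median proportion of new vacancies filled by immigrants, with a
    percentile-bootstrap 95% CI.

    Per-event fill is ``I_t / n_removed`` pooled over sites (events with a
    catch only).  Returns ``(median, ci_low, ci_high, n_events)``.
    """
    fills = np.array(
        [e.n_immigrants / e.n_removed for s in series_list for e in s if e.n_removed > 0]
    )
    if fills.size == 0:
        raise ValueError("no events with a positive number removed")
    rng = np.random.default_rng(seed)
    meds = np.median(
        fills[rng.integers(0, fills.size, size=(bootstrap_reps, fills.size))], axis=1
    )
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return float(np.median(fills)), float(lo), float(hi), int(fills.size)


class DensityDependenceSelector(BaseEstimator):
    """Sklearn-style selector fitting all six candidate functions.

    Parameters
    ----------
    family : str, default "negative_binomial"
        Error family for every candidate fit.
    tol : float
        Optimizer tolerance forwarded to each fit.

    Attributes
    ----------
    comparison_ : ComparisonTable
    best_function_ : str
    best_fit_ : FitResult
    weights_ : dict mapping function name to Akaike weight
    """

    def __init__(self, family: str = "negative_binomial", tol: float = 1e-8):
        self.family = family
        self.tol = tol

    def fit(self, X, y):
        D = np.asarray(X, dtype=float)
        if D.ndim == 2:
            D = D[:, 0]
        series = ScaledSeries(
            "selector",
            "per_site" if self.family == "negative_binomial" else "per_new_vacancy",
            [],
        )
        # bypass ScaledPoint construction cost: fit on raw arrays
        fits: dict[str, FitResult | None] = {}
        for name in CANONICAL_ORDER:
            try:
                fits[name] = fit_mle(name, (D, np.asarray(y, dtype=float)), self.family,
                                     tol=self.tol)
            except (FitError, TooFewEventsError) as exc:
                warnings.warn(f"{name} fit failed: {exc}")
                fits[name] = None
        self.comparison_ = compare_site(fits, site_id="selector", scaling=series.scaling)
        self.best_function_ = self.comparison_.best
        self.best_fit_ = fits[self.best_function_]
        self.weights_ = {r.function: r.weight for r in self.comparison_.rows}
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        D = np.asarray(X, dtype=float)
        if D.ndim == 2:
            D = D[:, 0]
        f = self.best_fit_
        return mean_function(f.function, f.a, f.b, D)


def format_comparison_tables(tables: Sequence[ComparisonTable]) -> str:
    """Render comparison tables as a functions x sites text table."""
    lines = ["function  " + "".join(f"{t.site_id:>18}" for t in tables)]
    for name in CANONICAL_ORDER:
        cells = []
        for t in tables:
            r = t.row(name)
            mark = "*" if t.best == name else " "
            cells.append(f"{r.aicc:9.2f} {r.weight:6.3f}{mark}")
        lines.append(f"{name:<8}  " + "".join(f"{c:>18}" for c in cells))
    return "\n".join(lines)
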