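"""The three response scalings of immigration against density.

Immigration after each removal event can be expressed three ways:

* **per site** — the raw immigrant count ``I_t`` (equivalent to per unit
  area, since site area is constant); defined at every event, including
  pre-removal visits and events after density reached zero.
* **per new vacancy** — ``I_t`` divided by the number just removed.  Events
  with no catch (pre-removal visits, post-extinction observations) are
  excluded because 0/0 is undefined.
* **per capita** — ``I_t`` divided by the number remaining.  Zero-density
  events are excluded because the ratio is undefined.  Note that per-capita
  scaling regresses ``Y/X`` on ``X`` and can manufacture a spurious negative
  trend (pseudo-density-dependence) even when immigration is density
  independent; see :mod:`densimm.validation_experiments`.

Densities can be re-expressed as a proportion of the site's initial
abundance (:func:`to_proportion`) to make sites comparable, and zero-density
points can be dropped (:func:`drop_zero_density`) for sensitivity
re-analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .experiment_io import SiteSeries

__all__ = [
    "ScaledPoint",
    "ScaledSeries",
    "SCALINGS",
    "per_site",
    "per_new_vacancy",
    "per_capita",
    "scale",
    "to_proportion",
    "drop_zero_density",
    "pool_series",
]

SCALINGS = ("per_site", "per_new_vacancy", "per_capita")
_ALIASES = {"per_vacancy": "per_new_vacancy"}


def canonical_scaling(label: str) -> str:
    label = _ALIASES.get(label, label)
    if label not in SCALINGS:
        raise ValueError(f"unknown scaling {label!r}; expected one of {SCALINGS}")
    return label


@dataclass(frozen=True)
class ScaledPoint:
    """One (density, scaled immigration) pair."""

    density: float
    response: float

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.response < 0:
            raise ValueError("response must be non-negative")


@dataclass
class ScaledSeries:
    """A site's (density, response) points under one scaling."""

    site_id: str
    scaling: str
    points: list[ScaledPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scaling = canonical_scaling(self.scaling)
        self.points = list(self.points)

    @property
    def densities(self) -> np.ndarray:
        return np.array([p.density for p in self.points], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([p.response for p in self.points], dtype=float)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[ScaledPoint]:
        return iter(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_id,
                "density": self.densities,
                "response": self.responses,
                "scaling": self.scaling,
            }
        )


def per_site(series: SiteSeries) -> ScaledSeries:
    """Raw immigrant counts at every event, including zero-density ones."""
    pts = [ScaledPoint(e.n_remaining, e.n_immigrants) for e in series]
    return ScaledSeries(series.site_id, "per_site", pts)


def per_new_vacancy(series: SiteSeries) -> ScaledSeries:
    """Immigrants per fish just removed; no-catch events are excluded."""
    pts = [
        ScaledPoint(e.n_remaining, e.n_immigrants / e.n_removed)
        for e in series
        if e.n_removed > 0
    ]
    return ScaledSeries(series.site_id, "per_new_vacancy", pts)


def per_capita(series: SiteSeries) -> ScaledSeries:
    """Immigrants per fish remaining; zero-density events are excluded."""
    pts = [
        ScaledPoint(e.n_remaining, e.n_immigrants / e.n_remaining)
        for e in series
        if e.n_remaining > 0
    ]
    return ScaledSeries(series.site_id, "per_capita", pts)


_SCALING_FUNCS = {
    "per_site": per_site,
    "per_new_vacancy": per_new_vacancy,
    "per_capita": per_capita,
}


def scale(series: SiteSeries, scaling: str) -> ScaledSeries:
    """Apply the named scaling to a site series."""
    return _SCALING_FUNCS[canonical_scaling(scaling)](series)


def to_proportion(series: ScaledSeries, n_initial: int) -> ScaledSeries:
    """Express densities as a proportion of the initial abundance.

    Proportions may slightly exceed 1 when immigration outpaced removal; no
    clamp is applied.  Responses are untouched.
    """
    if n_initial <= 0:
        raise ValueError("n_initial must be positive")
    pts = [ScaledPoint(p.density / n_initial, p.response) for p in series]
    return ScaledSeries(series.site_id, series.scaling, pts)


def drop_zero_density(series: ScaledSeries) -> ScaledSeries:
    """Remove zero-density points (sensitivity re-analysis)."""
    pts = [p for p in series if p.density != 0]
    return ScaledSeries(series.site_id, series.scaling, pts)


def pool_series(series_list: Sequence[ScaledSeries], site_id: str = "pooled") -> ScaledSeries:
    """Concatenate several scaled series (same scaling) into one."""
    scalings = {s.scaling for s in series_list}
    if len(scalings) != 1:
        raise ValueError(f"cannot pool mixed scalings: {sorted(scalings)}")
    pts = [p for s in series_list for p in s]
    return ScaledSeries(site_id, scalings.pop(), pts)
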