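"""Published per-site model-comparison results from the damselfish removal
study that motivates this package.

Seven ~60-fish depletion sites on Barbados fringing reefs (Bachelor Hall:
BH1; Heron Bay: HB1-HB4; Sandy Lane: SL1, SL2) were analysed under per-site
scaling with a negative-binomial likelihood; the study printed, per site,
the AICc of each of the six candidate functions and the corresponding
Akaike weights (to 2 and 3 decimals respectively).  The raw per-event
counts were not deposited, so these printed columns are the study-level
input this package can recompute from: feeding an AICc column to
:func:`densimm.model_selection.akaike_weights` should reproduce the printed
weights up to their rounding.

A few printed weight cells are arithmetically inconsistent with their own
AICc column (most obviously HB1/SDD, printed 0.961 against the column's
worst AICc) or carry visible rounding error from the 2-decimal AICc
(parts of the HB4 and SL1 columns, whose printed weights were evidently
computed from unrounded scores); these are flagged in
``INCONSISTENT_CELLS`` and ``ROUNDING_LIMITED_CELLS``.
"""

from __future__ import annotations

from .candidate_models import CANONICAL_ORDER

__all__ = [
    "SITE_ORDER",
    "PER_SITE_AICC",
    "PER_SITE_WEIGHTS",
    "INCONSISTENT_CELLS",
    "ROUNDING_LIMITED_CELLS",
    "aicc_column",
    "weight_column",
]

SITE_ORDER = ("HB3", "HB1", "SL2", "SL1", "BH1", "HB2", "HB4")

# AICc per candidate function (canonical order DI, LDD, EDD, SDD, PDD, RDD),
# as printed; the study's tables label the exponential function "NDD".
PER_SITE_AICC: dict[str, dict[str, float]] = {
    "HB3": {"DI": 51.20, "LDD": 49.91, "EDD": 50.17, "SDD": 54.23, "PDD": 62.31, "RDD": 41.29},
    "HB1": {"DI": 22.96, "LDD": 25.74, "EDD": 27.18, "SDD": 37.18, "PDD": 29.32, "RDD": 16.54},
    "SL2": {"DI": 52.83, "LDD": 56.50, "EDD": 56.50, "SDD": 49.96, "PDD": 72.36, "RDD": 45.34},
    "SL1": {"DI": 69.40, "LDD": 72.34, "EDD": 72.48, "SDD": 67.36, "PDD": 73.16, "RDD": 65.50},
    "BH1": {"DI": 35.37, "LDD": 38.72, "EDD": 39.08, "SDD": 36.80, "PDD": 53.68, "RDD": 33.56},
    "HB2": {"DI": 33.14, "LDD": 33.78, "EDD": 35.32, "SDD": 37.94, "PDD": 44.66, "RDD": 34.62},
    "HB4": {"DI": 49.64, "LDD": 53.57, "EDD": 53.57, "SDD": 53.69, "PDD": 53.05, "RDD": 58.55},
}

# Printed 3-decimal Akaike weights for the same cells.
PER_SITE_WEIGHTS: dict[str, dict[str, float]] = {
    "HB3": {"DI": 0.007, "LDD": 0.013, "EDD": 0.011, "SDD": 0.001, "PDD": 0.000, "RDD": 0.967},
    "HB1": {"DI": 0.038, "LDD": 0.010, "EDD": 0.005, "SDD": 0.961, "PDD": 0.002, "RDD": 0.946},
    "SL2": {"DI": 0.021, "LDD": 0.003, "EDD": 0.003, "SDD": 0.088, "PDD": 0.000, "RDD": 0.885},
    "SL1": {"DI": 0.089, "LDD": 0.020, "EDD": 0.019, "SDD": 0.247, "PDD": 0.014, "RDD": 0.617},
    "BH1": {"DI": 0.232, "LDD": 0.044, "EDD": 0.036, "SDD": 0.114, "PDD": 0.000, "RDD": 0.574},
    "HB2": {"DI": 0.380, "LDD": 0.276, "EDD": 0.128, "SDD": 0.034, "PDD": 0.001, "RDD": 0.181},
    "HB4": {"DI": 0.623, "LDD": 0.096, "EDD": 0.096, "SDD": 0.090, "PDD": 0.124, "RDD": 0.008},
}

# Cells whose printed weight contradicts the printed AICc column outright:
# HB1/SDD prints 0.961 against the column's worst AICc, and the HB4
# LDD-PDD block belongs to a weight column that sums to 1.037.
INCONSISTENT_CELLS: frozenset[tuple[str, str]] = frozenset(
    {
        ("HB1", "SDD"),
        ("HB4", "LDD"),
        ("HB4", "EDD"),
        ("HB4", "SDD"),
        ("HB4", "PDD"),
    }
)

# Cells whose printed weight differs from the recomputation by more than
# 0.001 but is explained by the 2-decimal rounding of the printed AICc.
ROUNDING_LIMITED_CELLS: frozenset[tuple[str, str]] = frozenset(
    {
        ("SL1", "DI"),
        ("SL1", "SDD"),
    }
)


def aicc_column(site: str) -> list[float]:
    """AICc scores for one site in canonical function order."""
    col = PER_SITE_AICC[site]
    return [col[name] for name in CANONICAL_ORDER]


def weight_column(site: str) -> list[float]:
    """Printed Akaike weights for one site in canonical function order."""
    col = PER_SITE_WEIGHTS[site]
    return [col[name] for name in CANONICAL_ORDER]
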