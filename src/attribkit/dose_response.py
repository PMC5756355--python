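"""Quantile-specific relative risks from a log-linear dose-response slope.

Meta-analyses of dietary intake typically report one relative risk per fixed
intake increment (here 100 g/day), assuming risk is log-linear in dose. To
attribute burden over intake quintiles, that slope is turned into one RR per
quintile: each quintile is represented by its lower intake bound, the log
slope per gram is multiplied by that bound, and all quintiles are rescaled so
the reference quantile (the most favourable one) has RR exactly 1.

The inverse operation — fitting the per-gram slope back from a printed set of
quantile RRs — supports calibration and consistency checks.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .data_model import DoseResponseRR, QuantileScheme

__all__ = [
    "log_slope_per_gram",
    "quantile_rrs_from_slope",
    "quantile_rr_cis_from_slope",
    "fit_slope_from_levels",
]


def log_slope_per_gram(dr: DoseResponseRR | float) -> float:
    """ln(RR per 100 g/day) / 100 — the log-RR per gram of daily intake.

    Negative for protective exposures (RR per increment < 1).
    """
    rr = dr.rr_per_100g if isinstance(dr, DoseResponseRR) else float(dr)
    if rr <= 0:
        raise ValueError(f"dose-response RR must be > 0, got {rr}")
    return math.log(rr) / 100.0


def quantile_rrs_from_slope(
    beta: float, scheme: QuantileScheme, round_decimals: int | None = None
) -> list[float]:
    """RR per quantile, relative to the scheme's reference quantile.

    RR_i = exp(beta * (L_i - L_ref)) with L_i the quantile's lower intake
    bound (g/day); the reference entry is exactly 1. ``round_decimals=2``
    gives the display convention of published tables.
    """
    ref = scheme.lower_bounds[scheme.reference_index]
    rrs = [math.exp(beta * (b - ref)) for b in scheme.lower_bounds]
    rrs[scheme.reference_index] = 1.0
    if round_decimals is not None:
        rrs = [round(rr, round_decimals) for rr in rrs]
    return rrs


def quantile_rr_cis_from_slope(
    dr: DoseResponseRR, scheme: QuantileScheme, round_decimals: int | None = None
) -> list[tuple[float, float, float]]:
    """(rr, ci_low, ci_high) per quantile; the CI bounds get the same transform
    as the point estimate."""
    out = []
    columns = [
        quantile_rrs_from_slope(log_slope_per_gram(v), scheme, round_decimals)
        for v in (dr.rr_per_100g, dr.ci_per_100g[0], dr.ci_per_100g[1])
    ]
    for rr, a, b in zip(*columns):
        lo, hi = min(a, b), max(a, b)
        out.append((rr, lo, hi))
    return out


def fit_slope_from_levels(
    levels: Sequence[tuple[float, float]], reference_index: int
) -> float:
    """Least-squares inverse of :func:`quantile_rrs_from_slope`.

    ``levels`` are (lower_bound g/day, rr) pairs with the reference entry at
    ``reference_index`` (rr 1 there by construction). Fits ln(RR_i) against
    (L_i - L_ref) through the origin; exact inversion when only one
    non-reference level is given.
    """
    if len(levels) < 2:
        raise ValueError("need at least two levels to fit a slope")
    bounds = [b for b, _ in levels]
    if len(set(bounds)) != len(bounds):
        raise ValueError("quantile lower bounds must be distinct")
    ref_bound = bounds[reference_index]
    x = np.array(
        [b - ref_bound for i, (b, _) in enumerate(levels) if i != reference_index]
    )
    y = np.array(
        [math.log(rr) for i, (_, rr) in enumerate(levels) if i != reference_index]
    )
    if np.all(y == 0.0) and np.all(x == 0.0):
        raise ValueError("all levels at the reference bound; slope undefined")
    return float((x * y).sum() / (x * x).sum())
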