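"""Confidence intervals for attributable fractions.

Two propagation routes are provided:

* a first-order **delta method** for Levin's formula, treating ln(RR) as
  normal with SD recovered from the published CI (and optionally a binomial
  SD for the prevalence), and
* seeded **Monte-Carlo** propagation, drawing ln(RR) per level from a normal
  (i.e. lognormal RR — the standard assumption for ratio measures), which
  also covers multi-level, region-pooled and multiplicatively combined PAFs
  where no closed-form variance is available.

Independence is assumed across levels and factors throughout; correlations
induced by shared meta-analytic slopes are ignored (a documented
approximation).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .data_model import Region, RiskFactorSpec, Sex, round_half_up
from .paf_core import levin_paf, multi_level_paf, pool_regions

__all__ = [
    "UncertaintySpec",
    "rr_log_sd",
    "paf_ci_delta",
    "paf_ci_mc",
    "percentile_ci",
    "paf_draws",
    "factor_paf_draws",
]


class UncertaintySpec(BaseModel):
    """How CIs are computed: z-multiplier, method, and Monte-Carlo budget."""

    z: float = Field(default=1.96, gt=0.0)
    method: str = Field(default="monte_carlo", pattern="^(delta|monte_carlo)$")
    draws: int = Field(default=5000, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "UncertaintySpec":
        if self.method == "monte_carlo" and self.draws < 1000:
            raise ValueError(f"monte_carlo needs >= 1000 draws, got {self.draws}")
        return self


def rr_log_sd(rr_ci: tuple[float, float], z: float = 1.96) -> float:
    """SD of ln(RR) recovered from a CI symmetric on the log scale:
    (ln(hi) - ln(lo)) / (2z)."""
    lo, hi = rr_ci
    if lo <= 0:
        raise ValueError(f"CI lower bound must be > 0, got {lo}")
    if hi < lo:
        raise ValueError(f"CI bounds out of order: ({lo}, {hi})")
    return (math.log(hi) - math.log(lo)) / (2.0 * z)


def _coverage_alpha(z: float) -> float:
    """Two-sided tail probability matching a +-z normal interval."""
    return 2.0 * (1.0 - 0.5 * (1.0 + math.erf(z / math.sqrt(2.0))))


def percentile_ci(draws: np.ndarray, z: float = 1.96) -> tuple[float, float]:
    """Percentile interval of Monte-Carlo PAF draws, truncated to [0, 1)."""
    alpha = _coverage_alpha(z)
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return max(float(lo), 0.0), min(float(hi), math.nextafter(1.0, 0.0))


def paf_ci_delta(
    p: float,
    rr: float,
    rr_ci: tuple[float, float],
    p_sd: Optional[float] = None,
    z: float = 1.96,
) -> tuple[float, float]:
    """Delta-method CI for Levin's PAF.

    var(PAF) ~ (dPAF/dRR)^2 (RR * sd_lnRR)^2 + (dPAF/dP)^2 sd_P^2 with
    dPAF/dRR = P / (1 + P(RR-1))^2 and dPAF/dP = (RR-1) / (1 + P(RR-1))^2;
    the prevalence term drops out when ``p_sd`` is absent. The interval is
    PAF +- z*sd, truncated to [0, 1).
    """
    paf = levin_paf(p, rr)
    denom = (1.0 + p * (rr - 1.0)) ** 2
    d_rr = p / denom
    d_p = (rr - 1.0) / denom
    var = (d_rr * rr * rr_log_sd(rr_ci, z)) ** 2
    if p_sd is not None:
        var += (d_p * p_sd) ** 2
    half = z * math.sqrt(var)
    return max(paf - half, 0.0), min(paf + half, math.nextafter(1.0, 0.0))


def paf_draws(
    levels: Sequence[tuple[float, float, float]], rng: np.random.Generator, draws: int
) -> np.ndarray:
    """Monte-Carlo PAF draws for one leveled exposure.

    ``levels`` are (prevalence, rr, sd_lnRR) triples for the non-reference
    levels; ln(RR) is drawn independently per level. Non-finite draws (never
    produced for finite sd, but guarded) are dropped.
    """
    p = np.array([lv[0] for lv in levels])
    log_rr = np.log([lv[1] for lv in levels])
    sd = np.array([lv[2] for lv in levels])
    rr = np.exp(rng.normal(log_rr, sd, size=(draws, len(levels))))
    excess = (p * (rr - 1.0)).sum(axis=1)
    out = excess / (excess + 1.0)
    return out[np.isfinite(out)]


def paf_ci_mc(
    levels: Sequence[tuple[float, float, tuple[float, float]]],
    spec: UncertaintySpec,
) -> tuple[float, float]:
    """Percentile CI for a (possibly multi-level) factor.

    ``levels`` are (prevalence, rr, (ci_lo, ci_hi)) triples; deterministic for
    a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    triples = [(p, rr, rr_log_sd(ci, spec.z)) for p, rr, ci in levels]
    d = paf_draws(triples, rng, spec.draws)
    point = multi_level_paf([(p, rr) for p, rr, _ in levels])
    lo, hi = percentile_ci(d, spec.z)
    return min(lo, point), max(hi, point)


def factor_paf_draws(
    factor: RiskFactorSpec,
    sex: Sex,
    urban_weight: float,
    z: float,
    rng: np.random.Generator,
    draws: int,
) -> np.ndarray:
    """PAF draws for one factor and sex, pooling urban/rural draws when the
    factor is region-split. Reference levels carry zero excess and are skipped."""
    by_region = {s.region: lv for s, lv in factor.levels.items() if s.sex == sex}

    def region_draws(levels) -> np.ndarray:
        triples = [
            (lv.prevalence, lv.rr, rr_log_sd(lv.rr_ci, z))
            for lv in levels
            if not lv.is_reference
        ]
        return paf_draws(triples, rng, draws)

    if Region.national in by_region:
        return region_draws(by_region[Region.national])
    urban = region_draws(by_region[Region.urban])
    rural = region_draws(by_region[Region.rural])
    n = min(urban.size, rural.size)
    return pool_regions(urban[:n], rural[:n], urban_weight)
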