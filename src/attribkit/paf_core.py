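"""Population attributable fractions: the three formulas and their orchestration.

* Levin's formula for a binary exposure,
  PAF = P(RR-1) / (P(RR-1) + 1).
* Its multi-level generalisation for leveled exposures under a full shift to
  the reference level, PAF = sum p_i(RR_i-1) / (sum p_i(RR_i-1) + 1).
* The multiplicative combination over independent factors,
  PAF = 1 - prod_k (1 - PAF_k).

Plus the bookkeeping that turns per-stratum PAFs into a published-style
burden table: urban/rural pooling, attributable-count conversion under a
display-compatible rounding policy, and sex pooling by attributable deaths.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .data_model import (
    BurdenCounts,
    PAFEstimate,
    Region,
    RiskFactorSpec,
    RoundingPolicy,
    Sex,
    Stratum,
    StudyConfig,
    round_half_up,
)

if TYPE_CHECKING:  # pragma: no cover
    from .uncertainty import UncertaintySpec

__all__ = [
    "levin_paf",
    "multi_level_paf",
    "combine_pafs",
    "pool_regions",
    "attributable_counts",
    "pool_sexes",
    "run_study",
    "factor_sex_paf",
    "table_from_reported_pafs",
]


def levin_paf(p: float, rr: float) -> float:
    """Levin's attributable fraction for a binary exposure.

    Negative when rr < 1 (protective coding); always < 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    if rr <= 0:
        raise ValueError(f"relative risk must be > 0, got {rr}")
    excess = p * (rr - 1.0)
    return excess / (excess + 1.0)


def multi_level_paf(levels: Sequence[tuple[float, float]]) -> float:
    """Attributable fraction for a leveled exposure under a full shift.

    ``levels`` are (prevalence, rr) pairs; reference levels (rr = 1) may be
    included or omitted — they contribute nothing. Reduces to Levin's formula
    for a single non-reference level.
    """
    total_p = 0.0
    excess = 0.0
    for p, rr in levels:
        if p < 0:
            raise ValueError(f"negative prevalence {p}")
        if rr <= 0:
            raise ValueError(f"relative risk must be > 0, got {rr}")
        total_p += p
        excess += p * (rr - 1.0)
    if total_p > 1.0 + 1e-9:
        raise ValueError(f"prevalences sum to {total_p} > 1")
    return excess / (excess + 1.0)


def combine_pafs(pafs: Iterable[float]) -> float:
    """Joint PAF of independent factors: 1 - prod(1 - PAF_k). Order-invariant."""
    complement = 1.0
    for paf in pafs:
        if paf >= 1.0:
            raise ValueError(f"PAF must be < 1, got {paf}")
        complement *= 1.0 - paf
    return 1.0 - complement


def pool_regions(urban_paf: float, rural_paf: float, urban_weight: float) -> float:
    """Population-weighted arithmetic mean of urban and rural PAFs."""
    if not 0.0 <= urban_weight <= 1.0:
        raise ValueError(f"urban weight must be in [0, 1], got {urban_weight}")
    return urban_weight * urban_paf + (1.0 - urban_weight) * rural_paf


def attributable_counts(
    paf: float, counts: int, policy: RoundingPolicy | None = None
) -> int:
    """Convert a PAF to an attributable count of deaths or cases.

    Under the default policy the PAF is first rounded to one decimal in
    percent, then multiplied by the burden and rounded half-up — the
    convention that makes published count columns exactly recomputable from
    their displayed PAFs.
    """
    if paf >= 1.0:
        raise ValueError(f"PAF must be < 1, got {paf}")
    policy = policy or RoundingPolicy()
    return int(round_half_up(policy.round_paf(paf) * counts))


def pool_sexes(
    male: PAFEstimate, female: PAFEstimate, burden: BurdenCounts
) -> PAFEstimate:
    """Sex-pooled total row: counts add; the pooled PAF is attributable deaths
    over total deaths. The CI is the deaths-weighted mean of the per-sex
    bounds (a display approximation; Monte-Carlo pooling in run_study is
    preferred)."""
    if male.factor != female.factor:
        raise ValueError(f"factor mismatch: {male.factor!r} vs {female.factor!r}")
    deaths = male.attributable_deaths + female.attributable_deaths
    cases = male.attributable_cases + female.attributable_cases
    paf = deaths / burden.total_deaths
    wm = burden.deaths[Sex.male] / burden.total_deaths
    ci = tuple(
        wm * m + (1 - wm) * f for m, f in zip(male.ci, female.ci)
    )
    ci = (min(ci[0], paf), max(ci[1], paf))
    return PAFEstimate(
        factor=male.factor,
        stratum="total",
        paf=paf,
        ci=ci,
        attributable_deaths=deaths,
        attributable_cases=cases,
    )


def factor_sex_paf(
    factor: RiskFactorSpec, sex: Sex, urban_weight: float
) -> float:
    """Point PAF of one factor for one sex, pooling urban/rural when split."""
    by_region = {s.region: lv for s, lv in factor.levels.items() if s.sex == sex}
    if Region.national in by_region:
        return multi_level_paf(
            [(lv.prevalence, lv.rr) for lv in by_region[Region.national]]
        )
    pafs = {
        region: multi_level_paf([(lv.prevalence, lv.rr) for lv in levels])
        for region, levels in by_region.items()
    }
    return pool_regions(pafs[Region.urban], pafs[Region.rural], urban_weight)


def run_study(
    config: StudyConfig, uncertainty: Optional["UncertaintySpec"] = None
) -> list[PAFEstimate]:
    """Full published-table reconstruction for a study configuration.

    Produces, in order: one row per factor for men, women and the sex-pooled
    total, then a "combined" row per sex and overall. Per-sex combined PAFs
    multiply the (policy-rounded) per-factor PAFs of that sex; the overall
    combined PAF multiplies the factor-level total PAFs, while overall
    combined counts are sums over sexes — the two are slightly inconsistent
    by construction, as in the source convention. Confidence intervals come
    from seeded Monte-Carlo propagation of the RR uncertainty (delta method
    for binary factors when requested).
    """
    from .uncertainty import UncertaintySpec, factor_paf_draws, paf_ci_delta, percentile_ci

    unc = uncertainty or UncertaintySpec()
    rng = np.random.default_rng(unc.seed)
    policy = config.rounding
    burden = config.burden
    sexes = (Sex.male, Sex.female)

    point: dict[tuple[str, Sex], float] = {}
    cis: dict[tuple[str, Sex], tuple[float, float]] = {}
    draws: dict[tuple[str, Sex], np.ndarray] = {}
    for factor in config.factors:
        for sex in sexes:
            paf = factor_sex_paf(factor, sex, config.urban_weight)
            if paf < 0:
                raise ValueError(
                    f"factor {factor.name!r} ({sex.value}): negative PAF {paf:.4f}; "
                    "code exposures so the harmful level carries rr >= 1"
                )
            point[(factor.name, sex)] = paf
            use_delta = (
                unc.method == "delta"
                and factor.kind == "binary"
                and not factor.has_region_split()
            )
            if use_delta:
                lv = next(
                    l
                    for l in factor.levels[Stratum(sex=sex, region=Region.national)]
                    if not l.is_reference
                )
                lo, hi = paf_ci_delta(lv.prevalence, lv.rr, lv.rr_ci, z=config.z)
                draws[(factor.name, sex)] = np.array([])
                cis[(factor.name, sex)] = (lo, hi)
            else:
                d = factor_paf_draws(
                    factor, sex, config.urban_weight, config.z, rng, unc.draws
                )
                draws[(factor.name, sex)] = d
                cis[(factor.name, sex)] = percentile_ci(d, config.z)

    estimates: list[PAFEstimate] = []
    total_point: dict[str, float] = {}
    total_draws: dict[str, np.ndarray] = {}
    wm = burden.deaths[Sex.male] / burden.total_deaths
    for factor in config.factors:
        per_sex: dict[Sex, PAFEstimate] = {}
        for sex in sexes:
            paf = point[(factor.name, sex)]
            lo, hi = cis[(factor.name, sex)]
            per_sex[sex] = PAFEstimate(
                factor=factor.name,
                stratum=sex.value,
                paf=paf,
                ci=(min(lo, paf), max(hi, paf)),
                attributable_deaths=attributable_counts(paf, burden.deaths[sex], policy),
                attributable_cases=attributable_counts(paf, burden.incidence[sex], policy),
            )
            estimates.append(per_sex[sex])
        total = pool_sexes(per_sex[Sex.male], per_sex[Sex.female], burden)
        dm, df = draws[(factor.name, Sex.male)], draws[(factor.name, Sex.female)]
        if dm.size and df.size:
            from .uncertainty import percentile_ci as _pci

            td = wm * dm + (1 - wm) * df
            lo, hi = _pci(td, config.z)
            total = total.model_copy(
                update={"ci": (min(lo, total.paf), max(hi, total.paf))}
            )
            total_draws[factor.name] = td
        estimates.append(total)
        total_point[factor.name] = total.paf

    # combined rows
    from .uncertainty import percentile_ci as _pci

    combined_sex_counts = {"deaths": 0, "cases": 0}
    for sex in sexes:
        pafs = [policy.round_paf(point[(f.name, sex)]) for f in config.factors]
        combined = combine_pafs(pafs)
        sex_draws = [draws[(f.name, sex)] for f in config.factors]
        if all(d.size for d in sex_draws):
            cd = 1.0 - np.prod([1.0 - d for d in sex_draws], axis=0)
            lo, hi = _pci(cd, config.z)
        else:
            lo = hi = combined
        deaths = attributable_counts(combined, burden.deaths[sex], policy)
        cases = attributable_counts(combined, burden.incidence[sex], policy)
        combined_sex_counts["deaths"] += deaths
        combined_sex_counts["cases"] += cases
        estimates.append(
            PAFEstimate(
                factor="combined",
                stratum=sex.value,
                paf=combined,
                ci=(min(lo, combined), max(hi, combined)),
                attributable_deaths=deaths,
                attributable_cases=cases,
            )
        )
    combined_total = combine_pafs(
        [policy.round_paf(total_point[f.name]) for f in config.factors]
    )
    if total_draws and len(total_draws) == len(config.factors):
        cd = 1.0 - np.prod([1.0 - total_draws[f.name] for f in config.factors], axis=0)
        lo, hi = _pci(cd, config.z)
    else:
        lo = hi = combined_total
    estimates.append(
        PAFEstimate(
            factor="combined",
            stratum="total",
            paf=combined_total,
            ci=(min(lo, combined_total), max(hi, combined_total)),
            attributable_deaths=combined_sex_counts["deaths"],
            attributable_cases=combined_sex_counts["cases"],
        )
    )
    return estimates


def table_from_reported_pafs(
    reported: pd.DataFrame,
    burden: BurdenCounts,
    policy: RoundingPolicy | None = None,
) -> pd.DataFrame:
    """Combined-burden arithmetic applied to an already-published per-sex PAF
    column (percent): factor totals by attributable-death pooling, combined
    rows by the multiplicative formula, counts under the rounding policy.

    This is the route that reconstructs a published table's bottom rows from
    its own displayed per-factor PAFs.
    """
    policy = policy or RoundingPolicy()
    rows = []
    factor_total_pafs = []
    for rec in reported.itertuples():
        m = rec.male_paf_pct / 100.0
        f = rec.female_paf_pct / 100.0
        md = attributable_counts(m, burden.deaths[Sex.male], policy)
        fd = attributable_counts(f, burden.deaths[Sex.female], policy)
        mc = attributable_counts(m, burden.incidence[Sex.male], policy)
        fc = attributable_counts(f, burden.incidence[Sex.female], policy)
        total_paf = (md + fd) / burden.total_deaths
        factor_total_pafs.append(policy.round_paf(total_paf))
        rows.append(
            {
                "factor": rec.factor,
                "male_paf": m,
                "female_paf": f,
                "total_paf": total_paf,
                "male_deaths": md,
                "female_deaths": fd,
                "total_deaths": md + fd,
                "male_cases": mc,
                "female_cases": fc,
                "total_cases": mc + fc,
            }
        )
    combined = {"factor": "combined"}
    combined_counts = {}
    for sex, col in ((Sex.male, "male"), (Sex.female, "female")):
        paf = combine_pafs(policy.round_paf(r[f"{col}_paf"]) for r in rows)
        combined[f"{col}_paf"] = paf
        combined_counts[f"{col}_deaths"] = attributable_counts(
            paf, burden.deaths[sex], policy
        )
        combined_counts[f"{col}_cases"] = attributable_counts(
            paf, burden.incidence[sex], policy
        )
    combined.update(combined_counts)
    combined["total_paf"] = combine_pafs(factor_total_pafs)
    combined["total_deaths"] = (
        combined_counts["male_deaths"] + combined_counts["female_deaths"]
    )
    combined["total_cases"] = (
        combined_counts["male_cases"] + combined_counts["female_cases"]
    )
    rows.append(combined)
    return pd.DataFrame(rows)
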