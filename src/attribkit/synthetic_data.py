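"""Synthetic studies with known ground-truth PAFs.

The generator emulates the data-generating processes behind a comparative
risk assessment: cross-sectional exposure surveys (Bernoulli/multinomial
sampling at the true prevalences), a finite cohort in which each individual's
disease probability is the baseline risk multiplied by the relative risks of
their exposure levels, and Poisson-like burden counts. Because the truth is
known in closed form, every pipeline stage can be tested for parameter
recovery without any external data.

Randomness is organised as one independent stream per (seed, factor, stratum)
tuple, so adding or removing a factor never perturbs another factor's draws.
"""

from __future__ import annotations

import zlib
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .data_model import (
    BurdenCounts,
    ExposureLevel,
    Region,
    RiskFactorSpec,
    RoundingPolicy,
    Sex,
    Stratum,
    StudyConfig,
)
from .paf_core import factor_sex_paf, multi_level_paf, pool_regions

__all__ = [
    "SyntheticConfig",
    "true_paf",
    "generate_survey",
    "generate_population_counts",
    "population_target_paf",
    "end_to_end_recovery",
    "synthetic_from_study",
    "realize_study",
]


class SyntheticConfig(BaseModel):
    """Generator parameters: the truth plus sampling sizes.

    ``factors`` reuse the study schema (prevalences and RRs per stratum are
    the ground truth). ``baseline_risk`` is the disease probability of a
    fully reference-level individual over the study period.
    """

    factors: list[RiskFactorSpec]
    survey_n: int = Field(ge=1)
    baseline_risk: float = Field(gt=0.0, lt=1.0)
    population_n: int = Field(ge=1)
    seed: int
    urban_weight: float = Field(default=1 / 3, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if not self.factors:
            raise ValueError("need at least one factor")
        max_joint = 1.0
        for f in self.factors:
            max_joint *= max(lv.rr for levels in f.levels.values() for lv in levels)
        if self.baseline_risk * max_joint >= 1.0:
            raise ValueError(
                f"baseline risk {self.baseline_risk} times joint max RR "
                f"{max_joint:.3f} reaches 1; individual case probability invalid"
            )
        return self

    def factor(self, name: str) -> RiskFactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def sexes(self) -> list[Sex]:
        seen = []
        for f in self.factors:
            for s in f.levels:
                if s.sex not in seen:
                    seen.append(s.sex)
        return seen


def _stream(seed: int, *keys: str) -> np.random.Generator:
    """Independent reproducible stream for a (seed, *keys) tuple."""
    entropy = [seed] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def true_paf(
    config: SyntheticConfig, factor_name: str, sex: Optional[Sex] = None
) -> float:
    """Closed-form PAF from the generating prevalences and RRs — the recovery
    target. Region-split factors are pooled with the config's urban weight."""
    factor = config.factor(factor_name)
    if sex is None:
        sexes = {s.sex for s in factor.levels}
        if len(sexes) != 1:
            raise ValueError(f"factor {factor_name!r} has strata for {sexes}; pass sex=")
        sex = next(iter(sexes))
    return factor_sex_paf(factor, sex, config.urban_weight)


def population_target_paf(config: SyntheticConfig, sex: Sex) -> float:
    """The PAF the finite-population oracle converges to: 1 - 1/E[W], with W
    the joint relative risk of a random individual.

    For a single-region factor this equals :func:`multi_level_paf` exactly.
    When urban and rural strata are merged into one population, E[W] mixes the
    regions *before* the ratio is taken, so the limit differs at second order
    from the weighted arithmetic mean of region PAFs used for reporting
    (the difference is O((S_u - S_r)^2) in the excess fractions).
    """
    expected_w = 1.0
    for factor in config.factors:
        by_region = {s.region: lv for s, lv in factor.levels.items() if s.sex == sex}
        if Region.national in by_region:
            expected_w *= sum(
                lv.prevalence * lv.rr for lv in by_region[Region.national]
            )
        else:
            w = config.urban_weight
            eu = sum(lv.prevalence * lv.rr for lv in by_region[Region.urban])
            er = sum(lv.prevalence * lv.rr for lv in by_region[Region.rural])
            expected_w *= w * eu + (1.0 - w) * er
    return 1.0 - 1.0 / expected_w


def generate_survey(
    config: SyntheticConfig,
    factor_name: str,
    stratum: Stratum,
    seed: Optional[int] = None,
) -> list[tuple[str, float]]:
    """One cross-sectional exposure survey: multinomial (or Bernoulli, for a
    binary factor) draw of size ``survey_n`` at the true prevalences.

    Returns (level label, estimated prevalence) pairs; estimates sum to 1.
    """
    factor = config.factor(factor_name)
    levels = factor.levels[stratum]
    rng = _stream(config.seed if seed is None else seed, factor_name, str(stratum))
    counts = rng.multinomial(config.survey_n, [lv.prevalence for lv in levels])
    return [(lv.label, c / config.survey_n) for lv, c in zip(levels, counts)]


def _assign_relative_risks(
    config: SyntheticConfig, sex: Sex, base_seed: int
) -> np.ndarray:
    """Joint relative risk per simulated individual: product over factors of
    the RR of the level each individual lands in (independent exposures).

    Each factor draws from its own stream, so the assignment of one factor is
    unchanged when another is added or removed."""
    n = config.population_n
    w = np.ones(n)
    # one region assignment shared across dietary factors of an individual
    region_u = _stream(base_seed, "population-region", sex.value).random(n) < config.urban_weight
    for factor in config.factors:
        rng = _stream(base_seed, "population", factor.name, sex.value)
        by_region = {s.region: lv for s, lv in factor.levels.items() if s.sex == sex}
        if Region.national in by_region:
            groups = [(np.ones(n, dtype=bool), by_region[Region.national])]
        else:
            groups = [(region_u, by_region[Region.urban]), (~region_u, by_region[Region.rural])]
        for mask, levels in groups:
            m = int(mask.sum())
            if m == 0:
                continue
            p = np.array([lv.prevalence for lv in levels])
            rr = np.array([lv.rr for lv in levels])
            idx = np.searchsorted(np.cumsum(p) / p.sum(), rng.random(m), side="right")
            w[mask] *= rr[np.minimum(idx, len(rr) - 1)]
    return w


def generate_population_counts(
    config: SyntheticConfig, seed: Optional[int] = None
) -> dict:
    """Finite-population counterfactual oracle.

    For each sex: assign every individual an exposure level per factor at the
    true prevalences, give them case probability r0 times their joint RR,
    and compare the expected factual case count with the counterfactual one
    (everyone at reference, probability r0). The *empirical PAF* is
    1 - E[counterfactual] / E[factual] computed on expected counts (the
    expected-value comparison keeps Monte-Carlo variance to the exposure
    assignment only); its MC standard error comes from the spread of the
    individual joint RRs. Drawn case counts feed the synthetic burden.
    """
    base_seed = config.seed if seed is None else seed
    r0 = config.baseline_risk
    n = config.population_n
    per_sex: dict[Sex, dict] = {}
    for sex in config.sexes():
        rng = _stream(base_seed, "population-cases", sex.value)
        w = _assign_relative_risks(config, sex, base_seed)
        expected_factual = r0 * float(w.sum())
        expected_cf = r0 * n
        mean_w = float(w.mean())
        mc_se = float(np.sqrt(w.var() / n) / mean_w**2)
        per_sex[sex] = {
            "expected_factual": expected_factual,
            "expected_counterfactual": expected_cf,
            "factual_cases": int(rng.binomial(1, np.minimum(r0 * w, 1.0)).sum()),
            "counterfactual_cases": int(rng.binomial(n, r0)),
            "empirical_paf": 1.0 - expected_cf / expected_factual,
            "mc_se": mc_se,
        }
    burden = None
    if set(per_sex) == {Sex.male, Sex.female}:
        rng_b = _stream(base_seed, "burden")
        burden = BurdenCounts(
            deaths={s: int(rng_b.poisson(per_sex[s]["expected_factual"])) for s in per_sex},
            incidence={s: int(rng_b.poisson(per_sex[s]["expected_factual"])) for s in per_sex},
        )
    return {"per_sex": per_sex, "burden": burden}


def _survey_paf_and_se(
    config: SyntheticConfig, factor: RiskFactorSpec, sex: Sex, seed: int
) -> tuple[float, float]:
    """Estimated PAF from survey prevalences + true RRs, and the binomially
    propagated SE of that estimate (independent-binomial delta propagation,
    slightly conservative versus the exact multinomial covariance)."""

    def one_region(stratum: Stratum) -> tuple[float, float]:
        levels = factor.levels[stratum]
        est = dict(generate_survey(config, factor.name, stratum, seed))
        pairs = [(est[lv.label], lv.rr) for lv in levels]
        paf = multi_level_paf(pairs)
        s_true = sum(lv.prevalence * (lv.rr - 1.0) for lv in levels)
        var = sum(
            ((lv.rr - 1.0) / (s_true + 1.0) ** 2) ** 2
            * lv.prevalence
            * (1.0 - lv.prevalence)
            / config.survey_n
            for lv in levels
            if not lv.is_reference
        )
        return paf, var

    strata = {s.region: s for s in factor.levels if s.sex == sex}
    if Region.national in strata:
        paf, var = one_region(strata[Region.national])
        return paf, var**0.5
    w = config.urban_weight
    paf_u, var_u = one_region(strata[Region.urban])
    paf_r, var_r = one_region(strata[Region.rural])
    return pool_regions(paf_u, paf_r, w), (w**2 * var_u + (1 - w) ** 2 * var_r) ** 0.5


def end_to_end_recovery(
    config: SyntheticConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """Survey -> PAF pipeline against the closed-form truth, per factor and sex.

    A factor passes when |estimate - truth| < 3 * SE with SE the binomially
    propagated sampling error of the survey prevalences.
    """
    base_seed = config.seed if seed is None else seed
    rows = []
    for factor in config.factors:
        for sex in sorted({s.sex for s in factor.levels}, key=lambda s: s.value):
            truth = true_paf(config, factor.name, sex)
            est, se = _survey_paf_and_se(config, factor, sex, base_seed)
            rows.append(
                {
                    "factor": factor.name,
                    "sex": sex.value,
                    "true_paf": truth,
                    "estimated_paf": est,
                    "error": est - truth,
                    "se": se,
                    "tolerance": 3.0 * se,
                    "recovered": abs(est - truth) < 3.0 * se,
                }
            )
    return pd.DataFrame(rows)


def synthetic_from_study(
    study: StudyConfig,
    survey_n: int = 50_000,
    baseline_risk: float = 0.002,
    population_n: int = 1_000_000,
    seed: int = 0,
) -> SyntheticConfig:
    """A generator whose truth equals an existing study's prevalences/RRs."""
    return SyntheticConfig(
        factors=study.factors,
        survey_n=survey_n,
        baseline_risk=baseline_risk,
        population_n=population_n,
        seed=seed,
        urban_weight=study.urban_weight,
    )


def realize_study(config: SyntheticConfig, seed: Optional[int] = None) -> StudyConfig:
    """Materialise one synthetic study: survey-estimated prevalences, true RRs,
    and Poisson burden counts — consumable by :func:`attribkit.paf_core.run_study`."""
    base_seed = config.seed if seed is None else seed
    factors = []
    for factor in config.factors:
        levels: dict[Stratum, list[ExposureLevel]] = {}
        for stratum, lvls in factor.levels.items():
            est = dict(generate_survey(config, factor.name, stratum, base_seed))
            levels[stratum] = [
                lv.model_copy(update={"prevalence": est[lv.label]}) for lv in lvls
            ]
        factors.append(factor.model_copy(update={"levels": levels}))
    oracle = generate_population_counts(config, base_seed)
    if oracle["burden"] is None:
        raise ValueError("realize_study needs strata for both sexes")
    return StudyConfig(
        name=f"synthetic_seed{base_seed}",
        factors=factors,
        burden=oracle["burden"],
        urban_weight=config.urban_weight,
        rounding=RoundingPolicy(enabled=False),
    )
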