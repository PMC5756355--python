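# Methods

## The estimand

`attribkit` computes population attributable fractions (PAFs): the share of
a disease burden that would be avoided if the whole population moved to a
reference exposure level, holding everything else fixed. Three formulas do
all of the work.

**Binary exposure (Levin).** With exposure prevalence *P* and relative risk
*RR*,

    PAF = P(RR − 1) / (P(RR − 1) + 1).

**Leveled exposure, full shift.** With level prevalences *pᵢ* and level
relative risks *RRᵢ* (reference level *RR* = 1), the counterfactual of
shifting everyone to the reference level gives

    PAF = Σ pᵢ(RRᵢ − 1) / (Σ pᵢ(RRᵢ − 1) + 1),

which reduces to Levin's formula for one non-reference level. The identity
behind both is the expected-case comparison: with baseline risk *r₀*,
expected cases are Σ pᵢ·r₀·RRᵢ observed versus *r₀* counterfactual, and
PAF = (E_obs − E_ref)/E_obs independently of *r₀*. The test suite checks
this identity to 1e-12 and against a simulated finite cohort.

**Combination over factors.** Assuming independent exposures acting
multiplicatively on risk,

    PAF_joint = 1 − Π_k (1 − PAF_k).

This is exact under those assumptions (the joint excess multiplies) and is
an approximation otherwise; no interaction or correlation adjustment is
attempted.

## Dose-response quantile categorisation

Dietary factors come as a meta-analytic relative risk per 100 g/day of
intake. The quantile ladder is built by taking β = ln(RR₁₀₀)/100 (log-RR per
gram), evaluating exp(β·Lᵢ) at each quantile's **lower intake bound** Lᵢ
(the first bound is 0), and dividing through by the reference quantile's
value so the reference RR is exactly 1. The lower bound — not the quantile
midpoint — is used deliberately: back-fitting the published ladders by
least squares of ln RRᵢ on (Lᵢ − L_ref) through the origin recovers
internally consistent slopes (≈0.91 vegetable, ≈0.94 fruit, ≈1.14 meat per
100 g/day; see `analysis/01_reconstruct_dose_response.py`), which the
midpoint reading does not. CI bounds of the slope receive the same
transform as the point estimate. Nonlinear dose-response shapes are out of
scope.

## The packaged China-2012 study

`fixtures/china_crc_2012/` carries the printed inputs of the source
comparative risk assessment of colorectal cancer in China in 2012: seven
risk factors (tobacco smoking, alcohol drinking, overweight/obesity as a
two-level factor, physical inactivity, and three dietary quintile factors
split by sex and urban/rural region), survey prevalences, relative risks
with 95% CIs, quintile intake cutpoints, and Globocan burden counts
(79,000/60,000 deaths and 147,000/107,000 incident cases for men/women).
Conventions preserved from the source rather than "corrected":

- **Smoking** pairs ever-smoker prevalence (57.4% men, 2.6% women) with the
  current-vs-never RR 1.16; the mismatch is the source's own usage.
- **Quintile prevalences** are fixed at 0.2 by construction and stored
  explicitly.
- **Incidence totals**: the sex-specific counts (147,000 + 107,000) are
  used because the count arithmetic requires them, even though the source
  also prints 245,000 and 253,000 elsewhere.
- **Dietary RRs** enter at their 2-decimal printed precision
  (the unrounded slopes behind them are not printed).

## Pooling and rounding conventions

- **Urban/rural pooling**: per-sex dietary PAFs are the weighted arithmetic
  mean of the urban and rural PAFs. The weight is not stated in the source;
  urban = 1/3 is a calibration that reproduces the printed male fruit
  (6.2%) and meat (9.1%) rows and is stable over weights in [0.30, 0.40].
  It is configurable (`urban_weight`, `--urban-weight`).
- **Rounding before multiplication**: attributable counts multiply the
  burden by the PAF rounded to 3 decimals (1 decimal in percent), rounding
  half-up — the only policy that reproduces the printed counts
  (79,000 × 0.084 = 6,636; the unrounded 0.08411 would give 6,645).
  Disable with `RoundingPolicy(enabled=False)` / `--no-round-paf`.
- **Sex pooling**: factor totals divide summed attributable deaths by total
  deaths. **Combined totals** follow the source's two inconsistent
  conventions at once: the combined total PAF is multiplicative over the
  factor-level total PAFs, while combined total counts are sums over sexes;
  63,102/139,000 = 45.4% ≠ 45.5% is reproduced, not reconciled.
- Exposures must be coded so harmful levels carry RR ≥ 1: the math allows
  negative PAFs but `run_study` rejects them with a clear error.

## Known non-reproductions

Three published per-sex dietary PAF cells cannot be obtained from the
printed quintile RRs with 0.2 prevalences and any reasonable urban weight:
male vegetable (published 18.8%, computed 18.5%), female vegetable (16.8%
vs 16.9%) and female fruit (6.7% vs 8.1% — no urban weight below 0.9 gets
near 6.7%). The source presumably used unrounded transformed RRs and/or a
different pooling for those cells. Consequently an honest re-run of the
pipeline gives a combined burden of 45.8% (63,623 deaths) rather than the
published 45.5% (63,102). The headline numbers are exactly recovered by the
documented second route — applying the combination and pooling arithmetic
to the published per-sex PAF column itself
(`table_from_reported_pafs`, `analysis/03_combined_burden.py`). Tests
assert the mismatching cells at their computed values so any behavioural
drift is caught. Published CIs are not reproduction targets at all: the
exact delta variant used is unstated and several printed intervals are not
recoverable from any standard variant tried.

## Uncertainty propagation

- **Delta method** (binary factors): treating ln RR as normal with
  SD = (ln hi − ln lo)/(2z) recovered from the published CI,
  var(PAF) ≈ (∂PAF/∂RR)²(RR·σ_lnRR)² + (∂PAF/∂P)²σ_P², with
  ∂PAF/∂RR = P/(1+P(RR−1))² and ∂PAF/∂P = (RR−1)/(1+P(RR−1))². Prevalence
  uncertainty defaults to none (σ_P = 0); a binomial σ_P can be supplied
  when a survey size is known. Intervals are PAF ± z·sd truncated to [0, 1).
- **Monte-Carlo** (everything, and the only option for leveled, pooled and
  combined PAFs): draw ln RRᵢ ~ Normal(ln RRᵢ, σᵢ) independently per level
  (lognormal RR — the standard assumption for ratio measures; the source
  does not say), recompute the full pipeline per draw, report percentile
  intervals matching the z coverage. Deterministic for a fixed seed;
  ≥ 1000 draws enforced, 5000 by default (the fixture runs in well under a
  second). Region-pooled draws pool per draw; factor-total draws weight the
  per-sex draws by deaths; combined draws multiply complements per draw.
  Independence across levels and factors is assumed — RRs derived from a
  shared meta-analytic slope are actually correlated, so dietary CIs are
  somewhat narrow (a documented approximation).
- Delta and MC half-widths agree within ~10% relative on binary factors
  over the tested grid (p ∈ [0.01, 0.6], RR ∈ [1.05, 2]).

## Synthetic data generator

The generator (`synthetic_data`) emulates the processes the real inputs came
from, with the packaged study's prevalences and RRs as defaults when built
via `synthetic_from_study`:

- **Exposure surveys**: multinomial draws of `survey_n` respondents per
  stratum at the true prevalences (50,000 by default, the scale of the
  national surveys being emulated).
- **Cohort oracle**: `population_n` individuals (10⁶ default) are assigned
  exposure levels independently per factor; disease probability is
  r₀ × Π RR (baseline risk r₀ = 0.002 by default, roughly a decade of
  colorectal-cancer risk at mid-life; configurations with r₀·max joint RR
  ≥ 1 are rejected). The empirical PAF compares expected factual and
  counterfactual case counts (expected-value comparison keeps the MC
  variance down to the exposure assignment); burden counts are Poisson
  draws around the expected counts.
- **Streams**: one PRNG stream per (seed, factor, stratum) via
  `SeedSequence`, so adding a factor never perturbs another factor's draws;
  the seed is mandatory and draws are bit-reproducible.

One subtlety the oracle exposed: merging urban and rural strata into a
single simulated population makes the empirical PAF converge to
1 − 1/E[RR] with expectations mixed *before* the ratio, which differs at
second order (≈2×10⁻⁴ for the meat factor) from the weighted arithmetic
mean of region PAFs used for reporting. `population_target_paf` provides
the correct simulation limit; the reporting convention is unchanged.

What the generator does **not** emulate: correlated exposures, confounding,
measurement error in self-reported intake, induction-lag dynamics, and
region/cluster survey design effects. Recovery tests therefore demonstrate
the pipeline's internal consistency and sampling behaviour, not robustness
of the source study's assumptions to real-world violations.

## Numerical choices and problem sizes

- Half-up rounding (ties away from zero) everywhere counts or displayed
  percentages are produced, implemented explicitly since Python's built-in
  rounds to even.
- PAF CIs truncate to [0, 1); prevalence sum-to-one checks use 1e-6
  (tables printed at limited precision) while formula-level checks use 1e-9.
- Test problem sizes: 10⁶-person cohorts and 10⁵-draw MC oracles keep the
  full suite around a few seconds; the recovery experiment uses
  survey_n = 50,000 matching the generator default.

## Limitations

- The combination formula assumes independent, multiplicatively acting
  exposures; the source explicitly did not adjust for interactions and
  neither does the toolkit.
- CIs ignore cross-level and cross-factor correlation.
- Prevalence uncertainty is off by default because the published intervals
  appear RR-driven; supplying survey sizes turns it on but the source's
  exact CI method remains unknown.
- The urban weight is a calibrated, not a measured, quantity.
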