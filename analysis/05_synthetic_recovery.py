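#!/usr/bin/env python
"""Ground-truth recovery experiment on synthetic studies.

Uses the packaged study's prevalences and RRs as generating truth, simulates
exposure surveys of 50,000 respondents per stratum, re-runs the PAF pipeline
on the survey estimates, and checks each factor's PAF is recovered within
3 propagated binomial standard errors. Also runs the million-person
counterfactual cohort oracle for the binary factors, confirming the Levin
formula matches the simulated counterfactual to Monte-Carlo precision.

Writes results/synthetic_recovery.csv.
"""

from pathlib import Path

import pandas as pd

from attribkit import load_china_crc_2012
from attribkit.data_model import Sex
from attribkit.paf_core import levin_paf
from attribkit.synthetic_data import (
    end_to_end_recovery,
    generate_population_counts,
    synthetic_from_study,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = load_china_crc_2012()
    cfg = synthetic_from_study(study, survey_n=50_000, seed=20120)
    report = end_to_end_recovery(cfg)
    OUT.mkdir(exist_ok=True)
    report.to_csv(OUT / "synthetic_recovery.csv", index=False)
    print(report.to_string(index=False, float_format=lambda x: f"{x:.5f}"))
    print(
        f"\n{int(report['recovered'].sum())}/{len(report)} factor-sex PAFs recovered "
        "within 3 propagated binomial SEs at survey_n = 50,000."
    )

    smoking_only = study.model_copy(update={"factors": [study.factor("tobacco_smoking")]})
    oracle_cfg = synthetic_from_study(
        smoking_only, population_n=1_000_000, baseline_risk=0.01, seed=11
    )
    res = generate_population_counts(oracle_cfg)["per_sex"][Sex.male]
    truth = levin_paf(0.574, 1.16)
    print(
        f"Counterfactual-cohort oracle (smoking, men, n=1e6): empirical PAF "
        f"{res['empirical_paf']:.5f} vs Levin {truth:.5f} "
        f"(|diff| = {abs(res['empirical_paf'] - truth):.2e}, MC SE = {res['mc_se']:.2e})."
    )


if __name__ == "__main__":
    main()
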