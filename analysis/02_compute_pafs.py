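#!/usr/bin/env python
"""Recompute the full attributable-burden table from the printed study inputs.

Runs the PAF pipeline (formulas, urban/rural pooling at weight 1/3,
rounding-before-multiplication counts, Monte-Carlo CIs) over the packaged
China-2012 inputs and compares every per-sex PAF cell against the published
column. Eleven of fourteen cells match at one-decimal display precision; the
three mismatches (male and female vegetable, female fruit) are cells the
printed quintile RRs cannot reproduce and are flagged, not patched.

Writes results/table3_replica.csv and results/table3_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from attribkit import UncertaintySpec, load_china_crc_2012, run_study, write_results_table
from attribkit.data_model import fixture_path, read_reported_pafs

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = load_china_crc_2012()
    estimates = run_study(study, UncertaintySpec(draws=20_000, seed=2012))
    OUT.mkdir(exist_ok=True)
    write_results_table(estimates, OUT / "table3_replica.csv")

    reported = read_reported_pafs(fixture_path() / "reported_pafs.csv")
    rows = []
    for rec in reported.itertuples():
        for sex, published in (("male", rec.male_paf_pct), ("female", rec.female_paf_pct)):
            est = next(e for e in estimates if e.factor == rec.factor and e.stratum == sex)
            rows.append(
                {
                    "factor": rec.factor,
                    "sex": sex,
                    "computed_paf_pct": est.paf_pct,
                    "published_paf_pct": published,
                    "match_at_1dp": est.paf_pct == published,
                }
            )
    cmp_df = pd.DataFrame(rows)
    cmp_df.to_csv(OUT / "table3_comparison.csv", index=False)
    print(cmp_df.to_string(index=False))
    n_match = int(cmp_df["match_at_1dp"].sum())
    print(
        f"\n{n_match}/{len(cmp_df)} per-sex PAF cells match the published table at 1 dp. "
        "Mismatches are confined to dietary cells whose printed quintile RRs do not "
        "reproduce the published PAF under 20% quintile prevalences and urban weight 1/3."
    )
    combined = next(e for e in estimates if e.factor == "combined" and e.stratum == "total")
    print(
        f"Honestly recomputed combined burden: {combined.paf_pct:.1f}% "
        f"({combined.attributable_deaths:,} deaths, {combined.attributable_cases:,} cases) "
        "versus published 45.5% (63,102 / 115,578) — see 03_combined_burden.py for the "
        "published-input route."
    )


if __name__ == "__main__":
    main()
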