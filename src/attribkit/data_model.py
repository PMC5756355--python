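"""Domain types, study-configuration schema, readers/writers and validation.

A *study* is the full input set of a comparative risk assessment: for each
risk factor, exposure prevalences and relative risks per stratum (sex, and
urban/rural region for the dietary factors), plus the disease burden (deaths
and incident cases) per sex. Everything internal is kept as fractions on
[0, 1]; percentages exist only at the display boundary.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "Sex",
    "Region",
    "Stratum",
    "ExposureLevel",
    "QuantileScheme",
    "DoseResponseRR",
    "RiskFactorSpec",
    "BurdenCounts",
    "RoundingPolicy",
    "PAFEstimate",
    "StudyConfig",
    "ConfigValidationError",
    "read_study_config",
    "write_study_config",
    "write_results_table",
    "read_results_table",
    "read_reported_pafs",
    "load_china_crc_2012",
    "fixture_path",
]

_PREV_TOL = 1e-9


class ConfigValidationError(ValueError):
    """A study configuration violated a schema rule; message names record and rule."""


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Region(str, enum.Enum):
    urban = "urban"
    rural = "rural"
    national = "national"  # no urban/rural split


class Stratum(BaseModel):
    """Key of every prevalence/RR record: (sex, region)."""

    model_config = ConfigDict(frozen=True)

    sex: Sex
    region: Region = Region.national

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.sex.value}/{self.region.value}"


class ExposureLevel(BaseModel):
    """One exposure category with its prevalence and relative risk."""

    label: str
    prevalence: float = Field(ge=0.0, le=1.0)
    rr: float = Field(gt=0.0)
    rr_ci: tuple[float, float] = (1.0, 1.0)
    is_reference: bool = False
    lower_bound: Optional[float] = None  # g/day, quantile factors only

    @model_validator(mode="after")
    def _check(self) -> "ExposureLevel":
        lo, hi = self.rr_ci
        if lo <= 0:
            raise ValueError(f"level {self.label!r}: CI lower bound must be > 0, got {lo}")
        if not (lo <= self.rr <= hi):
            raise ValueError(
                f"level {self.label!r}: CI ({lo}, {hi}) does not bracket rr {self.rr}"
            )
        if self.is_reference and self.rr != 1.0:
            raise ValueError(f"reference level {self.label!r} must have rr = 1, got {self.rr}")
        return self


class QuantileScheme(BaseModel):
    """Ordered intake-quantile lower bounds (g/day) with the reference quantile.

    For protective exposures (fruit, vegetable) the reference is the top
    quantile; for harmful ones (red/processed meat) the bottom.
    """

    lower_bounds: list[float]
    reference_index: int
    direction: str = Field(pattern="^(protective|harmful)$")

    @model_validator(mode="after")
    def _check(self) -> "QuantileScheme":
        b = self.lower_bounds
        if len(b) < 2:
            raise ValueError("quantile scheme needs at least two bounds")
        if b[0] != 0.0:
            raise ValueError(f"first quantile lower bound must be 0, got {b[0]}")
        if any(x < 0 for x in b):
            raise ValueError("quantile bounds must be non-negative")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"quantile bounds must be strictly increasing, got {b}")
        expected = len(b) - 1 if self.direction == "protective" else 0
        if self.reference_index != expected:
            raise ValueError(
                f"{self.direction} factor must reference quantile index {expected}, "
                f"got {self.reference_index}"
            )
        return self


class DoseResponseRR(BaseModel):
    """Log-linear relative risk per 100 g/day of intake."""

    rr_per_100g: float = Field(gt=0.0)
    ci_per_100g: tuple[float, float] = (1.0, 1.0)


class RiskFactorSpec(BaseModel):
    """One exposure: binary, multi-level, or quantile-categorised dose-response."""

    name: str
    kind: str = Field(pattern="^(binary|multi_level|quantile_dose_response)$")
    direction: str = Field(default="harmful", pattern="^(protective|harmful)$")
    levels: dict[Stratum, list[ExposureLevel]] = {}
    dose_response: Optional[DoseResponseRR] = None

    @model_validator(mode="after")
    def _check(self) -> "RiskFactorSpec":
        if not self.levels:
            raise ValueError(f"factor {self.name!r}: no strata")
        for stratum, levels in self.levels.items():
            where = f"factor {self.name!r}, stratum {stratum}"
            refs = [lv for lv in levels if lv.is_reference]
            if len(refs) != 1:
                raise ValueError(f"{where}: expected exactly one reference level, got {len(refs)}")
            total = sum(lv.prevalence for lv in levels)
            if total > 1.0 + _PREV_TOL:
                raise ValueError(f"{where}: prevalences sum to {total} > 1")
            if self.kind in ("multi_level", "quantile_dose_response") and not math.isclose(
                total, 1.0, abs_tol=1e-6
            ):
                raise ValueError(f"{where}: leveled prevalences must sum to 1, got {total}")
            if self.kind == "binary" and len([lv for lv in levels if not lv.is_reference]) != 1:
                raise ValueError(f"{where}: binary factor needs exactly one non-reference level")
            if self.kind == "quantile_dose_response":
                if any(lv.lower_bound is None for lv in levels):
                    raise ValueError(f"{where}: quantile factor levels need intake lower bounds")
                self.quantile_scheme(stratum)  # validates bounds / reference placement
        return self

    def strata(self) -> list[Stratum]:
        return list(self.levels.keys())

    def quantile_scheme(self, stratum: Stratum) -> QuantileScheme:
        levels = self.levels[stratum]
        bounds = [float(lv.lower_bound) for lv in levels]
        ref = next(i for i, lv in enumerate(levels) if lv.is_reference)
        return QuantileScheme(lower_bounds=bounds, reference_index=ref, direction=self.direction)

    def has_region_split(self) -> bool:
        return any(s.region is not Region.national for s in self.levels)


class BurdenCounts(BaseModel):
    """Deaths and incident cases per sex; totals are sums over sexes."""

    deaths: dict[Sex, int]
    incidence: dict[Sex, int]

    @model_validator(mode="after")
    def _check(self) -> "BurdenCounts":
        for name, d in (("deaths", self.deaths), ("incidence", self.incidence)):
            if set(d) != {Sex.male, Sex.female}:
                raise ValueError(f"burden {name}: need counts for both sexes")
            if any(v < 0 for v in d.values()):
                raise ValueError(f"burden {name}: counts must be non-negative")
        return self

    @property
    def total_deaths(self) -> int:
        return sum(self.deaths.values())

    @property
    def total_incidence(self) -> int:
        return sum(self.incidence.values())


class RoundingPolicy(BaseModel):
    """Display-compatible rounding: PAFs to `paf_decimals` before count math.

    With the default (3 decimals on the fraction, i.e. one decimal in percent)
    attributable counts reproduce published tables that multiply the displayed
    PAF by the burden. Disable for full-precision propagation.
    """

    enabled: bool = True
    paf_decimals: int = 3

    def round_paf(self, paf: float) -> float:
        if not self.enabled:
            return paf
        return round_half_up(paf, self.paf_decimals)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), unlike banker's rounding."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


class PAFEstimate(BaseModel):
    """A PAF with its CI and the burden it converts to.

    ``paf`` is the full-precision fraction; ``attributable_deaths``/``cases``
    were derived under the study's rounding policy.
    """

    factor: str
    stratum: str  # "male", "female" or "total"
    paf: float = Field(lt=1.0)
    ci: tuple[float, float] = (0.0, 0.0)
    attributable_deaths: int = Field(ge=0)
    attributable_cases: int = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "PAFEstimate":
        lo, hi = self.ci
        if not (lo - 1e-12 <= self.paf <= hi + 1e-12):
            raise ValueError(
                f"{self.factor}/{self.stratum}: CI ({lo}, {hi}) does not contain PAF {self.paf}"
            )
        return self

    @property
    def paf_pct(self) -> float:
        return round_half_up(100 * self.paf, 1)


class StudyConfig(BaseModel):
    """Everything needed to run a comparative risk assessment."""

    name: str = "study"
    factors: list[RiskFactorSpec]
    burden: BurdenCounts
    urban_weight: float = Field(default=1 / 3, ge=0.0, le=1.0)
    z: float = Field(default=1.96, gt=0.0)
    rounding: RoundingPolicy = RoundingPolicy()

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        if not self.factors:
            raise ValueError("study has no risk factors")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factor names: {names}")
        return self

    def factor(self, name: str) -> RiskFactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_EXPOSURE_COLUMNS = [
    "factor",
    "sex",
    "region",
    "level",
    "prevalence",
    "rr",
    "rr_lo",
    "rr_hi",
    "is_reference",
    "lower_bound",
]


def read_study_config(path: str | Path) -> StudyConfig:
    """Read and fully validate a study from its JSON skeleton.

    The skeleton names the factor list (name/kind/direction) and points at the
    exposure and burden CSV tables, which live next to it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    skeleton = json.loads(path.read_text())
    base = path.parent
    try:
        exposures = pd.read_csv(base / skeleton["exposure_table"])
        burden_df = pd.read_csv(base / skeleton["burden_table"])
    except KeyError as exc:
        raise ConfigValidationError(f"study skeleton missing field {exc}") from exc

    try:
        burden = BurdenCounts(
            deaths={Sex(r.sex): int(r.deaths) for r in burden_df.itertuples()},
            incidence={Sex(r.sex): int(r.incidence) for r in burden_df.itertuples()},
        )
    except (ValidationError, ValueError) as exc:
        raise ConfigValidationError(f"burden table invalid: {exc}") from exc

    factors = []
    for meta in skeleton.get("factors", []):
        name = meta.get("name", "<unnamed>")
        rows = exposures[exposures["factor"] == name]
        if rows.empty:
            raise ConfigValidationError(f"factor {name!r}: no rows in exposure table")
        levels: dict[Stratum, list[ExposureLevel]] = {}
        for row in rows.itertuples():
            try:
                stratum = Stratum(sex=Sex(row.sex), region=Region(row.region))
                level = ExposureLevel(
                    label=str(row.level),
                    prevalence=float(row.prevalence),
                    rr=float(row.rr),
                    rr_ci=(float(row.rr_lo), float(row.rr_hi)),
                    is_reference=bool(row.is_reference),
                    lower_bound=None if pd.isna(row.lower_bound) else float(row.lower_bound),
                )
            except (ValidationError, ValueError) as exc:
                raise ConfigValidationError(
                    f"factor {name!r}, level {row.level!r} ({row.sex}/{row.region}): {exc}"
                ) from exc
            levels.setdefault(stratum, []).append(level)
        try:
            factors.append(
                RiskFactorSpec(
                    name=name,
                    kind=meta.get("kind", "binary"),
                    direction=meta.get("direction", "harmful"),
                    levels=levels,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ConfigValidationError(f"factor {name!r}: {exc}") from exc

    try:
        return StudyConfig(
            name=skeleton.get("name", path.stem),
            factors=factors,
            burden=burden,
            urban_weight=skeleton.get("urban_weight", 1 / 3),
            z=skeleton.get("z", 1.96),
            rounding=RoundingPolicy(**skeleton.get("rounding", {})),
        )
    except (ValidationError, ValueError) as exc:
        raise ConfigValidationError(str(exc)) from exc


def write_study_config(config: StudyConfig, directory: str | Path) -> Path:
    """Write a study as skeleton JSON + CSV tables; inverse of read_study_config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in config.factors:
        for stratum, levels in f.levels.items():
            for lv in levels:
                rows.append(
                    {
                        "factor": f.name,
                        "sex": stratum.sex.value,
                        "region": stratum.region.value,
                        "level": lv.label,
                        "prevalence": lv.prevalence,
                        "rr": lv.rr,
                        "rr_lo": lv.rr_ci[0],
                        "rr_hi": lv.rr_ci[1],
                        "is_reference": lv.is_reference,
                        "lower_bound": lv.lower_bound,
                    }
                )
    pd.DataFrame(rows, columns=_EXPOSURE_COLUMNS).to_csv(directory / "exposures.csv", index=False)
    pd.DataFrame(
        [
            {
                "sex": sex.value,
                "deaths": config.burden.deaths[sex],
                "incidence": config.burden.incidence[sex],
            }
            for sex in (Sex.male, Sex.female)
        ]
    ).to_csv(directory / "burden.csv", index=False)
    skeleton = {
        "name": config.name,
        "exposure_table": "exposures.csv",
        "burden_table": "burden.csv",
        "urban_weight": config.urban_weight,
        "z": config.z,
        "rounding": config.rounding.model_dump(),
        "factors": [
            {"name": f.name, "kind": f.kind, "direction": f.direction} for f in config.factors
        ],
    }
    out = directory / "study.json"
    out.write_text(json.dumps(skeleton, indent=2) + "\n")
    return out


_RESULT_COLUMNS = [
    "factor",
    "stratum",
    "paf_pct",
    "ci_low_pct",
    "ci_high_pct",
    "attributable_deaths",
    "attributable_cases",
]


def write_results_table(estimates: Iterable[PAFEstimate], path: str | Path) -> None:
    """Write estimates as a CSV mirroring the published table layout (percent, 1 dp)."""
    rows = []
    seen = set()
    for est in estimates:
        key = (est.factor, est.stratum)
        if key in seen:
            raise ValueError(f"duplicate results row for {key}")
        seen.add(key)
        rows.append(
            {
                "factor": est.factor,
                "stratum": est.stratum,
                "paf_pct": f"{round_half_up(100 * est.paf, 1):.1f}",
                "ci_low_pct": f"{round_half_up(100 * est.ci[0], 1):.1f}",
                "ci_high_pct": f"{round_half_up(100 * est.ci[1], 1):.1f}",
                "attributable_deaths": est.attributable_deaths,
                "attributable_cases": est.attributable_cases,
            }
        )
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_reported_pafs(path: str | Path) -> pd.DataFrame:
    """Published per-factor per-sex PAF column (percent), as a DataFrame."""
    df = pd.read_csv(path)
    expected = {"factor", "male_paf_pct", "female_paf_pct"}
    if not expected.issubset(df.columns):
        raise ConfigValidationError(f"reported-PAF table needs columns {sorted(expected)}")
    return df


def fixture_path(name: str = "china_crc_2012") -> Path:
    """Directory of a packaged study fixture."""
    return Path(__file__).parent / "fixtures" / name


def load_china_crc_2012() -> StudyConfig:
    """The packaged China-2012 colorectal cancer study (printed survey prevalences,
    meta-analytic RRs and Globocan burden counts)."""
    return read_study_config(fixture_path() / "study.json")
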