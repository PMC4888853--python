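"""Auxological computations for delayed-puberty phenotyping.

Heights arrive already expressed as standard-deviation scores (HSDS)
against a national growth reference.  The module computes the
sex-specific mid-parental target height (TH) in SDS units, the distance
from target height at ages 4 and 8 (girls) / 9 (boys) years and at
adult height, and the change in height SDS between ages 4 and 8/9
(ΔHSDS).  Screening limits for these quantities come from published
population normal values (delta HSDS < 1.21; distance to TH < 1.76 at
4 y, < 1.72 at 8/9 y, < 1.44 at adult height).  Diagnostic thresholds
for delayed puberty: pubertal onset (testicular volume > 3 ml / Tanner
B2) after 13.5 y in boys or 13.0 y in girls for probands; for relatives
any one of growth-spurt takeoff after 12.9/11.3 y (M/F), peak height
velocity after 14.8/12.8 y, or adult height attained after 18/16 y.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from math import isfinite

import pandas as pd

from .types import DataValidationError, SEXES


@dataclass(frozen=True)
class GrowthRecord:
    """Growth time points and pubertal milestones for one individual."""

    individual_id: str
    sex: str
    hsds_4: float | None = None
    hsds_8or9: float | None = None
    adult_hsds: float | None = None
    midparental_hsds: float | None = None
    th_sds: float | None = None
    age_b2_or_g2: float | None = None
    age_takeoff: float | None = None
    age_phv: float | None = None
    age_adult_height: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataValidationError(f"unknown sex {self.sex!r}")
        for age in (self.age_b2_or_g2, self.age_takeoff, self.age_phv,
                    self.age_adult_height):
            if age is not None and age <= 0:
                raise DataValidationError("milestone ages must be > 0")

    def target_height(self) -> float | None:
        """TH SDS: the direct value if present, else from mid-parental HSDS."""
        if self.th_sds is not None:
            return self.th_sds
        if self.midparental_hsds is not None:
            return target_height_sds(self.midparental_hsds, self.sex)
        return None


@dataclass(frozen=True)
class NormalLimits:
    """Population screening limits; a value at or beyond a limit is abnormal."""

    delta_hsds_limit: float = 1.21
    dist_th_4y_limit: float = 1.76
    dist_th_8or9_limit: float = 1.72
    dist_th_adult_limit: float = 1.44


@dataclass(frozen=True)
class DPCriteria:
    """Diagnostic age thresholds (strict >) for delayed puberty."""

    proband_onset_male: float = 13.5     # G2 (testicular volume > 3 ml)
    proband_onset_female: float = 13.0   # B2
    takeoff_male: float = 12.9
    takeoff_female: float = 11.3
    phv_male: float = 14.8
    phv_female: float = 12.8
    adult_height_male: float = 18.0
    adult_height_female: float = 16.0


def target_height_sds(midparental_hsds: float, sex: str) -> float:
    """Sex-adjusted target height SDS from mean parental height SDS.

    Girls: 0.791·x − 0.147; boys: 0.886·x − 0.071.
    """
    if not isfinite(midparental_hsds):
        raise DataValidationError("midparental HSDS must be finite")
    if sex == "female":
        return 0.791 * midparental_hsds - 0.147
    if sex == "male":
        return 0.886 * midparental_hsds - 0.071
    raise DataValidationError(f"unknown sex {sex!r}")


def distance_to_target(th_sds: float, hsds_at_age: float) -> float:
    """TH − HSDS: positive when the child is short for the family target."""
    return th_sds - hsds_at_age


def delta_hsds(hsds_4: float, hsds_8or9: float) -> float:
    """Change in height SDS between ages 4 and 8/9 years."""
    return hsds_8or9 - hsds_4


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, as in the printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def classify_growth(record: GrowthRecord,
                    limits: NormalLimits = NormalLimits(),
                    ) -> dict[str, str]:
    """Flag each growth metric as within/outside normal limits.

    Distance metrics are abnormal when the signed value reaches the
    limit (only short-for-target is flagged); ΔHSDS is abnormal when its
    magnitude reaches the limit.  Metrics whose inputs are missing are
    flagged ``not evaluable``.
    """
    th = record.target_height()
    out: dict[str, str] = {}

    def flag(value: float | None, limit: float, absolute: bool) -> str:
        if value is None:
            return "not evaluable"
        v = abs(value) if absolute else value
        return "outside" if v >= limit else "within"

    d = (delta_hsds(record.hsds_4, record.hsds_8or9)
         if record.hsds_4 is not None and record.hsds_8or9 is not None
         else None)
    out["delta_hsds"] = flag(d, limits.delta_hsds_limit, absolute=True)

    for name, hsds, limit in (
            ("dist_th_4y", record.hsds_4, limits.dist_th_4y_limit),
            ("dist_th_8or9", record.hsds_8or9, limits.dist_th_8or9_limit),
            ("dist_th_adult", record.adult_hsds, limits.dist_th_adult_limit)):
        value = (distance_to_target(th, hsds)
                 if th is not None and hsds is not None else None)
        out[name] = flag(value, limit, absolute=False)
    return out


def diagnose_dp_proband(record: GrowthRecord,
                        criteria: DPCriteria = DPCriteria()) -> bool:
    """Proband criterion: pubertal onset strictly later than 13.5/13.0 y."""
    if record.age_b2_or_g2 is None:
        return False
    cut = (criteria.proband_onset_male if record.sex == "male"
           else criteria.proband_onset_female)
    return record.age_b2_or_g2 > cut


def diagnose_dp_relative(record: GrowthRecord,
                         criteria: DPCriteria = DPCriteria()) -> bool:
    """Relative criteria: any one of late takeoff, late PHV, or late
    attainment of adult height suffices."""
    male = record.sex == "male"
    checks = (
        (record.age_takeoff,
         criteria.takeoff_male if male else criteria.takeoff_female),
        (record.age_phv, criteria.phv_male if male else criteria.phv_female),
        (record.age_adult_height,
         criteria.adult_height_male if male else criteria.adult_height_female),
    )
    return any(age is not None and age > cut for age, cut in checks)


def load_proband_growth_table() -> pd.DataFrame:
    """Published growth data of the 10 discovery probands.

    Columns: case, sex, variant (protein change), hsds_4, hsds_8or9,
    th_sds, delta_hsds, dist_th_4y, dist_th_8or9, adult_hsds.  The
    delta/distance columns are the printed values; they are re-derivable
    from the HSDS and TH columns of the same row.
    """
    with resources.files("pedburden.data").joinpath(
            "proband_growth.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def analyze_growth_records(records: list[GrowthRecord],
                           limits: NormalLimits = NormalLimits(),
                           criteria: DPCriteria = DPCriteria(),
                           ) -> pd.DataFrame:
    """Tabulate TH, distances, ΔHSDS, normal-limit flags, and DP calls."""
    rows = []
    for r in records:
        th = r.target_height()
        flags = classify_growth(r, limits)
        rows.append({
            "individual_id": r.individual_id,
            "sex": r.sex,
            "th_sds": None if th is None else round_half_up(th),
            "delta_hsds": (None if r.hsds_4 is None or r.hsds_8or9 is None
                           else round_half_up(delta_hsds(r.hsds_4, r.hsds_8or9))),
            "dist_th_4y": (None if th is None or r.hsds_4 is None
                           else round_half_up(distance_to_target(th, r.hsds_4))),
            "dist_th_8or9": (None if th is None or r.hsds_8or9 is None
                             else round_half_up(distance_to_target(th, r.hsds_8or9))),
            "dist_th_adult": (None if th is None or r.adult_hsds is None
                              else round_half_up(distance_to_target(th, r.adult_hsds))),
            **{f"flag_{k}": v for k, v in flags.items()},
            "dp_proband_criterion": diagnose_dp_proband(r, criteria),
            "dp_relative_criterion": diagnose_dp_relative(r, criteria),
        })
    return pd.DataFrame(rows)
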