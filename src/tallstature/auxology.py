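"""Patient records, target-height calculators and the derived-quantity profile.

Target height (TH) is the expected adult height of a child given its parents'
heights.  Two forms are implemented, both without secular-trend correction:

* Tanner midparental form: (FH + MH) / 2 + 6.5 cm for boys, - 6.5 cm for girls.
* Conditional target height (cTH), a regression form correcting for the
  parent-parent and parent-offspring height correlations:
  44.5 + 0.376*FH + 0.411*MH (boys); 47.1 + 0.334*FH + 0.364*MH (girls).

:func:`build_profile` assembles every derived quantity the downstream
classifier needs: HSDS, TH/cTH on both cm and SDS scales, the three distances
(HSDS minus THSDS, minus cTHSDS, minus tallest-parent HSDS), bone-age
advancement (BA - CA), optional BMI / head-circumference / sitting-height-ratio
SDS, and the HSDS change over the available measurement history.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .errors import ValidationError
from .references import GrowthReference, MeasurementKind, Sex

__all__ = [
    "ClinicalFlags",
    "PatientRecord",
    "AuxologyProfile",
    "tanner_target_height",
    "conditional_target_height",
    "bone_age_advance",
    "build_profile",
]

# Coefficients of the conditional target height regression, per sex:
# intercept, weight on father's height, weight on mother's height (cm).
_CTH_COEF = {
    Sex.MALE: (44.5, 0.376, 0.411),
    Sex.FEMALE: (47.1, 0.334, 0.364),
}

_TANNER_OFFSET_CM = 6.5


class ClinicalFlags(BaseModel):
    """History/examination booleans feeding the red-flag screen."""

    developmental_or_speech_delay: bool = False
    behavioral_problems: bool = False
    dysmorphic_features: bool = False
    parent_delayed_puberty: bool = False
    parent_taller_than_2sds: bool = False
    signs_gh_excess: bool = False
    signs_hyperthyroidism: bool = False


class PatientRecord(BaseModel):
    """One child referred for tall stature.

    Heights are cm, weights kg, ages decimal years; bone age is a
    Greulich-Pyle rating in years.  Tanner stage 1-5: breast (girls) or
    genital (boys) plus pubic hair.  ``prior_measurements`` holds earlier
    (age, height_cm) pairs used for the growth-acceleration criterion.
    """

    id: str
    sex: Sex
    ca: float = Field(gt=0, lt=18, description="chronological age, decimal years")
    height_cm: float = Field(gt=40, lt=230)
    weight_kg: Optional[float] = Field(default=None, gt=0, lt=250)
    sitting_height_cm: Optional[float] = Field(default=None, gt=20, lt=150)
    head_circumference_cm: Optional[float] = Field(default=None, gt=25, lt=70)
    bone_age_years: Optional[float] = Field(default=None, gt=0, lt=20)
    father_height_cm: Optional[float] = Field(default=None, gt=120, lt=230)
    mother_height_cm: Optional[float] = Field(default=None, gt=120, lt=230)
    tanner_breast_or_genital: Optional[int] = Field(default=None, ge=1, le=5)
    tanner_pubic: Optional[int] = Field(default=None, ge=1, le=5)
    reported_puberty_onset_age: Optional[float] = Field(default=None, gt=0, lt=18)
    prior_measurements: list[tuple[float, float]] = Field(default_factory=list)
    flags: ClinicalFlags = Field(default_factory=ClinicalFlags)

    @model_validator(mode="after")
    def _check_priors(self) -> "PatientRecord":
        for age, h in self.prior_measurements:
            if not (0 < age < 18 and 40 < h < 230):
                raise ValueError(f"prior measurement ({age}, {h}) out of range")
        return self

    @property
    def has_parental_heights(self) -> bool:
        return self.father_height_cm is not None and self.mother_height_cm is not None


@dataclass
class AuxologyProfile:
    """All SDS-scale derived quantities for one record.

    ``dist_*`` fields are exactly the stated differences (hsds minus the
    respective target SDS); optional fields are ``None`` when the inputs
    were not recorded.  ``complete`` is False when parental heights were
    missing and the TH-dependent fields could not be derived.
    """

    record_id: str
    hsds: float
    th_tanner_cm: Optional[float] = None
    th_tanner_sds: Optional[float] = None
    cth_cm: Optional[float] = None
    cth_sds: Optional[float] = None
    dist_th: Optional[float] = None
    dist_cth: Optional[float] = None
    tallest_parent_hsds: Optional[float] = None
    dist_tallest_parent: Optional[float] = None
    ba_advance_years: Optional[float] = None
    bmi_sds: Optional[float] = None
    hc_sds: Optional[float] = None
    shh_sds: Optional[float] = None
    delta_hsds: Optional[float] = None
    complete: bool = True


def tanner_target_height(fh: float, mh: float, sex: Sex) -> float:
    """Tanner midparental target height: (FH + MH)/2 + 6.5 cm boys, - 6.5 girls."""
    _validate_parent(fh, "father")
    _validate_parent(mh, "mother")
    mid = (fh + mh) / 2.0
    return mid + _TANNER_OFFSET_CM if Sex(sex) is Sex.MALE else mid - _TANNER_OFFSET_CM


def conditional_target_height(fh: float, mh: float, sex: Sex) -> float:
    """Conditional target height regression (no secular-trend term)."""
    _validate_parent(fh, "father")
    _validate_parent(mh, "mother")
    a, bf, bm = _CTH_COEF[Sex(sex)]
    return a + bf * fh + bm * mh


def bone_age_advance(ba: float, ca: float) -> float:
    """Bone-age advancement: BA minus chronological age (signed, years)."""
    if ba <= 0 or ca <= 0:
        raise ValidationError("bone age and chronological age must be positive")
    return ba - ca


def _validate_parent(h: float, which: str) -> None:
    if not (120 < h < 230):
        raise ValidationError(f"{which} height {h!r} cm outside (120, 230)")


def build_profile(record: PatientRecord, ref: GrowthReference) -> AuxologyProfile:
    """Derive the full auxology profile for ``record`` against ``ref``.

    The tallest parent is the parent with the larger adult-height SDS (sex-
    specific), not the larger raw height, because the downstream comparison
    is against the child's SDS.  ``delta_hsds`` is the child's current HSDS
    minus the HSDS at the earliest prior measurement.
    """
    hsds = ref.sds(record.height_cm, record.ca, record.sex, MeasurementKind.HEIGHT)
    profile = AuxologyProfile(record_id=record.id, hsds=hsds)

    if record.has_parental_heights:
        fh, mh = record.father_height_cm, record.mother_height_cm
        profile.th_tanner_cm = tanner_target_height(fh, mh, record.sex)
        profile.th_tanner_sds = ref.adult_sds(profile.th_tanner_cm, record.sex)
        profile.cth_cm = conditional_target_height(fh, mh, record.sex)
        profile.cth_sds = ref.adult_sds(profile.cth_cm, record.sex)
        profile.dist_th = hsds - profile.th_tanner_sds
        profile.dist_cth = hsds - profile.cth_sds
        father_sds = ref.adult_sds(fh, Sex.MALE)
        mother_sds = ref.adult_sds(mh, Sex.FEMALE)
        profile.tallest_parent_hsds = max(father_sds, mother_sds)
        profile.dist_tallest_parent = hsds - profile.tallest_parent_hsds
    else:
        profile.complete = False

    if record.bone_age_years is not None:
        profile.ba_advance_years = bone_age_advance(record.bone_age_years, record.ca)

    if record.weight_kg is not None:
        bmi = record.weight_kg / (record.height_cm / 100.0) ** 2
        profile.bmi_sds = ref.sds(bmi, record.ca, record.sex, MeasurementKind.BMI)
    if record.head_circumference_cm is not None:
        profile.hc_sds = ref.sds(
            record.head_circumference_cm, record.ca, record.sex,
            MeasurementKind.HEAD_CIRCUMFERENCE,
        )
    if record.sitting_height_cm is not None:
        ratio = record.sitting_height_cm / record.height_cm
        profile.shh_sds = ref.sds(
            ratio, record.ca, record.sex, MeasurementKind.SITTING_HEIGHT_RATIO
        )

    if record.prior_measurements:
        earliest_age, earliest_h = min(record.prior_measurements, key=lambda p: p[0])
        earliest_sds = ref.sds(earliest_h, earliest_age, record.sex, MeasurementKind.HEIGHT)
        profile.delta_hsds = hsds - earliest_sds

    return profile
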