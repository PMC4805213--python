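"""Synthetic referral-cohort generator.

Emulates the statistical structure of a cohort referred for tall stature:

* parental heights drawn from the adult reference with assortative mating
  (parent-parent correlation);
* child height SDS regressed on the midparental SDS plus a residual, so the
  population marginal is standard normal;
* referral selection by a logistic function of the child's HSDS, calibrated
  so that about half of the retained cohort has HSDS <= 2.0 — referral
  clinics see many children who are not actually tall;
* bone-age advancement coupled to the height excess over target height, with
  the coupling solved so a requested Pearson correlation (default 0.45) is
  recovered;
* pubertal onset timing per sex, with Tanner stages progressing after onset;
* rare injected pathology (a precocious-puberty phenotype: early onset,
  pubertal Tanner stage, growth acceleration) at a configurable rate.

A single seeded generator drives every draw, so cohorts are reproducible —
byte-identical once serialized — for a fixed seed and configuration.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats
from scipy.special import expit

from .auxology import ClinicalFlags, PatientRecord
from .errors import ValidationError
from .references import GrowthReference, MeasurementKind, Sex, synthetic_reference

__all__ = ["SimulationConfig", "simulate_cohort", "inject_vignettes", "make_vignettes"]


class SimulationConfig(BaseModel):
    """Parameters of the generative model; defaults mirror the study setting."""

    n: int = Field(default=132, gt=0)
    seed: int = 0
    # Adult parental height distributions (cm); default to the packaged adult
    # reference so parents and children share one scale.
    father_mean_cm: float = 184.0
    father_sd_cm: float = 7.1
    mother_mean_cm: float = 170.6
    mother_sd_cm: float = 6.3
    assortative_corr: float = Field(default=0.25, gt=-1, lt=1)
    midparent_weight: float = 0.8          # regression of child HSDS on midparental SDS
    residual_sd: float = Field(default=0.775, gt=0)
    ba_coupling: Optional[float] = None    # years of BA advance per SDS of dist_th
    ba_noise_sd: float = Field(default=1.0, gt=0)
    target_ba_corr: Optional[float] = 0.45
    pathology_rate: float = Field(default=0.015, ge=0, le=1)
    parent_delayed_puberty_rate: float = Field(default=0.25, ge=0, le=1)
    puberty_onset_girls_mean: float = 11.0
    puberty_onset_girls_sd: float = Field(default=1.1, gt=0)
    puberty_onset_boys_mean: float = 11.5
    puberty_onset_boys_sd: float = Field(default=1.1, gt=0)
    age_mean: float = 10.9
    age_sd: float = Field(default=3.2, gt=0)
    age_min: float = 0.5
    age_max: float = 16.9
    # Logistic referral selection on HSDS, calibrated so the retained cohort
    # median HSDS is ~2.0 (half the cohort "not tall").
    selection_center: float = 2.77
    selection_scale: float = Field(default=0.4, gt=0)
    referral_bias: bool = True

    @model_validator(mode="after")
    def _check_corr(self) -> "SimulationConfig":
        if self.target_ba_corr is not None and not (-1 < self.target_ba_corr < 1):
            raise ValueError(
                f"target_ba_corr must lie strictly inside (-1, 1); "
                f"{self.target_ba_corr} is infeasible for any noise level"
            )
        return self


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _tanner_stage(ca: float, onset: float) -> int:
    if ca < onset:
        return 1
    return min(5, 2 + int((ca - onset) / 1.0))


def simulate_cohort(
    config: SimulationConfig, ref: Optional[GrowthReference] = None
) -> list[PatientRecord]:
    """Generate ``config.n`` referred children, reproducibly for a fixed seed."""
    ref = ref or synthetic_reference()
    rng = np.random.default_rng(config.seed)
    c = config

    # --- referred children's height SDS and parental SDS pairs -------------
    zf_list, zm_list, zc_list = [], [], []
    cov = np.array([[1.0, c.assortative_corr], [c.assortative_corr, 1.0]])
    chol = np.linalg.cholesky(cov)
    needed = c.n
    while needed > 0:
        batch = max(1000, needed * 4)
        par = rng.standard_normal((batch, 2)) @ chol.T
        mid = par.mean(axis=1)
        child = c.midparent_weight * mid + c.residual_sd * rng.standard_normal(batch)
        if c.referral_bias:
            p_ref = expit((child - c.selection_center) / c.selection_scale)
            keep = rng.random(batch) < p_ref
        else:
            keep = np.ones(batch, dtype=bool)
        take = min(needed, int(keep.sum()))
        idx = np.flatnonzero(keep)[:take]
        zf_list.append(par[idx, 0])
        zm_list.append(par[idx, 1])
        zc_list.append(child[idx])
        needed -= take
    zf = np.concatenate(zf_list)
    zm = np.concatenate(zm_list)
    zc = np.concatenate(zc_list)

    father_cm = np.clip(c.father_mean_cm + c.father_sd_cm * zf, 125, 225)
    mother_cm = np.clip(c.mother_mean_cm + c.mother_sd_cm * zm, 125, 225)

    sexes = np.where(rng.random(c.n) < 0.5, Sex.MALE.value, Sex.FEMALE.value)
    ages = _truncnorm(rng, c.age_mean, c.age_sd, c.age_min, c.age_max, c.n)

    # --- bone-age advancement coupled to height excess over target height --
    th_sds = np.empty(c.n)
    for i in range(c.n):
        sex = Sex(sexes[i])
        mid = (father_cm[i] + mother_cm[i]) / 2.0
        th = mid + 6.5 if sex is Sex.MALE else mid - 6.5
        th_sds[i] = ref.adult_sds(th, sex)
    dist_th = zc - th_sds
    if c.ba_coupling is not None:
        coupling = c.ba_coupling
    elif c.target_ba_corr is not None:
        r = c.target_ba_corr
        sd_x = float(np.std(dist_th))
        if sd_x == 0:
            raise ValidationError("degenerate dist_th spread; cannot solve coupling")
        coupling = r / math.sqrt(1 - r * r) * c.ba_noise_sd / sd_x
    else:
        coupling = 0.5
    ba_advance = coupling * (dist_th - dist_th.mean()) + c.ba_noise_sd * rng.standard_normal(c.n)

    # --- puberty, pathology, priors ----------------------------------------
    pathological = rng.random(c.n) < c.pathology_rate
    onset_draw = np.empty(c.n)
    for i in range(c.n):
        if Sex(sexes[i]) is Sex.FEMALE:
            onset_draw[i] = rng.normal(c.puberty_onset_girls_mean, c.puberty_onset_girls_sd)
        else:
            onset_draw[i] = rng.normal(c.puberty_onset_boys_mean, c.puberty_onset_boys_sd)
    onset_draw = np.clip(onset_draw, 6.0, 16.0)

    delta_prior = rng.normal(0.0, 0.15, c.n)  # benign HSDS drift over one year
    parent_delayed = rng.random(c.n) < c.parent_delayed_puberty_rate
    aux_z = rng.standard_normal((c.n, 3))  # BMI, head circumference, SH/H ratio

    records: list[PatientRecord] = []
    for i in range(c.n):
        sex = Sex(sexes[i])
        ca = float(ages[i])
        onset = float(onset_draw[i])
        hsds = float(zc[i])
        reported_onset = None
        if pathological[i]:
            thr = 8.0 if sex is Sex.FEMALE else 9.0
            onset = float(rng.uniform(thr - 3.0, thr - 0.1))
            if ca <= onset + 0.3:
                ca = min(c.age_max, onset + float(rng.uniform(0.5, 2.0)))
            reported_onset = round(onset, 1)
            delta = float(rng.uniform(1.1, 1.8))
        else:
            delta = float(delta_prior[i])
            if ca >= onset:
                reported_onset = round(onset, 1)

        stage = _tanner_stage(ca, onset)
        height_cm = ref.measurement(hsds, ca, sex, MeasurementKind.HEIGHT)

        prior: list[tuple[float, float]] = []
        if ca - 1.0 > ref.curve(MeasurementKind.HEIGHT, sex).age_min:
            prior_age = ca - 1.0
            prior_h = ref.measurement(hsds - delta, prior_age, sex, MeasurementKind.HEIGHT)
            prior.append((round(prior_age, 2), round(prior_h, 1)))

        bmi = ref.measurement(float(aux_z[i, 0]), ca, sex, MeasurementKind.BMI)
        weight = bmi * (height_cm / 100.0) ** 2
        hc = ref.measurement(
            float(np.clip(aux_z[i, 1], -3, 3)), ca, sex, MeasurementKind.HEAD_CIRCUMFERENCE
        )
        ratio = ref.measurement(
            float(np.clip(aux_z[i, 2], -3, 3)), ca, sex, MeasurementKind.SITTING_HEIGHT_RATIO
        )

        ba = float(np.clip(ca + ba_advance[i], 0.5, 19.5))
        records.append(
            PatientRecord(
                id=f"sim-{config.seed}-{i:05d}",
                sex=sex,
                ca=round(ca, 2),
                height_cm=round(height_cm, 1),
                weight_kg=round(weight, 1),
                sitting_height_cm=round(ratio * height_cm, 1),
                head_circumference_cm=round(hc, 1),
                bone_age_years=round(ba, 2),
                father_height_cm=round(float(father_cm[i]), 1),
                mother_height_cm=round(float(mother_cm[i]), 1),
                tanner_breast_or_genital=stage,
                tanner_pubic=max(1, stage - 1),
                reported_puberty_onset_age=reported_onset,
                prior_measurements=prior,
                flags=ClinicalFlags(
                    parent_delayed_puberty=bool(parent_delayed[i]),
                    parent_taller_than_2sds=bool(max(zf[i], zm[i]) > 2.0),
                ),
            )
        )
    return records


def make_vignettes(ref: Optional[GrowthReference] = None) -> list[PatientRecord]:
    """The two fixed pathological case fixtures (both precocious puberty).

    Case A: girl of 9.4 y, HSDS 2.3, bone age advanced, reported pubertal
    onset 7.5 y, Tanner B3/P3, with a recent growth acceleration.
    Case B: girl of 5.3 y, HSDS 0.9 (not tall), Tanner B2/P1.
    Heights are derived from the supplied reference so the encoded HSDS values
    hold exactly under it.
    """
    ref = ref or synthetic_reference()

    h_a = ref.measurement(2.3, 9.4, Sex.FEMALE, MeasurementKind.HEIGHT)
    h_a_prior = ref.measurement(1.1, 8.2, Sex.FEMALE, MeasurementKind.HEIGHT)
    vignette_a = PatientRecord(
        id="vignette-A",
        sex=Sex.FEMALE,
        ca=9.4,
        height_cm=round(h_a, 1),
        bone_age_years=11.9,
        father_height_cm=183.0,
        mother_height_cm=170.0,
        tanner_breast_or_genital=3,
        tanner_pubic=3,
        reported_puberty_onset_age=7.5,
        prior_measurements=[(8.2, round(h_a_prior, 1))],
    )
    h_b = ref.measurement(0.9, 5.3, Sex.FEMALE, MeasurementKind.HEIGHT)
    vignette_b = PatientRecord(
        id="vignette-B",
        sex=Sex.FEMALE,
        ca=5.3,
        height_cm=round(h_b, 1),
        father_height_cm=180.0,
        mother_height_cm=168.0,
        tanner_breast_or_genital=2,
        tanner_pubic=1,
    )
    return [vignette_a, vignette_b]


def inject_vignettes(
    cohort: list[PatientRecord], ref: Optional[GrowthReference] = None
) -> list[PatientRecord]:
    """Return the cohort with the two fixed case fixtures appended."""
    return list(cohort) + make_vignettes(ref)
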