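import numpy as np
import pytest

from tallstature import (
    ClinicalFlags,
    PatientRecord,
    Sex,
    SimulationConfig,
    simulate_cohort,
    synthetic_maturity_table,
    synthetic_reference,
)


@pytest.fixture(scope="session")
def ref():
    return synthetic_reference()


@pytest.fixture(scope="session")
def maturity_tables():
    return {sex: synthetic_maturity_table(sex) for sex in Sex}


@pytest.fixture(scope="session")
def small_cohort(ref):
    """500 simulated children, shared across tests that only read them."""
    return simulate_cohort(SimulationConfig(n=500, seed=2024), ref)


def make_record(**overrides) -> PatientRecord:
    """A plausible benign tall boy, overridable field by field."""
    base = dict(
        id="t-0",
        sex=Sex.MALE,
        ca=11.0,
        height_cm=158.0,
        father_height_cm=186.0,
        mother_height_cm=174.0,
        bone_age_years=11.5,
        tanner_breast_or_genital=1,
        tanner_pubic=1,
        flags=ClinicalFlags(),
    )
    base.update(overrides)
    return PatientRecord(**base)


def random_record(rng: np.random.Generator, ref) -> PatientRecord:
    """A syntactically valid random record with parental heights present."""
    sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
    ca = float(rng.uniform(0.6, 17.5))
    hsds = float(rng.normal(1.5, 1.5))
    height = ref.measurement(np.clip(hsds, -4, 4.5), ca, sex, "height")
    kwargs = dict(
        id=f"fuzz-{rng.integers(1e9)}",
        sex=sex,
        ca=ca,
        height_cm=float(np.clip(height, 41, 229)),
        father_height_cm=float(rng.uniform(160, 205)),
        mother_height_cm=float(rng.uniform(150, 195)),
    )
    if rng.random() < 0.8:
        kwargs["bone_age_years"] = float(np.clip(ca + rng.normal(0, 1.5), 0.5, 19.5))
    if rng.random() < 0.7:
        kwargs["tanner_breast_or_genital"] = int(rng.integers(1, 6))
    if rng.random() < 0.3:
        kwargs["reported_puberty_onset_age"] = float(rng.uniform(5, 15))
    if rng.random() < 0.5 and ca > 1.5:
        prior_age = ca - 1.0
        prior_h = ref.measurement(
            float(np.clip(hsds - rng.normal(0, 0.6), -4, 4.5)), prior_age, sex, "height"
        )
        kwargs["prior_measurements"] = [(prior_age, float(np.clip(prior_h, 41, 229)))]
    if rng.random() < 0.4:
        kwargs["sitting_height_cm"] = float(
            np.clip(kwargs["height_cm"] * rng.uniform(0.45, 0.62), 21, 149)
        )
    if rng.random() < 0.4:
        kwargs["head_circumference_cm"] = float(rng.uniform(42, 62))
    flag_names = list(ClinicalFlags.model_fields)
    kwargs["flags"] = ClinicalFlags(
        **{name: bool(rng.random() < 0.1) for name in flag_names}
    )
    return PatientRecord(**kwargs)
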