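"""Growth references and LMS standard-deviation-score conversion.

A growth reference stores, per measurement kind and sex, an age grid of LMS
triplets (L: Box-Cox skewness power, M: median, S: coefficient of variation).
A measurement x at age t converts to a standard deviation score via

    z = ((x / M)**L - 1) / (L * S)        (L != 0)
    z = ln(x / M) / S                     (L -> 0 limit)

with (L, M, S) interpolated linearly in age between grid points.  Ages outside
the grid raise: silently clamping a clinically wrong age would hide the error.

Adult height references (a mean/SD pair per sex) place target heights and
predicted adult heights on the SDS scale.  The packaged pair is Dutch-like:
under it 205 cm corresponds to +3.0 SDS for men and 185 cm to +2.3 SDS for
women at one-decimal rounding, the equivalences the screening thresholds use.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import AgeOutOfRangeError, DomainError, ParseError, ValidationError

__all__ = [
    "MeasurementKind",
    "Sex",
    "ReferenceCurve",
    "AdultHeightReference",
    "GrowthReference",
    "sds_from_measurement",
    "measurement_from_sds",
    "adult_height_sds",
    "load_reference",
    "write_reference",
    "synthetic_reference",
    "DUTCH_ADULT_HEIGHT",
]

# |L| below this is treated as the logarithmic limit.
_L_ZERO = 1e-7


class MeasurementKind(str, Enum):
    HEIGHT = "height"
    BMI = "weight_for_bmi"
    HEAD_CIRCUMFERENCE = "head_circumference"
    SITTING_HEIGHT_RATIO = "sitting_height_ratio"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class ReferenceCurve:
    """Sex-specific LMS curve for one measurement over an age grid."""

    measurement_kind: MeasurementKind
    sex: Sex
    ages: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ages", "L", "M", "S"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.ages.size
        if n < 2:
            raise ValidationError("a reference curve needs at least 2 grid points")
        if any(arr.size != n for arr in (self.L, self.M, self.S)):
            raise ValidationError("ages, L, M, S must have equal length")
        if not np.all(np.diff(self.ages) > 0):
            raise ValidationError("grid ages must be strictly increasing")
        if not np.all(self.M > 0):
            raise ValidationError("M must be positive at every grid point")
        if not np.all(self.S > 0):
            raise ValidationError("S must be positive at every grid point")

    @property
    def age_min(self) -> float:
        return float(self.ages[0])

    @property
    def age_max(self) -> float:
        return float(self.ages[-1])

    def lms_at(self, age: float) -> tuple[float, float, float]:
        """Linearly interpolated (L, M, S) at ``age``; refuses extrapolation."""
        if not np.isfinite(age):
            raise ValidationError("age must be finite")
        if age < self.age_min or age > self.age_max:
            raise AgeOutOfRangeError(
                f"age {age:g} y outside the {self.measurement_kind.value}/{self.sex.value} "
                f"reference span [{self.age_min:g}, {self.age_max:g}] y"
            )
        L = float(np.interp(age, self.ages, self.L))
        M = float(np.interp(age, self.ages, self.M))
        S = float(np.interp(age, self.ages, self.S))
        return L, M, S


@dataclass(frozen=True)
class AdultHeightReference:
    """Adult height distribution (mean/SD in cm) for one sex."""

    sex: Sex
    mean_cm: float
    sd_cm: float

    def __post_init__(self) -> None:
        if self.sd_cm <= 0:
            raise ValidationError("adult height SD must be positive")
        if not (120 < self.mean_cm < 230):
            raise ValidationError("adult mean height outside plausible range")


#: Packaged Dutch-like adult height reference: mean/SD chosen so that the
#: epiphysiodesis screening thresholds print as 205 cm = +3.0 SDS (men) and
#: 185 cm = +2.3 SDS (women) at one-decimal rounding.
DUTCH_ADULT_HEIGHT: dict[Sex, AdultHeightReference] = {
    Sex.MALE: AdultHeightReference(Sex.MALE, mean_cm=184.0, sd_cm=7.1),
    Sex.FEMALE: AdultHeightReference(Sex.FEMALE, mean_cm=170.6, sd_cm=6.3),
}


def _lms_to_z(value: float, L: float, M: float, S: float) -> float:
    if abs(L) < _L_ZERO:
        return float(np.log(value / M) / S)
    return float(((value / M) ** L - 1.0) / (L * S))


def _z_to_lms(z: float, L: float, M: float, S: float) -> float:
    if abs(L) < _L_ZERO:
        return float(M * np.exp(S * z))
    base = 1.0 + L * S * z
    if base <= 0:
        raise DomainError(
            f"SDS {z:g} outside the LMS domain (1 + L*S*z = {base:g} <= 0)"
        )
    return float(M * base ** (1.0 / L))


def sds_from_measurement(value: float, age: float, curve: ReferenceCurve) -> float:
    """Convert a raw measurement to its SDS against ``curve`` at ``age``."""
    if not (np.isfinite(value) and value > 0):
        raise ValidationError(f"measurement must be positive and finite, got {value!r}")
    L, M, S = curve.lms_at(age)
    return _lms_to_z(value, L, M, S)


def measurement_from_sds(z: float, age: float, curve: ReferenceCurve) -> float:
    """Inverse LMS transform: the measurement whose SDS is ``z`` at ``age``."""
    if not np.isfinite(z):
        raise ValidationError("SDS must be finite")
    L, M, S = curve.lms_at(age)
    value = _z_to_lms(z, L, M, S)
    if value <= 0:
        raise DomainError(f"inverse LMS produced non-positive measurement {value:g}")
    return value


def adult_height_sds(height_cm: float, ref: AdultHeightReference) -> float:
    """Adult height expressed as SDS: (height - mean) / SD."""
    if not (np.isfinite(height_cm) and height_cm > 0):
        raise ValidationError("height must be positive and finite")
    return (height_cm - ref.mean_cm) / ref.sd_cm


@dataclass
class GrowthReference:
    """A set of LMS curves keyed by (measurement kind, sex) plus adult heights."""

    curves: dict[tuple[MeasurementKind, Sex], ReferenceCurve]
    adult: dict[Sex, AdultHeightReference] = field(
        default_factory=lambda: dict(DUTCH_ADULT_HEIGHT)
    )

    def curve(self, kind: MeasurementKind, sex: Sex) -> ReferenceCurve:
        try:
            return self.curves[(MeasurementKind(kind), Sex(sex))]
        except KeyError:
            raise ValidationError(
                f"no {MeasurementKind(kind).value} curve for sex {Sex(sex).value}"
            ) from None

    def sds(self, value: float, age: float, sex: Sex, kind: MeasurementKind) -> float:
        return sds_from_measurement(value, age, self.curve(kind, sex))

    def measurement(self, z: float, age: float, sex: Sex, kind: MeasurementKind) -> float:
        return measurement_from_sds(z, age, self.curve(kind, sex))

    def adult_sds(self, height_cm: float, sex: Sex) -> float:
        return adult_height_sds(height_cm, self.adult[Sex(sex)])


# ---------------------------------------------------------------------------
# Table I/O: delimited text with columns measurement, sex, age, L, M, S.
# ---------------------------------------------------------------------------

_COLUMNS = ("measurement", "sex", "age", "L", "M", "S")


def load_reference(
    source: Union[str, Path, io.TextIOBase],
    *,
    sep: str = "\t",
    adult: dict[Sex, AdultHeightReference] | None = None,
) -> GrowthReference:
    """Read a growth reference from a delimited text table.

    One header line with columns ``measurement, sex, age, L, M, S``; rows
    grouped per (measurement, sex) with strictly increasing ages.  Raises
    :class:`ParseError` (naming the offending row) on malformed input.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty reference table")
    header = [c.strip() for c in lines[0].split(sep)]
    if header != list(_COLUMNS):
        raise ParseError(
            f"header row 1 must be {list(_COLUMNS)}, got {header}"
        )
    rows: dict[tuple[MeasurementKind, Sex], list[tuple[float, float, float, float]]] = {}
    seen: set[tuple[MeasurementKind, Sex, float]] = set()
    for i, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) != len(_COLUMNS):
            raise ParseError(f"row {i}: expected {len(_COLUMNS)} fields, got {len(parts)}")
        try:
            kind = MeasurementKind(parts[0])
            sex = Sex(parts[1])
            age, L, M, S = (float(p) for p in parts[2:])
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}") from None
        key3 = (kind, sex, age)
        if key3 in seen:
            raise ParseError(f"row {i}: duplicate (measurement, sex, age) = "
                             f"({kind.value}, {sex.value}, {age:g})")
        seen.add(key3)
        rows.setdefault((kind, sex), []).append((age, L, M, S))
    curves: dict[tuple[MeasurementKind, Sex], ReferenceCurve] = {}
    for key, pts in rows.items():
        ages = [p[0] for p in pts]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ParseError(
                f"ages not strictly increasing for ({key[0].value}, {key[1].value})"
            )
        try:
            curves[key] = ReferenceCurve(
                key[0], key[1],
                np.array(ages),
                np.array([p[1] for p in pts]),
                np.array([p[2] for p in pts]),
                np.array([p[3] for p in pts]),
            )
        except ValidationError as exc:
            raise ParseError(f"curve ({key[0].value}, {key[1].value}): {exc}") from None
    return GrowthReference(curves, adult=dict(adult or DUTCH_ADULT_HEIGHT))


def write_reference(ref: GrowthReference, path: Union[str, Path], *, sep: str = "\t") -> None:
    """Serialize a growth reference back to the delimited table format."""
    out = [sep.join(_COLUMNS)]
    for (kind, sex), curve in ref.curves.items():
        for age, L, M, S in zip(curve.ages, curve.L, curve.M, curve.S):
            out.append(sep.join([kind.value, sex.value,
                                 f"{age:g}", f"{L:g}", f"{M:.6g}", f"{S:.6g}"]))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Packaged synthetic reference: smooth, plausible curves generated in code.
# ---------------------------------------------------------------------------

def _smooth_curve(anchors_age, anchors_val, grid) -> np.ndarray:
    return PchipInterpolator(anchors_age, anchors_val)(grid)


def synthetic_reference() -> GrowthReference:
    """The packaged synthetic growth reference (ages 0.25-18.0 y).

    Curves are smooth monotone interpolations through anchor values typical of
    a northern-European pediatric population; they are synthetic and stand in
    for national LMS tables, which users supply via :func:`load_reference`.
    The height medians at 18 y equal the packaged adult means so child and
    adult SDS scales join continuously.
    """
    grid = np.round(np.arange(0.25, 18.01, 0.25), 2)
    curves: dict[tuple[MeasurementKind, Sex], ReferenceCurve] = {}

    height_anchors = {
        Sex.MALE: (
            [0.25, 1, 2, 4, 6, 8, 10, 12, 14, 16, 18],
            [62, 76, 88, 103.5, 116.5, 128, 139, 150.5, 164, 177.5, 184.0],
        ),
        Sex.FEMALE: (
            [0.25, 1, 2, 4, 6, 8, 10, 12, 14, 16, 18],
            [60.5, 74.5, 86.5, 102.5, 115.5, 127.5, 139.5, 153, 164, 169.5, 170.6],
        ),
    }
    # S tends to the adult CV so SD(18 y) = adult SD (7.1 / 6.3 cm).
    height_s = {
        Sex.MALE: ([0.25, 2, 8, 12, 14, 18], [0.036, 0.038, 0.041, 0.044, 0.043, 7.1 / 184.0]),
        Sex.FEMALE: ([0.25, 2, 8, 11, 13, 18], [0.036, 0.038, 0.041, 0.044, 0.040, 6.3 / 170.6]),
    }
    bmi_anchors = {
        Sex.MALE: ([0.25, 1, 3, 6, 10, 14, 18], [14.5, 17.0, 16.0, 15.5, 16.8, 19.2, 21.5]),
        Sex.FEMALE: ([0.25, 1, 3, 6, 10, 14, 18], [14.2, 16.6, 15.8, 15.4, 17.0, 19.5, 21.2]),
    }
    hc_anchors = {
        Sex.MALE: ([0.25, 1, 2, 5, 10, 18], [40.5, 46.5, 48.8, 51.0, 53.0, 56.0]),
        Sex.FEMALE: ([0.25, 1, 2, 5, 10, 18], [39.8, 45.5, 47.7, 50.0, 52.2, 55.0]),
    }
    shh_anchors = {
        Sex.MALE: ([0.25, 2, 6, 10, 14, 18], [0.66, 0.60, 0.55, 0.532, 0.522, 0.522]),
        Sex.FEMALE: ([0.25, 2, 6, 10, 14, 18], [0.66, 0.60, 0.552, 0.535, 0.528, 0.53]),
    }

    for sex in Sex:
        a, v = height_anchors[sex]
        sa, sv = height_s[sex]
        curves[(MeasurementKind.HEIGHT, sex)] = ReferenceCurve(
            MeasurementKind.HEIGHT, sex, grid,
            np.full_like(grid, 1.0),
            _smooth_curve(a, v, grid),
            _smooth_curve(sa, sv, grid),
        )
        a, v = bmi_anchors[sex]
        curves[(MeasurementKind.BMI, sex)] = ReferenceCurve(
            MeasurementKind.BMI, sex, grid,
            np.full_like(grid, -1.5),
            _smooth_curve(a, v, grid),
            np.full_like(grid, 0.11),
        )
        a, v = hc_anchors[sex]
        curves[(MeasurementKind.HEAD_CIRCUMFERENCE, sex)] = ReferenceCurve(
            MeasurementKind.HEAD_CIRCUMFERENCE, sex, grid,
            np.full_like(grid, 1.0),
            _smooth_curve(a, v, grid),
            np.full_like(grid, 0.028),
        )
        a, v = shh_anchors[sex]
        curves[(MeasurementKind.SITTING_HEIGHT_RATIO, sex)] = ReferenceCurve(
            MeasurementKind.SITTING_HEIGHT_RATIO, sex, grid,
            np.full_like(grid, 1.0),
            _smooth_curve(a, v, grid),
            np.full_like(grid, 0.022),
        )
    return GrowthReference(curves, adult=dict(DUTCH_ADULT_HEIGHT))
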