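"""Adult height prediction and epiphysiodesis screening.

Two prediction methods are offered:

* **De Waal** (updated regression; the default): a linear form in current
  height, conditional-target-height SDS, chronological age (CA) and bone age
  (BA), with a CA x BA interaction.  Applied from age 10, matching the
  clinical practice the regression was fitted in.
* **Bayley-Pinneau**: current height divided by the fraction of adult height
  attained at the current bone age, looked up from a maturity-fraction table.
  The classical three-tempo tables are simplified to a single user-suppliable
  fraction column per sex; a synthetic fixture table ships for testing.

Epiphysiodesis (surgical growth-plate arrest) is screened on the De Waal
prediction with strict thresholds: PAH > 205 cm in boys, > 185 cm in girls.
Bayley-Pinneau systematically over-predicts in tall children (particularly
boys), so it is kept for method comparison only and never feeds screening.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import AgeOutOfRangeError, ParseError, ValidationError
from .references import Sex

__all__ = [
    "PredictionMethod",
    "AdultHeightPrediction",
    "MaturityFractionTable",
    "pah_de_waal",
    "pah_bayley_pinneau",
    "epiphysiodesis_indicated",
    "EPIPHYSIODESIS_THRESHOLD_CM",
    "synthetic_maturity_table",
    "load_maturity_tables",
]

# De Waal regression coefficients per sex:
# intercept, height, cTH SDS, CA, BA, CA*BA
_DE_WAAL_COEF = {
    Sex.MALE: (267.02, 0.62, 2.75, -10.49, -12.98, 0.72),
    Sex.FEMALE: (158.42, 0.74, 1.47, -5.90, -7.70, 0.41),
}

#: Screening thresholds (strict ">"): predictions at exactly the threshold
#: fall on the non-treatment side.
EPIPHYSIODESIS_THRESHOLD_CM = {Sex.MALE: 205.0, Sex.FEMALE: 185.0}

_MIN_CA = 10.0


class PredictionMethod(str, Enum):
    DE_WAAL = "de_waal"
    BAYLEY_PINNEAU = "bayley_pinneau"


@dataclass(frozen=True)
class AdultHeightPrediction:
    method: PredictionMethod
    pah_cm: float
    pah_sds: Optional[float] = None
    inputs_echo: Optional[dict] = None

    def __post_init__(self) -> None:
        if not (130 < self.pah_cm < 240):
            raise ValidationError(
                f"predicted adult height {self.pah_cm:.1f} cm outside (130, 240); "
                "check inputs"
            )


@dataclass(frozen=True)
class MaturityFractionTable:
    """Fraction of adult height attained, by bone age, for one sex."""

    sex: Sex
    bone_ages: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bone_ages", np.asarray(self.bone_ages, dtype=float))
        object.__setattr__(self, "fractions", np.asarray(self.fractions, dtype=float))
        if self.bone_ages.size < 2 or self.bone_ages.size != self.fractions.size:
            raise ValidationError("maturity table needs >= 2 matched rows")
        if not np.all(np.diff(self.bone_ages) > 0):
            raise ValidationError("bone ages must be strictly increasing")
        if np.any(np.diff(self.fractions) < 0):
            raise ValidationError("fractions must be non-decreasing in bone age")
        if not (np.all(self.fractions > 0) and np.all(self.fractions <= 1.0)):
            raise ValidationError("fractions must lie in (0, 1]")
        if self.fractions[-1] != 1.0:
            raise ValidationError("final fraction must be exactly 1.0 (maturity)")

    def fraction_at(self, ba: float) -> float:
        if ba < self.bone_ages[0] or ba > self.bone_ages[-1]:
            raise AgeOutOfRangeError(
                f"bone age {ba:g} y outside maturity table span "
                f"[{self.bone_ages[0]:g}, {self.bone_ages[-1]:g}] y"
            )
        return float(np.interp(ba, self.bone_ages, self.fractions))


def pah_de_waal(height_cm: float, cth_sds: float, ca: float, ba: float, sex: Sex) -> float:
    """Predicted adult height (cm) by the De Waal regression.

    Restricted to CA in [10, 18): the prediction is defined for children
    above 10 years.  BA must lie in (6, 18].
    """
    if ca < _MIN_CA:
        raise ValidationError(
            f"De Waal prediction is defined for children above {_MIN_CA:g} years "
            f"of age; got CA {ca:g}"
        )
    if not (_MIN_CA <= ca < 18):
        raise ValidationError(f"CA {ca:g} outside [10, 18)")
    if not (6 < ba <= 18):
        raise ValidationError(f"bone age {ba:g} outside (6, 18]")
    if not (40 < height_cm < 230):
        raise ValidationError(f"height {height_cm!r} cm implausible")
    a, bh, bc, bca, bba, bint = _DE_WAAL_COEF[Sex(sex)]
    return a + bh * height_cm + bc * cth_sds + bca * ca + bba * ba + bint * ca * ba


def pah_bayley_pinneau(height_cm: float, ba: float, sex: Sex,
                       table: MaturityFractionTable) -> float:
    """Predicted adult height: current height / fraction-of-adult-height(BA)."""
    if Sex(sex) is not table.sex:
        raise ValidationError("maturity table sex does not match patient sex")
    if not (40 < height_cm < 230):
        raise ValidationError(f"height {height_cm!r} cm implausible")
    return height_cm / table.fraction_at(ba)


def epiphysiodesis_indicated(pah_cm: float, sex: Sex) -> bool:
    """True iff the De Waal prediction exceeds the sex-specific threshold.

    Strict inequality: exactly 205 cm (boys) / 185 cm (girls) is not an
    indication.  Caller contract: feed only De Waal predictions.
    """
    return pah_cm > EPIPHYSIODESIS_THRESHOLD_CM[Sex(sex)]


def synthetic_maturity_table(sex: Sex) -> MaturityFractionTable:
    """Synthetic Bayley-Pinneau-style maturity fractions for tests/demos.

    Smooth plausible fractions reaching 1.0 at skeletal maturity (BA 18 y
    boys, 16 y girls); not a transcription of any published table.
    """
    if Sex(sex) is Sex.MALE:
        ba = np.array([6, 8, 10, 11, 12, 13, 14, 15, 16, 17, 18], dtype=float)
        fr = np.array([0.680, 0.756, 0.800, 0.820, 0.840, 0.875, 0.920,
                       0.958, 0.980, 0.993, 1.000])
    else:
        ba = np.array([6, 8, 10, 11, 12, 13, 14, 15, 16], dtype=float)
        fr = np.array([0.720, 0.790, 0.860, 0.900, 0.940, 0.968, 0.986,
                       0.995, 1.000])
    return MaturityFractionTable(Sex(sex), ba, fr)


def load_maturity_tables(
    source: Union[str, Path, io.TextIOBase], *, sep: str = "\t"
) -> dict[Sex, MaturityFractionTable]:
    """Read maturity-fraction tables (columns sex, bone_age, fraction)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty maturity table")
    header = [c.strip() for c in lines[0].split(sep)]
    if header != ["sex", "bone_age", "fraction"]:
        raise ParseError(f"header must be ['sex', 'bone_age', 'fraction'], got {header}")
    rows: dict[Sex, list[tuple[float, float]]] = {}
    for i, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) != 3:
            raise ParseError(f"row {i}: expected 3 fields, got {len(parts)}")
        try:
            sex = Sex(parts[0])
            ba, fr = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}") from None
        rows.setdefault(sex, []).append((ba, fr))
    out = {}
    for sex, pts in rows.items():
        try:
            out[sex] = MaturityFractionTable(
                sex,
                np.array([p[0] for p in pts]),
                np.array([p[1] for p in pts]),
            )
        except ValidationError as exc:
            raise ParseError(f"table for {sex.value}: {exc}") from None
    return out
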