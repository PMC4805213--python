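"""Definitional classifier and diagnostic flow chart for tall-stature referrals.

Taxonomy
--------
A child is *tall* when HSDS > 2.0 (strict).  Tall children without suspected
pathology are idiopathic tall stature (ITS), split into:

* **FTS** (familial tall stature) — any of three criteria holds:
  (1) HSDS - THSDS < 2.0 (Tanner target-height range +/- 2.0 SD);
  (2) HSDS - cTHSDS < 1.6 (conditional target-height range +/- 1.6 SD);
  (3) the child is tall and HSDS - HSDS(tallest parent) < 1.6.
* **CAG** (constitutional advancement of growth) — none of the FTS criteria
  holds but bone age is advanced by more than 2.0 years; expected to reach a
  normal adult height.
* **NFTS (unexplained)** — none of the above.

Flow chart
----------
Two pathways branch on HSDS and the Tanner target-height distance.  The
not-tall pathway (HSDS <= 2.0 and HSDS-THSDS <= 2.0) normally ends in
reassurance — upgraded with a conditional re-referral advice when a parent
had delayed puberty — but endocrine red flags (inappropriate pubertal
development, unexplained growth acceleration) still route to endocrine
work-up: precocious puberty can present at a normal height.  The tall
pathway screens syndromic flags (-> genetic work-up), then endocrine flags
(-> endocrine work-up); a growth acceleration that is plausibly pubertal is
not escalated immediately but rechecked at a three-month follow-up visit.
With no flags the child is classified into the ITS subclasses, and from age
10 an adult-height prediction can add counselling about height reduction.

Every clinical threshold is a named field of :class:`Thresholds` with the
published value as default: the algorithm is policy, and policies get audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from .auxology import AuxologyProfile, PatientRecord
from .errors import IncompleteDataError
from .prediction import AdultHeightPrediction, PredictionMethod
from .references import Sex

__all__ = [
    "Thresholds",
    "DEFAULT_THRESHOLDS",
    "ItsSubclass",
    "Terminal",
    "FlagStatus",
    "RedFlag",
    "ClassificationResult",
    "FlowchartOutcome",
    "is_tall",
    "fts_criteria",
    "classify_its",
    "PubertalStatus",
    "pubertal_appropriateness",
    "disproportionate",
    "red_flags",
    "second_referral_advice",
    "run_flowchart",
    "classify_record",
]


@dataclass(frozen=True)
class Thresholds:
    """All clinical cut-offs, overridable per run."""

    tall_cutoff_sds: float = 2.0              # HSDS above which a child is tall
    fts_th_sds: float = 2.0                   # HSDS - THSDS (Tanner) range
    fts_cth_sds: float = 1.6                  # HSDS - cTHSDS range
    fts_tallest_parent_sds: float = 1.6       # HSDS - tallest-parent HSDS range
    cag_ba_advance_years: float = 2.0         # BA - CA above which CAG
    growth_accel_delta_hsds: float = 1.0      # HSDS change flagging acceleration
    macrocephaly_hc_sds: float = 2.0          # head circumference SDS
    disproportion_shh_sds: float = -2.2       # SH/H SDS below which long-legged
    precocious_onset_girls: float = 8.0       # puberty before this age, girls
    precocious_onset_boys: float = 9.0
    delayed_stage1_girls: float = 13.0        # Tanner 1 at/after this age, girls
    delayed_stage1_boys: float = 14.0
    epiphysiodesis_cm: dict[Sex, float] = field(
        default_factory=lambda: {Sex.MALE: 205.0, Sex.FEMALE: 185.0}
    )
    second_referral_height_cm: dict[Sex, float] = field(
        default_factory=lambda: {Sex.MALE: 185.0, Sex.FEMALE: 170.0}
    )
    second_referral_age_limit: dict[Sex, float] = field(
        default_factory=lambda: {Sex.MALE: 14.0, Sex.FEMALE: 12.5}
    )
    pah_age_min: float = 10.0

    def override(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)


DEFAULT_THRESHOLDS = Thresholds()


class ItsSubclass(str, Enum):
    FTS = "FTS"
    CAG = "CAG"
    NFTS_UNEXPLAINED = "NFTS_unexplained"
    NOT_APPLICABLE = "not_applicable"


class Terminal(str, Enum):
    REASSURE = "reassure"
    REASSURE_WITH_CONDITIONAL_REREFERRAL = "reassure_with_conditional_rereferral"
    FOLLOWUP_3_MONTHS = "followup_3_months"
    GENETIC_WORKUP = "genetic_workup"
    ENDOCRINE_WORKUP = "endocrine_workup"
    CLASSIFY_ITS_AND_FOLLOWUP = "classify_its_and_followup"
    PAH_AND_COUNSELLING = "pah_and_counselling"


class FlagStatus(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNEVALUABLE = "unevaluable"
    FOLLOWUP = "followup"  # pubertal-context growth acceleration: recheck, not escalate


class PubertalStatus(str, Enum):
    PREPUBERTAL_NORMAL = "prepubertal_normal"
    NORMAL = "normal"
    PRECOCIOUS = "precocious"
    DELAYED = "delayed"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class RedFlag:
    id: str
    category: str  # "syndromic" | "endocrine"
    status: FlagStatus
    rationale: str


@dataclass
class ClassificationResult:
    record_id: str
    is_tall: bool
    fts_by_th: Optional[bool]
    fts_by_cth: Optional[bool]
    fts_by_tallest_parent: Optional[bool]
    its_subclass: ItsSubclass
    pathology_suspected: bool
    epiphysiodesis_flag: Optional[bool] = None
    second_referral: Optional[tuple[float, float]] = None


@dataclass
class FlowchartOutcome:
    record_id: str
    triggered_flags: list[str]
    terminal: Terminal
    rationale: dict[str, str]


def is_tall(hsds: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> bool:
    """Tall stature: HSDS strictly above the cut-off (default 2.0)."""
    return hsds > thresholds.tall_cutoff_sds


def fts_criteria(
    profile: AuxologyProfile, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[Optional[bool], Optional[bool], Optional[bool]]:
    """Evaluate the three familial-tall-stature criteria.

    Returns a boolean per criterion, or ``None`` when the required distance
    is missing (undetermined, never silently false).
    """
    c1 = None if profile.dist_th is None else profile.dist_th < thresholds.fts_th_sds
    c2 = None if profile.dist_cth is None else profile.dist_cth < thresholds.fts_cth_sds
    if profile.dist_tallest_parent is None:
        c3 = None
    else:
        c3 = (
            is_tall(profile.hsds, thresholds)
            and profile.dist_tallest_parent < thresholds.fts_tallest_parent_sds
        )
    return c1, c2, c3


def classify_its(
    profile: AuxologyProfile,
    pathology_suspected: bool,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ItsSubclass:
    """Subclassify a tall child: FTS wins over CAG, CAG over unexplained NFTS.

    FTS is labelled whenever any criterion holds; CAG only within non-familial
    tall stature, requiring a bone-age advance > 2.0 years.  A tall child with
    no criterion satisfied and no bone age is undetermined (CAG cannot be
    excluded) and raises :class:`IncompleteDataError`.
    """
    if pathology_suspected:
        return ItsSubclass.NOT_APPLICABLE
    c1, c2, c3 = fts_criteria(profile, thresholds)
    if any(c is True for c in (c1, c2, c3)):
        return ItsSubclass.FTS
    if any(c is None for c in (c1, c2, c3)):
        raise IncompleteDataError(
            "an FTS criterion is undetermined and none holds; subclass unresolved"
        )
    if profile.ba_advance_years is None:
        raise IncompleteDataError(
            "no FTS criterion holds and bone age is missing: CAG cannot be excluded"
        )
    if profile.ba_advance_years > thresholds.cag_ba_advance_years:
        return ItsSubclass.CAG
    return ItsSubclass.NFTS_UNEXPLAINED


def pubertal_appropriateness(
    record: PatientRecord, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> PubertalStatus:
    """Rate pubertal development against chronological age.

    Precocious: pubertal signs (Tanner breast/genital stage >= 2) before age
    8 in girls / 9 in boys, or a reported onset below those ages.  Delayed:
    still Tanner stage 1 at >= 13 y (girls) / >= 14 y (boys).  Without any
    pubertal data the status is undetermined and surfaces as a
    data-completeness flag downstream.
    """
    girl = record.sex is Sex.FEMALE
    thr_prec = thresholds.precocious_onset_girls if girl else thresholds.precocious_onset_boys
    thr_del = thresholds.delayed_stage1_girls if girl else thresholds.delayed_stage1_boys
    onset = record.reported_puberty_onset_age
    stage = record.tanner_breast_or_genital

    if onset is not None and onset < thr_prec:
        return PubertalStatus.PRECOCIOUS
    if stage is not None:
        if stage >= 2:
            return PubertalStatus.PRECOCIOUS if record.ca < thr_prec else PubertalStatus.NORMAL
        if record.ca >= thr_del:
            return PubertalStatus.DELAYED
        return PubertalStatus.PREPUBERTAL_NORMAL
    if onset is not None:  # onset at a normal age, stage unrecorded
        return PubertalStatus.NORMAL
    return PubertalStatus.UNDETERMINED


def disproportionate(
    shh_sds: float, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Body disproportion: sitting-height/height ratio SDS below -2.2 (long legs)."""
    return shh_sds < thresholds.disproportion_shh_sds


_SYNDROMIC = ("developmental_or_speech_delay", "behavioral_problems",
              "dysmorphic_features", "disproportion", "macrocephaly")
_ENDOCRINE = ("th_distance", "growth_acceleration", "pubertal_inappropriate",
              "gh_excess_signs", "hyperthyroid_signs")


def red_flags(
    record: PatientRecord,
    profile: AuxologyProfile,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[RedFlag]:
    """Evaluate every red flag independently, in a fixed order.

    Syndromic flags (pointing to chromosomal/genetic overgrowth) come before
    endocrine flags (pointing to hormonal causes).  Missing inputs yield
    ``unevaluable`` entries rather than silent omission.  A growth
    acceleration in a child already in puberty at a normal age is downgraded
    to ``followup``: pubertal height velocity is expected, and a three-month
    recheck replaces immediate work-up.
    """
    t = thresholds
    flags: list[RedFlag] = []

    def add(fid, cat, status, why):
        flags.append(RedFlag(fid, cat, status, why))

    def present_absent(cond):
        return FlagStatus.PRESENT if cond else FlagStatus.ABSENT

    f = record.flags
    add("developmental_or_speech_delay", "syndromic",
        present_absent(f.developmental_or_speech_delay), "history questionnaire")
    add("behavioral_problems", "syndromic",
        present_absent(f.behavioral_problems), "history questionnaire")
    add("dysmorphic_features", "syndromic",
        present_absent(f.dysmorphic_features), "physical examination")
    if profile.shh_sds is None:
        add("disproportion", "syndromic", FlagStatus.UNEVALUABLE,
            "sitting height not measured")
    else:
        add("disproportion", "syndromic",
            present_absent(disproportionate(profile.shh_sds, t)),
            f"SH/H SDS {profile.shh_sds:.2f} vs < {t.disproportion_shh_sds:g}")
    if profile.hc_sds is None:
        add("macrocephaly", "syndromic", FlagStatus.UNEVALUABLE,
            "head circumference not measured")
    else:
        add("macrocephaly", "syndromic",
            present_absent(profile.hc_sds > t.macrocephaly_hc_sds),
            f"HC SDS {profile.hc_sds:.2f} vs > {t.macrocephaly_hc_sds:g}")

    if profile.dist_th is None:
        add("th_distance", "endocrine", FlagStatus.UNEVALUABLE,
            "parental heights missing")
    else:
        add("th_distance", "endocrine",
            present_absent(profile.dist_th > t.fts_th_sds),
            f"HSDS - THSDS {profile.dist_th:.2f} vs > {t.fts_th_sds:g}")

    pub = pubertal_appropriateness(record, t)
    if profile.delta_hsds is None:
        add("growth_acceleration", "endocrine", FlagStatus.UNEVALUABLE,
            "no prior height measurements")
    elif profile.delta_hsds > t.growth_accel_delta_hsds:
        in_normal_puberty = (
            record.tanner_breast_or_genital is not None
            and record.tanner_breast_or_genital >= 2
            and pub is PubertalStatus.NORMAL
        )
        if in_normal_puberty:
            add("growth_acceleration", "endocrine", FlagStatus.FOLLOWUP,
                f"ΔHSDS {profile.delta_hsds:.2f} but consistent with pubertal "
                "growth spurt; recheck in 3 months")
        else:
            add("growth_acceleration", "endocrine", FlagStatus.PRESENT,
                f"ΔHSDS {profile.delta_hsds:.2f} vs > {t.growth_accel_delta_hsds:g}")
    else:
        add("growth_acceleration", "endocrine", FlagStatus.ABSENT,
            f"ΔHSDS {profile.delta_hsds:.2f}")

    if pub is PubertalStatus.UNDETERMINED:
        add("pubertal_inappropriate", "endocrine", FlagStatus.UNEVALUABLE,
            "no pubertal staging or onset data")
    else:
        add("pubertal_inappropriate", "endocrine",
            present_absent(pub in (PubertalStatus.PRECOCIOUS, PubertalStatus.DELAYED)),
            f"pubertal development rated {pub.value}")

    add("gh_excess_signs", "endocrine", present_absent(f.signs_gh_excess),
        "clinical signs of growth hormone excess")
    add("hyperthyroid_signs", "endocrine", present_absent(f.signs_hyperthyroidism),
        "clinical signs of hyperthyroidism")
    return flags


def second_referral_advice(
    record: PatientRecord, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> Optional[tuple[float, float]]:
    """Conditional re-referral advice for children with familial pubertal delay.

    When a parent had delayed puberty, a currently not-tall child may still
    reach an extreme adult height; advise re-referral on reaching 170 cm
    before age 12.5 y (girls) or 185 cm before 14 y (boys).
    Returns ``(height_cm, age_limit_years)`` or ``None``.
    """
    if not record.flags.parent_delayed_puberty:
        return None
    sex = record.sex
    return (
        thresholds.second_referral_height_cm[sex],
        thresholds.second_referral_age_limit[sex],
    )


def run_flowchart(
    record: PatientRecord,
    profile: AuxologyProfile,
    prediction: Optional[AdultHeightPrediction] = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> FlowchartOutcome:
    """Route one child through the diagnostic flow chart to a single terminal.

    Requires HSDS and the Tanner target-height distance for the initial
    branch.  ``prediction`` (De Waal) is only consulted on the benign tall
    path for children above 10 years, where a prediction over the screening
    threshold routes to adult-height counselling.
    """
    if profile.dist_th is None:
        raise IncompleteDataError(
            "flow chart needs HSDS and HSDS - THSDS: parental heights missing"
        )
    t = thresholds
    flags = red_flags(record, profile, t)
    present = [f for f in flags if f.status is FlagStatus.PRESENT]
    followup = [f for f in flags if f.status is FlagStatus.FOLLOWUP]
    synd = [f for f in present if f.category == "syndromic"]
    endo = [f for f in present if f.category == "endocrine"]
    rationale = {f.id: f.rationale for f in present + followup}
    triggered = [f.id for f in present + followup]

    tall_pathway = (
        profile.hsds > t.tall_cutoff_sds or profile.dist_th > t.fts_th_sds
    )

    if not tall_pathway:
        # Not-tall pathway: endocrine pathology must not be swallowed.
        if endo:
            terminal = Terminal.ENDOCRINE_WORKUP
        elif followup:
            terminal = Terminal.FOLLOWUP_3_MONTHS
        elif second_referral_advice(record, t) is not None:
            terminal = Terminal.REASSURE_WITH_CONDITIONAL_REREFERRAL
            rationale["second_referral"] = (
                "family history of delayed puberty: re-refer on reaching "
                "%.0f cm before age %.1f y" % second_referral_advice(record, t)
            )
        else:
            terminal = Terminal.REASSURE
        return FlowchartOutcome(record.id, triggered, terminal, rationale)

    if synd:
        terminal = Terminal.GENETIC_WORKUP
    elif endo:
        terminal = Terminal.ENDOCRINE_WORKUP
    elif followup:
        terminal = Terminal.FOLLOWUP_3_MONTHS
    else:
        terminal = Terminal.CLASSIFY_ITS_AND_FOLLOWUP
        if (
            prediction is not None
            and prediction.method is PredictionMethod.DE_WAAL
            and record.ca > t.pah_age_min
            and prediction.pah_cm > t.epiphysiodesis_cm[record.sex]
        ):
            terminal = Terminal.PAH_AND_COUNSELLING
            rationale["pah"] = (
                f"De Waal PAH {prediction.pah_cm:.1f} cm exceeds "
                f"{t.epiphysiodesis_cm[record.sex]:g} cm"
            )
    return FlowchartOutcome(record.id, triggered, terminal, rationale)


def classify_record(
    record: PatientRecord,
    profile: AuxologyProfile,
    prediction: Optional[AdultHeightPrediction] = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    *,
    assume_workup_negative: bool = False,
) -> tuple[ClassificationResult, FlowchartOutcome]:
    """Full work-up of one child: flow chart plus definitional classification.

    Pathology is suspected when the flow chart routes to a genetic or
    endocrine work-up; by default the ITS subclassification then does not
    apply (the child is still under investigation).  With
    ``assume_workup_negative`` the definitional taxonomy is applied to every
    tall child regardless of routing — the reading used when work-up has
    already come back negative and the cohort is being subclassified.
    """
    outcome = run_flowchart(record, profile, prediction, thresholds)
    pathology = outcome.terminal in (Terminal.GENETIC_WORKUP, Terminal.ENDOCRINE_WORKUP)
    tall = is_tall(profile.hsds, thresholds)
    c1, c2, c3 = fts_criteria(profile, thresholds)
    if tall and (assume_workup_negative or not pathology):
        subclass = classify_its(profile, False, thresholds)
    else:
        subclass = ItsSubclass.NOT_APPLICABLE
    epi = None
    if prediction is not None and prediction.method is PredictionMethod.DE_WAAL:
        epi = prediction.pah_cm > thresholds.epiphysiodesis_cm[record.sex]
    result = ClassificationResult(
        record_id=record.id,
        is_tall=tall,
        fts_by_th=c1,
        fts_by_cth=c2,
        fts_by_tallest_parent=c3,
        its_subclass=subclass,
        pathology_suspected=pathology,
        epiphysiodesis_flag=epi,
        second_referral=second_referral_advice(record, thresholds),
    )
    return result, outcome
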