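# Methods

## Growth references and SDS conversion

All measurement↔SDS conversion uses the LMS parameterization: at age *t* a
measurement *x* has z-score

    z = ((x/M)^L − 1) / (L·S),   or   z = ln(x/M)/S  when |L| < 1e−7,

with (L, M, S) interpolated **linearly in age** between grid points. The
inverse is `x = M·(1 + L·S·z)^(1/L)`; requests with `1 + L·S·z ≤ 0` are a
domain error. Ages outside a curve's grid raise rather than clamp: silently
scoring a 19-year-old against an 18-year-old's distribution would hide a
clinically wrong input. The round-trip identity holds to 1e−9 across the
domain and SDS is strictly increasing in the measurement at fixed age; both
are enforced by property tests.

Two reference sets ship with the package:

* a **synthetic growth reference** (ages 0.25–18 y, four measurement kinds ×
  two sexes), smooth monotone-cubic interpolations through anchor values
  typical of a northern-European pediatric population. It is deliberately
  synthetic — national LMS tables are user-suppliable via a delimited text
  format (`measurement, sex, age, L, M, S`) and are never downloaded;
* a **Dutch-like adult height reference**, mean 184.0 / SD 7.1 cm for men
  and mean 170.6 / SD 6.3 cm for women. These constants were chosen so the
  surgical-counselling thresholds print with their conventional SDS
  equivalents at one-decimal rounding: (205 − 184)/7.1 = 2.96 → +3.0 and
  (185 − 170.6)/6.3 = 2.29 → +2.3. The synthetic height curves meet the
  adult means at age 18, so child and adult SDS scales join continuously.

SDS values are reported to 2 decimals in rendered output and kept at full
precision internally.

## Target height and adult height prediction

Tanner target height is `(FH + MH)/2 + 6.5` cm for boys and `− 6.5` cm for
girls (a fixed 13 cm sex offset). The conditional target height corrects
for parent–parent and parent–offspring height correlations:
`44.5 + 0.376·FH + 0.411·MH` (boys), `47.1 + 0.334·FH + 0.364·MH` (girls).
Neither form carries a secular-trend term. Reported (rather than measured)
parental heights are accepted unadjusted.

The **tallest parent** is the parent with the larger *adult-height SDS*,
not the larger raw height: the downstream comparison is against the child's
SDS, and a 180 cm mother is taller on that scale than a 183 cm father.

Adult height is predicted two ways:

* **De Waal regression** (default, and the only method feeding the
  epiphysiodesis screen): linear in current height, cTH SDS, CA and BA with
  a CA×BA interaction; coefficients per sex as printed in the README. The
  prediction is restricted to CA ∈ [10, 18) — the age range the regression
  is used in clinically — and is strictly decreasing in bone age over that
  range (∂PAH/∂BA = −12.98 + 0.72·CA < 0 for boys), strictly increasing in
  height and cTH SDS; a property test sweeps the CA×BA grid.
* **Bayley–Pinneau-style**: current height divided by the fraction of adult
  height attained at the current bone age. The classical three-tempo
  (average/advanced/retarded) tables are simplified to a single
  user-suppliable fraction column per sex; the packaged table is a smooth
  synthetic stand-in for testing, not a transcription of published values.
  The method systematically over-predicts in tall children and is retained
  for method comparison only.

Epiphysiodesis screening uses strict inequalities (PAH > 205 cm boys,
> 185 cm girls); a prediction exactly at the threshold is not an
indication.

## Classifier

Tall = HSDS > 2.0, strictly. The three FTS criteria are evaluated
independently, with strict boundaries matching the direction of each
printed inequality (a distance of exactly 2.0 or 1.6 falls on the
non-familial side); a missing distance makes that criterion *undetermined*,
never silently false. FTS takes precedence: CAG (BA−CA > 2.0 y) and
unexplained NFTS are only assigned when all three criteria are false, and a
tall child with no criterion satisfied and no bone age raises an error —
CAG cannot be excluded. The partition {FTS, CAG, NFTS-unexplained} is
exhaustive and mutually exclusive over tall, non-pathological inputs
(fuzzed over 10,000 random profiles).

`classify_record` treats a child routed to genetic or endocrine work-up as
"pathology suspected" and leaves the subclass unassigned by default; the
`assume_workup_negative` option applies the definitional taxonomy to every
tall child, which is the reading used when a cohort is tabulated after
work-up has come back negative.

## Flow chart

The initial branch computes HSDS and HSDS−THSDS (Tanner). Children with
HSDS ≤ 2.0 **and** distance ≤ 2.0 enter the not-tall pathway; all others
the tall pathway.

Red flags are evaluated in a fixed order (syndromic before endocrine, so
reported flag lists are deterministic; routing itself is order-independent):

* syndromic — developmental/speech delay, behavioral problems, dysmorphic
  features, disproportion (SH/H ratio SDS < −2.2, the long-legged pattern),
  macrocephaly (HC SDS > 2.0);
* endocrine — HSDS−THSDS > 2.0, growth acceleration (ΔHSDS > 1.0 over the
  available history), pubertal development inappropriate for age, signs of
  GH excess, signs of hyperthyroidism.

Missing inputs yield explicit *unevaluable* entries. Pubertal
appropriateness uses onset thresholds of 8 y (girls) / 9 y (boys) for
precocity and Tanner stage 1 at ≥ 13 y (girls) / ≥ 14 y (boys) for delay;
these are standard clinical bounds, exposed as configuration. A growth
acceleration in a child already in normal puberty is downgraded to a
**three-month follow-up** rather than immediate work-up: a pubertal height
spurt is expected, and a recheck avoids unnecessary testing.

Routing: in the tall pathway syndromic flags → genetic work-up, endocrine
flags → endocrine work-up, a downgraded acceleration → follow-up, no flags
→ ITS classification + follow-up, upgraded to adult-height counselling when
the child is over 10 and the De Waal prediction exceeds the screening
threshold. The not-tall pathway normally ends in reassurance — with a
conditional re-referral advice (girls: on reaching 170 cm before 12.5 y;
boys: 185 cm before 14 y) when a parent had delayed puberty, since such
children can still reach extreme adult heights — but endocrine flags still
route to endocrine work-up: precocious puberty can present at a normal
height, and the not-tall branch must not swallow it. Every syntactically
valid record reaches exactly one terminal (fuzz-tested), and removing a red
flag never escalates a child from a benign terminal to a work-up terminal.

### Design choices made where the design was open

* The disproportion threshold is implemented as SH/H SDS **< −2.2**
  (relatively long legs). The printed form of this rule is internally
  inconsistent as a ">" inequality — it would flag nearly everyone — and
  the long-leg reading matches its clinical purpose (marfanoid habitus).
  The symmetric alternative |SH/H SDS| > 2.2 is noted but not used.
* The growth-acceleration window is "earliest available measurement to
  now"; the criterion's period is conventionally undefined, so the window
  is exposed through which prior measurements are supplied.
* Which tempo column a Bayley–Pinneau user should take cannot be decided
  generically; the table is therefore a single column per sex.
* The tallest-parent comparison ranks parents by SDS (see above); ranking
  by cm is not meaningful across sexes.

## Cohort statistics

The 2×2 test is the **uncorrected** Pearson chi-square: on the
family-history table [[33, 33], [29, 37]] it gives χ² = 0.487, p = 0.486
(prints as 0.49), whereas the Yates-corrected test gives ≈ 0.60 — the
uncorrected convention is the one consistent with the reported comparison,
and a test asserts the corrected variant would *not* reproduce it. The
continuous two-group test is Welch's unequal-variance t (the pooled variant
differs immaterially at these sample sizes but the choice is documented);
correlation is Pearson's r with the two-sided t-transform p. All p-values
are two-sided. Summaries exclude missing values pairwise and report the
effective n per variable; an n = 1 cohort has no SD rather than a fake one.

## Synthetic referral cohort

The generator emulates the structure of a tall-stature referral clinic
population; defaults are:

| parameter | default | meaning |
|---|---|---|
| n | 132 | cohort size |
| father/mother mean (SD) | 184.0 (7.1) / 170.6 (6.3) cm | adult reference |
| assortative_corr | 0.25 | parent–parent height correlation |
| midparent_weight | 0.8 | regression of child HSDS on midparental SDS |
| residual_sd | 0.775 | chosen so the population child HSDS is ~N(0,1) |
| selection center / scale | 2.77 / 0.4 | logistic referral bias on HSDS |
| target_ba_corr | 0.45 | corr(HSDS−THSDS, BA−CA) to recover |
| ba_noise_sd | 1.0 y | bone-age rating noise |
| pathology_rate | 0.015 | injected precocious-puberty phenotypes |
| age | N(10.9, 3.2) truncated to [0.5, 16.9] y | referral age |
| puberty onset | N(11.0, 1.1) girls / N(11.5, 1.1) boys | timing |

The referral bias is a logistic acceptance probability in the child's HSDS,
calibrated numerically (against the standard-normal population density) so
the *median* HSDS of the retained cohort is 2.0 — i.e. about half of
referred children are not tall. The bone-age coupling is solved from the
requested correlation: with `x = HSDS − THSDS`,
`coupling = r/√(1−r²) · σ_noise/σ_x` using the cohort's empirical σ_x, so
the configured correlation is recovered within Monte-Carlo error
(±0.05 at n = 2000, verified over 20 replicates). A requested |r| ≥ 1 is a
configuration error. Injected pathological children always carry a
reported pubertal onset below the precocity threshold plus a growth
acceleration, so by construction the flow chart never misses them (the
endocrine-work-up fraction is ≥ the pathology rate).

One seeded generator drives every draw; serialized cohorts are
byte-identical across runs for a fixed seed and configuration.

**What the simulator does not emulate:** longitudinal growth trajectories
(each child has at most one prior point), syndromic phenotypes (syndromic
flags are never injected), secular trends, measurement rounding error
beyond output formatting, and referral behavior unrelated to height.
Passing tests therefore demonstrate the *internal consistency* of the
rules and the recoverability of the configured statistical structure — not
the clinical sensitivity or specificity of the flow chart on real referral
data, which would require a prospective cohort.

## Problem sizes and numerical conventions

Default test and acceptance runs use cohorts of 500–2000 children and
fuzz suites of 1,500–10,000 cases, which keep the full suite under a
minute on one core while leaving Monte-Carlo error well inside the asserted
bands. Tolerances: LMS round-trip 1e−9; oracle equivalence of profile
fields 1e−9; correlation recovery ±0.05; calibrated not-tall fraction
±5 percentage points. Ages are decimal years and are never rounded before
formula evaluation; ties at every clinical threshold resolve to the
non-flagged side.
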