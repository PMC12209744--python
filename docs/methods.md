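# Methods

`ifnstrat` implements a time-to-clinical-worsening (TTCW) analysis for
limited cutaneous systemic sclerosis (lcSSc): a serum type-I interferon
(IFN) score splits patients into high/low activation groups, a composite
"Morbi-mortality" endpoint is adjudicated from longitudinal visit records,
and the groups are compared with standard survival machinery.  Because the
motivating cohort's patient-level data are not publicly deposited, the
package ships a synthetic cohort generator whose defaults encode the
published summary statistics; every analysis stage is exercised and tested
against that stated world.

## The IFN score and its threshold

The score of a serum sample is the mean of the natural logarithms of six
chemokine concentrations (CCL2, CCL8, CCL19, CXCL9, CXCL10, CXCL11, in
pg/mL):

    score = (1/6) * sum_i ln c_i

It is dimensionless, permutation-invariant in the analytes, and shifts by
`ln k` when every concentration is multiplied by `k`.  The "high" boundary
is the healthy-control mean plus two standard deviations.  Choices the
source material leaves open, fixed here:

* the control SD uses the sample (n-1) denominator — standard for a
  72-subject reference sample;
* "above" is strict (`score > threshold`); ties classify low.  The score is
  continuous, so the tie set has measure zero and the convention is
  immaterial in practice;
* the threshold is always derived from control data at run time, never
  hard-coded.  Rounded published control statistics (mean 4.97, SD 0.27)
  give 5.51; the published threshold prints as 5.50, consistent to the
  displayed precision.

## Endpoint adjudication

TTCW is the time from the serum-sample baseline (month 0) to the first of:
SSc-related death; new right-heart-catheter-confirmed PAH (only for
subjects without PAH at baseline); new/progressive ILD; a major cardiac
complication (EF < 45%, haemodynamically relevant pericardial effusion,
treated arrhythmia, or device need); scleroderma renal crisis; severe GI
failure (enteral nutrition >= 3 weeks, any parenteral feeding, or admission
for (pseudo-)obstruction); severe digital vasculopathy requiring
hospitalization; or skin worsening (mRSS increase >= 5 units **and** >= 25%
over baseline, both inclusive; a baseline of 0 qualifies on the absolute
rule alone).  Death unrelated to SSc censors the subject at that visit;
otherwise censoring falls at min(last visit, 120 months).

Conventions where the published rules under-determine the computation:

* **ILD windows.** "An absolute FVC% drop of >= 10% in 12 months" is read as
  a rolling window: every ordered visit pair at most 12 months apart is
  scanned, not only baseline-anchored pairs.
* **DLco.** The companion rule (FVC drop of 5–9 points plus a 15% DLco
  reduction) treats the DLco decline as *relative* between the same visit
  pair, the usual ILD-progression convention.
* **Minor band.** FVC is continuous, so the published 5–9 point band is
  implemented as `5 <= drop < 10`; a drop of 9.5 points is not lost between
  the bands.
* **Ties.** Simultaneous qualifying events are broken by a fixed severity
  order (death > PAH > ILD > cardiac > renal > GI > digital > skin).  Real
  cohorts essentially never produce exact ties; the order only pins down
  determinism.
* **Confirmation.** No confirmation at a subsequent visit is required; the
  first qualifying measurement is the event.

Adjudication is deterministic, idempotent, and invariant to the input order
of visit rows.  The five-year sensitivity filter keeps subjects with an
observed event or at least 60 months of event-free follow-up (it drops
exactly the subjects censored before 60 months).

## Survival analysis

Kaplan–Meier estimation, its Greenwood variance, the restricted mean
survival time (RMST) and the two-group log-rank statistic are implemented
directly (the fixed-time contrasts and the RMST difference need the
per-step Greenwood variances, which packaged KM fits do not expose);
`lifelines` and R's `survival` serve as independent cross-checks in the
test suite.  Conventions:

* censorings tied with an event time remain at risk for that event;
* fixed-time contrasts use the plain difference in KM estimates with the
  summed Greenwood variances (a `cloglog`-scale variant is available but
  off by default);
* RMST comparisons truncate at the smaller of the two groups' maximum
  observed times; the variance is the Greenwood-weighted plug-in
  `sum_i A_i^2 d_i / (n_i (n_i - d_i))` with `A_i` the area under the curve
  beyond `t_i`, and the groups are treated as independent;
* "event probability" always means `1 - S(t)`.

## Cox modelling and discrimination

Fits go through `lifelines.CoxPHFitter` with Efron tie handling (visit-grid
data generate ties).  The smooth IFN term uses a natural cubic spline basis
with 4 total degrees of freedom (knots at quantiles, boundary at the data
range); the nonlinear basis columns are orthogonalised against the linear
column, so the coefficient on the raw score is exactly the linear-component
log-HR, and nonlinearity is tested by a likelihood-ratio test of the spline
model against its linear restriction.  This replaces a penalized spline
with AIC-chosen smoothing: at the event counts this design targets (~50),
a fixed small basis is statistically equivalent and keeps the
linear/nonlinear split exact.  Monotone partial likelihoods (complete
separation) are detected from the optimizer's diagnostics, flagged, and
refit with a light ridge penalty so the reported coefficient is finite.
Zero-variance covariates are dropped as neutral (HR 1) in exploratory fits
and raise a collinearity error in the pre-specified multivariable models.

The univariable screen fits one model per covariate and corrects its
p-values with Benjamini–Hochberg.  The two pre-specified multivariable
models are (1) spline IFN score and (2) IFN class, each adjusted for
baseline ILD, PAH, mRSS, DU disease and age.

**Time-dependent ROC.**  The incident/dynamic convention used here: at each
event time the cases are the subjects failing exactly then, the controls
those still at risk afterwards, and the risk-set AUC is the rank
concordance of cases versus controls.  `AUC(t)` reported at a horizon is
the comparable-pair-weighted average of risk-set AUCs over event times up
to `t`, and the C-index is the same average over all event times.  All
three are invariant under strictly increasing marker transformations, equal
1 for a perfect marker and 0.5 in expectation for an uninformative one.
The exact weighting used by the R packages in this literature is not
documented; the tests therefore assert these invariances rather than
numerical agreement with opaque defaults.  Standard errors come from a
seeded subject-level bootstrap stratified by event status (1,000 iterations
by default).

## Stratification and relative risk

Clinical involvement: *acral* = mRSS strictly greater than 4 or DU disease;
*cardiopulmonary* = baseline PAH or ILD; *dual* = both; *none* otherwise.
Crossing with the IFN class yields eight strata (upset-plot counts and
event rates are emitted, flagging strata above a 50% event rate).  The
*high-risk* group is "at least one involvement AND IFN-high"; everyone else
is low-risk.  Relative risk versus the whole cohort at a horizon is the
ratio of KM cumulative incidences.  Because each group is a subset of the
cohort the two estimates share subjects: reported CIs default to a
subject-level bootstrap that respects the overlap; an
independence-assuming delta-method CI on log-RR is available (and used in
high-volume simulation tests) as a cheap approximation.

## Trial power design

The required event count uses the Schoenfeld closed form
`ceil[(z_{1-a/2} + z_pow)^2 / (p(1-p) ln^2 HR)]`; per-arm sample sizes
divide the events by the allocation-weighted event probabilities, with the
arm-2 probability derived from the control incidence by the
proportional-hazards transform `P2 = 1 - (1 - P1)^HR`; a censoring
allowance inflates the total multiplicatively with a final ceiling.  At the
published design settings (HR 2.0, two-sided 5%, 80% power, 40% control
incidence) the transparent closed form requires 66 events; published
designs computed with accrual-model software (gsDesign-type) can print
smaller event counts (42) for the same nominal inputs because they model
accrual and follow-up explicitly.  No attempt is made to reproduce that
internal model; only the censoring-inflation arithmetic (112 -> 140 at 25%)
is treated as exactly reproducible.

## The synthetic cohort: what it does and does not emulate

Defaults are the published summary statistics: 72 controls with ln-score
N(4.97, 0.27²); 149 patients with score N(5.45, 0.46²) (the alternative
published cohort summary 5.50 ± 0.44 is configurable; the tabulated value
is the default), which puts ~45% of patients above the ~5.51 population
threshold; per-chemokine ln values equal to the subject score plus fixed
analyte offsets calibrated to the published patient means plus mean-zero
noise (SD 0.40) constrained to preserve the score exactly; baseline
prevalences and continuous moments from the published cohort table;
6-monthly visits; administrative censoring from staggered entry modelled as
a truncated normal (median 89, IQR 9, range 48–120 months).

The latent first event is exponential with a log-linear hazard.  The IFN
effect defaults to the published *design* hazard ratio 2.0 on the IFN-high
indicator.  The published *observed* group contrast (HR 5.5–6.2, ten-year
event fractions 55% vs 12%) is much larger than HR 2.0 can produce on its
own; rather than silently inflating the IFN coefficient, the default
hazard also carries clinical-covariate effects mirroring the published
multivariable associations (ILD HR 3.0, PAH 3.5, DU disease 1.8, mRSS 1.12
per unit).  The baseline rate (0.00132/month) was calibrated once by
simulation so the marginal ten-year event fraction matches the published
~32%, and then frozen.  Consequences: the synthetic IFN-high/low contrast
is *qualitatively* like the published one (high group always worse on
average) but *quantitatively* smaller, so single-cohort replicates at
n=149 can show statistically weak IFN separation — as the design value HR
2.0 implies at that sample size.  Green tests therefore establish
correctness and calibration of the machinery (parameter recovery, CI
coverage, type-I error), not a reproduction of the published effect sizes.

Event realization: the drawn event type is materialized in the visit stream
so that exactly the intended adjudication rule fires at the event visit —
an ILD truth drops FVC by 12 points at the event visit, a skin truth raises
mRSS by `max(5, ceil(0.25 * baseline))`, flag truths set the corresponding
visit flag; between-visit FVC/DLco noise (SD 1.2/2.0) is small enough that
spurious rule firings have negligible probability, and mRSS is otherwise
held constant.  Subjects with baseline PAH never draw a PAH event (the
endpoint requires *new* PAH).  The event-type mix follows the published
first-event distribution.  Not emulated: longitudinal drift of the IFN
score itself, treatment effects, informative censoring, missing visits,
measurement error in event capture, and non-SSc deaths (the generator's
default world has none; the adjudicator still handles the flag).

All randomness flows from `numpy.random.default_rng` seeded with
`(seed, replicate, stream)`; identical configurations reproduce identical
tables byte-for-byte.

## Numerical choices and degenerate inputs

Cox fits run Newton–Raphson to precision 1e-12 (the partial-likelihood
oracle tests compare at 1e-6).  `derive_threshold` requires two controls
and warns on zero variance (threshold = mean).  KM contrasts refuse
timepoints beyond either group's observed support; the cloglog transform
drops S in {0, 1} and judges parallelism only on the stable mid-range
S in [0.1, 0.9] (default flag threshold: maximum offset deviation > 0.4).
`censoring_inflation` rounds before the ceiling so that binary float
artifacts (100 x 1.1 = 110.000...01) do not inflate by one.  Empty visit
streams adjudicate to censoring at 0 with a warning.  The RR of a group
against a cohort with zero incidence at the horizon is refused rather than
returned as infinity.

## Known limitations

* The generator's trajectories are deliberately clean; adjudication
  performance on noisy real-world lung-function series is not established
  by these tests.
* RMST and fixed-time inference use normal approximations on the survival
  scale; very small risk sets near tau will be anti-conservative.
* The delta-method RR interval ignores group/cohort overlap (the bootstrap
  default does not).
* The td-ROC convention is one member of the incident/dynamic family;
  numbers are comparable across runs of this package but not guaranteed to
  match other implementations' weights.
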