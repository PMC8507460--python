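# Methods

This note documents the estimation procedures, the synthetic-data model, the
defaults and the numerical conventions implemented in `popdose`, and what the
test suite does and does not demonstrate.

## Examination construction

An examination is one or more exposures of an anatomical region with a
single modality during a single visit. "Visit" is not observable in billing
data; we operationalize it as one calendar day at one facility, the coarsest
defensible session key. Invoice lines are grouped by
(patient, facility, date, modality, region); repeated identical codes in a
session collapse into one examination with `n_source_codes` recording the
absorbed lines, so the sum of `n_source_codes` always equals the number of
mapped invoice lines (a tested conservation law).

Combined-region CT sessions are an increasingly common practice and are
billed as separate component codes. Merge rules (default: chest + abdomen →
"chest and abdomen") therefore apply *within CT sessions only*: when all of
a rule's components are present, the component examinations — and any
pre-existing examination already carrying the merged label — are replaced by
one combined examination. The policy is explicitly greedy and
non-transitive: with chest+abdomen+pelvis present and only the
chest+abdomen rule configured, pelvis stays separate. Two applicable rules
sharing a component raise an ambiguity error rather than picking an order.
Code maps are total by contract; a strict/lenient flag decides whether
unmapped codes abort or are dropped with a warning.

Verification against the RIS reports, per modality and in total, the
relative difference (billing − RIS)/billing × 100, anchored on the billing
figure so that published verification tables are reproduced exactly; a
modality absent from the billing side yields an undefined (NaN) difference,
not an error.

## Frequency estimation

Three source channels feed the frequency table, with the authoritative
channel configured per modality (billing for radiography, CT, diagnostic
mammography and interventional procedures; professional-society reports for
screening mammography and cardiology; web survey for dental, CBCT and
nuclear medicine):

* **Billing**: national = observed / factor. Two factors are first-class and
  reported side by side: the covered population fraction (0.107 by default)
  and an activity ratio (0.101), i.e. the imaging-to-general-medical
  activity ratio under the hypothesis that imaging indication is homogeneous
  nationally. The activity ratio is exogenous configuration — its derivation
  requires general-medical activity data that the survey context does not
  make reproducible.
* **Web survey**: national = responding count / response rate (defaults
  29.1% dental, 27% CBCT, 94.1% nuclear medicine, 18.1% diagnostic
  mammography).
* **Society reports**: taken as complete (handled as the survey channel with
  rate 1).

Frequencies are per 1000 inhabitants with the population an explicit
parameter (national surveys rarely state their denominator; nothing in the
pipeline depends on a hard-coded one). Presentation rounding (one decimal)
happens only at render time.

## CT dosimetry

Per region, the median DLP is computed pooled and per practice stratum
(university vs non-university), median convention: mean of the two central
order statistics for even counts. Effective dose is k × median DLP with
region-specific conversion coefficients. The shipped coefficient table is
illustrative adult configuration — national coefficient sets are external
publications and deliberately not re-derived — and is overridable; every
dose output scales linearly in it (a tested invariant).

The CT dose vector is the frequency-weighted mean of per-region doses, with
weights from the billing-derived region frequencies. The central estimate
uses the pooled medians; the strata enter only through the uncertainty:
recomputing the vector with each stratum's medians (pooled fallback where a
stratum has no records for a region) gives per-stratum estimates whose
sample standard deviation (n−1) over mean is reported as the relative
uncertainty. On the published 2018 stratum estimates {6.73, 7.5} mSv this
ratio is 7.7%, rounding to the reported ~8%; with a single stratum it is
reported as absent rather than zero.

Recomputing the vector from the published per-region table gives 7.18 mSv
against the printed 7.1: the printed per-region doses are rounded to 2–3
significant figures, so the recomputed value legitimately differs in the
second digit. The printed per-region contribution column is likewise treated
as approximate; contributions are always recomputed from the inputs.

## Non-CT dose vectors and nuclear medicine

Radiography, mammography, dental and interventional vectors are exogenous
literature/DRL values carried with mandatory provenance strings; assembly
never rescales them (bit-for-bit pass-through, tested). The nuclear-medicine
vector is Σ share × (activity × coefficient + DLP × k for the co-acquired
CT, whether attenuation-map or diagnostic). The shipped two-procedure mix
(bone SPECT-CT, FDG PET-CT) is *illustrative*: it is calibrated so the
modality vector equals the 2017 national reference value of 8.04 mSv, since
no per-procedure national mix is published. Explicit per-modality overrides
win over every channel and are flagged in provenance.

## Survey result and trends

Dose per inhabitant is Σ_m f_m Ē_m / 1000, additive by construction.
Contribution shares use the nuclear-medicine-inclusive totals as
denominator; the headline dental frequency share pools plain dental
radiography with CBCT (the convention under which the published 47.89%
reproduces). Trend changes are (new − old)/old × 100 on the earlier survey;
dose-per-exam changes compare dose/inhabitant ÷ frequency × 1000. Overall
changes use the without-nuclear-medicine totals, matching the scope of
published trend tables. Modalities present in only one survey are kept with
absent changes. All rounding is render-time only; note that totals of
rounded parts can differ from rounded totals in the last printed digit
(1.379 vs a printed 1.378), which is why reproduction checks carry a
±0.005 mSv slack.

## Synthetic-data generator

The generator's defaults *are* the 2018 survey conditions: per-modality true
frequencies equal the published per-1000 values; the CT region mix follows
the published CT table, with the chest+abdomen combination emitted as
co-billed component codes at rate 22.1/134.9 of CT sessions; billing covers
10.7% of national volume; response rates are the published ones.

Structural choices:

* **Counts** are Poisson per facility (independent across facilities), with
  expectation frequency × population/1000 allocated by facility volume
  share — a simple, variance-honest null for recovery tests.
* **Facilities**: 5 university (45% of volume), 18 regional (35%), 300
  private practices/centres (20%). The high university share makes the
  stratum mixture's pooled chest median consistent with the published
  pooled 3.8 mSv given the published 2.9/4.7 mSv per-stratum values. Dental
  imaging and CBCT are routed 90/10 to private/regional facilities and
  nuclear medicine 50/50 to university/regional, mirroring the real
  installation registry; with dental concentrated in a few large hospitals
  the response-rate estimator would carry an unrealistic ~35% design error.
* **Coverage** is a deterministic greedy facility selection approaching the
  target volume fraction; the realized fraction is exposed and used by the
  analysis, as a real analyst would establish it from the covered panel.
* **DLP** is log-normal per (region, stratum) — standard for dose-indicator
  distributions and making configured medians exact parameters — with
  σ_log = 0.5 and medians set to (reference median dose)/k so the configured
  truth is self-consistent with the default conversion factors. Only chest
  differs by stratum by default.
* **RIS discrepancies** are symmetric by default (half deletions, half
  duplications at a 5% rate; the split is configurable), so billing-vs-RIS
  differences are centred on zero in the null.
* **Reproducibility**: one `SeedSequence` per bundle spawns a deterministic
  sub-stream per table; identical (config, seed) gives byte-identical
  bundles.

What the generator does *not* emulate: patient age/sex structure and
size-dependent dose, per-scanner protocol variation, seasonal patterns,
informative non-response (response is independent of facility volume), and
real billing-code taxonomies (codes are synthetic one-per-(modality,
region)). Passing recovery tests therefore demonstrate the correctness of
the estimation chain under the stated sampling model, not robustness to
those real-data features.

## Verification strategy and problem sizes

Recovery tests compare estimates against configured truth within 3 design
standard errors with fixed seeds. For billing modalities the SE is the
Poisson form √(1000 f/(pop·c)); for surveyed modalities the design variance
includes the Bernoulli facility-response term, which dominates when few
facilities carry the volume — using the bare Poisson SE there would be
simply wrong, not conservative. The expected CT chest dose under the
stratum mixture is computed in the tests by numerically solving the mixture
median (Brent root-finding on the mixture CDF), independent of the package's
estimator. Examination grouping is checked against an exhaustive
plain-Python oracle, exactly on ≤20-line property-based inputs.

Test problem sizes (population 200 000–500 000; 1 000 000 in the acceptance
script) are chosen so that every per-(region, stratum) median check has
≥2000 records and the whole suite completes in well under a minute, while
keeping 3-SE recovery bands meaningful.

## Known limitations

* The activity-ratio extrapolation factor and all non-CT dose vectors are
  exogenous: the package propagates, but cannot validate, their values.
* The uncertainty treatment mirrors survey practice (verification
  differences for frequency, stratum spread for CT dose) and is
  deliberately not a full error propagation.
* Session identity by calendar day cannot distinguish two genuine clinical
  questions for the same region on the same day (undercount), nor link
  visits spanning midnight (overcount); both effects are far below the
  design error at survey scale.
* With merge rules whose components coincidentally co-occur for unrelated
  clinical questions, merging slightly undercounts; at published combination
  rates this is negligible but it is a structural assumption, not a bug.
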