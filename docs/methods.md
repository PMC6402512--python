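# Methods

## The estimator

The analysis regresses the natural log of the age-band incidence rate
on the natural log of a band age point by unweighted ordinary least
squares. The slope estimates *n* − 1, the number of rate-limiting
steps completed during life before the final, manifesting step; the
intercept estimates c = ln(Πλₖ) up to the units of the rate; adjusted
R² = 1 − (1 − R²)(k − 1)/(k − 2) over k bands is the linearity
diagnostic. The 95% CI for the slope uses the t distribution with
k − 2 degrees of freedom. The step count is round(slope + 1), halves
away from zero — the only rounding convention consistent with every
published slope/step pair we checked (e.g. 12.82→14, 8.92→10,
15.02→16, 11.72→13).

**Band construction.** Half-open bands [l, l+w) on the grid
{origin + k·w}, default w = 5 y and origin 0, giving the conventional
epidemiologic categories [45,50), [50,55), …. A participant
contributes the overlap of [entry, exit) with each band; the event is
counted in the band containing the exit age, which for an exit exactly
on a boundary is the upper band (half-open convention) — the one case
where a band can hold an event without person-time from that subject.
No continuity correction is applied to zero-event bands; the rate
filter removes them before any logarithm is taken.

**Band filter.** Bands with person-years < 500 or incidence rate
< 1/1000 per person-year are excluded before fitting; both thresholds
are inclusive minima (a band at exactly 500 py or exactly 0.001/py is
retained), keeping the printed thresholds meaningful as minima. The
exclusion report counts the person-years dropped and the participants
whose exit age falls below the first retained band. Fewer than three
retained bands is an insufficient-data error: a line cannot be
meaningfully assessed on two points.

**Age point.** Which abscissa represents a 5-year category is
genuinely open; the default is the band midpoint (62.5 for [60,65)),
with the lower bound and the person-time-weighted mean age selectable.
On simulated power-law cohorts the midpoint convention leaves the
slope asymptotically unbiased (4.99 at N = 2×10⁶ for a 6-step truth).

**Poisson mode.** `fit_loglog(..., method="poisson")` replaces the OLS
with a Poisson log-link regression of band event counts with a log
person-years offset. It is a sensitivity analysis only — the primary
estimator is the unweighted OLS — and it reports no R².

## Genetic stratification

APOE ε4 carriers are participants with ≥ 1 ε4 allele; (ε4, ε4) is a
homozygote, (ε2, ε4)/(ε3, ε4) heterozygotes. The weighted genetic risk
score is Σ dosageᵢ·βᵢ over 23 AD-associated variants excluding APOE,
matched by variant id (never by column position); any missing dosage
makes the score missing and excludes the participant from GRS strata.
Tertile cuts are the empirical 1/3 and 2/3 quantiles of the analysed
(complete-data) population, computed once and shared by the combined
APOE × tertile scheme (mutually exclusive categories; re-cutting
within APOE strata is the documented alternative, not used). Scores
exactly at a cut go to the lower tertile — deterministic, never
random. Zygosity rows are flagged exploratory: homozygote strata are
small and their fits unstable.

Each stratum is fitted completely independently, including re-applying
the band filter, so strata with different age-incidence profiles keep
their own usable age ranges. A stratum that fails the filter becomes a
flagged row rather than an error.

The packaged 23-variant weight file is **synthetic**: the variant ids
are real AD-associated loci but the betas are illustrative values, and
the file exists so the scoring machinery is runnable end-to-end.
Dosages are assumed pre-oriented to the effect allele.

## The generative model

The simulator draws, per subject: a genetic stratum (defaults: 28%
ε4 carriers, 2.8% homozygous — frequencies typical of the
European-ancestry elderly cohorts this analysis targets), an onset
age, an entry age, and a censoring age. Genetic risk is modelled as
steps inherited at birth: a stratum with deficit k runs an (n − k)-step
chain (defaults: heterozygotes k = 2, homozygotes k = 4, matching the
published ordering of carrier step counts). Left truncation is by
rejection — subjects with onset before entry are redrawn — exactly
mirroring a cohort that excludes prevalent cases at baseline.
Competing censoring is a single exponential mortality clock from entry
(default 0.02/y) plus an administrative end of follow-up (default age
100); entry is uniform on [45, 85] y.

Two onset-age modes:

- **hypoexponential** (default): the onset age is the sum of n
  independent exponential waiting times — the exact law of one
  sequential chain. Equal rates give a gamma distribution, which is
  the closed-form oracle used in tests.
- **powerlaw**: onset is drawn by inverting the cumulative hazard
  H(t) = (Πλ)tⁿ/n!. This is the rare-event, many-independent-chains
  limit in which incidence is exactly ∝ t^(n−1).

The distinction matters and is deliberate. The log-log estimator
targets the power-law limit; the exact single-chain law only obeys it
while λ·t ≪ 1. At the calibrations used for recovery experiments
(e.g. 20% cumulative risk by age 100 with 14 equal rates), the
single-chain hazard is already saturating at observed ages (λ·t ≈ 5–10)
and its local log-log slope is ≈ 4–6 rather than 13 — a model-error
regime, not an estimator defect. Recovery, CI-calibration and
deficit-ordering experiments therefore simulate in power-law mode,
where the estimand is well-defined; the hypoexponential mode is kept
as the default generative mode precisely so that the gap between the
two can be studied.

`calibrate_rates(n, target, horizon)` converts "X% cumulative risk by
age Y" into equal per-step rates, solved by bracketed root-finding on
the gamma CDF (hypoexponential) to 1e-12 relative, or in closed form
for the power-law mode.

**Reproducibility.** One global seed is split into named substreams
(zygosity, e2 assignment, dosages, mortality, and one per truncation
redraw round and step-count group), with every draw laid out in
subject order. Consequence: enlarging `sample_size` reproduces the
original subjects as an exact prefix, and identical parameters give a
byte-identical cohort file.

**What the simulator does not emulate.** Diagnostic misclassification,
screening artifacts, calendar-period effects, a realistic life table
(mortality is a single exponential), linkage disequilibrium between
the score variants, or any dosage-level effect of the 23 variants on
onset (the score's machinery is under test, not a per-variant disease
model). Passing recovery tests therefore shows the estimator recovers
truth under its own assumptions — not that those assumptions hold in
any real cohort.

## Validation and known limitations

The suite validates each stage against an independent oracle: accrual
against a 0.001-year interval-walking accumulator (within 0.002
y/band); OLS against the closed-form normal equations (1e-12
relative); the hypoexponential sampler against its analytic moments
(Σ1/λₖ, Σ1/λₖ²) and, for equal rates, the gamma CDF (KS < 0.01 at 10⁵
draws); rate calibration against the gamma CDF round trip.

End-to-end, a 14-step power-law cohort of 2×10⁵ subjects is recovered
to within ±2 steps in 10/10 seeds, and a carrier stratum given a
2-step deficit at n = 12 ranks below the non-carrier stratum in 10/10
seeds (10⁵ subjects per stratum). Problem sizes for the replicated
experiments (N between 5×10⁴ and 2×10⁵, 10–200 replicates) were chosen
as the smallest at which band-level rates are stable through the
500-py/0.001-rate filter.

Two caveats the experiments themselves expose:

- **CI under-coverage.** At n = 6, N = 5×10⁴, 200 replicates, the
  nominal 95% slope CI covers the true slope ≈ 87% of the time. The
  homoscedastic OLS interval understates the slope variance because
  Poisson log-rate noise is largest in the sparse low-age bands, which
  also carry the highest leverage; additionally, a band whose true
  rate sits just below the 1/1000 threshold enters the fit only when
  noise lifts it over, a selection that biases the first point upward.
  Both effects are properties of the published estimator (unweighted
  OLS after threshold filtering), not of the implementation: the
  slope itself is asymptotically unbiased. Confidence intervals from
  this estimator should be read as approximate.
- **Mixture flattening.** A whole-population fit over genetically
  heterogeneous strata (carriers with inherited steps mixed with
  non-carriers) yields a slope below every stratum-specific exponent;
  whole-population step counts under genetic heterogeneity are
  best interpreted jointly with the stratified table.
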