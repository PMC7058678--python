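# Methods

## Model

`wardsim` simulates a network of hospital wards in discrete time, one day
per step, with the midnight bed census as the state of interest.  The model
is an infinite-server queueing network: a ward admits every patient who
arrives, and ward capacities are used only to report the probability that
demand exceeds them.  This deliberately excludes turn-away, outlier
placement and other congestion behaviours; the model answers "what will
demand be?", not "what will management do when demand exceeds supply?".

Per day and ward, emergency admissions are a random count drawn from an
empirical per-weekday distribution; elective admissions are deterministic
decision variables (a schedule), optionally thinned by an independent
non-attendance probability (default 0).  Each admission draws a ward length
of stay `T` (WLOS, in midnights, minimum 1) from the empirical distribution
for its (ward, admission type, weekday of arrival at the ward).  When a
stay ends the patient is discharged or transferred according to a
row-stochastic matrix per admission type; transfers happen at day
boundaries, occupy only the destination ward at that midnight, and draw a
fresh WLOS conditional on the destination ward and the transfer-day
weekday.  Transition probabilities depend only on the current ward and
admission type (a first-order, memoryless chain over wards), and the
admission type is carried unchanged through the spell.

### Date and counting conventions

Days are calendar dates; a stay `[arrival, departure)` is half-open, so a
patient is present at midnight `t` iff `arrival <= t < departure` and the
WLOS equals `departure - arrival`.  Spells whose hospital admission and
final discharge fall on the same calendar day never span a midnight and are
excluded from the census, the snapshot and all estimators — at spell level,
so a same-day transfer segment inside a multi-day spell is kept.  Within a
simulated day, departures and transfers resolve before the census is
recorded and the day's arrivals are included in it, so each patient counts
exactly once per midnight.

## Estimation

All simulator inputs are estimated empirically, without smoothing:

* **Ward selection.**  Wards ranked by mean midnight occupancy; the
  shortest prefix covering 90% (configurable) of total mean occupancy is
  modelled individually, the rest are pooled into a pseudo-ward `Other`, so
  the population is captured entirely while modelling effort concentrates
  on the significant wards.
* **Arrivals.**  Per (ward, weekday), the empirical pmf of the daily count
  of emergency hospital admissions at that ward (transfers are produced by
  the transition process, not the arrival process); days with no arrivals
  contribute zeros.
* **WLOS.**  Per (ward, type, weekday of ward arrival), the empirical pmf
  of `departure - arrival` over closed stays.  Sparse strata fall back
  through the pooling ladder (ward, type, weekday) → (ward, type) →
  (ward) → global; the first non-empty level supplies the pmf.  The
  weekday condition uses arrival at the *current* ward (not hospital
  admission) because WLOS is a per-ward quantity; the same convention is
  used for snapshot residents.
* **Transitions.**  `pi_ij^type` is the proportion of departures from ward
  `i` whose next stay in the same spell starts at ward `j` on the
  departure date; discharge is the complementary destination.  A stay
  followed by a still-open stay counts as a transfer (not a discharge);
  wards with no observed departures default to certain discharge.

## Symbiotic re-initialisation

A snapshot records, per resident: ward, admission type, ward-arrival
weekday, elapsed midnights `s = capture_date - ward_arrival_date`, and
optionally the true remaining stay (retrospectively available from closed
records, or supplied as a clinician's estimate).  Remaining stays are drawn
by inverse transform from the conditional distribution
`F_R(r, s) = (F_T(s+r) - F_T(s-1)) / (1 - F_T(s-1))` with `F_T(-1) = 0`.

One counting subtlety matters.  Presence at the capture midnight implies
`T >= s + 1` under the half-open convention, so the engine conditions a
resident's residual at `s + 1` and interprets the draw as the number of
midnights still to be spent *after* the capture midnight (0 = departs at
the next boundary).  Conditioning at `s` instead would give positive mass
to the already-contradicted event `T = s` and systematically shorten
resurrected stays — for geometric(0.4) WLOS by about 0.6 nights per
resident — biasing every downstream census low.  With the convention used
here, a resident with `s = 0` draws bit-identically to a fresh admission
given the same uniform (a tested invariant), and a resident's known true
remaining stay slots in exactly.  Residents whose elapsed time exceeds the
empirical support (long-stayers unseen in training data) are clamped to
the largest supported elapsed time and kept in-system, with a log warning.

Day 0 of a snapshot-initialised run reproduces the captured census exactly
and generates no arrivals (the snapshot already reflects that midnight);
dynamics start at day 1.  Decision-support reports exclude day 0, since the
state there is given rather than predicted.

## Random-number discipline

Each replication derives its stream from `(seed, replication)` via numpy
`SeedSequence`, making every run bit-reproducible.  In common-random-number
(CRN) mode each entity — arrival-count cell, emergency patient, elective
slot, snapshot resident — gets its own stream keyed by its identity, so
schedule variants differing in a few elective slots share every other
random outcome pathwise; schedule comparisons and the discharge-estimate
experiment use this mode.  Defaults: 100 replications for validation runs,
400 for decision support (the level at which occupancy distributions were
observed to stabilise).

## Validation: the delta-method

The re-initialised model's output distribution is a function of the time
`h` since initialisation, so ordinary long-run comparisons do not apply.
The delta-method pools observed changes `delta_{t,h} = M_t - M_{t+h}` over
all `N - h` day pairs, and simulated changes `M_{t0} - Mhat_{t0+h}` over
(weekly initiation points of a chosen weekday) x (replications), per ward
and per `h = 1..6`, then compares the two empirical CDFs as a P-P plot.
The maximum absolute deviation from the identity is reported as a
convenience summary; it is not a test statistic with a null distribution.
At `h = 0` the two pools coincide by construction (the collapse property).
Elective admissions observed in the records during each window are
replayed as that window's schedule.  Prediction-interval coverage uses
linearly interpolated empirical percentiles across replications, with
endpoint ties counted as covered, pooled over wards and non-initiation
days.  The weekday-mean check compares the observed trajectory's weekday
mean per admission type with the central band of per-replication weekday
means: a band across replications, not a confidence interval for the grand
mean, because the observed series is a single trajectory and should fall
inside such a band about 90% of the time under a correct model.

## Synthetic hospital

The generator produces ward-stay records and live snapshots from exactly
the process the simulator implements, with known parameters, so every
stage can be checked against ground truth.  Three bundled configurations:

* `default()` — a small acute hospital (4 wards, weekday-dipped emergency
  arrivals, weekday elective lists, geometric WLOS with means ~2.5-10
  nights, light transfer traffic to a rehabilitation ward).  Arrival
  counts default to Poisson per weekday (closed-form test oracles);
  explicit pmf tables are also supported.
* `recovery_scenario()` — a high-volume two-ward system sized so each
  (ward, type, weekday) WLOS stratum holds ~10,000 closed stays, putting
  each pmf point's binomial standard error near 0.005 so a ±0.02 pointwise
  recovery band is a ~4-sigma statement across all strata simultaneously.
  (At a few tens of thousands of total departures split across 28 weekday
  strata, that band would be a <2-sigma per-point event — unattainable for
  any unbiased estimator — so recovery is demonstrated at a volume where
  it is decisive.)
* `validation_scenario()` — a weekday-homogeneous, slowly mixing long-stay
  two-ward network (geometric WLOS, mean ~33 nights, ~100-bed wards,
  20,000 observed days) for delta-method self-checks.  Two a-priori
  considerations drive this choice.  First, the simulated delta pool mixes
  over a limited number of initiation states; each state shifts the
  conditional delta distribution by ~`(1 - (1-p)^h) * sd(M)`, adding
  state-sampling noise of order `0.4 * sqrt(h*p/2) / sqrt(#initiations)`
  to the P-P coordinates.  With 50 Monday initiations and acute LOS
  (p ≈ 0.2-0.3) that noise alone reaches 0.05-0.07 — indistinguishable
  from genuine misspecification — whereas at p = 0.03 it stays near 0.02.
  Second, the observed pool spans all weekdays while the simulated pool is
  Monday-initialised, so the two distributions differ by construction
  whenever dynamics are weekday-dependent; homogeneous arrivals make them
  estimands of the same quantity.  The scenario verifies the machinery; it
  does not claim acute hospitals look like this.

What the generator does not emulate — and therefore what green tests do
not certify about real data: seasonality and trend, case-mix and clinical
covariates, LOS dependence on occupancy, data-entry lag and coding errors
in real PA extracts, and any behavioural response to congestion.

## Numerical choices

* Inverse transform sampling everywhere: the smallest support value whose
  CDF exceeds the uniform draw (right-continuous generalised inverse).
* Empirical pmfs are validated to sum to 1 within 1e-9; probabilities are
  stored exactly as estimated (no smoothing) and serialise losslessly
  through JSON.
* Percentiles are linearly interpolated order statistics; interval
  endpoints count as covered.
* Exceedance comparisons are strict: occupancy must exceed
  `0.9 * capacity` (real-valued) or the capacity itself.
* WLOS draws are floored at 1 midnight in simulation; the census metric
  excludes same-day spells, so 0-night stays are never generated.
* Degenerate inputs: wards with no departures transition to discharge with
  probability 1; empty arrival strata are point masses at 0; a ward with
  no closed stays at all is an error rather than a guess.

## Limitations

The infinite-server assumption means predicted exceedance probabilities
describe *offered* load, not what a capacity-constrained ward would record.
The transition chain is first-order; paths with strong history dependence
(e.g. ICU round trips) are averaged.  The d-parameter experiment models
estimate quality as a Bernoulli mixture of exact knowledge and the
marginal distribution; real clinician estimates have intermediate,
correlated errors.  Delta-method summaries are descriptive — no formal
hypothesis test is attached to the P-P deviation.
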