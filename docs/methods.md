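# Methods

This note records the models, the defaults and the numerical choices
behind `circarest`, and what the synthetic validation does and does not
demonstrate about real telemonitoring data.

## Data model and preprocessing

Input is per-minute physical activity (arbitrary non-negative
accelerometry units — sensor scale is deliberately not modelled) and
chest surface temperature (°C) on a strict 1-minute local-clock grid,
with missing values explicit (never encoded as zero), plus a diary of
work intervals and questionnaire metadata.  Time is naive local clock;
daylight-saving transitions are out of scope for one-week windows.

Activity is averaged into clock-aligned 5-min bins and square-root
transformed (the scale on which Gaussian emissions are defensible for
count-like accelerometry); temperature into hourly bins for spectral
work.  A bin with at least one observed minute counts as observed (its
mean); only all-missing bins are missing.  This maximizes data use and
is harmless at the few-percent missingness the pipeline targets; the
rule is a single point of change in `cohort.resample`.

Days are partitioned into 24-h windows anchored at 00:00 for day
shifters and at the night-shift start for night shifters (21:00 when the
diary is ambiguous between 20:00 and 21:00 — the scheduled start); a
window is a workday iff a diary work interval starts inside it.
Subjects need ≥ 1 workday and ≥ 1 free day to be analysed, since the
work/free contrast is the point of the design.

## Harmonic HMM

Square-root 5-min activity is a 3-state Gaussian-emission HMM
(rest < moderate < high activity by emission mean) with time-varying
transitions: row j of the transition matrix is a multinomial logit with
the self-transition as reference and, on each non-reference logit, H
sin/cos pairs of fundamental period 24 h (H = 1 by default, 2
selectable).  The two-oscillator variant gives work and free days
separate harmonic coefficients; emissions and baseline logits are
shared, on the view that the schedule moves the oscillator, not the
states themselves.

Assumptions worth keeping in mind: Gaussian sqrt-scale emissions,
first-order Markov dependence at the 5-min scale, a smooth (single- or
two-harmonic) 24-h modulation, and missingness ignorable given the
states (missing bins contribute emission likelihood 1 to every state;
transitions still apply, so posteriors across gaps follow the chain).

Estimation is EM:

- E-step: scaled forward–backward with per-bin transition matrices
  evaluated at the source bin's clock time (numba-compiled when
  available, NumPy fallback otherwise).
- M-step: closed-form emission updates on observed bins (SDs floored at
  1e-3); each transition row is a weighted multinomial-logit fit
  (L-BFGS with analytic gradients, warm-started).  The row update
  carries a weak ridge — λ = 1 on harmonic coefficients, 0.01 on
  baseline logits.  Without it, a transition type with near-zero
  expected counts makes the weighted logit quasi-separable and its
  coefficients diverge, which in practice produced wild spurious
  oscillations on rhythmless data; against the hundreds of observed
  transitions in a week of data the penalty is negligible (recovery
  experiments show rest-row transition-curve RMSE ≈ 0.03 at 7 days,
  shrinking to ≈ 0.01–0.035 at 28 days).  Formally the fit is MAP-EM,
  and monotonicity/convergence are tracked on the penalized objective
  (|Δ| < 1e-5, max 500 iterations).
- Initialization: state means at the 25th/60th/95th percentiles of
  observed sqrt-activity, equal SDs, diagonal-dominant transitions (0.9
  self), zero harmonics; additional restarts jitter these (default 5
  restarts, best penalized objective wins).  Percentile ordering plus
  the final sort-by-mean prevents label switching.
- The initial distribution is re-estimated each iteration (configurable
  to fixed-uniform).  A constant series triggers a flagged single-state
  fallback rather than a silent degenerate fit; non-convergence flags
  the result.

Decoding is *local*: per-bin argmax of the smoothed posterior (not
Viterbi), because the circadian parameters are functionals of the
marginal posteriors, not of one best path.

## Circadian parameters

- **Rest profile**: mean posterior rest probability per 5-min clock slot
  across the scope's days; bins whose observation is missing are
  excluded from their slot's mean (their posterior is prior-propagated,
  not data-driven).  Slots never observed (rare at ~3% missingness) are
  filled with the profile mean to keep the 288-vector complete.
- **p1-1**: occupancy-weighted time-average of the realized rest→rest
  transition probability, weights = posterior rest probability; the
  unweighted clock average is available.  Weighting reflects rest
  quality *during actual rest episodes* rather than at 4 pm.
- **Rest amount**: area under the profile (h).
- **Centre of rest**: circular first moment of the profile on the 24-h
  clock — circular because night shifters' rest routinely wraps
  midnight; undefined (flagged) when the resultant is ~0.
- **Rhythm Index**: with A = rest amount and c = centre, RI =
  clip(mean inside − mean outside, 0, 1) over the circular window of
  width A centred at c.  This operationalization is a documented proxy
  chosen to satisfy the two defining boundary conditions: RI = 1 for a
  perfectly regular probability-one rest window and RI = 0 for any flat
  profile.  Flatness (undefined centre) takes precedence over the
  A = 24 edge case, so constant profiles score 0 at every level.  Two
  consequences are worth noting: RI is *not* invariant to adding a
  constant (the window width grows with A), and its value depends
  mildly on slot discretization at window edges.
- The alternative phase marker (max rest probability in 07:00–20:00,
  earliest tie wins) serves night shifters whose profile peak falls in
  the day.

## Spectral analysis

The period content of hourly temperature is estimated with a normalized
Lomb-Scargle periodogram over periods 2–40 h in 0.1-h steps —
least-squares sinusoid regression per period, hence tolerant of missing
samples — after mean removal (so the estimate is invariant to constant
shifts), lightly smoothed with a 3-point moving (Daniell-type) window.
Peaks are local maxima above a noise floor of 0.1 normalized power; at
that floor, white-noise series of one week produce a spurious peak in
well under 10% of replicates while genuine rhythms at variance-SNR ≥ 5
sit an order of magnitude above it.  Series spanning fewer than 3 cycles
of the longest grid period get a truncated grid (warned); with nothing
above the floor the dominant period is "undetectable".

Peak-period 90% CIs come from a day-block bootstrap: whole 24-h blocks
are resampled with replacement, the spectrum re-estimated, and each peak
re-located within ±25% of its original period; the 5th/95th percentiles,
widened by half a grid step for discretization, form the interval
(default 100 replicates).  Dominant periods are classified circadian
(20–28 h), circa-12 h (10–14 h) or circa-8 h (7–9 h); the circadian band
is this package's choice, the narrower bands follow the conventional
half-width readings, and all are configurable.  The spectral gravity
centre ∫p·f(p)dp / ∫f(p)dp summarises mixed 12 h/24 h content.

Ultradian analysis restricts to *rest bouts*: maximal runs of decoded
rest, merged across gaps < 10 min (decode flicker should not split a
sleep episode), kept if 2–12 h long.  Within each bout, 5-min
temperature or LIDS activity (100/(activity+1) after a 30-min moving
average; the +1 keeps zeros finite) is linearly detrended and its
dominant period found on a 0.5 h–min(6, duration/2) h grid in 0.05-h
steps; a subject's sub-period is the median over usable bouts (≥ 2 h
observed each).

## Clustering

Subjects are represented by work‖free rest profiles anchored
20:00→19:59 (576 values, probabilities — not re-standardized).  Ward
linkage on Euclidean distance (scipy); W_k is computed with squared
distances so it equals the within-cluster sum of squares Ward minimizes.
k is the largest flattening of W_k — argmax of the second difference
over k = 2..k_max−1, k_max = 8, ties to the smaller k (parsimony) — with
a flagged k = 1 when no positive curvature exists.  Cluster comparisons
use Kruskal–Wallis; singleton clusters are included but flagged.

## Copula regression

Work-day and free-day values of each parameter are paired within
subject, so the two marginal regressions (shift type as 0/1, age in
years, chronotype score, years of night work, pairwise interactions
under marginality) are bound by a copula with dependence θ.  Families:
Gaussian (default), Clayton, Frank, Gumbel, each with an unconstrained
internal parameterization; Gaussian margins with identity or log links
(identity for the log-odds responses LOP1-1 and LORI, log for rest
amount).  Centre-time responses are treated linearly in hours with the
late-evening cluster unwrapped below zero to keep night sleep
contiguous across midnight; full circular regression is a known
limitation.  Covariates are not centred.

Estimation: inference-for-margins start (per-margin OLS/GLM, θ profiled
on a grid over the PIT residuals), then joint BFGS on the full
likelihood; SEs from the observed information (numerical Hessian); Wald
z-tests; θ at a family boundary or non-convergence flags the fit.  With
θ fixed at independence the joint likelihood factorizes exactly into
the two margins — the validation anchor.  Model selection is greedy
backward elimination from the full 10-term model per margin under AICc
with marginality respected; the search scores candidates at their IFM
estimates for speed and refits the winner by joint ML, ties to fewer
parameters, path logged.

Sample-size support: smallest per-group n for a two-sided two-sample
t-test, power evaluated exactly via the noncentral t (e.g. n = 64 per
group at d = 0.5, α = 0.05, power 0.80).

## The synthetic cohort generator

The generator exists because the participant data are access-restricted;
it reproduces the *statistical structure the analysis assumes* so every
stage can be validated end to end.

Defaults (chosen once to emulate the study conditions): 7-day monitoring
with work days first and the last two days free; DS alternate
07:00–14:00 and 14:00–21:00 shifts, NS work 21:00–07:00.  Activity comes
from the fitted model class itself — a 3-state chain on the 5-min grid
whose transition logits carry a 24-h sinusoid raising rest entry and
suppressing rest exit around an acrophase (03:00 work / 03:30 free for
DS; 11:00 work / 05:30 free for NS, with the NS work-day amplitude
reduced to ~40% to produce the fragmented, weakly rhythmic day sleep of
night work).  Baselines are calibrated so the periodic-chain occupancy
gives ≈ 8.5 h rest/day and occupancy-weighted p1-1 ≈ 0.97 (DS), with NS
work days at ≈ 5.3 h and ≈ 0.95.  Emissions are drawn once per 5-min bin
on the sqrt scale (means 1.3/4.0/6.5, SDs 0.45/0.9/0.9) and squared, so
the analysis-side sqrt of the bin mean recovers the Gaussian draw.
Temperature is 24/12/8-h harmonics (1.2/0.45/0.15 °C) around 35 °C plus
an ultradian sinusoid (2.2 h DS, 1.8 h NS; amplitude 0.35 °C) restarted
at each rest-episode onset and active only during rest, with 0.25 °C
white noise.  Missingness is block-structured — geometric gap lengths of
mean 30 min placed until ≈ 3% of minutes are removed — because telemetry
dropouts are bursty, not i.i.d.  Metadata are drawn from the cohort's
covariate ranges (age 22–62, chronotype score 24–74, years of night work
0–35 for NS and 0 for DS by default, configurable).

What passing tests therefore show: the estimators recover the truth when
the model class is correct, at the study's own record length, and the
pipeline's group contrasts (lower NS work-day RI and p1-1, later NS
centre of rest, shorter NS ultradian periods) emerge from the planted
structure.  What they do not show: robustness to emission
non-Gaussianity, posture/meal artefacts, within-bin activity variation,
diary errors, or ultradian cycles in *activity* (the generator plants
them in temperature only; activity ultradian recovery is validated on
purpose-built series).  Real-data performance on those axes is untested
by construction.

## Numerical conventions

- EM: |Δ penalized loglik| < 1e-5, ≤ 500 iterations, 5 restarts.
- Emission likelihoods clipped at 1e-300; SD floors 1e-3.
- Posterior row sums asserted to 1e-8; realized transition rows to 1e-12.
- Centre of rest undefined when the circular resultant < 1e-6.
- AICc = AIC + 2k(k+1)/(n−k−1); an error (not NaN) when n ≤ k+1, except
  in the pipeline's regression table where small-n cohorts report NaN.
- Elbow ties → smaller k; daytime-maximum ties → earliest time.
- Seeds are explicit everywhere; a pipeline manifest (config hash,
  package version, stage list, timings) makes runs reproducible
  bit-for-bit.

## Known limitations

- The RI proxy and the spectral-resampling scheme are principled
  reconstructions of quantities whose canonical definitions are not
  fully standardized; both are documented and configurable.
- Centre-time regression is linear-with-unwrapping, not circular.
- The 2-HHMM shares baseline logits across day types, so a pure
  level-shift in rest quality between work and free days loads on the
  harmonic terms only imperfectly.
- Per-subject transition-curve estimates at 7 days carry an irreducible
  sampling noise floor (RMSE up to ~0.1); cohort-level medians are the
  reliable summaries at this record length.
- No sex-specific analyses; 3-D sensor orientation is not used.
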