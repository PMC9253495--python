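# circarest

Circadian rest-activity and temperature rhythm analysis for shift-worker
telemonitoring.

Hospital night work disrupts the circadian timing system, and that
disruption is associated with elevated cardiovascular and cancer risk.
One week of chest-worn accelerometry and skin temperature, plus a work
diary, is enough to quantify it per individual — if the analysis respects
the circadian structure of the data.  `circarest` implements that
analysis as a reusable, tested pipeline for biostatisticians and sleep /
occupational-health researchers working with per-minute actigraphy from
day-shift (DS) and night-shift (NS) workers, together with a synthetic
cohort generator so every stage can be exercised and validated without
access to restricted participant data.

## What it computes

**Harmonic hidden Markov model (HHMM).**  Square-root 5-min activity
y_t is modelled with a 3-state Gaussian-emission HMM — inactive/rest
(IA), moderately active (MA), highly active (HA) — whose transition
matrix varies with clock time: each row is a multinomial logit
(reference = self-transition) with sinusoidal terms of period 24 h,

  logit P(S_t = k | S_{t-1} = j) = α_jk + a_jk cos(2πt/24) + b_jk sin(2πt/24),

so a circadian oscillator modulates the chain.  The two-oscillator
variant (2-HHMM) gives work days and free days separate harmonic
coefficients with shared emissions and baselines.  Estimation is EM
(ridge-stabilised multinomial-logit M-step); decoding is local
(posterior argmax).

**Four circadian parameters** per subject and scope (whole / work /
free): p1-1, the occupancy-weighted probability of remaining at rest
(rest quality); the 288-slot daily rest profile; rest amount (area under
the profile, hours); centre time of rest (circular mean of the profile);
and the Rhythm Index RI ∈ [0, 1], an inside-vs-outside-window contrast
that is 1 for perfectly regular probability-one rest and 0 for a flat
profile.

**Spectral analysis.**  Missing-tolerant Lomb-Scargle periodograms of
hourly chest temperature on a 2–40 h period grid with day-block
bootstrap 90% CIs for peak periods, dominant-period band classification
(circadian / circa-12 h / circa-8 h), spectral gravity centre, and
ultradian (0.5–6 h) sub-periods of LIDS-transformed activity
(LIDS = 100/(activity+1)) and temperature inside decoded rest bouts
(2–12 h rest spans).

**Rest-profile clustering.**  Ward/Euclidean agglomerative clustering of
the concatenated work‖free rest profiles (576 values, anchored
20:00→19:59), with the number of clusters chosen by the elbow of the
within-cluster sum of squares W_k.

**Bivariate copula regression.**  Each parameter's paired (work-day,
free-day) response is regressed on shift type, age, chronotype score and
years of night work (plus pairwise interactions) through two Gaussian
margins bound by a Gaussian/Clayton/Frank/Gumbel copula with dependence
θ; joint ML with IFM starts, Wald z-tests, AICc backward selection.
Probability-valued responses enter as log odds (LOP1-1, LORI).

## Worked example

```python
import pandas as pd
from circarest import (generate_cohort, partition_days, HarmonicHMM,
                       circadian_params)

cohort = generate_cohort(n_ds=1, n_ns=1, n_days=7, seed=42)
subj = cohort["NS001"]                      # a night shifter
span = (subj.series.timestamps[0].to_pydatetime(),
        (subj.series.timestamps[-1] + pd.Timedelta(minutes=1)).to_pydatetime())
part = partition_days(subj.diary, subj.meta, span)

fit = HarmonicHMM.from_series(subj.series, part).fit(seed=0)   # 2-HHMM
print(fit.summary())
for scope in ("work", "free"):
    cp = circadian_params(fit, fit.decode(), part, scope, subj.subject_id)
    print(f"{scope:5s}  p1-1={cp.p11:.3f}  rest={cp.rest_amount_h:.1f} h  "
          f"centre={cp.centre_time:.1f} h  RI={cp.rhythm_index:.2f}")
```

prints

```
Harmonic HMM results
============================================================
states: 3   harmonics: 1   oscillators: work/free
n_obs: 1963   n_params: 38
loglik: -2828.139   AICc: 5733.819   converged: True
------------------------------------------------------------
state         mean (sqrt-PA)        sd       pi0
IA (rest)             1.2892    0.4512    0.0000
MA                    4.0446    0.8653    1.0000
HA                    6.5692    0.8326    0.0000

work   p1-1=0.951  rest=7.8 h  centre=12.0 h  RI=0.43
free   p1-1=0.972  rest=7.5 h  centre=4.7 h  RI=0.83
```

Read: the three activity states are well separated on the sqrt scale
(means 1.3 / 4.0 / 6.6).  On work days this night shifter sleeps around
midday (centre of rest 12.0 h) with fragmented, weakly rhythmic rest
(RI 0.43, p1-1 0.951); on free days rest re-consolidates at night
(centre 4.7 h, RI 0.83, p1-1 0.972) — the work/free contrast the
two-oscillator model is built to expose.

The full pipeline (eligibility screening → HHMM fits → spectra →
parameters → clustering → regression → ultradian analysis) runs from the
command line:

```bash
circarest run --outdir runs/demo          # default 20 DS + 20 NS synthetic cohort
circarest report runs/demo                # markdown summary of all tables
```

## Layout

| module | contents |
|---|---|
| `circarest.cohort` | data model (MinuteSeries/Diary/SubjectMeta), CSV IO, resampling, sqrt transform, day partitioning, eligibility |
| `circarest.simulate` | synthetic DS/NS cohort generator |
| `circarest.hhmm` | `HarmonicHMM` / `HHMMResults` (EM, decoding, AICc) |
| `circarest.metrics` | rest profile, p1-1, rest amount, centre of rest, Rhythm Index |
| `circarest.spectral` | periodograms + bootstrap CIs, LIDS, rest bouts, ultradian sub-periods |
| `circarest.clustering` | profile vectors, Ward/W_k/elbow, cluster comparisons |
| `circarest.regression` | `CopulaRegression` / `CopulaResults`, model selection, group tests, power |
| `circarest.pipeline`, `circarest.cli` | orchestration, manifests, reports, `circarest` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
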