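# Methods

`glucowear` implements a feature-driven pipeline for predicting interstitial
glucose (IG, mg/dL) from non-invasive wearable sensor streams, together with
a synthetic cohort generator that reproduces the statistical structure the
pipeline assumes. This note documents the models, the numerical conventions,
and the design decisions that were genuinely open.

## Data model and preprocessing

All time lives on one master clock (seconds since the UNIX epoch); readers
for device dialects (Empatica-E4-style per-channel exports, Libre-style CGM
CSV) convert at parse time. Glucose is mg/dL throughout; a mmol/L option
converts by the factor 18.016 when reading.

Heterogeneous channels (native rates 1–200 Hz) are aligned by resampling
onto a master timeline with fixed equidistant steps (default 20 Hz,
configurable; the shipped scenarios use 4 Hz, see *Problem sizes*). Three
interpolation schemes are provided:

* **linear** — first-order polynomial between the bracketing nodes; the
  default for continuous channels;
* **nearest** — value of the closest node, with an equidistant tie resolved
  to the *earlier* node (documented, arbitrary);
* **Lagrange, order 5** — evaluated piecewise over sliding 6-node
  neighbourhoods rather than as one global polynomial, because global
  high-order fits oscillate (Runge); when fewer than 6 nodes exist the
  largest available order is used. The barycentric form is used for
  numerical stability; it is algebraically the same polynomial. Dense
  glucose curves (1 value/min for the ablation analysis) use this scheme.

No extrapolation is ever performed; queries outside the node span raise.
Interior gaps longer than 5 s are bridged by the selected interpolant but
logged, since sensor dropouts carry no information worth inventing.

Body temperature can be synthesised from core and skin temperature as
`BTEMP = α·CTEMP + (1−α)·STEMP` with α = 0.67.

Outliers are defined per stream as samples beyond `μ ± 4σ`, with μ and σ
(population, divisor *n*) computed **once** on the original values; flagged
samples are replaced by μ in a single pass (no re-flagging). The population
σ is a fixed convention — the sample/population choice is not dictated by
the definition, and fixing it keeps runs reproducible across languages.

Prediction windows END at each glucose label: for a label at time *t* and a
prediction horizon (PH) of *p* minutes, the window is the half-open interval
`(t − p, t]`, which makes consecutive windows disjoint when the label
cadence equals *p*. Labels whose preceding span is not fully covered by
every channel are dropped, not zero-padded — partial windows would bias
spectral features. The nominal window count follows `|J| = span/p + 1` on an
equidistant label grid; when labels arrive faster than the horizon (5-min
CGM cadence with a 15-min PH), the window stride equals the cadence and the
count bookkeeping uses the stride.

## Feature engineering

Per usable window and channel the registry produces:

* **Statistical order features** (11 per channel): mean, max, min,
  population SD, median, zero crossings of the mean-centred signal (sign(0)
  treated as positive), 20th/50th/80th percentiles (linear interpolation
  between order statistics), the 25–75 interquartile difference, and lag-1
  Pearson autocorrelation. The STEMP−BTEMP temperature difference (window
  means) is emitted once per window. Degenerate conventions: single-sample
  or constant windows get SD = 0 and autocorrelation = 0.
* **Frequency/amplitude features** (23 per channel): counts and mean
  amplitudes of relative-extrema peaks and pits (`argrelextrema`, order 3);
  mean/SD/energy of the Daubechies-4 wavelet approximation and (pooled)
  detail coefficients at decomposition level `min(3, max possible)`, with a
  logged fallback to level 1 below the filter support; the magnitudes of the
  first **10** coefficients of the inverse FFT of the window's spectrum
  envelope (ten, not fewer, so the registry closes at 23 features per
  channel); excess (Fisher) kurtosis; spectral energy `Σ|X_k|²` under the
  unnormalised DFT convention; and Shannon spectral entropy (natural log) of
  the L1-normalised one-sided power spectrum (a constant window has entropy
  0 by construction).
* **Time context**: `minutes_from_midnight` ∈ [0, 1440) encodes circadian
  timing and `days_from_2021` (whole days since 2021-01-01) encodes season.
  Calendar arithmetic is done directly on the master clock, which is treated
  as already local.
* **Demographics** (`bio_age`, `bio_sex`, `bio_bmi`), constant per
  participant; in the main-study configuration a `phase_marker`
  (washout/MMT/OGTT) and optionally a `consumed_food` diary category are
  added, and both are omitted in the follow-up configuration where food
  information is deliberately withheld.

Z-score variants `Γ = (x − μ)/σ` are appended *alongside* the raw values for
every sensor-data feature, with μ, σ (population) computed per participant;
σ = 0 maps to all zeros. Per-participant standardisation addresses
between-subject level differences without leaking across participants.
Whether z-variants should cover all sensor features or a subset was open;
the registry defaults to all of them and is configurable. The enumerated
statistical list above yields 11 per-channel statistics plus the
temperature difference; the registry is the source of truth for all counts
and the tests assert column counts against it, never against a hard-coded
total.

## Feature selection (BoRFE)

Layer 1 — **Boruta** (re-implemented here): in each of 100 iterations every
candidate feature receives a shuffled shadow copy; the estimator is fitted
on candidates + shadows and a feature scores a *hit* when its importance
exceeds the maximum shadow importance. Features are confirmed/rejected by a
two-sided binomial test against p = 0.5 at α = 0.05 with Bonferroni
correction, anything else staying tentative. Tentative features are kept
into layer 2 by default (lenient; the next layer can still drop them).

Layer 2 — **RFE** with step 1, scored by mean RMSE under
leave-one-participant-out CV (LOPOCV); importance is impurity decrease for
the forest and split gain for the boosting model, matching the family used
downstream. Elimination ties drop the lexicographically last name; equal CV
scores prefer the smaller subset. The selected subset is the CV-optimal one.
One master seed fans out to shadow shuffles, estimator seeds and fold order,
all recorded in the result.

Whether selection should re-run inside each outer fold (no selection bias)
or once globally was open; both modes exist (`per_fold` default, `global`
provided for single-ranking analyses).

## Models and evaluation

Two estimator families behind one contract, with the shipped default
hyperparameters: random forest (100 trees, max depth 16) and LightGBM
(gbdt, 5000 leaves, learning rate 0.1, 100 estimators, max depth 16, mse
objective, bagging fraction 0.6, feature fraction 1.0, L2 regularisation
0.9, gain importance). Evaluation is LOPOCV: one fold per participant, the
held-out participant never in training; per-fold estimator seeds are master
seed + fold index. Metric dispersion is reported as the SD across folds
(repeat-run SD is identically zero by the determinism contract, so the fold
SD is the meaningful dispersion; both interpretations are computable).

Metrics: `RMSE = √mean((pred−ref)²)` mg/dL and
`MAPE = mean(|pred−ref|/ref)·100` % (references are ≥ 40 mg/dL, so no
small-denominator guard is needed). Clarke error grid zones follow the
widely used piecewise boundary dialect of Clarke et al. (1987): zone A is
agreement within 20% (or both values ≤ 70 mg/dL), E the opposite-diagnosis
corners, C the overcorrection wedges, D the failure-to-detect bands, B the
benign remainder. Because published implementations differ in boundary
details, the exact dialect is pinned by a frozen zone-count snapshot over
the full 1-mg/dL grid on [40, 400]²; any silent dialect drift fails the
suite. Hypoglycemia is tabulated at < 70 (level 1) and < 54 mg/dL
(level 2), nested — level 1 includes level 2 — with the minimum reported.

Feature ranking averages per-fold importance vectors (each fold normalised
first so folds weigh equally), normalises the average to sum to 1, retains
the across-fold variance, and rolls up to the four main categories
(demographics, time domain, phase marker, sensor data) and the functional
subcategories carried by the registry.

The modality ablation regresses densified glucose (1/min, Lagrange) on raw
resampled channel values over two-hour post-meal segments (MMT or OGTT,
washout excluded), with no feature engineering. Scores are mean held-out R²
over 32 shuffled K-fold splits (the participant-grouped alternative is
available); the tree family averages a decision tree and a random forest,
and the boosted family averages two gradient-boosting configurations of the
same engine (differing seeds and leaf budgets) to avoid a second heavy
dependency.

## Synthetic cohorts

Glucose is baseline + circadian sinusoid + meal bumps + AR(1) noise,
clamped to [40, 400] mg/dL. The meal kernel is a difference of
exponentials `A·(e^(−t/decay) − e^(−t/rise))/norm`, normalised so its peak
equals the configured amplitude (a smooth, two-parameter postprandial
shape); coincident rise/decay constants degrade gracefully to a gamma-like
bump. The AR(1) coefficient is 0.8 at the CGM cadence, reflecting the
strong autocorrelation of adjacent CGM readings. Defaults mirror the
devices: STEMP/EDA 4 Hz, BVP 64 Hz, HR 1 Hz, chest channels 200 Hz, CGM
cadence 15 or 5 min, participants aged 20–40.

Each sensor channel is
`baseline + nonlinearity(gain·(glucose(t−lag) − baseline_glucose)) +
confound + noise + ambient`, with saturating (`s·tanh(u/s)`) and threshold
nonlinearities available, seeded missing-sample deletion, and injected
artifact spikes of 6–10σ (isolated, so the 4σ detector can be exercised).
Temperature channels carry a per-calendar-day ambient offset following a
seasonal sinusoid, making `days_from_2021` genuinely informative.

The confound ("drift") is the load-bearing design choice. It is a smooth
random process (sum of random-phase sinusoids with 20–240 min periods),
split into a per-participant **shared** component and per-channel private
components by a mixing weight `confound_shared_fraction`. Two properties
follow:

1. each channel alone is confound-dominated (the shipped scenarios put the
   drift at ≈ 2.6–8× the signal SD per channel), so single-channel
   regressions have almost no skill;
2. the per-channel confound-to-gain ratios **differ**, so the glucose and
   drift directions are not collinear in channel space and a multi-channel
   learner can cancel the shared drift. (If every channel carried the same
   ratio, the two directions would coincide and no combination of channels
   could separate them — a degenerate design this generator avoids on
   purpose.)

This realises, by construction, the qualitative pattern the pipeline is
designed around: single-modality R² near zero, multi-modality R² high. The
coupling strengths are scenario parameters chosen for that statistical
structure, not physiological estimates; the generator is explicitly not a
mechanistic glucose–insulin model (no insulin compartment, no
dose–response), and passing tests demonstrate pipeline correctness on data
with the assumed dependence structure, not clinical performance on real
cohorts. Real wearable data adds motion artifacts with temporal structure,
device-specific filtering, and physiological confounds that are neither
shared nor stationary.

## Shipped scenarios and problem sizes

* **Coupled cohort** (follow-up-style): 5 participants × 10 days, 5-min
  CGM cadence, 6 recorded hours/day, all five wristband channels at 4 Hz,
  saturating nonlinearities and 0–3 min lags, drift 97% shared, 2% missing
  samples, 0.2 artifacts/h; meal times jitter ±45 min per participant-day
  and circadian phases are drawn per participant so clock time alone does
  not predict glucose across participants.
* **Zero-coupling control**: identical shape with all gains 0 and meal
  times scattered ±150 min — no channel or time feature carries
  cross-participant information; held-out R² at chance level is the
  expected outcome.
* **Ablation cohort** (main-study-style): 6 participants × 2 days, sensors
  8:00–15:00, MMT at 9:00 and OGTT at 13:00 with two-hour intervention
  phases and washout between, linear lag-free couplings, fully shared
  drift.
* **Mini cohort**: 2 participants × 3 h for round-trip and bit-exactness
  checks.

The 4 Hz scenario rate and 6–7 recorded hours/day are the package's own
working sizes for the shipped scenarios; the generator accepts the full
device-native rates and day spans. At these sizes the whole suite and the
reproduction script run comfortably on a single CPU.

## Determinism

Every stochastic component draws from `numpy` generators derived from one
master seed via seed sequences keyed by (seed, participant, stream role),
so identical configurations give bit-identical cohorts, matrices and
predictions; the suite asserts bit-identity of all serialized artifacts
across pipeline re-runs.

## Known limitations

* The generator's confound is stationary and largely shared; real-world
  drifts (motion, ambient, device re-seating) are messier, so measured
  skill here upper-bounds nothing about real cohorts.
* The Lagrange scheme assumes reasonably separated nodes; pathological node
  clustering degrades conditioning (the pipeline only feeds it equidistant
  CGM grids).
* `featurize_records` bridges overnight gaps by interpolation before
  windowing; the handful of windows that reach back across a session
  boundary therefore mix in bridged values (logged, and bounded by the
  horizon length).
* LightGBM's bagging fraction is configured as shipped but is inert without
  a bagging frequency; it is kept verbatim for fidelity to the reference
  configuration rather than "fixed".
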