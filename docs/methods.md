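# Methods notes

This document records the models behind each stage, the parameters that
matter, and the design decisions taken where the method left genuine
freedom. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

Recordings are 9-channel referential neonatal EEG (Fp1, Fp2, C3, C4, O1,
O2, T3, T4 + reference) sampled at 256 Hz, at least 40 min long, carried
as 16-bit EDF in µV. Preprocessing applies a 4th-order Butterworth
band-pass, 0.3–70 Hz, forward–backward (`sosfiltfilt`). Only the cutoffs
are fixed by the acquisition convention; the order and zero-phase
application are our choice — zero phase because the synchrony stage
compares channels at zero lag and filter group delay would bias it.
Channel labels are normalised by stripping an `EEG ` prefix and reference
suffixes (`-Ref`, `-A1`, …), case-insensitively. Time is seconds from
recording start; annotation intervals are half-open `[onset, onset+dur)`.

Quiet-sleep (QS) segments come from annotation files — visual sleep
staging itself is out of scope. Segments are clipped to the recording and
kept only if ≥ 5 min long, the minimum for stable discontinuity and
synchrony estimates. Artifact handling is a non-goal: the simulator
produces clean signals, and results on real data would require an
artifact-rejection front end this package does not provide.

## Spectral analysis

Welch PSD with 2-s epochs, 50 % overlap, Hamming taper, constant detrend
per epoch (standard Welch hygiene; the frequency grid step is 0.5 Hz so
every band edge lies on the grid). Band powers are trapezoidal integrals
over Delta1 [0.5, 1), Delta2 [1, 4), Theta [4, 8), Alpha [8, 13), Beta
[13, 30) Hz; adjacent bands share their edge grid point, which makes the
five band integrals telescope exactly to the total-band (0.5–30 Hz)
integral — the partition identity the tests assert at 1e-9 relative.
Relative power divides by the total-band power (assumed to be 0.5–30 Hz
exactly), so the five relative powers sum to 100 % per channel. Multiple
QS segments are pooled by duration-weighted averaging of per-segment PSDs
before integration, which is equivalent to Welch over the pooled windows
and hence invariant to how a contiguous stretch was split. Regional
values are arithmetic means of member channels (frontal = Fp1/Fp2,
central = C3/C4, occipital = O1/O2, centrotemporal right = C4/T4,
left = C3/T3, total = all eight); a missing member makes the region
missing rather than silently renormalising.

## Burst detection and discontinuity

The detector thresholds a line-length feature: mean absolute first
difference (µV per sample step) in 1-s frames at 0.5-s hop, smoothed by a
3-frame median. A frame is a burst when the feature exceeds

```
threshold = clip(theta_rel * median(feature), theta_floor, theta_ceil)
```

with `theta_rel = 1.5`, `theta_floor = 3.5`, `theta_ceil = 6.5`. The clip
(rather than a pure `max(theta_abs, theta_rel·median)` rule) is load
bearing: fully continuous EEG has its median at burst level, and an
unbounded relative threshold would then call everything suppressed, while
the ceiling guarantees genuinely high-amplitude continuous activity is
never suppressed. The floor/ceiling sit between the feature levels of
suppression (≈ 0.5–0.8 after band-passing, at 2–5 µV rms) and bursts
(≈ 7–9, at 30–60 µV rms), so frames mixing the two classes split near
50 % content and event durations are recovered without systematic bias.
Bursts shorter than 1 s and suppressions shorter than 2 s are merged into
their neighbours (neonatal convention; configurable). The consensus mask
calls a frame suppressed when more than 50 % of channels are suppressed.

MSC is the time average of the suppression curve (fraction of channels
suppressed per frame). IBIs are maximal consensus suppression runs,
discarding runs that touch a segment edge (truncated, biased short);
IBI95 is the empirical 95th percentile with linear interpolation between
order statistics, `p(k) = (k−1)/(n−1)`, chosen so a brute-force oracle is
exact. Derivation-level mean IBIs run the same detector per bipolar
derivation and average within the centro-occipital and fronto-central
groups; a derivation with no complete IBI drops out of its group mean.

## Activation synchrony index

Each channel is reduced to an activation envelope: band-pass 0.5–8 Hz,
magnitude, low-pass 0.5 Hz, sampled at 4 Hz. Envelopes are quantized into
q = 4 equal-occupancy levels (rank-based, hence invariant to any monotone
amplitude transform). ASI is `log₂(MI₀ / mean MI_null)` with MI the
plug-in estimator on the 4×4 joint histogram and the null from 40
circular time shifts of at least 30 s, drawn uniformly; the same
estimator in numerator and denominator cancels the plug-in bias in the
ratio. Two implementation details matter:

- *Exact symmetry.* Each surrogate averages the shift applied to x and to
  y, and the MI reduction averages both summation orders of the joint
  histogram, so `asi(x, y) == asi(y, x)` bit-exactly.
- *Shared surrogate shifts.* All pairs of one recording share one seeded
  shift sequence. This keeps the statistic a pure function of the
  envelopes (identical channels get identical ASI) and remains a valid
  null draw; per-pair independent shifts would only add Monte-Carlo
  jitter between entries.

With multiple QS segments, envelopes are computed per segment and
concatenated; surrogate shifts roll within segments so the null never
mixes samples across segment joins. The log-ratio has a small negative
Jensen bias under exact independence (the mean of `log(MI₀/⟨MI_null⟩)` is
slightly below 0 because MI₀ fluctuates in the denominator's scale); the
calibration study bounds the null mean within ±0.2. The concrete
envelope/quantization/surrogate constants are this package's
operationalisation of the activation-synchrony idea; all are exposed in
`AsiParams`.

Summaries: the global ASI averages all 28 referential pairs; the six
symmetric-pair values compare homologous left/right bipolar derivations
(Fp1-C3 vs Fp2-C4, Fp1-T3 vs Fp2-T4, Fp1-O1 vs Fp2-O2, C3-O1 vs C4-O2,
T3-O1 vs T4-O2, C3-T3 vs C4-T4).

## EEG maturational age

The EMA regressor is ridge regression (closed form, α = 1.0) on the
22-entry feature vector: 5 absolute + 5 relative band powers of the total
region, MSC, IBI95, the two derivation-group mean IBIs, global ASI, the
six symmetric-pair ASIs, and the pooled amplitude IQR. This reduced,
documented feature set is a stand-in for the much larger heuristic
feature banks of published age-from-EEG models; ridge was chosen for
transparency and determinism, and the model class is pluggable behind the
JSON-serialised `EMAModel` contract. Features are mean-imputed (training
means) and standardised inside the model; constant features are dropped
with a warning. Useful identities: the prediction at the training
centroid is the mean training age, translating all training ages shifts
every prediction by the same amount, and rescaling any feature leaves
predictions unchanged.

EMA features default to the whole recording (sleep-state-agnostic, as
age-from-EEG models are usually trained); the QS-only variant is emitted
alongside. Validation is leave-one-*subject*-out — both recordings of an
infant leave together, so the report is free of within-subject leakage.
In the pipeline, EMA for each recording is its LOSO prediction within the
analysed cohort (no external reference model is assumed); the endpoints
are the gap (EMA − PMA) and the per-infant change in gap from T1 to T2.

## Cohort inference

Nutrition: per-infant arithmetic means over days of life 1–7;
energy = 4·(proteins + carbohydrates) + 9·lipids kcal/kg/day, an identity
asserted for every emitted summary.

GEE: one model per (metric, nutrient): `metric ~ nutrient + PMA`,
clusters = infants, Gaussian mean model, working independence. With only
~28 clusters the plain sandwich/normal-reference combination is
anticonservative (measured near 10 % type-I at nominal 5 %), so standard
small-sample practice is used instead: the bias-reduced (Mancl–DeRouen)
sandwich covariance and a t reference with (clusters − parameters)
degrees of freedom. With singleton clusters this collapses exactly to OLS
with HC3 standard errors, which the tests assert. No multiplicity
correction is applied to the primary p-values (α = 0.05); a
Benjamini-Hochberg column is emitted alongside, labelled as an extension.
Rows with a missing response or predictor are dropped per model
(complete case).

Outcome comparisons use the two-sided Mann-Whitney U test: exact for
combined n ≤ 20 without ties, normal approximation with tie correction
otherwise. Groups are `normal` vs `mild_moderate`; groups smaller than 2
skip the metric with a note, and an infant missing one session drops out
of that session's comparison only.

## Synthetic cohort

The generator emulates the study conditions of a VLBW serial-EEG
nutrition cohort. Demographics: GA ~ N(28.4, 2.1²) truncated to
[24.3, 32.0] weeks; session PMAs ~ N(32.4, 0.7²) in [30.4, 33.6] and
N(36.7, 0.9²) in [35.3, 39.1]. First-week intakes: proteins
N(2.54, 0.36²), lipids N(2.03, 0.42²), carbohydrates N(10.31, 0.72²)
g/kg/day, with 5 % day-to-day wobble over 7 days. The causal structure
the inference stage must recover is an infant-level maturation shift

```
delta_i = beta_protein·(protein_i − mean) + beta_lipid·(lipid_i − mean) + N(0, 0.4²)  [weeks]
```

with defaults `beta_protein = 1.0`, `beta_lipid = 0.6` weeks per g/kg/day
— sized so that the programmed protein effect is a realistically
detectable effect in a 28-infant serial design (≈ 90 % power at α = 0.05),
the regime the study design presumes. Outcome labels put the lowest-delta
quantile (12/28) into `mild_moderate` with 10 % label noise — a testing
device, not a biological claim.

EEG synthesis (per recording, 40 min at 256 Hz): a semi-Markov
burst/suppression alternation with lognormal durations fills the
quiet-sleep block (default 12 min); suppression median 6 s at 32 w
effective age falling ~18 %/week, burst median 3 s rising ~10 %/week.
Bursts are 1/f^α noise (α = 1.5 at 32 w, declining 0.06/week, spectrally
flat below 0.5 Hz) at 45 µV rms declining 6 %/week; suppressions are 3 µV
rms; the surrounding active-sleep filler is continuous 25 µV rms noise so
state extraction is genuinely exercised. Homologous channel pairs share a
slow lognormal amplitude-modulation driver with weight ρ rising from 0.3
at 32 w by 0.06/week — the handle behind interhemispheric-synchrony
maturation. Anterior channels (Fp1, Fp2, C3, C4) start each burst 0.5 s
late, so fronto-central derivations carry longer IBIs than
centro-occipital ones, mimicking the posterior-to-anterior maturation
gradient. All synthesized suppression events, per channel, are logged to
`ground_truth.json`, so detector output can be scored event-wise.

Every random draw descends from one master seed through counter-based
`SeedSequence` keys (infant, session, channel, stream), so any single
recording regenerates in isolation and full datasets are byte-identical
across runs.

Because the burst/suppression *timing* is shared across channels (needed
for a meaningful >50 %-of-channels consensus and hence for MSC/IBI), all
pair ASIs inherit a common-drive floor even at ρ = 0; ρ controls the
*additional* homologous coupling. Surrogate-null calibration of ASI is
therefore validated on `simulate_coupled_envelopes`, a direct
envelope-level generator (shared driver of weight ρ; ρ = 0 gives exact
independence), which is also what the coupling-monotonicity studies use.

What the simulator does **not** model: delta brushes, tracé alternant
morphology and other biophysical waveform detail; artifacts; real
inter-channel spectral differences. Passing tests therefore demonstrate
estimator correctness and pipeline integrity under the assumed
generative structure, not clinical validity on real recordings.

## Problem sizes and numerics

- Test and calibration studies use scaled problem sizes chosen as the
  package's own defaults for desk-scale verification: 10–20-min
  recordings with a 10-min QS block for EEG-level tests; 40 infants for
  the EMA validation cohort; 100–500 cohort replicates for power/type-I
  studies, run at the feature level (`simulate_feature_table`, which
  draws the identical cohort-level causal structure without synthesizing
  EEG — replicating full EEG cohorts would add runtime, not information,
  to a calibration of the inference stage).
- The acceptance script runs the full default study: 28 infants × 2
  recordings × 40 min, exactly as generated.
- EDF is written 16-bit with per-channel physical ranges; round-trip
  error is bounded by the quantization step (range/65535).
- Degenerate inputs: flat channels detect as fully suppressed (with a
  warning); constant envelopes yield NaN ASI; zero total power flags
  relative powers missing; recordings with no usable QS produce NaN
  metric rows that downstream models drop per-model.

## Known limitations

- The ASI constants (band, envelope rate, q, shift scheme) are defaults
  of this implementation, not a validated match to any published
  parameterisation.
- The EMA feature set is deliberately small; absolute EMA values are only
  meaningful relative to the cohort the model was fitted on, which is why
  the gap and its change — not raw EMA — are the endpoints.
- GEE small-sample inference uses one (widely recommended) correction;
  other choices (Kauermann-Carroll, score tests) would give slightly
  different p-values at this cohort size.
- Real-data use requires artifact rejection and sleep staging upstream.
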