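# Methods

`pcct_ews` forecasts respiratory and cardiovascular deterioration up to 15
minutes ahead during paediatric critical-care transport (PCCT), from 1 Hz
multichannel vital signs plus episode-level clinical metadata. Because the
motivating data are private NHS transport records, the package ships a
synthetic-episode simulator that reproduces the *schema and phenomenology* of
such data; every empirical statement below is about behaviour on that
simulator, computed by the test suite or `scripts/acceptance.py`.

## Episode model and schema

An episode is one interhospital transport: a metadata record (age, weight,
sex, PIM3 mortality risk, free-text and categorical diagnosis, comorbidity
flags, pre-transport interventions, respiratory/cardiovascular support,
hospitals, team arrival time) and a 16-channel time series on a strict
1-second grid with a boolean observedness matrix. The 16 channels are SpO₂,
heart rate, two EtCO₂ channels (per-second min and max), airway and impedance
respiratory rates, non-invasive and invasive systolic/mean/diastolic
pressures, and four temperature sites. Eligibility requires age ≤ 18 years and
≥ 30 minutes of recording.

The model consumes 18 feature channels: the 16 vitals plus two per-second
*prior-event flags* (a respiratory or cardiovascular event, as labelled by the
dynamic-threshold labeller, is in progress at that second). Concatenating an
observedness flag per channel gives 36 features per time step. The flag pair
is a reconstruction: monitoring setups in this domain report "18 input
features" while listing 16 physiological channels, and timestamped prior
events are the natural additional inputs; the choice is isolated in
`preprocess.FEATURE_CHANNELS` and `windows.event_flag_channels`.

## Synthetic cohort generator

Each channel is simulated as an age-dependent baseline plus a discrete
Ornstein–Uhlenbeck (AR(1), relaxation time 300 s) process, a per-episode
random offset, and a slow sinusoidal drift (period 20–60 min). The age →
(mean, SD) reference grid over {0, 0.08, 1, 4, 11, 18} years is the *same
table* the standardiser uses, so a quiet simulated episode z-scores to ≈ 0 by
construction; the values follow the usual paediatric trajectory (neonatal
heart rate ≈ 145 bpm falling to ≈ 75 bpm by 18 y, etc.) and are package
reference values, not clinical centiles.

Defaults (the study conditions; all config-exposed in `SimulationConfig`):

| parameter | default | why |
| --- | --- | --- |
| episode duration | lognormal, median 113 min, σ = 0.56, clipped to [35, 360] min | median/IQR of a typical regional transport service |
| within-patient OU SD | 0.35 × reference SD | short-horizon variability is smaller than the between-patient spread |
| between-patient offset | 0.5 × reference SD | critical-care baselines sit off the healthy centre |
| event rates | 0.15 (resp) / 0.20 (cv) per hour, scaled by (1 + 6·PIM3) and ×1.5 with vasoactive support | yields ~30 % of episodes with ≥ 1 event and < 10 % of 15-min windows positive, the class balance typical of transport data; the acuity scaling plants a learnable static signal |
| event duration | uniform 120–300 s | minute-grid labelling cannot resolve sub-2-minute events |
| effect sizes | SpO₂ 1.2, EtCO₂ 1.5, RR 2.0, HR 2.5, BP 2.5 (reference-SD units) | deep enough that SpO₂ falls below 94 % and HR/BP excursions clear adaptive bands |
| precursor lead | uniform 600–900 s, linear ramp; the drift level persists through the event | the premise that subtle physiological shifts precede deterioration, as a minimal learnable form |
| arterial-line probability | 0.36 | invasive pressures are informatively missing in roughly that fraction of transports |
| NIBP cadence | one cuff reading per 180–300 s, plus 45-s cycling around events | standard vs. stat cuff modes |
| random dropout | 0.4 %/min chance of a 30–90 s sensor gap, per channel | occasional, not routine, signal loss |

Informative missingness is deterministic: invasive pressures exist iff the
arterial-line flag is drawn; EtCO₂ and airway respiratory rate exist iff the
patient is invasively ventilated; temperature sites are sparse.

What the simulator does **not** emulate: artefact morphology (motion spikes,
probe detachment ramps), medication responses, ventilator interactions,
correlated multi-channel artefacts, or any real covariance structure between
diagnosis and physiology. Passing tests therefore demonstrate pipeline
correctness and learnability of planted structure — not clinical performance.

## Dynamic-threshold labelling

Labels are generated, not annotated. On one-minute means of cleaned,
carried-forward, native-unit vitals, each channel keeps a recursive
exponentially weighted mean m and mean-of-squares s (half-life 10 min;
variance = s − m²), giving bands m ± max(k·EWMSTD, floor·m) with k = 2,
floor = 5 % of the EMA (2.5 % for SpO₂, whose variability is inherently low).

Two implementation decisions matter and are deliberate:

- **Prior-state judging.** Minute t is compared against the band derived from
  the state through minute t−1. Including minute t in its own band lets an
  excursion inflate the EWMSTD the moment it starts.
- **Winsorised updates.** A minute outside its judging band contributes only
  its band-edge-clipped value to the state update. A plain update absorbs the
  anomaly within 1–2 minutes (bands swallow the event they should flag); a
  hard freeze never re-converges after genuine level shifts. Winsorising
  bounds the adaptation rate at α·half-width per minute — with the default
  half-life that tracks drifts of up to ~7 % of the band per minute while
  holding 2+ SD excursions out indefinitely. Measured on the simulator,
  plain updates recover ~30–70 % of injected events; winsorised prior-state
  judging recovers ≥ 90 % (the packaged recovery property).

Respiratory deterioration: SpO₂ minute-mean strictly below min(94 %, dynamic
lower bound) *and* at least one other respiratory parameter (either
respiratory rate or either EtCO₂ channel) outside its bands in the same
minute. Cardiovascular: heart rate and blood pressure simultaneously outside
their bands (either direction). The authoritative pressure is invasive mean
arterial when the episode has any invasive data, else non-invasive mean
arterial. Candidate runs of ≥ 1 minute become events; an event is kept only
if the 5 minutes before and after have no missing minute-mean in SpO₂ plus at
least one triggering secondary (respiratory) or in both HR and the BP channel
(cardiovascular). The first 10 minutes are a warm-up with indeterminate
flags: EWMSTD starts at zero, and before ~one half-life the bands sit on
their floors and trip on ordinary variability.

## Preprocessing

Cleaning removes values strictly outside plausibility bounds (HR < 30 or
> 300 bpm, SpO₂ < 10 or > 100 %, EtCO₂ > 15 kPa, BP < 5 mmHg, temperature
< 25 or > 45 °C); boundary values are retained. Temperature and NIBP are
carried forward between measurements; carried cells count as observed in the
mask (the mask encodes sensor dropout, not cadence) with provenance kept in a
separate layer. SpO₂ standardises as (x−97)/6, EtCO₂ as (x−5.25)/1.5,
temperature as (x−36.75)/1.5; HR, RR and BP are z-scored against the
age-interpolated reference grid (ages outside [0, 18] clamp to the nearest
grid point). Missing values are mean-imputed — zero post-standardisation —
with the observedness flag set to 0.

Baseline encodings: age, weight and PIM3 min-max scaled over fixed a-priori
ranges ([0, 18] y, [1, 90] kg, [0, 1]), missing → −1; sex binary; categorical
fields one-hot with explicit other/unknown slots. The *reduced* configuration
covers nine variable groups (age, weight, sex, PIM3, destination care area,
primary diagnosis, comorbidities, respiratory and cardiovascular support).
The *full* configuration adds ethnicity, referring and destination hospitals
(units with < 10 retrievals grouped as "other"), a day/night flag from team
arrival time, and 17 named pre-transport intervention flags — 30 groups in
total; the exact membership of the full set is a reconstruction documented
here because no canonical list exists.

Free-text diagnoses embed into 768-dimensional unit vectors via hashed word
uni/bi-grams (blake2b index + sign, L2-normalised) — deterministic, offline,
and cacheable. This is a structural stand-in with the same interface and
dimensionality as a clinical language-model embedding; it preserves lexical,
not semantic, similarity. An external embedding provider can be swapped in
through the same `embed(text)` interface.

## Windowing and split

Episodes tile into consecutive non-overlapping 15-minute blocks from t = 0.
Each block after the first yields a sample: fine input = the preceding block's
(rows × 36) matrix; context = 24 five-minute rows covering [t0−135 min,
t0−15 min), each holding per-channel means, two event-occurrence flags and a
validity flag (rows before episode start are zeroed, validity 0); label = any
detected event of the task's kind overlapping [t0, t0+15 min). Both interval
conventions are half-open. Nothing at or after t0 feeds any feature (enforced
by a mutate-and-compare test). `input_hz` < 1 strides the fine matrix (0.2 Hz
→ 180 rows) without changing window semantics; desk-scale runs use 0.2 Hz.

The split is episode-level and stratified: episodes group into none /
respiratory-only / cardiovascular-only / both by their detected events, and
each stratum splits 80/10/10 by seeded shuffle with largest-remainder
rounding. All windows of an episode share its split.

## Model family

Six architectures share a branch vocabulary:

1. `baseline_only_ff` — feed-forward over the full baseline ⊕ feed-forward
   over the diagnosis embedding.
2. `combined_ff` — a time-distributed linear + ReLU + mean-pool over the fine
   matrix and the context ⊕ reduced baseline ⊕ diagnosis embedding.
3. `vitals_only_transformer` — the transformer branch alone.
4. `combined_transformer_onehot_reduced` — transformer ⊕ reduced baseline
   (which already carries the one-hot diagnosis block).
5. `combined_transformer_vector_reduced` — transformer ⊕ reduced baseline ⊕
   diagnosis embedding (the flagship).
6. `combined_transformer_vector_full` — as 5 with the full baseline.

The transformer is decoder-only (strictly causal attention, verified by test)
with rotary positional embeddings. The 24 context rows are linearly projected
to model width and prepended as coarse tokens before the fine tokens, with
rotary positions continuing across the boundary; the last token's hidden
state (which attends everything) feeds the head. Defaults: width 64, 2
layers, 4 heads, feed-forward multiplier 2, dropout 0.1 — 143,617 trainable
parameters for the flagship at the reduced-baseline width, comfortably under
the 700,000-parameter envelope the design targets for edge deployment.

Token-projection biases are initialised at small non-zero values: with
zero biases, the all-zero ("fully imputed") input maps every token exactly
onto layer normalisation's degenerate point, making the network's output
effectively discontinuous there — which breaks any attribution path anchored
at that baseline (see below).

Everything runs on a compact reverse-mode autodiff engine over numpy
(float32 by default, float64 preserved end-to-end for gradient checks), with
fused attention/layer-norm/GELU/rotary kernels whose hand-written backwards
are verified against central differences. Training uses Adam,
binary cross-entropy with positive-class weight n_neg/n_pos (inverse
prevalence), optional L2 and max-norm constraints, seeded shuffling and
dropout, and best-epoch selection by tuning-set AUROC. "Positional
weighting", offered as a searchable toggle, linearly scales token embeddings
by recency (0.5 → 1.5); the `batch_norm` toggle applies per-branch layer
normalisation (batch-independent, so prediction stays batch-size invariant).
Hyperparameter search is random sampling from a declared space, ranked by
tuning AUROC, with the full leaderboard persisted.

## Evaluation

AUROC via the rank/Mann–Whitney identity (mid-ranks for ties); AUPRC by
step integration (Σ ΔR·P, no trapezoid). The operating threshold is chosen on
the tuning set as the smallest observed score whose false positive rate is
≤ 20 % — the most sensitive cut with specificity ≥ 80 % — and frozen for the
test set. Predicted positive means score ≥ threshold. Confidence intervals
are class-stratified bootstrap percentiles (2.5/97.5) over 5,000 replicates
by default, resampling positives and negatives separately with class counts
preserved; replicates where a metric is undefined (e.g. PPV with no predicted
positives) are excluded from that metric's percentiles and counted. Class is
the only stratum used for resampling.

## Attribution

Integrated Gradients with a midpoint Riemann path (default 50 steps) from an
all-zero baseline — the model's "fully imputed / no information" reference,
which coincides with the mean-imputation convention. All path points are
evaluated as one batch; gradients flow to the inputs through the same
autodiff graph used for training. The completeness gap |Σ attributions −
(F(x) − F(baseline))| is reported on every call and falls below 0.01 on the
probability scale by 200 steps. Cohort-level importance sums |attribution|
within named feature groups (channels merged per modality, value + mask
columns together, diagnosis embedding as one block; context channel-means
join their channel's group), averaged over windows and stratified by
predicted class; per-second traces for a named channel sum the value and mask
column magnitudes for plotting against the raw signal. Masks are attributed
together with values — whether to attribute masks at all is a genuinely open
choice; summing both per channel reports the channel's total influence
including its informative missingness.

## Pipeline

`pipeline run` executes simulate → label → window → train → evaluate →
explain under one output directory with one YAML config. Every stage records
a key (hash of its config section and its input artifact hashes) and a
content hash of its outputs in `manifest.json`; a stage re-runs only when its
key changes or its outputs are missing. Caching is content-addressed: if a
deleted intermediate regenerates byte-identically, downstream stages may
validly remain up to date. `benchmark_inference` reports per-window latency
statistics and deliberately asserts nothing.

## Problem sizes

The packaged study conditions are 200 simulated episodes at the default
configuration, windowed at 0.2 Hz (≈ 1,400 windows), with the flagship
transformer trained for 4 epochs and ablation/threshold checks on smaller
variants (width 32, 1 layer, 2 epochs). These sizes are the package's chosen
desk-scale defaults; all of them are config fields.

## Known limitations

- Synthetic data only; no claim about real-transport performance transfers.
- The labeller's EMA half-life, band multiplier, warm-up, and the winsorised
  update rule are defensible defaults, not identified from data.
- The hashing diagnosis embedding carries no clinical semantics; two
  synonymous diagnoses written differently embed far apart.
- The generator's precursor is a linear ramp — the simplest learnable
  lead-time signal; real precursors are heterogeneous.
- Full-baseline membership (30 groups) is a reconstruction.
- The bootstrap stratifies by class only, not by the four deterioration
  strata.
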