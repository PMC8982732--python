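# Methods

This note records the models behind `recoverhome`, the parameters that
matter, the choices made where the design was genuinely open, and what
the synthetic data does and does not establish.

## Time and units

All internal timestamps are seconds from the observation start, with
t = 0 at local midnight of day 0 and day 0 a Monday (`day % 7 ≥ 5` is
the weekend). CSV serialisation anchors this axis at 2018-01-01T00:00Z,
a Monday. Acceleration is in g with gravity included, so a motionless
wrist reads |a| ≈ 1; RSSI is in dB (all values negative).

## RSSI channel and fingerprint localisation

Received power from a gateway at distance d follows the log-distance
model `rssi = P₀ − 10·n·log₁₀(d) + N(0, σ)` with defaults
P₀ = −40 dBm (power at 1 m), path-loss exponent n = 2.5 (indoor,
through-wall propagation), shadowing σ = 3 dB, and a −100 dB
out-of-range cut-off. Gateways emit nominally once per second with 10%
packet loss — a cadence choice, since real deployments vary; the
per-window reading counts are kept in `DataFrame.attrs` so the effect
on the cadence-dependent *sum* statistic stays auditable. Floors are
3 m apart; distances are 3-D and clamped at 0.3 m.

Fingerprints are built over half-open windows [t, t+1) aligned to
integer seconds. A window where every gateway is silent yields no
vector at all (no data exists); a silent gateway inside a covered
window is treated as a single synthetic reading at −100 dB, making its
block (−100, −100, −100, −100, 0) — the minimal, order-preserving
reading of the substitution rule. Variances use ddof = 0 so one reading
gives variance 0.

The classifier is scikit-learn's `MLPClassifier` with hidden layers
(10, 10, 10) behind a `StandardScaler` (the −100 substitutions put
features on wildly different scales; standardisation is needed for the
optimiser to converge). Labelled vectors from both walk-around passes
are pooled, shuffled and split 60/40, stratified by room so rare rooms
appear on both sides. The grid — solver ∈ {adam, sgd} ×
learning-rate ∈ {10⁻², 10⁻³, 10⁻⁴} × momentum ∈ {0.5, 0.9} (momentum
applies to sgd only) — is selected on *training-set* score, an
optimistic rule kept deliberately; held-out metrics are accuracy and
support-weighted precision/recall/F1. Ties in the MLP's class scores
resolve to scikit-learn's default (first class in sorted label order).

Behaviour to expect: with a fully deterministic channel (shadowing and
packet loss both zero) each room maps to one exact fingerprint and test
accuracy is 1.0; with packet loss alone the substitution randomises
fingerprints combinatorially and the small MLP sits near 0.96; accuracy
then degrades monotonically with shadowing (≈ 0.92 at 3 dB, ≈ 0.75 at
6 dB, ≈ 0.57 at 10 dB on the 7-room home). Rooms closer than ~1.5 m
(kitchen/laundry, hall/stairs in the 11-room layout) dominate the
confusion matrix.

## Actigraphy

The magnitude series is summarised per second (mean/min/max/std,
ddof = 0) and then per minute: `mean_g` is the minute mean of
per-second means and `std_g` the minute mean of per-second standard
deviations. Minutes with no samples are imputed — zero by default (the
simplest defensible rule for "out of home means no movement recorded"),
or linearly interpolated — and flagged.

**Activity index.** Rhythm metrics are computed on `std_g` (movement),
not on raw `mean_g`. Raw mean magnitude contains the constant 1 g
gravity offset, so a sleeping participant would register *high*
activity relative to zero-imputed out-of-home minutes, and the
least-active window would lock onto the longest out-of-home stretch
rather than sleep. Movement is the quantity the rest–activity concepts
are about; every rhythm function takes an explicit column argument for
users who want a different index.

L5/M10 are found on the average 24-h profile (mean per clock minute
across full midnight-to-midnight days; partial edge days excluded),
scanning all 1440 window starts with wrap-around; ties break to the
first start scanning from 00:00. For a span of days with zero activity
23:00–07:00, every 5-h window inside the zero span ties and the rule
returns 00:00. IS and IV follow the hourly-means convention of
non-parametric actigraphy (hourly means of the minute epochs; p = 24
clock-hour bins):

    IS = (n · Σₕ (x̄ₕ − x̄)²) / (p · Σᵢ (xᵢ − x̄)²)
    IV = (n · Σᵢ (xᵢ − xᵢ₋₁)²) / ((n − 1) · Σᵢ (xᵢ − x̄)²)

Closed forms used as oracles: identical days give IS = 1; an
alternating ±1 hourly series gives IV = 4 exactly; an hourly sinusoid
gives IV = 2(1 − cos 2π/24) ≈ 0.068; i.i.d. noise gives IV ≈ 2. IV is
defined on the *linear* hourly sequence, so shifting all timestamps by
6 h changes one boundary difference term; onsets, IS and RA are exactly
shift-equivariant, IV to O(1/n). Constant series make IS/IV undefined
and raise. ΔT is the signed circular minute difference in (−720, 720],
positive when L5 starts after the reported bedtime.

The daily movement trend is the per-day mean of `std_g` over observed
(non-imputed) minutes only — imputed zeros would conflate "away from
home" with "immobile". Rhythm metrics, by contrast, keep the zeros, in
line with zero-imputation being part of that analysis.

## Activity recognition

Windows are 6 s with a 3-s step (150 samples at 25 Hz, 50% overlap);
windows never span gaps (sample spacing > 1.5× nominal breaks a run),
and a contiguous T-second run yields ⌊(T − 6)/3⌋ + 1 windows. The
gravity-free signal is the L2 norm of the axes minus 1 g: the histogram
bins span [−4, 4] symmetrically, which only makes sense for a
zero-centred signal, so the static offset must come off. Per-axis
mean/std are computed on raw axes (orientation is itself informative —
lying rotates gravity into a different axis). Histogram counts are
divided by the window's sample count with out-of-range samples clipped
into the edge bins, so the block always sums to 1.

The forest is scikit-learn's `RandomForestClassifier` with 100 trees,
Gini splits, √p features per split, bootstrap resampling. The forest
seed is chosen from a pool by highest training accuracy — preserved as
the study protocol but flagged here as optimistic (training accuracy
for a forest is near 1 and the choice is close to arbitrary); reported
performance comes from pooled out-of-fold predictions of a stratified
5-fold CV, which is unaffected by that selection. Folds shuffle windows
globally; a `groups` split per home is a natural hardening but is
deliberately not the default, matching the study design.

## The synthetic home

The generator is the package's definition of the study conditions, not
a tuning knob.

*Layout.* Rooms come from a fixed catalogue (bedroom, kitchen,
bathroom, living room, hall, study, dining room, then stairs, laundry,
porch, bedroom 2) on a two-floor grid with ±0.15 m jitter; homes of
≥ 11 rooms contain two adjoining pairs (kitchen/laundry, hall/stairs,
< 1.5 m apart) that make localisation genuinely hard. Gateways sit near
an even spread of rooms. Adjacency is the Euclidean MST plus all pairs
under 2 m.

*Routines.* Days run 07:00–23:00 awake with sleep in the bedroom
(lay down). Daytime is allocated by per-profile shares, round-robin in
four chunks per activity so every hour mixes postures, with one
contiguous mid-day out-of-home block. `control`: out on weekdays
(09:00–17:00-ish), home at weekends, bedtime exactly 23:00.
`recovering`: out-of-home time and walking ramp up linearly over the
span while daytime bedroom rest shrinks. `withdrawing`: bedroom share
and sitting grow, walking declines. Bedtimes for the patient profiles
jitter by ±15 min (clamped to 22:00–23:45) and are recorded per day as
the self-report for ΔT.

*Acceleration.* Per activity: a gravity direction (lying rotates
gravity to the x axis; sitting tilts it), an isotropic jitter expressed
as a multiple of the sensor noise floor (`accel_noise_std_g`, default
0.01 g; multiples 1.0 / 1.5 / 3 / 3 / 4 for lay down / sit / stand /
walk / stair) and, for walk and stair, a sinusoid at the gait frequency
(1.8 Hz, amplitudes 0.30 and 0.45 g). Walking comes in bouts (mean 12 s)
separated by standing pauses (mean 4 s), and standing includes
occasional shuffling bursts — this overlap is what makes walk↔stand the
dominant confusion, the error mode wrist-worn recognisers actually
show. A zero noise floor reduces lay-down to pure gravity (|a| = 1
exactly).

*Out of home* is total silence on both channels (the wearable is out of
BLE range). Gateway failures remove whole days of one gateway's RSSI,
leaving acceleration untouched. Day-chunked simulation
(`simulate_stream_days`) slices routines at midnight and draws each
day's randomness from a (seed, day) stream, since a 90-day 25 Hz record
(~200 M samples) should never be materialised at once.

What the generator does *not* emulate — multipath and furniture-driven
RSSI drift, multi-resident interference, wearable non-wear, irregular
real-world routines — bounds what green tests mean: they show the
analysis chain recovers the structure the models assume, not that it
is robust to every failure mode of real homes.

## Reporting

The hourly modal grid takes, per day × hour, the plurality location
(ties → the label more frequent overall, then lexicographic; empty
hours are *unknown*) and the plurality activity, flagging hours whose
dominant activity is ambulatory (walk/stair) or standing; L5/M10 bands
are drawn at the profile's onsets. The movement spiral keeps per-minute
`std_g` values at or above the 75th percentile (linear-interpolation
quantile, ties retained), blanking the rest. `run_pipeline` derives all
stage seeds from one master seed via `SeedSequence`, writes only inside
its output directory, and produces byte-identical non-image artefacts
for identical configs.

## Problem sizes

Tests and the acceptance script run the walk-around protocol at its
natural size (2 passes × ~50 s × rooms), rest–activity analysis on 7–14
simulated days, trend recovery on the full 90-day span (day-chunked,
single-modality streams), and the classifier benchmarks on ten scripted
experiments (~1300 windows). These sizes are the package's standard
benchmark configuration.

## Known limitations

- The −100 dB substitution makes fingerprints depend on packet loss;
  a localiser robust to gateway outages (e.g. per-gateway ensembles or
  failure-augmented training) is intentionally out of scope, and the
  outage pathology (predictions drifting toward rooms near surviving
  gateways) is left observable.
- Zero-imputation biases rhythm metrics for participants who are often
  out: the averaged profile mixes "away" with "rest". The epoch table
  flags imputed minutes so alternative imputations can be compared; IV
  shifts under imputation choice are regression-tested, not pinned.
- Seed-selection by training accuracy and tuning on training-set score
  are retained as protocol; both are optimistic and are documented as
  such rather than silently corrected.
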