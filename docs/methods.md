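# Methods

This note documents the models implemented in `sleepmat`, the synthetic
data they are validated on, the numerical choices, and what the tests
do and do not demonstrate.

## Sensor model

A piezoelectric channel under periodic force `F(t) = F_m sin ωt`
produces, through the charge constant `d33` and the amplifier's
equivalent input resistance/capacitance `R_M, C_M` with gain `β`, the
voltage amplitude

```
U = β d33 F_m ω R_M / sqrt(1 + (ω R_M C_M)^2).
```

For `(ω R_M C_M)² ≫ 1` this saturates at `U = β d33 F_m / C_M`: output
is proportional to force and the sensitivity is frequency-independent
(the linear regime). Motion artifacts violate this regime, which is
why nonlinearity-sensitive entropy features can detect them. With the
default constants (`d33 = 200 pC/N, β = 100, R_M = 10 MΩ, C_M = 10 nF`)
the condition holds well at the BCG carrier (~6 Hz, ωR_MC_M ≈ 3.8) and
only marginally at the respiratory frequency (0.25 Hz, ωR_MC_M ≈ 0.16).
The simulator applies the linear map throughout and the intensity
estimator inverts the saturated form; this tension is inherited from
the device description and noted here rather than resolved.

## Synthetic cohort

No clinical dataset of this device type is publicly deposited, so the
generator is part of the package's contract, not a test fixture. One
minute of one channel is

```
U_c(t) = w_res,c · U_res(t) + w_bcg,c · U_bcg(t) + σ · w̄_c · ε(t)
```

* `U_res`: sinusoid at `f_res` (default 0.25 Hz) with per-cycle
  amplitude jitter (SD 5 %) and *anchored* per-cycle frequency jitter
  (SD 1 %): cycle boundary *i* sits at `(i + η_i)/f` with independent
  `η_i`, so durations fluctuate but phase does not random-walk. A
  drifting phase would annihilate the constant-frequency fits (the AM
  carrier sees ~360 cycles/minute), contradicting the fit quality
  observed on real mats; anchored jitter reproduces it.
* `U_bcg`: `U_Am (1 + M_bcg cos 2πψ) cos 2π·5ψ` with beat phase ψ from
  the same anchored construction — exactly five carrier (IJKL) cycles
  per heartbeat. Defaults `U_Am = 0.26, M_bcg = 0.4`.
* `ε`: white Gaussian noise, `σ = 0.12`, scaled by the mean coupling
  weight `w̄_c` (body-coupled noise dominates sensor noise; this keeps
  the energy mix channel-invariant).

The amplitude defaults were set by closed-form power arithmetic
(sinusoid power `A²/2`, AM power `U_Am²/2·(1+M²/2)`, band-split noise)
so that the decomposition yields ≈ 90 % respiratory, 5–8 % BCG, < 3 %
residual energy — the energy budget characteristic of chest-area piezoelectric recordings. The
FIR window attenuation (42 dB) is part of that calibration: passband
droop moves respiratory energy into the *residual-defined* deviation
energy, so flatness and stopband depth were balanced.

**Spatial templates.** Coupling weights live on the 4 × 8 grid
(row-major channels, columns increasing toward the subject's left).
Supine: broad thoracic contact, cardiac lobe slightly left of midline.
Lateral: a narrow ridge on the supporting side plus a broad
counterweight on the opposite side, so the weight *centroid* falls
opposite the *maximum* relative to the grid midline (static moment
balance — the body tilts opposite to its centre-of-gravity offset).
Subject-level templates redraw lobe widths (body build), counterweight
strength, body position on the mat, and per-channel coupling jitter;
supine sleepers may carry a partial lateral tilt. This structural
diversity is calibrated so posture classification from maps of unseen
subjects is good but imperfect, matching the imperfect map separability
seen on real mats rather than a trivially separable geometry.

**Physiology.** Subjects draw `f_res ~ N(0.25, 0.025)` Hz,
`f_hea ~ N(1.2, 0.10)` Hz, lognormal amplitude scales, and a movement
rate ≈ 11 % of minutes. Posture modulates physiology at the population
level (supine: slower, deeper breathing; left vs right lateral:
opposite small shifts of heart rate and of BCG coupling — the heart
sits left of the midline), giving the temporal pathway genuine but
imperfect posture information, as real-mat ablation behaviour implies.
Within a night, rates drift a few percent from minute to minute
(lognormal SD 6 % for breathing, 4 % for heart rate), reflecting sleep
depth changes; without this drift a subject's absolute heart rate is an
unrealistic "fingerprint" that a classifier can memorise.

**Movement.** A contaminated minute receives 1–4 bursts of 2–10 s on
7–32 channels: random-walk excursions hard-clipped at 3× the clean
signal range (saturation is the nonlinearity the entropy features
target). Schedules hold 16–26 posture segments per full night; supine
bouts run longer than lateral ones (mean duration ∝ 1/(1−π)), which
makes the expected time mix equal the target 49.8/33.6/16.7 % split.

## Decomposition

1000-tap (order 999) linear-phase FIR band-passes built as the
difference of two DC-normalised Dolph-Chebyshev (42 dB) low-passes —
this places an exact null at DC. Applied in a single pass over
odd-reflection-padded signals (point symmetry about the endpoints, as
in zero-phase filtering), with the 500-sample group delay removed; the
residual half-sample shift is negligible below 15 Hz. Note a physical
limit: at fs = 100 Hz a 1000-tap filter has a ≈ 0.2 Hz transition band,
so strong attenuation one octave below the 0.1 Hz edge (i.e. at
0.05 Hz) is unattainable at this order; the design is instead exact at
DC and ≥ 40 dB an octave outside all other edges.

Energies are sums of squares of the delay-compensated components over
the full minute (edge transients included; with odd-reflection padding
they are ≲ 0.1 % of energy). The deviation energy is *defined* as
`composite − (resp + bcg)` energy and can differ slightly from the
energy of the deviation signal; on clean synthetic minutes the two
agree within 2 % of composite energy at the minute level (individual
channels can deviate a few percent through the edge transients).

## Artifact screening

Energy entropy: Shannon entropy (natural log) of the normalised
per-window energy vector; windows that would overrun the signal are
dropped; an all-zero signal scores 0. ApEn follows the standard
convention (self-matches included, Chebyshev distance,
`r = 0.2·SD`); the implementation counts neighbour pairs exactly with
a sorted-window sweep (O(N·W), numba-compiled) and is tested to 1e-9
against a naive O(N²) reference. For the per-channel feature vector,
ApEn is computed on bandwidth-matched decimated components (respiration
×10, BCG ×2, deviation ×5): the regularity contrast survives decimation
while the cost of 96 ApEn evaluations per minute drops by two orders of
magnitude. The six features are z-scored (their natural scales span
0.2–8 nats) and feed an `sklearn` MLP (one hidden layer of 12 logistic
units, ≤ 500 iterations, stopping on a training-loss plateau, decision
threshold 0.5) trained on the generator's per-channel ground truth; a
minute is flagged at ≥ 7 interfered channels (count-reaches-threshold
reading).

One empirical note: under the clipped-burst artifact model the
*deviation-component* ApEn falls on contaminated channels (bursts
inflate SD and hence `r`; clipped plateaus are self-similar) while the
respiratory-component ApEn rises; both directions are stable in ≥ 90 %
of paired trials and the classifier uses them symmetrically.

## Feature extraction

The respiration fit solves amplitude/phase linearly on a frequency grid
around the in-band DFT peak (±1 bin, parabolic sub-bin start). The AM
fit estimates the heart rate from the envelope's DFT peak and the
carrier from the raw spectrum, seeds `U_Am, M` from a linear
three-cosine fit (carrier plus both sidebands with free phases — the
same collapse that motivates the AM form), then refines the constrained
AM model with bounded least squares. Minutes whose *global* spectral
peak falls outside the physiological band (respiration 0.1–0.8 Hz,
envelope 0.8–3 Hz) are rejected as unusable. The envelope is the
analytic-signal magnitude smoothed by a forward-backward 4th-order
Butterworth at 3 Hz.

Intensities: for a sinusoid of amplitude A the summed absolute
first difference over N samples equals `4 A f N Δt` (4A per cycle),
so `A = Σ|ΔU| / (4 f N Δt)` needs neither phase nor time origin; the
force intensity is `A · C_M/(β d33)`. For the cardiac map the input is
the BCG envelope, whose oscillating amplitude is `U_Am·M`, and the
estimate divides by the separately fitted `M`. The estimator is exact
on noiseless sinusoids (≤ 1 %); in-band noise biases it upward, which
is immaterial for the maps (the CNN sees per-map max-normalised
images) and is why the *parameter-recovery* checks use the fits, not
the variation estimator. Maps are upsampled 4× by bicubic
interpolation (16 × 32), clipped at zero (bicubic overshoot), and
smoothed with a Gaussian of σ = 1 upsampled-grid unit.

Temporal features aggregate channels by band-energy weighting (the
best-contact channels dominate), then: respiration → 5-point moving
average → peaks between upward zero crossings (open half-cycles at
the record edges included; half-cycles under 20 % of the median span
discarded as crossing artifacts) → piecewise-constant
expansion (amplitude and gap-in-seconds held between peaks, 2 × 6000)
→ linear resampling to 2 × 90; heartbeat → envelope → the same chain →
2 × 180. Intervals are stored in seconds; the network only needs a
consistent unit.

## The network

Branch shapes follow the fixed layer table; maps are fed long-axis
first (32 × 16) so the final (4, 2) valid convolution reduces exactly
to 1 × 1 × 32 (with 16 × 32 orientation those shapes are infeasible);
an adaptive max pool guards the reduction. The 1-D branches end in
global average pooling, so all four branches emit 32-vectors; the
32 × 4 stack flattens into dense 64 → 96 → softmax(3) (widths as
specified, even though narrowing then widening is unusual). Training:
Adam lr 1e-3, batch 48, hard cap 100 epochs, L2 weight decay 5e-4 in
the optimiser *and* L1 1e-5 on dense weights (both regularisers are
part of the published recipe), dropout 0.5 after each dense layer.
Initialisation is fan-in uniform from one seeded generator; training is
bit-reproducible given (data, seed). Temporal input rows are z-scored
per row type with training-set statistics; maps arrive max-normalised
per map. The net has ≈ 55 k parameters and runs in float32 (a module
switch restores float64 for gradient verification, which matches
central differences to 1e-7).

## Evaluation protocol and problem sizes

Folds partition subjects (10 folds; 2–3 subjects per fold at cohort
size 22), never minutes; per round the 10 confusion matrices are
summed and metrics computed from the sum; macro averaging over the
three classes; "total AUC" is the macro mean of one-vs-rest areas.
Contaminated minutes are excluded before CV. If a split's training
fold misses a class, the plan is reshuffled and logged.

Problem sizes in the shipped benchmarks are the package's choices for a
single-workstation run: the energy/fit statistics use 50 simulated
minutes, parameter recovery 100, artifact screening 500 (train on three
subjects' channels, test on two held-out subjects), and the CV
benchmark 12 subjects × 120 minutes with one round of 10-fold CV and
30 epochs per fold, per ablation variant (temporal-only, spatial-only,
combined). On this benchmark the combined network exceeds 85 % accuracy
and the ablation ordering (temporal < spatial < combined) reproduces
the qualitative finding that map and rhythm information are
complementary.

## What passing tests show — and what they do not

The synthetic cohort demonstrates *internal* correctness: filters meet
their design points, estimators recover the generating parameters,
the artifact stage detects the nonlinearity it was built for, and the
network learns and fuses both feature families under subject-grouped
validation. It does not demonstrate clinical performance: real mats
face unmodelled phenomena — posture transitions inside a minute,
bed-partners, prone posture, apnea events, long-term sensor drift,
body-type extremes — and the generator's posture-physiology couplings,
while directionally defensible, are stylised. Accuracy figures on the
synthetic benchmark are therefore properties of the benchmark, not
claims about patients.

## Known limitations

* The deviation component is defined by subtraction, so filter
  passband imperfections surface there; the 42 dB window is a
  compromise, not an optimum.
* ApEn decimation factors are tuned to the default bands; radically
  different physiology would warrant re-matching.
* The AM fit fixes one carrier and one modulator; arrhythmic beats
  violate it and surface as rejected or low-R² minutes.
* `estimate_intensity` assumes the saturated (high-frequency) sensor
  transfer for all components, marginal at respiratory frequencies.
* With 12 synthetic subjects, fold composition is a visible source of
  CV variance; the benchmark fixes its seeds for reproducibility.
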