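# Methods

`mupool` reimplements, over simulated recordings with known ground truth,
the full analysis chain used to characterise motor-unit rate coding from
high-density surface EMG (HD-EMG): signal generation, convolutive
blind-source-separation (BSS) decomposition into motor-unit spike trains,
tracking of the same units across contraction levels, waveform-based
validation, and rate-coding characterisation. This note records the
models, the parameters that matter, the numerical choices made where the
design was genuinely open, and what the simulations do and do not show
about real recordings.

## Signal model and synthetic data

A motor unit comprises one alpha motoneuron and the muscle fibres it
innervates; each discharge imprints a spatiotemporal action-potential
waveform (MUAP) on the electrode grid. The monopolar HD-EMG recording is
modelled as a linear convolutive mixture: per unit, a unique spatial
template convolved with its discharge train, summed over units, plus
additive white Gaussian noise scaled to a prescribed signal-to-noise
ratio (20 dB by default, defined as clean-signal power over noise power
averaged across channels).

The simulator emulates the force-matching protocol used in isometric
ramp studies: trapezoidal targets with ramps at 5 %MVC·s⁻¹ and plateaus
of 20 s (targets up to 40 %MVC), 15 s (50–60 %MVC) or 10 s (70–80 %MVC),
sampled at 2048 Hz on 13×5 electrode grids with one corner electrode
absent (64 electrodes per grid, 4 mm inter-electrode distance; four
grids give 256 monopolar channels).

The motoneuron pool follows the size principle:

- **Recruitment thresholds** lie on an exponential-in-rank ladder
  rt_i = rt_lo·(rt_hi/rt_lo)^((i−1)/(n−1)) with 3% multiplicative
  jitter, reproducing the many-low/few-high density of thresholds
  observed in vivo (defaults span 0.9–73.4 %MVC for the 150-unit pool).
- **Rate coding** above recruitment follows f(F) = a·ln(F) + b (pps,
  F in %MVC), clipped below at a minimum rate of 4 pps so that the
  logarithm never implies sub-physiological rates just above
  recruitment. Per unit, a and b are solved from a rate at recruitment
  drawn in 6–10 pps and a rate at 100 %MVC drawn in 25–45 pps.
- **Discharge variability**: inter-spike intervals are the reciprocal of
  the instantaneous rate jittered by a multiplicative Gaussian factor
  truncated at ±3 SD, with coefficient of variation 0.15 by default — a
  conventional renewal-process surrogate; the exact ISI noise model is
  an open choice and is exposed in the configuration.
- **Hysteresis on demand**: each unit carries a derecruitment offset
  (default 0). A negative offset keeps the unit firing below its
  recruitment threshold on the ramp-down, producing a positive
  recruitment-minus-derecruitment hysteresis, the signature of
  persistent inward currents.
- **MUAP templates** are a surrogate for a full cylindrical
  volume-conductor model: a first-order Hermite–Rodriguez waveform
  (t/σ)·e^(−(t/σ)²) with per-unit σ in 0.8–2.5 ms, amplitude decaying
  exponentially (length scale 5–10 mm) with electrode distance from a
  random territory centre, onset delayed by |y − y_iz|/v along the
  fibre (column) direction from a per-unit innervation zone at
  propagation velocity 3–5 m/s, and peak amplitude proportional to unit
  size (sizes grow exponentially with recruitment rank). Downstream
  stages only require what this surrogate guarantees: a unique spatial
  signature per unit, amplitude decay with distance, and propagation
  along columns.

Force is prescribed, not emergent from twitch summation, so the
simulation cannot probe force-production questions — only the
signal-analysis chain.

## Decomposition

The convolutive mixture is made approximately instantaneous by extending
each channel with delayed copies — the extension factor is the smallest
R with channels·R ≥ 1000 extended channels; row k·R+d is channel k
delayed d samples with leading zeros — then centring and spatial
whitening by eigen-decomposition of the covariance. Eigenvalues below
10⁻⁹ of the largest are floored to the mean of the smallest half of the
spectrum: rank-deficient inputs (duplicated or silent channels) are
handled without failure, while well-conditioned inputs whiten exactly
(post-whitening covariance within 10⁻⁶ of identity, which is also the
tested invariant).

Separation vectors are estimated one at a time by a fixed-point
iteration on the log-cosh contrast, w ← E[z·tanh(wᵀz)] −
E[1−tanh²(wᵀz)]·w, renormalised each step and orthogonalised against
previously accepted vectors (deflation). Convergence is declared when
|1 − |wₙᵀwₙ₋₁|| < 10⁻⁴, the standard fixed-point angle criterion;
formulations based on the change of a pulse-train sparsity statistic
exist but no canonical statistic is established, so the angle criterion
is used at the same tolerance. Each attempt is
initialised with the whitened observation column at the time of highest
squared activity not yet claimed by an accepted unit; 40 attempts per
recording by default.

Discharges are the high peaks of the squared source estimate: local
maxima at least 10 ms apart (physiological refractoriness; the minimum
distance is not stated in the source and is configurable) are split into
two amplitude classes by 2-class centroid clustering, and the
higher-centroid class is kept. Acceptance requires a two-class
silhouette — averaged over the spike class — of at least 0.9, and at
least 10 discharges. Duplicate estimates (the same unit recovered at a
different delay) are linked when, after aligning the binarised trains at
the lag maximising their cross-correlation, at least 30% of discharges
coincide within 0.5 ms; the denominator is min(n₁, n₂), the conservative
reading. Within each connected component of duplicates the train with
the lowest ISI coefficient of variation is retained.

## Tracking across contraction levels

Consecutive contraction levels are decomposed independently; tracking
then asks which estimates are the same physical unit. A unit's
separation vector from one level is carried into the other level's
recording: the second recording is extended with the first
decomposition's extension factor, centred with its stored mean, whitened
with its stored whitening operator, and projected onto its vectors — the
only self-consistent choice, since the vectors live in that whitened
space. Reprojected trains are used only when the spike class separates
cleanly from the noise, operationalised as silhouette ≥ 0.9, and matched
against the natively identified units with the same >30%-common-discharge
criterion as duplicate removal.

One design choice deserves emphasis: the vectors of the **higher** level
are projected onto the **lower** level's recording, the reverse of the
direction usually described for this procedure. In the forward direction the
lower-level vectors meet interference from newly recruited — typically
larger — units they have never seen, which contaminates the pulse trains
and fails the silhouette gate for most shared units in our simulations;
in the reverse direction newly recruited units simply fall silent, and
every shared, cleanly decomposed unit reprojects at rate-of-agreement
1.0. The outcome structure is identical: units only at the lower level,
units at both, units only at the higher level. Pairwise matches between
consecutive levels are merged transitively into a registry of unique
units; conflicting chains are resolved by the highest common fraction.

Agreement between two discharge series is scored as
RoA = TP/(TP+FN+FP) with greedy one-to-one nearest matching after
optimal lag alignment. Where the 0.5 ms window of the duplicate
criterion is prescribed, it is used; agreement with simulation ground
truth uses a 2 ms tolerance, since peak detection on the squared source
jitters by about a sample around the convolution-aligned discharge time.

## Waveform validation

Explained signal power: monopolar signals are differentiated along grid
columns into single-differential (SD) channels (236 for four
13×5-minus-corner grids); each unit's SD action-potential template is
the spike-triggered average over 25 ms windows centred on its
discharges; templates convolved with the discharge trains and summed
give a synthetic EMG, and the ratio of synthetic to recorded mean-square
power (per channel, then averaged across channels) over the force
plateau estimates the fraction of signal variance the decomposition
explains. In the simulation this ratio has a known ceiling,
P_clean/(P_clean + P_noise) — about 0.99 at 20 dB — against which the
measured ratio is compared.

Uniqueness audit: per tracked unit and level, 50 ms templates
(floor(0.050·fs) = 102 samples at 2048 Hz) over all SD channels are
concatenated into one matrix. Because separate decompositions recover a
unit's train at arbitrary constant delays, each level's matrix is first
aligned to the unit's first-level matrix by the best joint time shift.
The unit's reference value is the mean RMSE between its matrices across
levels (all pairs when tracked over more than two levels); RMSE between
two matrices is normalised by the maximum absolute amplitude over both
(keeping the measure symmetric) and reported in percent. A unit is
unique when its reference lies below the 5th percentile of its RMSE
distribution against all other units' mean templates; units whose
reference exceeds the 95th percentile of the pooled reference
distribution are flagged as probable tracking errors and excluded from
rate-coding analyses.

## Rate-coding characterisation

Instantaneous rate is the reciprocal ISI assigned to the later discharge
of each pair. Per unit, (force, rate) pairs pooled over all ramp-up
phases where it was tracked are fitted with three candidates — linear
aF+b (p=2), rising exponential a(1−e^(−F/b))+c (p=3), natural logarithm
a·ln F+b (p=2) — on the same points. The linear and logarithmic models
are linear in their parameters and solved directly; the exponential uses
a bounded nonlinear least-squares solver capped at 1000 iterations,
started from the data range. The best model minimises
BIC = n·ln(sse/n) + p·ln(n); ties go to fewer parameters, then to the
logarithm. Ramp-down phases are fitted the same way.

The initial acceleration of firing rate is the derivative of the
logarithmic fit at the recruitment threshold, a/rt, in pps per %MVC; the
5 %MVC·s⁻¹ ramp maps it to pps·s⁻¹ (both are reported, since the two
scales appear interchangeably in the literature). The recruitment
threshold is the force at the unit's first discharge when that falls in
the ramp-up; the derecruitment threshold is the force at its last
discharge in the ramp-down; units firing only during the plateau are
flagged not-assessable, and thresholds pooled over several contractions
are averaged. Hysteresis is rt − drt with the printed sign convention:
negative values indicate prolonged firing on the ramp-down (a
hysteresis), positive the reverse. Second-stage rate coding is the mean
instantaneous rate over each plateau and its increment between
consecutive 10 %MVC levels. Pool-level relations (requiring at least 20
units): initial acceleration vs rt fitted as c/rt (the form implied by
the derivative of the log model) with adjusted R²; increment vs rt by a
linear fit with Pearson r and p; rt vs drt by linear and quadratic fits
compared by BIC. Units are grouped by recruitment threshold as low
(0–25 %MVC), medium (25–50) and high (50–75).

## Validation scenario and problem sizes

The standing validation condition is ten well-separated units
(thresholds 2–25 %MVC, amplitude span 1–3, ISI CoV 0.15) recorded on one
64-electrode grid at 20 dB over three contractions at 10/20/30 %MVC,
with all randomness derived from a single seed. At this scale one full
run — simulation, three decompositions, tracking, validation, fitting —
takes a few minutes on one core. The model-selection study samples
(force, rate) observations directly from each generating model (n=500
over 5–80 %MVC, noise SD 5% of the rate range), within the mild-noise
envelope under which BIC selection is expected to be consistent;
generator-driven (spike-train) log-fit recovery is verified separately
at the 10% tolerance appropriate to its higher intrinsic rate noise.

## Known limitations

- The MUAP surrogate has no volume-conductor physics (no far-field
  components, no fibre-length effects, no non-propagating end-of-fibre
  potentials); uniqueness and explained-power results on it bound what
  the code does, not what real tissue does.
- Simulated units are stationary; real recordings drift (electrode
  shift, fatigue), so real tracking yields will be lower than the
  near-perfect yields measured here.
- Superposition is exactly linear and noise is white and Gaussian;
  amplitude cancellation and coloured physiological noise in real EMG
  reduce decomposition depth in ways the simulation does not model.
- No manual editing stage exists: pulse trains are accepted or rejected
  purely by the silhouette gate.
- Fitted `b` (the logarithmic model's value at 1 %MVC) is an
  extrapolation far below the sampled force range when a unit is only
  observed at low-to-moderate forces; its recovery through the full
  pipeline is correspondingly noisier than the gain term `a`.
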