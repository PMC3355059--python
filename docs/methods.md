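# Methods

This note documents the models, estimators and numerical choices behind
`colliculus`, in the package's own terms: what is computed, with which
parameters and defaults, what the synthetic-data generator does and does
not emulate, and where the open design choices were settled.

## The motor map

Saccade vectors [*R*, Φ] (degrees; Φ counter-clockwise from rightward
horizontal, normalized to (−180, 180]) map onto Cartesian motor-map
coordinates [*u*, *v*] (mm) through the complex-logarithmic transform

    u = B_u · ln( √(R² + 2AR·cosΦ + A²) / A )
    v = B_v · atan2(R·sinΦ, R·cosΦ + A)

with defaults **A = 3.0 deg, B_u = 1.4 mm, B_v = 1.8 mm/rad** — the
standard monkey-SC parameterization.  (The literature also circulates a
version of these three numbers with the units permuted; the assignment
above is the only dimensionally consistent one.)  The efferent map is
the exact inverse, `R·e^{iΦ} = A·(e^{u/B_u + i·v/B_v} − 1)`; round trips
are accurate to ~1e−15 and are tested to 1e−9.  Only the contralateral
hemifield is represented; inputs with |Φ| > 170° and R > 1° trigger a
warning rather than an error.  Angles are degrees at every interface and
radians only inside formulas.

## Burst statistics

Spike trains are event times at 1 ms resolution.  The spike density is
the train of delta pulses convolved with a unit-area Gaussian kernel
(default σ = 5 ms), in spk/s, so its time integral equals the spike
count; grids are padded 50 ms past the analysis window and kernels
truncated 5σ beyond the grid, keeping conservation errors below 1e−6.

Burst parameters use the half-open window **[onset − 20 ms,
offset − 20 ms)** — a fixed 20 ms efferent lead.  The half-open
convention guarantees each spike is counted at most once across
abutting windows.  *N_s* is the raw count; *F_m* = N_s / saccade
duration; *F_p* and *T_p* are the maximum and argmax (1 ms grid, no
sub-sample interpolation) of the spike density within the window —
for movement-field-center analyses, of the *trial-averaged* density
aligned on saccade onset.  Skewness γ₁ is the normalized third
**population** moment (divide-by-N) of spike times relative to saccade
onset, defined for N_s ≥ 3 and nonzero spread; undefined values are
flagged and excluded from regressions rather than filled in.

## Movement fields

Expected spike count is a circular Gaussian on the map,
`N = N_pref·exp(−d²/2σ_mf²)` with *d* the Euclidean map distance to the
field center — map coordinates absorb the amplitude asymmetry that the
same field shows in visual space.  The four parameters are fitted by
Nelder-Mead least squares with σ_mf and N_pref in log space (keeps the
simplex unconstrained yet positive), initialized at the count-weighted
centroid with σ_mf = 0.5 mm and N_pref = max count, plus five seeded
restarts; the best SSE wins (xatol 1e−6, fatol 1e−10, ≤4000 iterations).

When the responses sample only one flank of the field, the Gaussian is
unidentifiable: the optimizer walks the center away and inflates N_pref
without bound.  Fits are therefore rejected when the fitted center lies
more than 1 mm from every sampled point, σ_mf exceeds 3 mm, or N_pref
exceeds 10× the largest observed count.  These limits matter in
practice for cells at the edge of a sampled region.

Center-trial selection starts at radius 0.2·σ_mf around the fitted
center and widens in 0.01·σ_mf steps until ≥ 5 trials qualify or the
radius exceeds 0.5·σ_mf; cells failing that are excluded from the
center-response analyses (a 1e−9 mm tolerance absorbs floating-point
rim effects).

## Signal-dependent noise

Responses are grouped by complete-linkage agglomerative clustering in
(u, v) cut at 1·σ_mf — complete linkage directly enforces the
"every pairwise distance below the cut" diameter constraint — and
clusters with fewer than 5 members are discarded.  Per cluster we take
the mean count, its SD, and the *residual* SD around the fitted
movement-field prediction (root mean squared residual), which removes
count variability explained by the field gradient within the cluster.
The coefficient of variation C_v is the OLS slope of (residual) SD on
mean across clusters; the intercept estimates additive noise in spikes.
Cells need ≥ 5 clusters spanning ≥ 30% of N_pref in mean count;
regression is unweighted (cluster sizes vary little by construction).
Because independent noise sources add in quadrature
(SD = √(C_v²μ² + σ_add²)), the fitted straight line's intercept sits
below σ_add when all cluster means are far from zero; the recovery
experiment accounts for this.

## Population dynamics

For a target vector, each cell's preferred direction is rotated onto
the horizontal meridian (its trials rotated identically), and trials
whose rotated saccade lands within **0.3 mm** (map distance *d*) of the
target are averaged with Gaussian weights `exp(−d²/2σ_d²)`,
σ_d = 0.15 mm — half the cutoff; any smooth weight that is maximal at
d = 0 and monotone in d serves here.  Per-cell averages are pooled over
the rostral-caudal axis with a spatial Gaussian (σ = 0.25 mm) on a
0.2 mm grid, restricted to cells within 1.25 mm of the population
center that fire more than 5% of their own preferred count.

Cross-correlation between the center profile and another profile is
computed on raw (non-mean-subtracted) densities over a window from
20 ms before saccade onset to saccade offset, normalized by
`√(Σf_c²·Σf_x²)` so the autocorrelation at lag 0 equals exactly 1.
Values outside a profile's sampled support count as zero.  The optimal
delay is the argmax over lags ±50 ms at 1 ms steps, ties broken toward
zero.  Note that r(τ) at τ ≠ 0 can marginally exceed r(0) when burst
mass lies outside the correlation window (the normalization is fixed at
τ = 0); delays are therefore only meaningful for bursts contained in
the window.

Gradient regressions treat the preferred amplitude R_pref as the
rostral-caudal index of a cell's map position and report, per burst
parameter, mean ± SD, OLS slope ± SE, intercept ± SE, Pearson r and a
two-tailed t-test (stars at p < 0.01, 0.001, 1e−6).  Fewer than 10
cells or an eccentricity span under 10° triggers a warning, not an
error.

## Ensemble decoder and brainstem

Each spike at map site (u, v) contributes the fixed displacement
`κ·(R cosΦ, R sinΦ)` of the site's efferent vector.  With cell density
ρ, peak count N₀ and population width σ₀, the closed form
**κ = 1/(ρ·N₀·2π·σ₀²)** normalizes a full Gaussian population burst to
decode its own amplitude (Gaussian-integral calibration; a numerical
re-calibration at a 10° reference, `DecoderConfig.calibrated()`,
removes the residual few-percent continuum bias if exact unit gain is
wanted).  Summation is a running cumulative sum at 1 ms; the final
displacement equals the total spike-vector sum exactly, and decoding is
additive over populations.

The brainstem is two independent, identical, linear feedback circuits:

    v[n] = B · ( ΔE[n − δ_sc] − e[n − δ_fb] ),   e[n] = e[n−1] + dt·v[n−1]

solved exactly as a linear recurrence (scipy.signal.lfilter), input held
150 ms past its end so position settles.  Stability of the delayed loop
requires B·δ_fb < π/2 (checked at construction; divergence additionally
raises at run time).  The oculomotor plant and its pulse-step
innervation are treated as an exact inverse pair, so commanded velocity
equals eye velocity.

**Defaults: B = 135 s⁻¹, δ_sc = 20 ms, δ_fb = 2 ms** (stability margin
B·δ_fb = 0.27).  These three numbers are free parameters of the model
and were calibrated, as one calibrates such a model against behavior,
so that saccades decoded from ideal synthetic populations land on the
primate main sequence: durations ~25–61 ms and peak velocities
~350–830 deg/s over 5–30°, velocity-profile skewness growing with
amplitude.  A lower gain (e.g. B = 60 s⁻¹) makes the loop lag
(1/B ≈ 17 ms) comparable to a small saccade's entire burst, which
low-passes the burst-shape gradient out of the velocity profiles;
a much higher gain with δ_fb = 5 ms rings.

Saccade detection on simulated traces uses a vectorial speed threshold
of 30 deg/s, taking the contiguous above-threshold run containing the
global speed peak.  The onset is then refined backward to a 10 deg/s
boundary: a bare 30 deg/s crossing lags true movement start by up to
15 ms for small saccades, which would clip the burst rise out of the
spike-count window and masquerade as a rostral spike-count deficit.
The offset keeps the strict criterion so that low-velocity (glissadic)
tails do not count as part of the movement.  Kinematic metrics:
amplitude |endpoint − start|, duration offset − onset, peak vectorial
speed, velocity skewness as the normalized third moment of the speed
profile treated as a distribution over time, and straightness as the
maximum perpendicular deviation from the start→end chord divided by
amplitude.

## The synthetic-data generator

The generator encodes the study conditions; its defaults are not free
dials.  Cells sit on a jittered grid (uniform ±0.3 of the spacing) over
u ∈ [0, 4] mm × v ∈ [−2, 2] mm, each with σ_mf = 0.5 mm and
N_pref = N₀ = 18 spikes.  Per trial:

* the target endpoint gets isotropic jitter (SD 0.5°), emulating
  behavioral scatter;
* every cell within 3σ₀ of the population center draws an independent
  multiplicative gain from a gamma distribution with mean 1 and
  SD = C_v = 0.30 (a config switch adds one gain shared across cells
  for covariance experiments), giving the expected count
  `g·N₀·exp(−d²/2σ₀²)`, rounded, plus a Poisson additive count with
  mean 0.5 spikes;
* spike times are drawn i.i.d. from a single burst template shared by
  the whole recruited population — count first, then times: an
  inhomogeneous-Poisson profile conditioned on its count, the simplest
  process consistent with count-level noise analysis.  The shared
  template is what makes bursts synchronized, scaled copies of each
  other across the map;
* the eye trace is produced by actually running the spike-vector
  decoder and brainstem on the generated spikes; onset, offset and the
  realized saccade vector are detected from that trace, so decoded
  kinematics feed back into every stored trial.  Movements that never
  cross the detection threshold are flagged and dropped.

The template is a gamma density with shape k(R) interpolated
log-linearly between k(5°) = 8 (nearly symmetric) and k(30°) = 3
(right-skewed), clamped at ≥ 2.  Its central 98% interval (1%–99%
quantiles) is scaled onto the count window of duration
**D(R) = 20 ms + 1.8 ms/deg · R**, with the mode pinned at
T_p = −1 ms relative to the nominal saccade onset; mass falling outside
the window is clipped and the remainder renormalized, so sampled spikes
always land inside the count window.  This mapping makes the burst
genuinely span D(R): peak firing rate then falls roughly as 1/D with
amplitude (the rostral-brief/caudal-flat gradient), while k(R) carries
the skewness gradient.  Mapping a wider quantile span instead
concentrates small-amplitude bursts in a fraction of their window and
destroys the peak-rate gradient.

`generate_dataset` emulates single-electrode sessions: for each cell,
the target list (default: a 7×7 map-space movement-field scan at
offsets ±{0, 0.2, 0.6, 1.2}·σ_mf, denser near the center so the
center-selection rule can be met; alternatively a rose scan) is
presented n_reps times, the whole population is simulated per trial,
and only the recorded cell's spike train is stored.  The manifest
captures every generator parameter and seed; regeneration from the same
manifest is byte-identical.

**What the generator does not emulate**: inter-cell noise covariances
(unknown from single-unit data; independent by default), build-up or
fixation activity, reaction times and visual delays, biophysical burst
mechanisms, head-free gaze shifts, and both colliculi (one hemifield
only).  Passing tests therefore validate the analysis chain and the
internal consistency of the linear-ensemble account — not those aspects
of real recordings.

## Problem sizes in the verification experiments

The end-to-end experiments (`colliculus.experiments`) run at desk
scale, chosen so the complete set finishes in a few minutes on one
core: 400-point map round-trip grids; 1000 random trains for the
skewness oracle; 100 Monte-Carlo seeds × 50 trials for movement-field
recovery; 100 seeds × 15 clusters × 10 trials for C_v recovery; one
100-cell dataset (~10,000 trials) for the gradient pipeline; 6400-cell
(0.05 mm spacing) noise-free populations for the kinematics and
oblique-saccade experiments — at coarser grids, discrete-sampling gain
fluctuations of a few deg/s alias into the marginal peak-velocity
increments; 150 trials per target for synchrony (weakly recruited cells
average ~1 spike per trial, and their density estimates need that many
trials for 1-ms-stable delays); 200 trials per amplitude for endpoint
variance.  In the synchrony trend test, cells within one run share
trials, so their delay errors correlate; the no-trend check therefore
uses the between-run scatter of independent target runs rather than the
per-run regression SE.

## Known limitations

* Decoded amplitude undershoots for R ≳ 25° because the recruited
  Gaussian population truncates at the caudal map edge (u = 4 mm); the
  real SC faces the same geometry, and the undershoot bends the top of
  the simulated main sequence.
* Measured T_p on synthetic data sits near −4 ms rather than −1 ms (the
  residual onset-detection lag), with a mild amplitude dependence from
  threshold-crossing geometry.
* The γ₁ gradient generated by the k(R) anchors (≈ 0.03 deg⁻¹) is
  steeper than is typical of cortical-recording reports (≈ 0.01 deg⁻¹);
  the sign and significance structure, not the magnitude, is the
  contract here.
* C_v recovered through the full pipeline averages ≈ 0.26 for a
  generating value of 0.30: rounding, finite-cluster SD bias and the
  quadrature additive component all attenuate the regression slope
  slightly.  The controlled recovery experiment (clusters built at the
  estimator's assumptions) recovers 0.29 ± SE.
* The 1 ms simulation grid quantizes delays and durations; no
  sub-sample interpolation is attempted anywhere, by design.
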