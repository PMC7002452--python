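# Methods

## The device and its forward model

Each pixel of the sensor is an ISFET whose Si₃N₄ surface potential
shifts with proton concentration; the readout chain reports this as a
voltage. The package models transduction as linear around neutral pH:

    V = offset − S · (pH − 7.0)

with sensitivity S > 0 in mV per pH unit (default 51.6, the
central-pixel value of the characterized device). The sign convention —
surface potential rises as pH falls, from proton adsorption — is a
modeling choice; only the magnitude of S is physically pinned, and the
calibration fit carries the signed slope so either convention works.

Geometry defaults: 128 rows × 32 columns, 23.55 µm pitch, 50 frames s⁻¹.
Row 0 is the sensor tip and enters the tissue first, so an insertion is
a single boundary row: rows below it are inside the brain.

## Synthetic experiment

The generator emulates the full visual-stimulation session:

* **Protocol** — 120 s gray pre-phase, then trials of 2 s drifting
  grating + 8 s gray interval; 30 trials for each of 8 direction angles
  (0°–315° in 45° steps) in a seeded uniform random order. All counts
  and durations are parameters, not constants.
* **Calibration sets** — per-pixel readouts in the three standard
  buffers, with zero-mean Gaussian inter-pixel noise expressed in
  pH-equivalent units (per-buffer SD defaults 0.0171 / 0.0037 / 0.0061
  for pH 4.01 / 6.86 / 9.18, matching the characterized spread), plus
  stuck-at-constant defective pixels injected as a seeded Bernoulli
  process (default rate 2.89%). Stuck-at-constant is the package's
  failure model; real failure modes are not documented.
* **Response fields** — per-angle signed amplitude maps (alkaline +,
  acidic −) built as smoothed Gaussian random fields (correlation length
  3 px, pixel SD half the mean amplitude) around signed per-angle means:
  angles 0/90/270° alkaline, 45/135/180° acidic, the rest neutral,
  mirroring the direction-dependent shifts seen in cortex. No generative
  spatial model exists for the real tissue; this is the simulator's
  definition. Default evoked amplitude 0.01 pH, in the range of the
  observed per-pixel shifts; per-frame pixel noise 0.005 pH.
* **Kinetics** — evoked responses follow a rising two-component
  exponential during stimulation,
  k(t) = f·(1 − e^(−t/τ_f)) + (1 − f)·(1 − e^(−t/τ_s)), and by default
  relax after stimulus offset with each component decaying from its
  attained level at its own time constant. Defaults: alkaline
  τ = 250.2 ms / 14.19 s, acidic τ = 231.0 ms / 6.99 s, f = 0.5 (the
  amplitude split between components is not documented; equal split is
  the neutral choice). Whether evoked transients persist through the 8 s
  interval in vivo is unknown, so persistence is exposed as a `relax`
  flag rather than asserted.
* **Conditions** — `brain` uses the response field; `hepes` (buffered
  saline) forces it to zero: the null condition shares everything else.
* **Illumination segments** — 10 s pre-exposure + 10 s white light;
  non-inserted rows gain the full photovoltage (default +20 mV), inserted
  rows an attenuated fraction (default 5%, light scattered into tissue).

Identical parameters and seed give bit-identical output; every operation
draws from its own `default_rng(seed)`.

What the generator does **not** emulate: slow electrode drift,
hemodynamic or motion artifacts, spatially correlated noise, bleeding or
tissue damage at the insertion site, temperature effects, and charge
transfer nonlinearity. Passing recovery tests therefore demonstrate that
the analysis inverts its own forward model at realistic noise levels —
not that these unmodeled disturbances are handled.

## Calibration and conversion

Per pixel, an unweighted OLS line through the (pH, voltage) buffer
points (three points per pixel; robust fitting would be meaningless).
The reported device sensitivity is the mean |slope| over the five
central pixels, defined as the center pixel plus its 4-neighbors — the
exact layout is not documented, and any compact central cluster gives
the same answer on a homogeneous array.

Defective pixels: slope more than 5 scaled-MADs from the array median
(with a relative floor so that noiseless arrays flag any measurable
deviation), or a buffer response that reverses direction against the
array trend by more than the robust residual scale. The criterion is the
package's; only the resulting rate is documented for the device.

Inter-pixel variation converts every pixel's buffer voltage through one
array-median curve and takes the cross-pixel SD per buffer. Using each
pixel's own curve would absorb exactly the variation being measured;
the median-curve choice makes transduction differences visible as pH
spread. Buffer distributions are compared with a one-way ANOVA plus
Tukey HSD on the same converted values.

pH conversion of movies inverts each pixel's own curve by default
(pH = 7 + (V − intercept)/slope); a single median-curve conversion is
available (`curve='median'`). Defective pixels become NaN and stay NaN
through every downstream statistic.

## Boundary detection

Difference map = time-mean voltage during illumination minus time-mean
during pre-exposure, per pixel. The row profile is the median across
columns (robust to defective pixels). The default threshold is the
midpoint of the profile's 10th and 90th percentiles — parameter-free and
gain-independent; a fixed-mV threshold is an override. The first row
from the tip exceeding the threshold is the boundary. A profile with no
contrast (span < 1 mV) or that never crosses the fixed threshold yields
`boundary_row = n_rows` with a fully-inserted flag: an all-low profile is
indistinguishable from a fully inserted chip without an absolute
reference. No sub-row interpolation is attempted.

## Response statistic

Trials are segmented with half-open windows ([onset, onset+2 s) for
stimulation, the following [.., +8 s) for the interval); a frame belongs
to a window iff its timestamp midpoint falls inside, which resolves
edge ties deterministically. The inter-trial interval is attributed to
the trial it follows, in full; the 120 s pre-phase belongs to no trial.
Trials extending past the movie raise an error unless explicitly allowed
to be dropped.

The seven derived quantities (interval means per angle and overall,
per-trial and per-angle ΔpH, the overall ΔpH, and the two response
statistics Δ(ΔpH) and Δ(ΔpH_trial)) follow the definitions in the
README. Two identities are exact by construction and enforced in tests
to 1e−12: the mean of Δ(ΔpH) over angles vanishes at every finite pixel,
and the per-angle trial mean of Δ(ΔpH_trial) equals that angle's Δ(ΔpH).

## Pixel classification

**Threshold rule.** All finite per-pixel, per-angle Δ(ΔpH) values from
the null (saline) runs are pooled — across runs and across angles, one
global threshold pair — and the thresholds are mean ± 1.96 SD of that
pixel distribution. This is deliberately the 95% interval of the
*distribution*, not the standard-error interval of its mean: with tens
of thousands of pooled pixels an SE interval is vanishingly narrow and
would label essentially every pixel, inconsistent with the observable
~5% null exceedance this rule is designed to produce. The SE variant
exists behind `method='se'`.

**t-test rule.** Per (pixel, angle), a two-sided one-sample t-test of
the angle's Δ(ΔpH_trial) values against zero at α = 0.05, no
multiple-testing correction (a Benjamini–Hochberg option exists but is
off by default, matching the per-pixel p < 0.05 convention).
Zero-variance trial sets are defined as not significant. One property
deserves emphasis: Δ(ΔpH_trial) equals pH_stim,trial minus the grand
mean over *all* trials of that pixel, so the tested angle's own 30
trials contribute 1/8 of the grand mean; under the null the variance of
the angle mean is deflated by (1 − 1/8) and the true type-I rate is
≈3.8%, not 5%. The implementation is faithful to the published
procedure; the conservatism is inherent to it and is measured, not
corrected.

**Group comparison.** Per-run, per-angle significant-pixel counts enter
a two-way ANOVA, `count ~ C(condition) * C(angle)` with type-II F tests
(the design is unbalanced: 9 brain vs 3 null runs), plus an unpaired
t-test on per-run counts summed over angles. In the replica the same
insertion mask is applied in both conditions so counts are comparable.

## Peri-stimulus dynamics

PSTHs span 2 s pre-stim, 2 s stim, 4 s post-stim at the frame period.
Each trial snippet is referenced to its own pre-window mean before
averaging — the referencing scheme is not documented for the original
analysis, but pre-onset-centered PSTHs require it. For trial 1 the pre
window falls in the tail of the gray pre-phase.

Categorization per (pixel, angle): two-sample t-test between the 30
per-trial pre-stim means and stim means (α = 0.05); increased = alkaline,
decreased = acidic, else neutral. Display sorting is by category
(alkaline, neutral, acidic), then by the median trace value in the stim
window, descending (the sort direction is a choice), ties broken by
(row, col, angle).

**Biexponential fitting.** Category-mean traces are fitted with the
rising form y(t) = a_f(1 − e^(−t/τ_f)) + a_s(1 − e^(−t/τ_s)) over
[0, 6] s (stim + post) by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trf). Initialization is a deterministic
multi-start: all ordered pairs from the τ grid {0.1, 0.3, 1, 3, 10} s,
amplitudes initialized by linear projection (for fixed time constants
the model is linear in the amplitudes); the lowest-RSS solution is kept
and τ_fast ≤ τ_slow enforced by post-fit ordering. No random restarts,
so fits are reproducible. Failure at every start returns
`converged=False` with NaN parameters rather than raising. Numerical
bounds: τ ∈ [10⁻³, 10⁴] s.

Two caveats. First, the slow time constants (14.19 s, 6.99 s) exceed
the 6 s window: they are extrapolated, weakly identified quantities, and
the recovery studies use a correspondingly wider tolerance (25% vs 10%
for the fast constants). Second, the rising model describes a response
that develops through the fitted window; the τ-recovery studies
therefore simulate sustained responses (the generator's `relax=False`
path) so that model and data agree over [0, 6] s. When the fitter is
applied to movie-replica PSTHs generated with default post-offset
relaxation, the rise-then-decay trace collapses the fit toward a single
effective ~1 s constant — visible in the replica report, and expected:
the fit family and the relaxing trace disagree beyond stimulus offset.

## Study sizes

The recovery studies run at sizes chosen for a desk machine: the
τ-recovery study pools 60 responding pixels × 30 trials at 50 Hz
(SNR 5); defective-pixel recovery averages 20 seeded full 128 × 32
arrays; inter-pixel spread uses 12 simulated devices; null calibration
uses a 42 × 32 grid (10 752 pixel-angle draws per run, 3 pooled null
runs plus a fresh one) under the full 240-trial protocol; boundary
recovery uses 100 noisy full-geometry segments at SNR 10. The replica
runs 9 + 3 sessions at a reduced grid (32 × 16, 25 Hz, 10 trials per
angle); every count generalizes because trial and angle counts are
protocol parameters throughout.

## Known limitations

* The linear transduction model ignores temperature drift, hysteresis
  and gain nonlinearity; three calibration points cannot detect
  curvature anyway.
* The boundary is a single straight row; a per-column variant exists in
  the difference map but is not the default decision rule.
* The t-test classifier's conservatism (above) is inherent to testing
  Eq.-7-style values against zero; consumers comparing its rate to a
  nominal α should expect ≈0.75·α with 8 angles.
* The fitted slow time constants extrapolate beyond the observation
  window and should be read as trend parameters, not precise rates.
* Synthetic-data realism limits are listed under the generator section;
  recovery results bound algorithmic correctness, not in-vivo validity.
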