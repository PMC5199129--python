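# Methods

This note documents the model implemented by `phenotaxis`, the parameters
that matter, the calibration and numerical choices, and what the package's
tests do and do not establish.  Units are fixed package-wide: µm, s, mM,
molecules/cell.

## 1. Gene expression and non-genetic diversity

Each cell's chemotaxis proteome (CheA, CheW, CheR, CheB, CheY, CheZ, Tar,
Tsr) is sampled from a two-level log-normal model:

- a single **extrinsic** factor E per cell, log-normal with mean 1 and
  CV ω (default 0.08), multiplies the mean of every gene — the operon is
  expressed coherently, so protein *ratios* are largely preserved across
  cells while absolute levels co-fluctuate;
- independent **intrinsic** log-normal noise per gene (CV 0.1 by default)
  perturbs the ratios;
- draws are rounded half-to-even and clipped at zero (a zero mean models a
  deletion exactly).

Wild-type means use the standard copy-number census (CheR 140, CheB 240,
CheY 8200, CheZ 3200, CheA = CheW = 6700, Tar 5000, Tsr 10000); induction
conditions change only the CheR mean (140 / 120 / 13), and the CheY
deletion sets CheY = 0.  Richer operon structure can be substituted behind
`sample_proteomes`.

Because CheY-P is compared against a fixed motor threshold, the extrinsic
factor (through CheY·E) is the dominant source of tumble-bias diversity;
intrinsic noise on CheR/CheB diversifies the adapted activity itself.

## 2. Signaling

Receptor teams of N = 6 Tar units are two-state with free energy (kT)

    F(m, L) = N [ε₀ + ε_m m + ln(1 + L/K_off) − ln(1 + L/K_on)],

activity a = 1/(1 + e^F).  K_off = 0.0182 mM and K_on = 3 mM are the
Tar–MeAsp dissociation constants of the inactive/active conformation, so
attractant raises F and suppresses activity, and the team senses
log-concentration over the 0.02–3 mM range.  Tsr is carried in the data
model but does not sense MeAsp.

Methylation follows linear kinetics dm/dt = k_r R (1 − a) − k_b B a with
fixed point a* = k_r R/(k_r R + k_b B): perfect adaptation, with the
adapted activity set only by the CheR/CheB ratio.  The linearized
relaxation rate is λ = (k_r R + k_b B)·N·|ε_m|·a*(1 − a*); doubling both
enzymes halves the adaptation time at the same fixed point, and low-CheR
cells both run more and adapt more slowly (the inverse TB–τ correlation).
m is clipped to [0, 8] (the methylation ceiling; cells near the 1 mM
source saturate and run).

**Adaptation noise.**  An Ornstein–Uhlenbeck process with correlation time
τ_η = 10 s contributes its increments to m.  Its per-cell stationary SD is
σ_m·sqrt(140/CheR) with σ_m = 0.6: methylation fluctuations grow as the
methyltransferase becomes scarce, which is what lets CheR = 13 cells —
whose mean activity sits far below the motor threshold — tumble
occasionally, in rare noise-driven bursts.  Under the methylation
feedback the effective stationary SD of m is σ/sqrt(1 + λτ_η) (the
feedback high-passes the noise); this closed form is the test oracle.
Because dm/dt is linear in a, the noise does not shift mean activity away
from a*.

**CheY-P.**  Phosphorylation is much faster than methylation, so CheY-P is
computed at quasi-steady state, yp = Y·flux/(flux + k_z Z) with
flux = k_y k_a a A and k_a = 12.35 s⁻¹.  k_z = 9.5 puts the wild-type
operating point near half-saturation, which softens the (otherwise
Hill-10-amplified) sensitivity of tumble bias to CheR.

## 3. Motors and kinematics

Each of 5 flagella is an independent two-state Markov motor with total
switching rate 1/0.7 s⁻¹ split so the stationary CW probability equals the
Hill-10 CW bias cw(yp) = yp¹⁰/(yp¹⁰ + K¹⁰), K = 4500 molecules.  A cell
runs while ≥ 3 flagella rotate CCW; the stationary tumble bias is exactly
BinomCDF(2; 5, 1 − cw), the analytic oracle used for `unstim_tb` and in
tests.  Per-step flip probabilities use the linear form rate·dt, which
keeps the discrete chain's stationary distribution exactly at cw for any
dt.

Runs advance the cell at its per-cell speed (Gaussian per condition:
30 ± 7, 26 ± 6, 20 ± 5, 21 ± 6 µm/s; truncated at 2 µm/s) with rotational
diffusion 0.062 rad²/s; tumbles do not translate; the post-tumble heading
is uniform (mean run-to-run turn 90°, no directional persistence).  The
10-µm-deep chamber is treated as strictly 2D.  A cell crossing a wall is
placed on the wall with its heading turned parallel, preserving its
tangential sense, so cells slide along walls until redirected.

## 4. Environment and simulation

Chamber: 10 mm × 1 mm with a 0.3 mm reservoir behind the gate at x = 0;
the gradient is a linear 0.1 mM/mm ramp from zero at the gate to 1 mM at
the source (behind the gate the buffer holds c(0); a fitted space–time
concentration surface can be plugged in as `custom_fn`).

Cells start uniformly in the reservoir, internally adapted to the local
concentration, and equilibrate for 60 s behind the closed gate so motor
and pathway states decorrelate from initialization; at t = 0 the gate is
removed.  Positions and ground-truth run/tumble labels are recorded at
8.78 Hz; the integration step is the frame interval divided into 11 equal
steps (≈ 10.4 ms), so sample times are exactly uniform.  The per-run RNG
seed drives expression, initialization, and dynamics through separate
spawned streams; fixed seeds reproduce populations bit-for-bit.

**Control mode** gives every cell the rounded population-mean proteome and
the same internal state (adapted at the gate concentration), skips
equilibration (the synchronized start is the point), disables adaptation
noise, and records per frame the *instantaneous expected* tumble bias —
the binomial oracle applied to instantaneous CheY-P — rather than realized
tumbles, which removes sampling noise from the stimulated-vs-unstimulated
comparison.

## 5. Observation model

The pseudo-microscope replays the acquisition: per sweep, eight 1-min
movies at 8.78 frames/s tile the chamber sink-to-source with a 10.9 s
stage overhead between movies (sweep midpoints then fall at ≈ 4.6, 14.1,
23.5, 33.0, 42.5, 51.9, 61.4 min); no-gradient runs use four fields over
the first 4.5 mm.  Camera fields are 1330 µm wide with 80 µm overlaps
trimmed at midlines, so every position belongs to exactly one field.
Every maximal run of consecutive samples of one cell inside a movie's
time window and field extent becomes an independent track — cells leaving
and re-entering a field fragment into separate tracks, exactly as a
tracker would see them.

Track filters: mean speed and mean run speed within 5–60 µm/s, maximum
mean-squared displacement ≥ 30 µm² (computed at the largest available
lag, i.e. end-to-end), tumble bias within [0, 0.5], duration ≥ 6 s
(53 frames).  The detection-noise spatial-SD filter of real tracking has
no counterpart here (the simulation has no detection noise); a hook is
left in the filter signature.

## 6. Run/tumble classification

Per frame, three kinematic features: speed (forward-differenced
displacement × fps), acceleration (frame-to-frame velocity change × fps),
and angular acceleration (rate of change of the wrapped heading change;
the change-of-change is wrapped again so near-reversals do not alias).
Features are z-scored pooled over the whole dataset and clustered with a
3-component full-covariance Gaussian mixture (seeded; subsampled fit
above 200k frames).  The stalled cluster is the tumble, the fast cluster
the run, the remainder intermediate.  Two refinements:

- clusters moving faster than half the run cluster's speed are never
  labeled tumble (guards tumble-free data such as the CheY deletion);
- intermediate-labeled frames slower than half their track's mean run
  speed are promoted to tumble: the first/last instants of a tumble are
  stalled but inherit the neighboring motion's accelerations, and without
  this pass the mixture undercounts tumble instants by about one frame
  per event (TB bias ≈ −0.05; with it, TB MAE vs ground truth ≈ 0.003).

Tumble bias is tumble frames over all frames (granularity 1/n; a single
tumble frame in a 527-frame movie is ≈ 0.002, the smallest measurable
value).  Intermediate frames count in the denominator only, and are
excluded from mean run speed.

## 7. Analysis definitions

All position statistics weight each observed *sample* equally, matching
the fractional cell-counting convention (one frame = 1/527 cell; a track
spanning a whole movie is one cell; counts are additive).  Mean positions
per TB bin use the four equal bins on [0, 0.5] (the low-CheR analysis
prepends the 0–0.005 and 0.005–0.05 categories, i.e. 0–1 and 2–26
tumbles/min); the time coordinate is the sweep midpoint; spreads are two
standard errors.  Kymographs split each movie into five equal regions and
interpolate density linearly over the space–time grid, leaving unobserved
nodes blank.

The performance map φ_t(TB) bins TB at width 0.005 from zero (lowest bin
center 0.0025) and reports the mean distance past the gate per (bin,
sweep), suppressing bins with fewer than 45 cell-equivalents (at reduced
desk scales the tests lower this threshold; the default is the plotting
threshold of the full-scale analysis).  Conditions are pooled by simple
union of tracks.  The Jensen comparison reports, per sweep, E[φ(TB)]
(mean position of all samples) against φ(E[TB]) (mean position of samples
whose track TB lies within 0.01 of the population mean).

Gamma-population predictions integrate the linearly interpolated map
against a gamma(k, θ) density truncated and renormalized on the map's
populated support; the piecewise-linear integrand makes the integral
exact via gamma partial expectations, so affine maps return a + b·kθ to
machine precision.  If more than 20% of the gamma mass falls outside the
support the prediction raises rather than extrapolate.

## 8. Calibration constants

ε₀ = 1, ε_m = −0.5, k_r = k_b = 0.004 s⁻¹ per enzyme, k_z = 9.5, motor
K = 4500, σ_m = 0.6 (at CheR = 140), τ_η = 10 s are calibration constants,
not measured values.  They were set, in this order, so that:

1. wild-type census counts give an adapted tumble bias near the wild-type
   mode (~0.15) with the extrinsic/intrinsic noise producing a broad
   distribution over [0, 0.5];
2. small-signal adaptation is fast for wild type (τ ≈ 1 s) and slow for
   CheR = 13 (τ ≈ 7 s), preserving the inverse TB–τ correlation and
   leaving climbing wild-type cells nearly re-adapted beyond the first
   millimeter of the chamber;
3. the low-CheR condition's *observed in-gradient* TB distribution
   matches the low-induction condition (mean ≈ 0.04, with mass in both
   the 0–0.005 and 0.005–0.05 categories) — low-CheR climbers are
   stimulus-suppressed, so this sets σ_m above the value that would match
   the same distribution in a uniform environment.

## 9. Desk-scale problem sizes

The full-scale study condition is 16,000 cells for ~65 min.  The test
suite and the acceptance script use reduced sizes chosen as the package's
own desk-scale defaults: 1,000 cells / 47 min for the wild-type race
(five sweeps, the last centered near 42.5 min), 500 cells / 45 min for
the control simulation, 400 cells per CheR condition for the Jensen and
map analyses (with the map's cell threshold lowered to 3), and 25–150
cells for unit-level checks.  Session-scoped fixtures share each
condition across tests.

## 10. Limitations

- The gene-expression model is a two-level log-normal stand-in; real
  operon structure (shared mRNAs, translational coupling) would correlate
  specific protein pairs more strongly.
- The wild-type TB distribution is heavier-tailed than the measured one
  at both ends; in particular its near-zero-TB mass produces run-only
  wanderers whose dispersal is unchecked because hydrodynamic wall
  trapping, 3D swimming, and cell–cell interactions are not modeled — the
  extreme no-gradient penetration distance is therefore overestimated.
- Flagellar interactions are reduced to the 3-of-5 bundle rule with
  independent motors; tumble-duration statistics beyond the mean are not
  calibrated.
- The control-mode residual and the race statistics depend on the
  calibration constants above; they reproduce the documented desk-scale
  behaviors but are not parameter-free predictions.
- Passing tests establish internal consistency (oracles, conservation,
  determinism) and the documented population-level patterns on synthetic
  data; they do not validate the model against new experimental
  recordings, which the simulation's clean observation model (no
  detection noise, no linking errors) does not emulate.
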