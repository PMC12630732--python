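# Methods

## Model of the instrument

The simulator reproduces the measurement chain of a camera-based
stabilization add-on for single-molecule microscopes.

**Scene.** Fiducial markers are parametric Gaussian spots: a marker at
sample position `p` (nm) with the sample offset `d = (dx, dy, dz)` is
rendered at image position `(p + (dx, dy)) / pixel_size` px. Spots are
*pixel-integrated* Gaussians (differences of error functions per pixel),
not point-sampled ones, so rendering stays correct when the spot width
approaches the pixel pitch, and so the fitting model below can recover
parameters exactly on noiseless input. The focus reflection is a larger
Gaussian whose image position responds only to defocus:
`r = r_base + g · dz · u`, with gain `g` (nm lateral per nm axial, sign
free) and unit direction `u`. Lateral sample motion does not move it —
it is a reflection of a fixed beam off the coverslip.

**Noise.** Per-pixel Poisson noise on the expected photon image
(optional), then a constant camera baseline and Gaussian read noise,
clipped at zero. Defaults: baseline 100 counts, read noise 2 counts.

**Drift.** Advection plus Brownian motion:
`d(t+dt) = d(t) + v·dt + N(0, D·dt)` per axis. Defaults
`v = (0.6, −0.6, 0.45)` nm/s (|v| ≈ 0.96 nm/s, the fast end of what
well-isolated microscopes show) and `D = (0.3, 0.3, 0.2)` nm²/s so the
path is irregular rather than a straight line.

**Stage.** An open-loop piezo: commanded targets are mapped through a
signed axis permutation, clamped to the centered travel range
(±travel/2), and rounded **half-to-even** to the lattice
`travel / 2^bit_depth` — 0.61 nm for the default 20 µm / 15-bit stage.
Half-to-even avoids a directional bias when many near-half-quantum
corrections are issued. `settle_lag` (default 0) can delay commands by
whole loop iterations; the default models triggered operation in which
moves complete between exposures, so an image is never acquired while
the stage is moving.

**Photon budgets** (free parameters of the simulation, not measured
quantities): 50 000 expected photons per fiducial per 50 ms exposure and
200 000 for the focus reflection. Gold nanoparticles of 200 nm are
extremely bright scatterers and a specular reflection brighter still;
these budgets give a per-marker localization precision of
σ_spot/√N ≈ 184/√50000 ≈ 0.8 nm, consistent with the sub-nanometer
closed-loop residuals the system is designed to reach. Halving or
doubling them moves the residuals by roughly √2 but breaks nothing.

## Localization

**Fiducials.** Weighted least squares of
`A · Ix(x; x0, σx) · Iy(y; y0, σy) + b` on the ROI, where `Ix, Iy` are
unit-mass Gaussians integrated over pixels and `A` is therefore the
total spot photon count. Residuals are divided by `sqrt(max(counts, 1))`
(shot-noise weighting): an unweighted fit has ~35% excess localization
variance because it overweights the bright, noisy center. The optimizer
is Levenberg–Marquardt with tight tolerances; seeds come from the
previous frame's fit, else from intensity moments. Every failure mode
returns a `converged=False` flag instead of raising — one bad frame must
not stop a control loop. Background is a free offset, not pre-subtracted,
which is robust to the residual background of the dark-field-like
fiducial image. ROI defaults: 11×11 px for fiducials (≥ ±2σ at the
default σ ≈ 2.3 px), 31×31 px for the larger focus spot.

**Focus spot.** Center of mass above a relative threshold (default 0.2
of the ROI maximum) with the threshold level subtracted before
weighting; a plain center of mass is biased toward the ROI center by any
baseline. Δz is the *signed* projection of the spot shift onto the
calibrated direction times the calibrated response — using the signed
projection rather than the shift modulus preserves the sign of defocus.

**Detachment monitoring.** A marker is invalidated when its displacement
deviates from the median displacement of the tracked markers by more
than 50 nm for 3 consecutive frames, or when its fit fails 3 frames in a
row. The median is over all tracked markers including the candidate: a
leave-one-out median over two values degenerates to their mean, and a
single runaway marker would then drag every reference with it.
Invalidation is sticky until an explicit reset — a marker that detached
once cannot be trusted again. With fewer than two tracked markers the
relative comparison is disabled.

## Control

Per-axis PI response `c = −(kp·e + ki·∫e dt)`, output and integral both
clamped (anti-windup). Defaults kp = 0.8, ki = 0: proportional-dominant
control converges on a step disturbance in <5 iterations
(`e_{n+1} = (1−kp)·e_n`) and is robust to the stage quantization;
an integral term is unnecessary because drift per 54 ms period
(~0.05 nm) is far below the measurement noise. Corrections are issued as
**absolute targets** (accumulated commanded position + correction) so
quantization error cannot build up, and corrections below half a stage
quantum are not sent (dead-band) to prevent limit cycles on the 0.61 nm
lattice. XY and Z channels are fully decoupled; axes outside the active
mode are never commanded, which the tests assert on the stage command
log. Loss of all fiducials pauses XY (Z continues); stage command
failures are logged as trace annotations, never aborts. Time in
simulation is virtual — each acquisition advances the clock by one
54 ms period — making runs deterministic and much faster than real time.

Reference shifts move the stored setpoints by δ/pixel_size (and z₀ by
δz); the loop then drives the sample to the new reference, which is how
controlled stage moves are made without releasing the lock. Shifts that
would push a marker within 3 px of its ROI edge are refused.

## Calibration

Both calibrations use the stage as the length reference, with
stabilization disabled (the loop would fight the calibration motion),
and regress against the *read-back* stage position rather than the
commanded target so stage quantization does not bias the slope. Each
step list is swept up then down and the two visits averaged, which
cancels drift that is linear in time over the sweep; 3 frames are
averaged per visit.

* Pixel size: lateral steps (default 0…400 nm in 5 points), fiducial
  localized in a window tracked incrementally (the pixel size is unknown
  during its own calibration); inverse slope of px vs nm.
* Z response: axial steps (default ±150 nm in 5 points), reflection
  center of mass recorded; the principal direction of spot motion (SVD)
  is the z axis, oriented so the projection grows with +z, and the
  inverse slope of projection vs nm is the response. The ±150 nm range
  keeps the slope error well under 1% against the axial drift jitter
  accumulated during the sweep. The model is strictly linear; curvature
  would appear as a depressed r².

`cmd_simulate` always stabilizes with the *recovered* calibration, not
the simulator's ground truth, so every end-to-end run also exercises
calibration error propagation.

## Precision statistics

Per-axis histograms with Freedman–Diaconis binning (the binning rule is
a documented choice; results are insensitive to it at the trace lengths
used), Gaussian fit for the headline σ, sample standard deviation always
co-reported as a binning-insensitive cross-check — for a Gaussian-like
trace the two agree within 15%. Degenerate (constant) traces report a
sample std of 0 with the fit flagged as rejected. σ_Total combines an
externally supplied σ_CRB with σ_Stabilization in quadrature; computing
σ_CRB itself (estimator theory of the downstream localization method) is
out of scope.

## Problem sizes and determinism

The packaged experiments use 600 simulated seconds (11 111 iterations)
for the headline closed-loop run and 100–1000 repetitions for
Monte-Carlo checks; shorter property tests use 2–20 s runs. All
randomness flows from one `SeedSequence` per scope, with independent
child streams for drift and frame noise, so identical seeds give
bit-identical frame sequences and traces, and enabling one noise source
never perturbs another.

## What the simulation does and does not show

The virtual microscope emulates spot statistics, drift, quantization and
feedback timing, so passing tests demonstrate that the *algorithms* —
localization, calibration, detachment handling, decoupled PI control on
a quantized actuator — reach sub-nanometer residuals under realistic
photon budgets and drift rates. It does not model aperture/dark-field
optics, evanescent-field physics or nanoparticle scattering spectra
(spots are parametric Gaussians), vibrations faster than the frame rate,
non-Gaussian reflection shapes, piezo hysteresis or creep, or camera
fixed-pattern noise. Real-hardware residuals therefore depend on
conditions the simulation fixes by assumption; the hardware-free claim
is about the control software, not the optics.
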