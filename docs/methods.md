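# Methods

`perchsense` asks a sensor-placement question about standing balance: if a
body perched on a moving substrate carries inertial sensors at the hip and at
the head, which location senses substrate (foot) acceleration faster and
reconstructs it better?  The question is motivated by birds, which carry a
pelvic balance-sensing structure (the lumbosacral organ) in addition to the
vestibular system in the head.  The package answers it on a synthetic
mechanical stand-in, with the same estimators one would apply to rig or
animal recordings.

## The mechanical stand-in

The perched body is a per-axis serial two-stage linear chain:

    platform --[k_leg, c_leg]-- m_body --[k_neck, c_neck]-- m_head

with equations of motion (per axis, platform position p):

    m_body ẍ_h = −k_leg (x_h − p) − c_leg (ẋ_h − ṗ) − k_neck (x_h − x_d) − c_neck (ẋ_h − ẋ_d)
    m_head ẍ_d = −k_neck (x_d − x_h) − c_neck (ẋ_d − ẋ_h)

Feet are rigidly attached to the platform, so the foot accelerometer reads
the platform acceleration (implemented as the discrete second difference of
platform position times the squared sampling rate); hip and head
accelerometers read ẍ_h and ẍ_d.  Because the chain is linear, it is
integrated by exact zero-order-hold discretization of the continuous
state-space at the sampling rate (1 kHz by default) — bit-reproducible,
exact at the sample instants for piecewise-constant inputs, and fast.  The
state recursion itself runs through a modal decomposition (eigenbasis plus
scalar IIR filters) with a plain-recursion fallback for defective matrices;
the two paths agree to machine precision and are property-tested against
each other.

Accelerometer outputs contain only perturbation-induced fluctuations (no
gravity/DC term): every downstream analysis mean-removes its input, so a DC
offset would be inert.  Measurement noise is i.i.d. zero-mean Gaussian per
channel (default SD 0.05 m/s², a plausible MEMS accelerometer noise floor
over this bandwidth); the noiseless traces are retained in recording
metadata for provenance.

### Default parameters

| parameter | default | why |
|---|---|---|
| m_body | 1.3 kg | torso/hip lumped mass of a guinea-fowl-sized model |
| m_head | 0.12 kg | head + upper neck lumped mass |
| k_leg (x, y, z) | 1600, 2000, 2400 N/m | body resonance ≈ 6 Hz, above the neck band; ±20 % per-axis asymmetry mimics a body symmetric only in the sagittal plane |
| c_leg | 15 N·s/m | leg-stage damping ratio ≈ 0.15 |
| k_neck low / high | 26.5 / 49.3 N/m | head-stage resonance ≈ 2.4 / 3.2 Hz; stiffness ratio ≈ 1.9 between the two interchangeable neck presets |
| c_neck low / high | 0.5 / 0.7 N·s/m | light damping, ζ ≈ 0.14 |
| noise SD | 0.05 m/s² | MEMS-class accelerometer noise |

The leg stage is deliberately stiffer than the neck stage so that the two
stages separate in frequency: the head, low-passed by the compliant neck,
exhibits its spectral peak at the neck mode.  This is the structural premise
that makes the resonance-based stiffness estimator meaningful — the
frequency of maximal head-acceleration power tracks the neck preset — and
it also produces serial propagation delays (foot → hip shorter than foot →
head) of realistic magnitude (≈ 0.02 s vs ≈ 0.07–0.10 s).  All defaults
live in `perchsense.config.DEFAULTS` and can be overridden from a single
JSON file.

### Perturbation protocol

Each trial applies `n_moves` (default 3,000) center-out-and-back platform
displacements to the surface of a sphere of radius 2, 5, 10 or 20 mm, along
directions drawn uniformly on the unit sphere.  The displacement profile is
a half-cosine out and a half-cosine back (default 0.4 s per move, peak
exactly on the sphere surface, zero endpoint velocity) followed by a 0.1 s
dwell at the origin — a smooth, band-limited stand-in for a commanded
point-to-point robot move, whose velocity profile is otherwise unspecified.
One master seed per trial is split deterministically into independent
direction and noise streams.

The full grid is 8 trials (4 radii × 2 neck presets), labelled
`Trial_LS_2` … `Trial_HS_20`.

## Estimators

**Effective stiffness.**  The resonant frequency f (Hz) of head
acceleration is the frequency of maximal Welch power (Hann windows, 4 s,
50 % overlap, band 0.5–50 Hz) and is converted to a stiffness K = m f² with
m the head mass (0.12 kg).  Note the deliberate convention: with f in Hz
this quantity is the physical spring constant divided by (2π)² — the
estimator is proportional, not equal, to k, which is harmless for
comparisons between conditions and is verified against a known oscillator
in the tests (the ratio check).  A non-prominent spectral peak (< 10× the
median in-band power) triggers a diagnostic warning.  The stiffness
bootstrap draws random 30 s segments and a random axis per iteration; the
random axis propagates the direction dependence of the chain's response
into the bootstrap spread, mirroring the variability a physical
asymmetric body produces.

**Sensing delays.**  The delay between foot and hip (or head) acceleration
is the lag maximizing the normalized cross-correlation of the mean-removed
traces within ±0.5 s (the delays of interest are an order of magnitude
smaller; the bound merely limits the search).  Positive delay means the
sensor lags the foot.  Exact ties are broken toward the smallest |lag|,
then negative before positive, so the output is deterministic.  Per-axis
delays are computed and pooled into one distribution.

**Foot-acceleration estimation (MOESP).**  A discrete-time state-space
model

    x(k+1) = A x(k) + B u(k)
    y(k)   = C x(k) + D u(k)

is identified mapping sensor channels u (hip: 3, head: 3, fusion: 6) to the
3-axis foot acceleration y.  The identification is ordinary MOESP:
block-Hankel matrices of u and y with s = 10 block rows; the output Hankel
matrix is projected onto the orthogonal complement of the input row space
(computed by explicit projection through a pivoted QR of the input Hankel
transpose, which stays well-defined when input channels are duplicated or
collinear); the SVD of the projection gives the singular-value spectrum and
the extended observability matrix, whose first block row is C and whose
shift invariance gives A by least squares; B, D and the initial state
follow by ordinary linear least squares, since the output is linear in them
for fixed (A, C).  Model order defaults to 3 (a largest-log-gap
singular-value criterion is available, plus a `fixed:n` override).

Two numerical choices matter:

* *Stability projection.*  The quasi-periodic platform excitation can push
  marginally unstable oscillatory modes into the shift-invariance estimate
  of A (spectral radius slightly above 1), which makes the B/D regression
  and any simulation diverge.  When that happens the eigenvalues with
  |λ| ≥ 1 are reflected inside the unit circle (λ → λ/|λ|², capped just
  below 1), keeping their phase.  A stable estimate passes through
  bit-unchanged, so exact recovery of stable systems is unaffected; the
  noiseless oracle tests recover eigenvalues and Markov parameters to
  ~1e-13.
* *Held-out scoring.*  Within each 40 s bootstrap window the model is fit
  on the first 4,000 samples (4 s) and its prediction VAF is scored on the
  remaining 36 s, simulated from zero initial state.  In-sample
  identification VAF (score on the training span, fitted initial state) is
  available via `held_out=False`.  Held-out scoring is the default because
  in-sample VAF mechanically rewards the extra parameters of the 6-input
  fusion model, which would bias the fusion-versus-hip comparison.

**VAF.**  Fit quality is %VAF = 100·(1 − var(ŷ − y)/var(y)) per channel,
with population variances (divide by N; fixed so exact-value tests are
stable), pooled across channels by variance weighting.  100 % is perfect
reconstruction, 0 % is no better than predicting the mean; negative values
are possible for pathological fits and are reported unclipped by default.

## Resampling and comparisons

Statistics are bootstrapped over n_iter contiguous windows (default 100 ×
40 s) whose starts are uniform with replacement; results are summarized as
median (interquartile range), with linear-interpolation (type-7) quantiles.
Conditions are compared with a two-sample t-test (Welch by default, pooled
available), two-sided, α = 0.05.  Because bootstrap windows overlap, the
per-window values are not independent and these t-tests are
anti-conservative; the package emits an `OverlappingWindowsWarning` and the
experiment report carries the caveat.  The procedure is retained as-is for
fidelity with common rig-study practice; p-values should be read as
descriptive.  The comparison machinery itself is calibrated: under the
null, its empirical type-I rate over 1,000 seeded repetitions is ≈ 0.05.

## Problem sizes

The full protocol (3,000 moves ≈ 25 min of 1 kHz data per trial, 1,000
stiffness iterations, 100 bootstrap windows) is the default configuration.
The shipped `fast_profile` (300 moves ≈ 150 s per trial, 20 bootstrap
windows, 100 stiffness iterations) is the package's scaled-down study size:
the reproduction tests run it over 20 master seeds, and
`scripts/acceptance.py` over 5, which is ample for the medians and
orderings being checked while keeping a laptop run in minutes.

## What the synthetic stand-in does and does not show

The generator emulates: serial mechanical propagation from substrate to hip
to head, neck-stiffness presets with a ≈ 1.9 stiffness ratio, direction
randomness on the sphere, per-axis asymmetry, sphere-radius scaling
(linear), and sensor noise.  It does not emulate: articulated multi-link
skeletal geometry, rubber-band (muscle-tendon) routing and its
nonlinearity, cross-axis coupling (off by default; a small symmetric
coupling stiffness can be switched on for robustness checks), robot-arm
kinematics, or sensor electronics beyond additive Gaussian noise.
Consequently, passing tests show that the estimators recover the *structure*
a serially compliant body imposes — shorter hip delays, better hip-based
reconstruction, head estimates that improve with neck stiffness, no gain
from fusing head onto hip — not that the specific printed magnitudes of any
physical rig are reproduced.  On this stand-in the hip/head VAF gap is
wider than a flexible multi-modal body would give, because the lumped head
stage discards high-frequency information more aggressively than a real
neck.

## Known limitations

* The chain is per-axis linear; superposition is exact, so radius acts only
  as a scale factor and any amplitude-dependent effect is out of reach.
* The exact map from sensor acceleration back to foot acceleration is
  non-causal/improper (it inverts a low-pass); a causal order-3 model can
  only approximate it, and the achievable VAF depends on noise, order and
  excitation bandwidth.  This mirrors the estimation problem any real
  balance-sensing system faces, and is the point of the comparison rather
  than a defect.
* t-tests on overlapping bootstrap windows are anti-conservative (see
  above).
* The rigid-neck limit of the simulator is only resolved when the stiffened
  neck mode lies below the Nyquist frequency; the corresponding test raises
  the sampling rate accordingly.
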