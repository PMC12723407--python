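# Methods

This note documents the models implemented in `opmcal`, the defaults they
use, what the synthetic data do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Synthetic array model

The helmet is a spherical cap: `make_helmet_slots` distributes slots with a
Fibonacci spiral over the upper 70 % of a sphere of scalp radius 0.09 m,
which gives near-uniform areal density (nearest-neighbour spacing has a
coefficient of variation well below 0.5). Each vapour cell sits at
`scalp_radius + offset`, with the offset drawn from a normal of mean 6.2 mm
and sd 5.0 mm truncated to [1 mm, 30 mm]; the untruncated distribution has
negative mass, so truncation is needed to keep the standoff physical. The
casing long axis points radially outward, the other two axes are
tangential, and the triad is right-handed.

All methods in the package depend only on channel positions, orientations
and gains — not on scalp shape — so a spherical cap is an adequate stand-in
for an MRI-derived helmet surface.

Per channel, the true sensitive orientation is its casing axis rotated by
an angle drawn from the folded normal |N(mean, sd)| — X: 18.7 ± 7.3°,
Y: 4.5 ± 2.0°, Z: 9.3 ± 5.4° — about a uniformly random axis perpendicular
to the casing axis. Only angle magnitudes are specified by measurement;
the rotation direction is unconstrained, and offsets are sampled
independently per axis (whether a common casing-level misalignment couples
the three axes of one sensor is unknown; we deliberately do not guess).
Gains are uniform in [0.8, 1.4]; noise is white at 17 fT/√Hz per channel.
All three channels of a sensor share one cell position: the two-beam cell
is treated as a point, which is why the calibration's sensor position is
defined as the mean of its three channel positions.

What the generator does *not* emulate: crosstalk between neighbouring
sensors (static crosstalk is absorbed into effective gains/orientations,
which is exactly what calibration estimates, so it needs no separate term),
sensor phase lags, drift or 1/f noise, movement, and environmental
interference. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated noise model, not robustness to every
real-world artefact.

## Field models

Reference gradients are completed to symmetric traceless 3×3 tensors
(`Gyy = −(Gxx + Gzz)`), making the simulated "coil" fields divergence- and
curl-free; the same tensors appear in the position-solver design matrix, so
the model and the simulated coil are consistent by construction. The
phantom coils are free-space point magnetic dipoles
(B = (μ0/4π)(3(m·r̂)r̂ − m)/r³, μ0/4π ≡ 1e-7 exactly); a 1-mm spiral at
≥ 2 cm standoff deviates from the point approximation by well under 0.1 %
(verified against Biot–Savart integration of a 40-turn loop). Brain-like
sources for sensitivity analyses use the analytic homogeneous-sphere
current-dipole (Sarvas) closed form — chosen over a single-shell boundary
model because it is closed-form and exactly testable (radial dipoles are
silent; the radial field component equals the primary-current term), and
the ‖l‖-based analyses depend only on having a physical lead field. A
guard radius of 5 mm around point sources prevents singular evaluations.

## Calibration

Defaults (all configurable through `CalibrationProtocol`): uniform fields
0.2 nT at 3, 4, 5 Hz (x, y, z); gradients 2 nT/m at 6, 7, 8, 9, 10 Hz in
the order dBx/dx, dBx/dy, dBx/dz, dBz/dz, dBy/dz; 4 s recording at 375 Hz;
demodulation window of 1 s starting at 0.5 s. These amplitudes keep the
superposed field below 1 nT at every cell (measured maximum ≈ 0.72 nT for
the default helmet), which is what keeps open-loop OPMs in their linear
range.

Demodulation computes the signed in-phase projection
(2/N)Σ x(t)·sin(2πf t) over a rectangular window containing an integer
number of cycles of every component (any whole-second window qualifies for
the 3–10 Hz comb), which makes the eight estimates exactly orthogonal — no
window tapering is needed or used. The reference sine has zero phase at
stimulus onset, fixing the sign of g (and hence the orientation/gain
split: gain = |g| > 0) relative to the drive; the simulator has no sensor
phase lag, so the quadrature component carries no signal and is discarded.
With 17 fT/√Hz noise, each amplitude estimate has sd
noise_density/√T ≈ 17 fT for T = 1 s, against 200-pT signals — hence
orientation errors of a few millidegrees and position errors of tens of
microns in closed loop. Matrix-coil current quantisation (1-pT LSB) is not
modelled: it is three orders of magnitude below the 200-pT reference
amplitudes and, unlike sensor noise, does not accumulate per channel.

Per channel the solver is the pseudo-inverse of a 3×3 (orientation/gain)
and a 5×3 (position) system; both agree with brute-force normal-equation
least squares to 1e-10 in tests. Channels with |g| < 1e-6 are flagged dead
and excluded; calibration completes for the rest. Whether a weighting
should be applied across the five gradient rows is unspecified; unweighted
least squares is used.

## Phantom QA

The phantom's five dipoles sit on a 7.5-cm circle at 30° intervals,
arranged symmetrically about the PCB's vertical axis; the default pose
stands the PCB upright in the helmet's x–z plane (dipoles running left to
right, moments tangential). The pose is configurable and — deliberately —
never revealed to the fitter: only relative (pairwise-distance) errors are
scored, which are invariant to any rigid transform of the fitted set.

The effective dipole moment is reconstructed from the manufacturing
parameters: 40 turns × (V/56 kΩ) × mean turn area, the mean of πr² over 40
radii uniformly spaced in [1.4 mm, 6.3 mm] (5.32e-5 m²), giving
1.90e-8 A·m² peak at 1 V pp. This is an engineering reconstruction — the
moment is not directly specified anywhere — but the QA metrics are
insensitive to its exact value (fits solve the moment freely).

Within each averaged trial the 27-Hz drive has 2·27·2 = 108 extrema in the
2-s on-window; the first 4 and last 4 peaks are dropped, leaving 100
fitting time points (the only reading consistent with both printed
counts). No filtering is applied to the averaged trial. Each snapshot is
fitted independently by separable least squares: the moment is linear given
a position and solved in closed form, so the nonlinear search runs over
position only. Numerical choices: residuals are normalised by the snapshot
norm so convergence tolerances are scale-invariant (fields are
1e-13–1e-10 T); multi-start from the 5 strongest-|signal| channel positions
pulled 20 % toward the helmet centre plus the centre itself, with a warm
start from the previous extremum's fit inside a session; trust-region
reflective steps with x_scale = 1 cm; distances floored at the 5-mm guard
radius inside the optimiser so it can traverse near-sensor positions.
Fitted positions are averaged over all localisations of a dipole (200 for
two repeats) before pairwise distances are computed.

Under the default noise and a simulated calibration, the mean relative
distance error is ~0.01 mm and the mean field-model correlation ~0.999998;
with CAD-only geometry (casing axes, unit gains) the same seeds give
~1.4 mm and ~0.98. The closed-loop simulation shares its forward model
with the fitter, so these numbers bound what the estimation machinery
itself contributes; real systems add unmodelled systematics and sit nearer
1 mm even when calibrated.

## Array metrics

"Judicious" and "poor" placement have no canonical algorithm; greedy
ordering by per-sensor lead-field power (descending/ascending) was chosen
as the simplest reproducible proxy, with whole sensors (3 channels) moved
together in best/worst modes and single channels in random mode. HFC is
implemented in its uniform-field-only form (3 orientation regressors);
higher-order harmonic variants are out of scope. PSD estimation uses
non-overlapping 10-s chunks with a flat-top window and averaged
periodograms (density scaling), reported as amplitude spectral density in
fT/√Hz; channels with a 60–80-Hz band mean below 7 fT/√Hz are flagged
dead, above 40 fT/√Hz noisy.

## Problem sizes and determinism

Default analyses run the full study conditions: 128 sensors / 384
channels, 4-s calibration recordings, 150-s phantom sessions, 5 dipoles ×
2 repeats × 100 extrema = 1,000 dipole fits. Every stochastic operation
takes an integer seed; child seeds are derived via `numpy.random
.SeedSequence`, and identical seeds reproduce outputs bit for bit.

## Known limitations

* No crosstalk, phase-lag, drift or movement models (see above).
* The conductor model for brain-like sources is a homogeneous sphere, not
  a realistic head.
* Matrix-coil fields are ideal uniform/gradient patterns; spatial
  imperfection of a real coil array is not modelled (a perturbation hook
  exists in the design but no magnitude is specified to justify a default).
* The phantom spiral is a point dipole; finite-size corrections are
  negligible at the simulated standoffs but would matter below ~1 cm.
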