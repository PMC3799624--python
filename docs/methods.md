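# Methods

## The problem

Sedimentation velocity (SV) analytical ultracentrifugation observes the
migration and spreading of macromolecular concentration boundaries under a
strong centrifugal field. With the confocal fluorescence detection system
(FDS), proteins can be followed down to nanomolar concentrations, but the
optics superimpose instrument signatures on the data that standard
absorbance/interference sedimentation models do not describe: sloping
solution plateaus from scanner tracking out of the plane of rotation,
slow intensity drifts from laser power and photobleaching, a shadow cast
by the centerpiece on the excitation/detection cone near the cell bottom,
radial smearing from the finite beam cross-section, and potentially a
non-linear signal response from inner-filter effects. `fdsvel` fits FDS-SV
data directly with sedimentation models augmented by explicit transforms
for each of these effects, so that the affected data can stay in the fit
and the detector parameters are refined together with the physics.

## Sedimentation model

The concentration evolution chi(r, t) of an ideal species with
sedimentation coefficient s and diffusion coefficient D in a sector-shaped
column obeys the Lamm equation

    d(chi)/dt = (1/r) d/dr [ r D d(chi)/dr - s omega^2 r^2 chi ],

with zero-flux boundaries at the meniscus m and bottom b. The solver
(`lamm_core.solve_lamm`) discretizes the conservation form on a uniform
radial grid (default 1000 points) by finite volumes with
Scharfetter–Gummel exponentially fitted face fluxes and advances with
Crank–Nicolson steps, the sub-step chosen so the advective Courant number
stays at or below a configurable limit (default 0.5). This construction
conserves the sector mass `sum V_i chi_i` to machine precision for any
Peclet number, degrades gracefully to pure upwinding at D = 0, and
reproduces the analytic radial-dilution law exp(-2 s omega^2 t) of the
plateau to better than 0.5% and the Faxen boundary-midpoint migration
ln(r_mid/m) = s * integral(omega^2 dt) to 0.2% at small D.

Finite rotor acceleration is treated by the effective-time transformation:
for a linear speed ramp completing at t_acc, the constant-speed solution
is evaluated at `integral(omega^2 dt)/omega^2`, which equals
omega^2 (t - 2 t_acc/3) after the ramp. This is the standard first-order
treatment; it is exact for the advective term and approximate for the
(much slower) diffusive evolution during the ramp.

## Detector signal model

Four transforms map chi into the recorded fluorescence signal
(`fds_model`), each linear in chi and therefore applicable per basis
function of a distribution analysis:

1. **Magnification gradient and drift** (T_rt): the signal is
   `[1 + (de/dr)0 (r - m) + (de/dt)0 t] * chi`, a first-order expansion of
   the space- and time-dependent magnification normalized to 1 at the
   meniscus at t = 0. Fitted concentration amplitudes are therefore in
   signal units at the meniscus at the start of centrifugation. The
   additive (rather than multiplicative) combination of the two gradients
   was chosen because both terms are first-order Taylor expansions around
   the same normalization point; the alternatives differ only at second
   order. An exponential drift mode, `exp((de/dt)0 t)` in place of
   `1 + (de/dt)0 t`, is available for strongly bleaching fluorophores; it
   agrees with the linear mode to first order.
2. **Bottom shadow** (T_S): a uniform circular beam cross-section of
   radius delta centered at radius r is cut by the wall at b; the signal
   is attenuated by the unobscured area fraction `1 - B(r, b, delta)` with
   the circular-segment formula
   `B = [delta^2 arccos(h/delta) - h sqrt(delta^2 - h^2)]/(pi delta^2)`,
   h = b - r. B rises from 0 at r = b - delta to exactly 1/2 at r = b and
   is continued symmetrically to 1 at r >= b + delta so the model remains
   total under optimizer excursions of b. Values of h within one part in
   1e12 of the beam edge are snapped to the exact limits, where the
   arccos evaluation has no significant digits left. delta = 0 disables
   the transform.
3. **Radial convolution** (T_C): an ad-hoc Gaussian kernel
   `exp(-(dr/sigma)^2)` truncated at `trunc_n * sigma` (default 3),
   renormalized to unit sum with local edge renormalization so constants
   are preserved exactly everywhere. Under this kernel convention the
   FWHM is `2 sigma sqrt(ln 2) ~ 1.67 sigma` (the standard-deviation
   convention would give 2.355 sigma). T_C is applied after T_rt and T_S.
   Convolution requires uniformly spaced radii (tolerance 1e-6 cm);
   non-uniform input is an error by default.
4. **Power-law non-linearity**: `a_obs = a0 + c^kappa`. Because this
   breaks the linearity the distribution analysis relies on, the data are
   back-transformed into concentration-linear units,
   `c = (a_obs - a0)^(1/kappa)`, the analysis (including TI/RI noise) runs
   in that space, and the fitted model is forward-transformed for residual
   inspection. Reported rmsd and residuals are in the raw data space;
   the noise distortion introduced by the back-transform is negligible at
   the high signal/noise ratios where non-linearity matters. For
   kappa = 1 both transforms reduce to exact offsets (no clamping), so the
   non-linear path is bit-identical to the linear path; for kappa != 1
   values below a0 are clamped to zero and counted.

## Distribution analysis

The c(s) model (`boundary_fit`) describes the data as

    data(r, t) ~= integral c(s) T[ chi(s, D(s); r, t) ] ds + TI(r) + RI(t)

with `D(s) = (sqrt2/18 pi) kT s^(-1/2) (eta f/f0)^(-3/2) ((1-vbar rho)/vbar)^(1/2)`
tying diffusion to one signal-average frictional ratio f/f0. The s-grid is
linear (default 100 points over 0.1–10 S, configurable); basis functions
are scaled by trapezoid quadrature weights so fitted amplitudes are
densities and `integrate_cs` recovers amplitude (= boundary signal at the
meniscus) and the signal-weighted s_w consistently; the first moment is
integrated exactly for the piecewise-linear density. Apparent molar mass
follows from the Svedberg equation M = s R T / (D (1 - vbar rho)) at s_w.

Time-invariant (per-radius) and radial-invariant (per-scan) offsets are
eliminated algebraically: data and basis are projected onto the orthogonal
complement of the offset subspaces (column/row centering), the
non-negative amplitudes solve the projected problem by NNLS with an
optional Tikhonov second-difference penalty, and TI/RI are recovered from
the residual field afterwards (the shared-constant degeneracy is resolved
by giving RI zero mean). This is exactly equivalent to the joint bounded
least-squares problem, so fitted amplitudes and rmsd are invariant to
1e-8 under the addition of arbitrary TI/RI fields.

The regularization weight can be fixed or selected by the one-standard-
deviation F-ratio criterion (P ~ 0.68): alpha is increased until the
regularized chi-square crosses `chi2_0 * F_crit`, then refined by
log-bisection. The outer parameter refinement runs unregularized, and the
selected smoothing is applied to the final distribution only — the
parameter estimates should not depend on the smoothing level, and this
keeps the refinement cost linear in the number of function evaluations.

The outer refinement over {meniscus, bottom, f/f0, de/dr, de/dt, delta,
sigma} (each individually fixable) uses a derivative-free Nelder–Mead
simplex with box constraints through a sin^2 transformation, because the
inner objective is non-smooth in m and b through grid alignment. Initial
values placed exactly at a bound are nudged 2% into the interior so the
transform has a usable derivative. Default boxes: meniscus/bottom ±0.05 cm
around the initial guesses, f/f0 in [1, 4], de/dr in ±2 /cm, de/dt in
±0.2 /h, delta in [0, 0.5] cm, sigma in [0, 0.1] cm. With fewer than 10
scans a warning flags that the temporal drift is weakly identified against
radial dilution (both compress the plateau sequence).

The default radial fit window is [m + 2 delta, b]: data closer to the
meniscus than the detection-cone diameter (as measured from the bottom
shadow) are excluded, because reflection and refraction at the meniscus
are not modeled; the bottom region is retained because T_S describes it.

Weighted fits are not used by default (rmsd is reported in plain counts);
a per-point standard-deviation column, when present in scan files, is
parsed and retained for optional use.

## Synthetic data

`synthetic.simulate_scanset` generates the only data the test suite
consumes. The forward model per gain g is

    signal = g * delinearize(compose_fds(sum_i chi_i)) + TI(r) + RI(t) + noise

with additive Gaussian noise of constant standard deviation in counts
(matching the counts-scale rmsd convention of FDS work; an optional
signal-proportional term exists for stress tests), an optional smooth
low-order-polynomial-plus-spikes TI field and small per-scan RI offsets,
all drawn from one seeded generator so output is bit-reproducible. The
EGFP-like preset encodes the reference acquisition: a 12 mm column
(meniscus 6.0 cm, bottom 7.2 cm) at 50,000 rpm, 1-minute scans at 0.002 cm
radial spacing, gains 1/2/4/8, a single species with s = 2.584 S
(buffer-uncorrected) and f/f0 = 1.39, and a 14-point dilution series
spanning 5.5 nM to 5.56 uM.

What the generator does *not* emulate: photon-counting statistics and
detector dead time, meniscus-region reflection/refraction optics, rotor
stretch, scan-time skew within one radial sweep, and run-to-run drifts of
the focal geometry. Passing recovery tests therefore demonstrate that the
fitter inverts its own forward model class at realistic noise, geometry
and distortion magnitudes — not that every physical effect in real FDS
data is captured.

## Problem sizes used in the test suite

The automated tests run reduced-size versions of the reference experiment,
chosen as the smallest problems that still exercise every term of the
model: end-to-end recovery uses 40 scans at 600 s intervals with 0.005 cm
radial spacing (241 radii), a 30-point s-grid over 0.5–5 S, a 300-point
internal solver grid, and 1% noise; solver-accuracy checks use the full
0.002 cm sampling and 1000–2000 point grids. At these sizes the complete
suite runs in a few minutes on one CPU. The generator's distortion
magnitudes in those tests (de/dr = 0.25 /cm, de/dt = 1%/h,
delta = 0.15 cm, sigma = 0.02 cm) sit in the middle of the ranges the
reference experiments report.

The "naive analysis" used as the degradation control in the recovery test
fits without any detector terms and excludes the bottom ~1 mm of the
column — the pre-correction protocol for FDS data, where the shadow region
had to be discarded. Against this control, the corrected fit roughly
halves the rmsd and removes an upward bias of the frictional ratio (the
unmodeled magnification gradient and drift masquerade as extra boundary
spread).

## Numerical choices and edge cases

* Tie-break in NNLS rank deficiency: a small second-difference
  regularization floor is applied with a logged warning.
* `solve_lamm` accepts radii outside [m, b] only with `clamp=True`
  (boundary-value extension), used by the fitter when the bottom position
  floats below the last data point; the shadow transform dominates there.
* A zero c(s) integral leaves s_w undefined (NaN) with a warning rather
  than raising, so batch runs continue.
* Scan files are written with 15 significant digits; read/write round
  trips are lossless to well below 1e-12 relative.
* All s-values are entered in Svedberg (1e-13 s) at the API surface and
  converted internally; de/dt is entered per hour and converted to per
  second; angular velocity is rpm * pi/30.

## Known limitations

* Single-channel, non-interacting species only; reaction-coupled Lamm
  equations, maximum-entropy regularization and Bayesian priors are out of
  scope.
* The shadow model assumes a uniformly illuminated circular beam
  cross-section; real power-density profiles will deviate in detail.
* Whether the shadow attenuates excitation, emission, or their product is
  not distinguishable in this first-order description; a single
  multiplicative factor is used.
* The exponential drift mode is a plain exponential in time; more complex
  photobleaching kinetics are not modeled.
* Rotor stretch and finite scan time are not corrected.
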