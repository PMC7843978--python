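# Methods

`ppgsim` synthesizes the reflectance photoplethysmogram (PPG) of the radial
artery at the volar wrist: a travelling pressure pulse dilates the artery,
the dilated segment displaces adipose tissue with strongly absorbing blood,
and the light collected by a surface sensor 0.97 cm from the source dips as
the dilated segment passes beneath it.  The model has three parts: elastic
wall mechanics, a voxelized layered tissue geometry with a travelling
double-ellipsoid lumen envelope, and weighted-photon voxel Monte Carlo light
transport.

## Vessel mechanics

The radial artery is a pressurized elastic tube: inner diameter 2.5 mm, wall
0.2 mm, Young's modulus 0.70 MPa, Poisson ratio 0.49 (wall mass density is
carried for completeness but inert in statics).  Two closed-form models are
provided:

* thin-wall (membrane): dD = D * P r / (t E) — the default; at 130 mmHg
  (133.322 Pa/mmHg) it gives dD = 0.39 mm, ~15% diametral strain, inside the
  10-20% range reported for arterial walls;
* thick-wall (Lame, plane stress): u(a) = (P a / E)((a^2 + b^2)/(b^2 - a^2) + nu),
  dD = 2 u(a), for checking the membrane approximation (they agree to first
  order in t/a).

The 0.4 mm dilation is interpreted as lumen (inner-diameter) dilation.  An
incompressible-wall variant recomputes the dilated wall thickness at
conserved wall cross-section; it differs from the constant-thickness
convention by <15%, and the constant convention is the default.

## Pulse envelope and tissue volume

The dilated lumen is the union of the baseline cylinder with two coaxial
ellipsoids (closed surfaces; boundary voxels count as inside) whose x/z
semi-axes are the dilated radii and whose y semi-axes set the along-vessel
extent.  Membership is tested at voxel centers.  The wall is the set of
voxels within one wall thickness (Euclidean distance transform with the
anisotropic voxel pitch) of the lumen, held constant along the envelope; the
center-to-center distances bias the shell by O(pitch), vanishing under grid
refinement.  On the coarse grid the shell can be locally one voxel thin —
an accepted discretization artifact with a small optical effect (wall and
surrounding media differ modestly).

The volume is a z-stack: one voxel layer of epidermis whose absorption and
scattering are rescaled by (0.010 cm / dz) to preserve the optical thickness
of the anatomical 0.10 mm epidermis; dermis of the scenario's thickness;
subcutaneous adipose below; artery embedded at the scenario's depth.  Depth
is datumed at the *top* of the baseline lumen, so the axis sits at
depth + 1.25 mm.  Default grid: 1.4 x 1.4 x 0.8 cm^3 at 200 x 100 x 100
voxels (finest pitch transverse to the vessel); reduced-budget runs use the
same domain at 100 x 50 x 50.

Default envelope parameters are calibration choices, not published
quantities: IDx comes from the thin-wall mechanics (2.887 mm), the secondary
dilation is 40% of the primary one, and pwd1 = 0.30 cm, pwd2 = 0.35 cm,
psep = 0.55 cm — a continuous 1.2 cm dilated union with a waist between the
systolic and dicrotic lobes.  The calibration is constrained by a strong
nonlinearity of the detected response: a uniformly dilated artery produces a
23% dip, the long 1.45 cm overlapped envelope 15-28%, but every envelope
shorter than ~1 cm (separated or merged) saturates at only 2-6%, because the
signal responds strongly only when the dilation reaches the high-sensitivity
columns directly beneath source and detector.  The chosen parameters put the
non-obese dip at ~8% with its broad minimum at pulse position y = -0.2 cm;
that evaluation position is frozen as part of the calibration.  The
89-position trajectory spans the grid plus the envelope extent, so the
envelope is entirely outside the field of view at both ends.

## Optical properties

Five media (epidermis, dermis, subcutis, vessel wall, blood) are tabulated
at the two source peaks, 660 and 890 nm; source bandwidth (22/54 nm FWHM) is
not integrated over.  The tabulated dermis absorption at 890 nm is stored as
2.459 cm^-1 (the raw printed magnitude would be physically implausible).
Physiological adjustments touch absorption only:

* Dermis: mu_a = B mu_a,blood + W mu_a,water + residual, with baseline
  fractions W0 = 0.65 and B0 = 0.02 (blood near the low end of the reported
  0.2-7% range).  Trans-epidermal water loss scales W down,
  W = W0 (1 - p/100); perfusion scales B up, B = B0 (1 + p/100) — obesity
  dries the dermis and raises its blood content.  The residual (dry matrix)
  is calibrated so the non-obese scenario reproduces the tabulated dermis
  value exactly; the water constants (0.0036 / 0.0617 cm^-1) are
  compilation inputs whose exact values therefore never shift the baseline.
  With them, the 60% TEWL and +40% blood extremes move dermal mu_a at
  660 nm by only -0.3% and +3%: water is almost transparent here, so the
  model predicts weak AC/DC sensitivity to these two factors.
* Epidermis: mu_a = M mu_a,mel + (1 - M) mu_a,non-mel with the melanosome
  reference spectrum ~519 (lambda/500 nm)^-3 cm^-1.  The reference fraction
  at which the table row holds is 0 (i.e. the tabulated epidermis is treated
  as melanin-free): with the standard melanosome constant, any appreciable
  reference fraction would exceed the small tabulated value, so a nonzero
  reference would force a negative non-melanin component.  Melanin sweeps
  span 3-43% volume fraction.

Scattering, anisotropy and refractive index are never adjusted: the obesity
and melanin parameterizations are chromophore-content changes.

## Monte Carlo transport

mcxyz-lineage weighted-photon transport on the labeled voxel grid:
exponential scattering free paths (sampled against mu_s), continuous
Beer-Lambert absorption weighting along every traversed voxel segment (the
absorption map accumulates the deposits and always totals the absorbed
tally), Henyey-Greenstein deflection, unpolarized Fresnel
reflection/refraction at the surface and at internal index mismatches (the
1.47/1.4 steps at the vessel; disable-able), Russian roulette below weight
1e-4 with survival multiplier 10, and termination with tallying at the
lateral and bottom faces.  The beam is a gaussian spot (1/e^2 radius
0.06 cm) entering normally; normal-incidence specular reflection is tallied
at launch.  Detection uses a 0.35 cm square aperture with NA 0.866,
evaluated on the ambient-side angle after refraction.  Energy conservation
(specular + diffuse + escape + absorbed + roulette net) holds to ~1e-12 per
run and is asserted at 1e-6.

Randomness is counter-based (splitmix64 substream per global photon index):
partitioned runs merge bit-exactly, and — deliberately — the *same* photon
substreams are used at every pulse position and scenario.  These common
random numbers make identical volumes give identical tallies (the
envelope-outside trajectory tail is simulated once) and make waveform
differences across positions and scenarios far less noisy than independent
seeding would.  In particular, configurations that differ only in absorption
coefficients (TEWL, dermal blood, melanin) retrace *identical* photon paths
under the continuous-absorption scheme, so their signal ratios are nearly
noise-free.

Two detection estimators are built in.  Analog detection tallies photons
that physically exit through the aperture inside the NA cone; at this
geometry only ~1e-5 of launched weight is detected, so analog estimates are
hopeless at desk budgets.  The default shadow-ray (next-event) estimator
scores, at every scattering event near the detector, the expected
uncollided escape into the internal acceptance cone:
w P_HG(cos psi) Omega_cone T (1 - R), with T the exponential of the optical
depth marched along the straight exit ray.  It is unbiased (every analog
detection has a last collision) and agrees with analog within Monte Carlo
error; index-mismatch faces on the shadow ray contribute their transmission
factor but not their refractive bending (such rays are attenuated to
nothing in practice).

For variance, the kernel supports importance weight windows: a coarse
(8^3-supervoxel) importance map is built from an adjoint-style run launched
at the detector, and photons split (up to 4096-fold cumulative) when their
weight exceeds twice the local target I(source)/I(r), or play roulette below
half of it (suppression capped at 256).  Split children spawn substreams
from the parent state, preserving determinism.  Windows redistribute
variance only; one map (built on the undilated baseline volume) serves a
whole sweep, which also preserves the common random numbers across swept
geometries.  Remaining caveat: the detected-weight estimator has a
heavy-tailed per-run distribution, so small ensembles can under- or
overshoot by a few percent more than their empirical standard error
suggests; ratio metrics cancel much of this.

## Waveform metrics

DC is the mean detected fraction over envelope-outside positions (cached
single run, given a larger photon budget since DC noise propagates directly
into the ratio).  AC is the largest excursion from DC of the
Savitzky-Golay-smoothed waveform (window 9, quadratic — passes a parabolic
dip unchanged, suppresses the extremum-selection bias a raw minimum over 89
noisy points would add).  AC/DC is reported in percent; the baseline change
between scenarios is the relative DC drop.  The paper-style plots invert
and min-max normalize (reflectance dips become upward PPG pulses); raw
detected fractions are always retained.  Measured traces are registered to
the position axis by a piecewise-linear time map anchored at the trace
start, primary peak and end.

Sweeps hold everything at the non-obese row except the swept factor
(isolated TEWL / blood / thickness / depth series from the BMI parameter
table), sweep melanin on the non-obese geometry, or advance the combined
obesity levels (dermal thickness 1.0 -> 2.5 mm with artery depth
2.5 -> 4.5 mm over four levels; the parameter table itself stops at 3.5 mm —
both depth series are supported, the combined default follows the wider
range).  Sweep drivers simulate the first configuration over the full
trajectory and later ones over the dip region plus the DC reference, with
the shared importance map and substreams.

## Problem sizes and reproduction

The headline simulations behind the published figures used 1e8-1e9 photons
per pulse position; as the package's own desk-scale conditions,
`scripts/acceptance.py` runs the coarsened grid and evaluates each
scenario's AC/DC as (DC - dip)/DC at the calibrated dip position: absolute
ratios use weight-windowed runs of 150,000 photons each (one-sigma about
2.5 percentage points per ratio — the windowed estimator is heavy-tailed,
so declines built from two absolute ratios carry tens of points of noise),
while declines between absorption-only scenarios (melanin, dermal water,
dermal blood) use windowless 200,000-photon common-random-number pairs,
whose identical paths pin the relative signal shifts to ~0.1% and are
combined exactly with the reference ratio
(:func:`ratio_under_absorption_change`).  Fixed-position evaluation also
avoids the upward bias that searching a noisy waveform for its extremum
would add; `waveform_metrics` accepts a pinned extremum position for the
same reason, and the sweep drivers use it for every level after the first.
Tolerances in the test suite widen with the inverse square root of the
budget.

## Known limitations

* Flat wrist surface; no arterioles, muscle, or radial styloid; homogeneous
  layers.  Pulse positions are geometric samples, not timestamps — no pulse
  wave velocity or multi-beat synthesis.
* The synthetic generator emulates study conditions, not a particular
  subject: passing tests demonstrate internal consistency and reproduction
  of the modeled effect sizes, not clinical accuracy of any waveform.
* With standard water optical constants, dermal water loss barely changes
  660 nm absorption; reproducing double-digit AC/DC declines for the
  TEWL/blood factors would require much stronger chromophore contrasts than
  the standard compilations provide.  The package reports what its physics
  yields.
* Wall realization on coarse grids is a thin, occasionally broken shell
  (EDT center-to-center bias); refined grids converge.
* Shadow-ray estimator ignores refractive bending (not attenuation) on the
  rare exit rays crossing index mismatches.
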