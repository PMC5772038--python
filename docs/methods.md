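# Methods

## Coordinate and profile conventions

All coordinates are in nm with the membrane normal along z and the bilayer
midplane at z = 0.  Readers recenter each frame so the phosphate centre of
mass sits at z = 0 (a pressure-coupled box drifts along the normal, and
every metric here is a relative position), then wrap coordinates into the
box; the synthetic generator emits frames already recentered.

Density profiles are per-frame histograms of a particle selection,
normalised by the frame's lateral area times the bin width and then
averaged over frames.  The per-frame matrix is retained so that all
resampling happens on binned densities rather than raw coordinates.  The
default bin width is 0.1 nm: fine enough to resolve head-group peaks
(0.3–0.5 nm wide) without starving per-bin counts on ensembles of ~100
frames.  Number density (not mass density) is used throughout; selections
count single marker atoms (water oxygen, alcohol hydroxyl oxygen), which
keeps the bulk/membrane assignment of a molecule unambiguous.

Peak locations are the argmax bin refined by a 3-point parabolic vertex.  A
wider 5-point least-squares refinement was evaluated and rejected: over ±2
bins the parabola misfits a ~0.15 nm-wide Gaussian enough to create a
grid-phase-dependent vertex bias, which enters the thickness twice (once
per leaflet).  Profile crossings are bracketed on a lightly smoothed
difference (3-bin moving average — suppresses single-bin noise crossings;
reported profiles are never smoothed) and located by linear interpolation
between bin centres, so piecewise-linear profiles are resolved exactly.
Zero or multiple sign changes raise a structured error listing the
candidate crossings; multiple crossings are the signature of pore-like or
disrupted membranes, and the package deliberately refuses to pick one.

## Uncertainty conventions

All intervals are 95%, two ways:

* **Frame bootstrap** (percentile, default 100 resamples, resample size =
  n_frames) for everything derived from profile intercepts and peaks:
  interior water, partitioning, insertion depths, peak locations.  Joint
  quantities (a depth is a difference of two peaks; partitioning needs the
  bulk boundary and the per-frame counts) resample frames once per draw so
  correlations are preserved.  Percentile, not BCa; one seeded stream per
  invocation.
* **Block averaging** (5 contiguous blocks, Student-t on block means or
  block re-estimates) for box-derived and order observables, whose frame
  series are autocorrelated in real trajectories: area per lipid,
  thickness, per-carbon and chain-mean S_CD.

Percentile bootstrap intervals are systematically slightly narrow at small
frame counts (an ideal mean-of-100-frames interval covers ≈93.5%, worse
below that); the recovery suite therefore runs at 200 frames, where every
estimator's measured coverage is ≥90% — still far below the ~10⁴ frames a
production trajectory analysis would average.  `IntervalEstimate` widens an
interval, if necessary, to contain the point estimate, since a percentile
interval from a skewed resampling distribution can otherwise exclude it.

## Membrane metrics

* **Area per lipid** divides the lateral box area by the lipids *per
  leaflet* (64 for the 128-lipid reference composition): each leaflet
  independently tiles the membrane plane, and this convention reproduces
  the familiar ~0.5 nm² scale for a fluid bilayer.
* **Thickness** is the distance between the phosphate density peaks of the
  two leaflets; its uncertainty is a t-interval over per-block peak
  distances.
* **S_CD** uses explicit C–H bond vectors when tail hydrogens are present
  (with the minimum-image convention — wrapped coordinates would otherwise
  corrupt bonds at the box boundary).  Hydrogen-free chains fall back to
  the geometric reconstruction ⟨S_CH⟩ = −S_aa/2 from the local chain axis
  a = C(i−1)→C(i+1), flagged in the result.  Signed per-carbon values are
  exposed; the chain mean averages |S_CD| over interior carbons, so "lower
  order" is always a decrease of a positive quantity.
* **Interior water** counts waters strictly between the two crossings of
  the IPC-tail and water densities; the per-frame counts and the crossings
  are bootstrapped jointly.
* **Partitioning** classifies an alcohol by its hydroxyl oxygen against the
  bulk-water region (outboard of the water/phosphate crossings, searched
  outward from the phosphate peak so the inner tail-region crossing is
  never confused with the bulk boundary).  Membrane and bulk fractions sum
  to one per frame by construction.
* **Insertion depth** is the group's density-peak distance from the POPI
  glycerol peak, computed on leaflet-folded |z| profiles (0.05 nm bins) and
  signed positive toward the bilayer centre.
* **Solvent composition** converts a nominal g/L alcohol concentration to
  molecule counts under the additive-volume convention (alcohol volume at
  its bulk density, remainder water at 0.997 g/mL).  The reported
  alcohol-per-lipid ratio keeps the unrounded mole fraction; the integer
  molecule count is what a box builder would use.  Above ~80 g/L the
  additive-volume and mass-per-litre conventions diverge noticeably, which
  warns but does not error.

Significance between two estimates is the disjointness of their 95%
intervals — deliberately conservative (its null rate is well under 5%,
verified by the calibration test).

## Uptake analysis

Counting efficiency and the labelled:total dilution of the acid mixture are
folded into the calibration slope, because the standards are prepared from
the same mixture and counted in the same counter; no separate CPM→DPM
factor is applied.  Sample counts are corrected by the natural background
and the condition's blank (filter/cell-surface adsorption); corrections
overshooting the signal floor at zero with a warning rather than erroring —
blanks can exceed small signals at the earliest time point.  nmol per mg
dry weight divided by the cell volume (2 µL/mg) is mM exactly.

Initial rates and diffusion constants use zero-intercept least squares:
passive diffusion has zero rate at zero acid.  A with-intercept variant
exists behind the standard fit functions but is not the default.  The
accumulation plateau and rate constant come from a first-order fit
C(t) = plateau·(1 − e^(−kt)).  The pH inference is undefined at or below
the extracellular undissociated fraction f_out and raises there; pH_i is
reported to one decimal.  Condition comparisons use Welch's t-test (no
equal-variance assumption).

Growth curves: µ_max is the steepest log-linear sliding-window slope
(3 h windows, ≥5 points, r² ≥ 0.98, windows must span ≥80% of the nominal
width so end-of-record stubs cannot win on noise); failure to find a
qualifying window flags "non-exponential growth".  Glucose depletion is
proxied by the minimum of the smoothed instantaneous growth rate after the
exponential phase (odd-width smoothing kernel, ~0.5 h; the edge-affected
last points are excluded from the search); cultures that never reach 1.5×
their starting OD are flagged "no growth in T hours".

## Synthetic generators

The generators are statistical mimics, not simulations: particles are drawn
from the per-role distributions the estimators are defined on, with no
bonded dynamics or energetics.  This is deliberate — the package tests
estimators, and a mimic with known parameters is the only input whose truth
is exactly known.

The bilayer generator places Gaussian phosphate layers at ±1.9 nm
(leaflet-symmetric, 3 marker particles per phospholipid), the POPI glycerol
layer 0.3 nm inward, IPC chains spanning a ±1.0 nm tail slab with two
hydrogens per carbon, bulk water rising linearly from 0.3 nm outboard of
the slab edge to its bulk level at 2.6 nm (mimicking the head-group water
depletion of a real bilayer; the gap keeps ramp waters from leaking into
the measured interior region), and alcohols split between a head-group
Gaussian and the bulk.  Two generator choices matter for testability:

* the interior water count per frame is Poisson(target), not exactly the
  target — a constant count would give the frame bootstrap (near-)zero
  variance and make interval coverage of the generating value meaningless;
* C–H tilt angles come from a single-parameter family |cos θ| = c + ε with
  ε ~ N(0, 0.05) and c solved so E[(3cos²θ−1)/2] equals the per-carbon
  target; the inversion is independent of the estimator, so direct
  averaging over drawn cosines is a valid oracle.

Default scales follow the reference system (44 DOPC + 44 POPI + 20 IPC +
20 ergosterol, box ≈ 5.83 nm, ~5000 waters); the test suite mostly uses a
reduced variant (1200 waters, 40 interior waters) for speed.  What passing
the recovery suite shows: the estimators are unbiased and their intervals
approximately calibrated *for ensembles matching the generator's
assumptions* — independent frames, Gaussian layers, a single bilayer with
no pores.  It does not validate behaviour on autocorrelated trajectories
(block averaging exists for that but its benefit is only demonstrated on
AR(1) series), on disrupted membranes (which raise structured errors by
design), or on real force-field density shapes.

The uptake generator follows C_in(t) = A·c_out·(1 − e^(−kt)) with Poisson
counting noise on expected counts (slope·nmol + blank + background), the
default time points at 15 s–10 min, and standards spanning the signal
range.  The growth generator runs exponential growth at µ, dips the
instantaneous rate to a floor exactly at t_dip (Gaussian dip, 0.5 h width)
and resumes at a slower respiratory rate, with log-normal OD noise.

## Problem sizes

The recovery acceptance suite uses 50 replicates of 200-frame ensembles
with 300 bootstrap resamples per interval; oracle-equivalence and
round-trip checks use 50–80-frame ensembles and 3 seeds.  These sizes put
the interval methods inside their validity regime while keeping the whole
suite around a minute of CPU.

## Known limitations

* The GRO reader handles only the fixed-column coordinate format (no
  velocities parsing, no topology); binary trajectory formats are out of
  scope.
* The axis-reconstruction S_CD assumes hydrogens distribute uniformly
  around the chain axis, which underestimates |S_CD| for chains with
  strongly anisotropic rotameric states.
* `time_to_glucose_depletion` cannot resolve a dip within ~3 samples of
  the end of the record (edge-noise exclusion).
* The partitioning bulk boundary requires the water and phosphate profiles
  to cross outboard of each phosphate peak; heavily disrupted membranes
  fail loudly rather than produce a number.
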