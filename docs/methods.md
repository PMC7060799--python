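# Methods

`cinequant` quantifies biventricular function from *segmented* cine cardiac
MRI: label stacks (LV blood pool, LV myocardium, RV blood pool) over one
cardiac cycle in a short-axis (SAX) multi-slice stack plus 2-chamber and
4-chamber long-axis (LAX) views. Segmentation itself is out of scope; the
package covers everything downstream — inter-stack alignment, volume and
mass measurement, filling/ejection dynamics, feature-tracking strain,
post-analysis quality control, and cohort statistics — together with a
parametric phantom that gives every stage an analytic ground truth.

## Volume curve model

The phantom prescribes each ventricle's volume over the cycle as a
piecewise raised-cosine pulse train in dV/dt, parameterized on the cycle
fraction t ∈ [0, 1]:

- ejection: one raised-cosine pulse of integral SV = EDV − ESV on
  [0, t_es] (default t_es = 0.35);
- early filling (E wave): a raised-cosine pulse of integral A_E centred at
  t_E (defaults A_E = 0.7·SV, t_E = 0.55, width 0.30);
- diastasis: dV/dt = 0 between the waves;
- atrial filling (A wave): integral A_A = SV − A_E centred at t_A
  (defaults A_A = 0.3·SV, t_A = 0.85, width 0.20).

Because a unit-area raised-cosine of width w peaks at 2/w, the dynamics
have closed forms: PER = 2·SV/(t_es·RR), PEFR = 2·A_E/(w_E·RR),
PAFR = 2·A_A/(w_A·RR), AC = A_A. The curve is C¹, closes exactly
(V(0) = V(1) = EDV), and its minimum is ESV. Defaults were chosen once to
give rates in the physiologic range for a resting adult (PER ≈ 500–600
ml/s, PEFR ≈ 400–500 ml/s, PAFR ≈ 250–350 ml/s at RR = 1 s).

## Phantom geometry and motion

The LV blood pool is a half-ellipsoid of circular cross-section (base
plane at z = 0, default pool length 90 mm) whose base radius follows from
the prescribed EDV. The epicardium is the concentric half-ellipsoid whose
volume exceeds the pool by the prescribed wall volume (default 100 ml), so
wall thickness tapers toward the apex. Motion is an in-plane radial map
about the long axis: pool radii scale by s(t) = sqrt(V(t)/EDV); wall
points map area-preservingly, r → sqrt(r² + (s²−1)·R_pool(z)²), which
keeps the wall volume constant through the cycle (incompressible
myocardium) and makes the mid-wall circumferential strain analytic:
ε_circ(z, t) = r_mid(z, t)/r_mid(z, 0) − 1.

The RV is a crescent: a clipped ellipsoid (restricted to the septal side)
minus the current LV epicardial region, evaluated in *current* coordinates
so the RV can never overlap LV labels. Its in-plane scale is calibrated
per frame by one-step fixed-point correction so that the voxelized volume
tracks the prescribed RV curve (no closed form is claimed for the crescent;
the voxel curve is the RV ground truth, and it matches the prescription to
≲1% at acquisition resolution).

SAX slices sit at the midpoints of consecutive slice cells from the base
plane, so Simpson slice summation sees the midpoint-rule sample of each
cell. LAX views are exact planar evaluations of the same implicit geometry
(4-chamber: the plane through both ventricles; 2-chamber: the orthogonal
plane through the LV axis only). Acquisition defaults emulate a biobank
protocol: 1.8 mm in-plane, 8 mm slices with 2 mm gap, 50 frames, RR = 1 s.

What the phantom does *not* emulate: MR contrast and noise, papillary
muscles, trabeculation, through-plane (longitudinal) myocardial motion,
breathing drift within an acquisition, and atria/valves. In particular,
because motion is purely in-plane, the phantom's longitudinal strain is a
few percent rather than the ~−16% seen in vivo; tests therefore validate
the longitudinal-strain *machinery* (arc-length ratios, invariances)
rather than its physiologic magnitude. Passing tests show the measurement
chain is correct on ideal labelled anatomy, not that segmentation errors
of real images are absorbed.

Artifact injection covers the failure modes the QC stage is meant to
catch: dropped basal/apical slices, a per-slice breath-hold translation
(quantized to whole voxels so the injected truth is exact and recorded in
provenance), an off-axis LAX plane (affine tilt anchored near the base),
an RV/LV stroke-volume mismatch (RV re-voxelized toward a rescaled
excursion), and a mis-trigger surrogate (one frame's labels replaced by
the previous frame's). All generator outputs are pure functions of
(spec, seed).

## Volumetry and dynamics

Volumes use Simpson slice summation: labelled in-plane area × (slice
thickness + gap), summed over slices. Volume curves are smoothed by
periodic Fourier truncation (default 10 harmonics — enough to pass the
widest phantom wave undistorted while suppressing voxelization noise) and
differentiated spectrally; curve and derivative are evaluated on a dense
cyclic grid (720 points) so extrema are not quantized to the frame raster.
ED/ES are the smoothed extrema; PER is the largest −dV/dt on the ejection
arc; the E peak is the first local dV/dt maximum after ES and the A peak
the last before the cycle closes, with local maxima of prominence below 5%
of max|dV/dt| ignored as ripple; diastasis is the |dV/dt| minimum between
the two peaks. AC is defined as V(end-of-cycle ED) − V(diastasis) — a
convention, stated here because "atrial contribution" admits several. A
fused E/A pattern reports PAFR and AC as missing with a reason rather than
a number. LV mass is myocardial volume × 1.05 g/ml at ED (ED chosen as
the pool-volume argmax, guarding against cycles that do not start exactly
at ED). BSA indexing uses DuBois: 0.007184·w^0.425·h^0.725 (kg, cm).
Whether peak rates should also be BSA-indexed is left to the caller; raw
ml/s is always emitted.

## Alignment

Breath-hold offsets are modelled as one in-plane translation per SAX slice
(and per LAX view) — no rotation or out-of-plane motion. Along the
intersection line of a SAX slice plane with a LAX plane, label-boundary
crossings (sub-voxel, from bilinear mask interpolation) must coincide
between the two views at ED. A slice translation moves its crossings by
exactly the translation's component along the line, so each iteration
solves the 2-D shift per slice in closed form from the mean crossing
offsets on its two lines (weighted least squares), then refines the LAX
views against all slices, until the largest update is below tol (default
0.1 mm, max 10 iterations, shifts capped at 15 mm). The LAX shift
component along the stack normal produces no crossing offset and is left
at zero — a stated blind spot of this objective. Estimated shifts are the
displacement; the applied correction is their negation,
nearest-neighbour-resampled per frame. Estimates are exact to ~0.1 mm on
matched-resolution phantoms; with mixed SAX/LAX resolutions the noise
floor is roughly half the coarser in-plane voxel, which is what the
idempotence tests assert.

## Strain

Feature tracking is deliberately pluggable: the strain mathematics is the
tested contract, the tracker is exchangeable. ED contours are sampled on
three SAX slices at 25/50/75% of the segmented LV extent (endo/epi as
sub-voxel closed polylines of the myocardium label, arc-length resampled
to 48 points; mid-wall as their pointwise mean) plus an open mid-myocardial
midline per LAX view traced by an angular ray sweep from the basal centre.
Points are advected either by displacement fields (phantom ground truth,
a `displacement.nii.gz` exported with a bundle, or any external
registrar's output) or by a built-in frame-to-frame 2-D diffeomorphic
demons registration (SimpleITK) on intensity images, composed pointwise.
Strains are Lagrangian percentages relative to ED: mid-wall perimeter
(circumferential, averaged over the three slices, unweighted), mean
endo–epi distance (radial; a thickness-based definition, chosen over
regional area change and documented as such), and midline arc length
(longitudinal, per view). ε(0) = 0 holds exactly by construction. Peaks
are signed minima for circumferential/longitudinal, maxima for radial;
times to peak are in ms from ED.

## Quality control

Geometric rules (on the aligned study): both LAX planes must cross LV
labels in the most basal and most apical SAX slices that carry ≥ 10 mm²
of LV (a lone boundary voxel is not an anchor); and the SAX and LAX LV
extents along the stack normal must each cover ≥ 90% of the other
(threshold configurable; the value is a package choice). Output rules:
|LV SV − RV SV| relative to the *mean* of the two SVs must be ≤ 10% (the
denominator convention is configurable and documented because "percent
difference" is ambiguous), and first/last-phase volumes must agree within
10% for both chambers. Curve-shape anomaly detection uses two soft-margin
RBF SVMs (volume curves, strain curves) on standardized features: the
curve resampled to 32 points and amplitude-normalized, plus six scalars
(fractional excursion, closure gap, largest frame-to-frame jump,
normalized rise/fall rates, extremum position). Training data come from
the curve-exemplar generator: jittered phantom curves against non-closure,
spike, clipped-plateau and sign-flip pathologies; 5-fold cross-validated
balanced accuracy is reported and models serialize/reload bit-compatibly.
The exact feature set is a reconstruction — a declared design choice, not
an inference about any particular trained system. A verdict flags for
review iff any rule flags or either SVM says anomalous; a pre-analysis
image-QC hook is exposed for external detectors but none ship here.
Pipeline stage crashes convert to QC flags carrying the stage name, so a
case report always contains a verdict. A bundle with no tracking input
records `strain_inputs: not_applicable` instead of a failure flag.

## Statistics

Bland–Altman bias and 1.96·SD limits of agreement with a paired t-test of
the differences against zero (degenerate SD = 0 reports p = 1 for identity
and p = 0 for an exact shift); Dice overlap (defined 1.0 for two empty
masks); mean-absolute-error group comparison (paired t, or Welch when
unpaired); sensitivity/specificity/balanced accuracy for error detection.
Reference values are stratified by sex × age decade (45–54, 55–64, 65–74);
within each stratum and parameter, values beyond 3 IQRs outside Q1/Q3 are
removed first (type-7 linear-interpolation quartiles — pinned because the
3-IQR rule depends on it), then the 95% prediction interval is the
Gaussian mean ± t₀.₉₇₅,ₙ₋₁·s·√(1+1/n); an empirical-percentile variant
sits behind a switch. Age effects are per-sex OLS slopes with Bonferroni
correction over the parameter family within one sex.

## Numerical and test-scale choices

Grids are sized from the anatomy plus an 8 mm margin; voxelization uses
voxel-centre membership. The RV per-frame calibration stops when the scale
correction is below 5×10⁻⁴. The dense cycle grid (720 points) bounds
timing quantization at ~1.4 ms for a 1 s cycle. Convergence of the
voxelized-volume error under voxel halving is assessed on the mean
relative error over a small spec set per resolution, since per-spec errors
at fine resolutions are dominated by voxelization jitter.

Test problem sizes are chosen to keep the suite fast while staying at the
scale the defaults describe: the headline phantom recoveries run at 1 mm
isotropic voxels with 50 frames; the volumetric oracle covers 50 random
specs at 1 mm (4 frames each); rule specificity uses 100 intact phantoms
at acquisition resolution; dynamics recovery uses 50 random analytic
curves at 50 frames (the voxelization chain being covered separately);
the smaller in-suite parameter-recovery batch uses 3 voxelized specs.

## Known limitations

Only translation is corrected between stacks; LAX through-stack offset is
unobservable to the alignment objective. The built-in demons tracker is a
simple frame-to-frame 2-D scheme that underestimates large deformations —
it exists so image-based tracking is exercised end-to-end, and any serious
application should supply registration-derived displacement fields. The
phantom's longitudinal mechanics are not physiologic (see above).
Segmental (AHA) strain, strain rate, RV strain, torsion, atrial volumetry
and papillary-muscle conventions are out of scope.
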