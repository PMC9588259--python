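# Methods

## Measurement model

A pulsed radiography acquisition is modelled as N = round(f · D) frames
at frame rate f (default 15 Hz) over duration D (default 20 s) on a
square 16-bit detector (native 1062 px at 0.4 mm pitch, source-to-
detector distance 120 cm).  A point-like target at object-to-detector
distance OID projects with geometric magnification

M = SDD / (SDD − OID),

so an object-plane displacement d mm appears as d·M/p pixels (pitch p).
All reported amplitudes are object-plane millimetres: pixel excursions
are multiplied by p and divided by M.  For patients the OID is taken as
the tumor-to-skin distance on the detector side (back skin for the AP
projection, bodyside skin for the lateral projection), i.e. the skin is
assumed to rest at the detector plane; any couch or cover stand-off can
be added explicitly (`detector_gap_mm`, default 0).  For the phantom the
platform calibration states M directly (1.09/1.15/1.20/1.27× for
platform offsets 0/50/100/150 mm), so `ProjectionGeometry` accepts a
magnification override that bypasses the closed form.

Amplitude is defined globally as max − min of the calibrated coordinate
over all non-lost frames — the distance between peak exhalation and
peak inhalation anywhere in the acquisition.  This deliberately includes
cycle-to-cycle variability; per-cycle excursions are reported separately
(below).

## Synthetic phantom generator

The generator stands in for a programmable respiratory motion platform
and the imaging hardware; it is first-class, tested code.

**Waveforms.**  Linear orbits displace the target sinusoidally with
peak-to-peak amplitude A and period T along a line rotated θ from the
vertical detector axis (components A·sinθ horizontal, A·cosθ vertical;
an `axis_swap` flag reproduces the opposite mounting convention).
Parallelogram orbits combine a vertical sinusoid (peak-to-peak V) with
a horizontal offset of ±H/2 whose sign follows the vertical velocity —
the orbit's exact shape is unspecified by the platform description, and
this construction pins the per-axis peak-to-peak components to (H, V)
exactly, which is the only property the validation measures.  Motion
starts at mid-position (phase 0), configurable.

**Sampling.**  15 Hz sampling of a sinusoid underestimates the true
peak-to-peak by at most A·(1 − cos(π·Δt/T)) (both extremes combined,
Δt = 1/f); at the suite's fastest setting (T = 2 s) this is 0.11 mm of
a 20 mm motion.  The property suite asserts this bound for every
amplitude/period combination.

**Rendering.**  Each frame is a deterministic low-frequency cosine
background (level 30000, texture amplitude 500) plus seeded additive
Gaussian noise, minus an attenuation disk whose profile is the projected
chord length of a sphere (diameter 2 mm × M, peak deficit 12000),
blurred by a Gaussian system PSF (σ = 0.8 px).  Sub-pixel placement
uses 4× supersampling with box-averaging, keeping the rendered centroid
within 0.1 px of ground truth.  The default noise SD of 240 is 2% of
the disk contrast.  The texture amplitude is set to ~4% of the sphere
contrast: a lead sphere is far denser than any soft-tissue background
structure, and the texture's role is only to make correlation tracking
non-degenerate — a much stronger static texture would dominate the
feature window and bias a refreshed template toward the background.

**Irregular breathing.**  Patient-like vertical motion is a
concatenation of half-sine cycles with per-cycle (period, amplitude)
pairs, plus an optional cardiac-frequency ripple; a horizontal component
is a scaled copy delayed by a hysteresis phase (expressed against the
mean cycle period), producing the open inhale/exhale loop seen in some
tumors.  The default random trace draws periods from 1.6–4.2 s and
amplitudes up to 17.6 mm — the spread observed across the breathing
cycles of a free-breathing adult during a 20-s acquisition.

**What the generator does not emulate:** anatomy (ribs, diaphragm,
vessels), low-contrast ground-glass lesions, target deformation or
rotation, scatter, and detector lag.  Passing the validation suite
therefore demonstrates the correctness of the tracking and calibration
chain on a well-contrasted target, not clinical detectability —
low-contrast tumors that defeat radiographic tracking defeat this
tracker too.

## Tracker

Zero-normalized cross-correlation between a 25-px feature window and a
61-px search window centred on the last accepted position.  The search
span covers inter-frame steps up to ~18 px; the fastest suite motion
(40 mm, 2 s, 1.27×) peaks near 16 px/frame.  The NCC denominator uses
the template's and each patch's standard deviation; zero-variance
patches score 0 and a zero-variance template is an error.  The integer
peak (ties toward the smallest row/column) is refined per axis by the
vertex of the parabola through the peak and its two axial neighbours,
clamped to ±0.5 px.

Matches with peak NCC below 0.5 are flagged `low_confidence` with the
template frozen; five consecutive low-confidence frames (one third of a
second) mark the track `lost`.  The search window is clamped at image
borders (never wrapped) and a clamped frame is treated as low
confidence.  Template update defaults to `on_accept` (refresh from the
newly matched patch), which tolerates slow appearance change at the
cost of drift; `never`/`always` are available.  To avoid re-quantizing
the trajectory at each refresh, the sub-pixel offset between the
tracked point and the template's integer centre is carried as an anchor
and added to every subsequent match.

Re-seeding replaces the position at a chosen frame, captures a fresh
template there, and re-runs forward; earlier frames are untouched.

## Cycle segmentation

The calibrated vertical signal is segmented at troughs (local minima
with prominence ≥ 1 mm by default, which suppresses cardiac ripple); a
cycle spans consecutive troughs, its period the time between them and
its amplitude the max − min excursion within it.  An end sample also
counts as a trough when it lies near trough level (within
max(prominence, 10% of the excursion) of the deepest minimum), so a
recording that starts or ends at exhalation still bounds its first or
last cycle; cycles shallower than the prominence are discarded.  A
signal with fewer than two troughs yields no cycles.

## Statistics

Spearman's ρ is the Pearson correlation of average-ranked values; for
n ≤ 9 complete pairs the two-sided p is exact (proportion of all n!
permutations with |ρ| at least the observed), otherwise the
t-approximation with n − 2 df.  The Wilcoxon signed-rank test drops
zero differences (count reported), average-ranks |d|, takes
W = min(W⁺, W⁻), and for m ≤ 20 computes the exact two-sided p from
the full 2^m sign-assignment distribution (built by subset-sum counting
over doubled ranks, which are integers even under ties); beyond that a
normal approximation with continuity correction and the tie-exact
variance Σrᵢ²/4.  Quartiles use linear interpolation between order
statistics (R type 7 / numpy default).  Pairs with a missing member are
excluded and counted, never imputed — mirroring tumors measurable in
only one projection.

## Validation suite and problem sizes

The validation suite enumerates the 13 unique platform settings
(4 amplitudes at T = 4 s; periods 2/6 s; diagonals 30°/45°; two
parallelogram orbits; platform offsets 0/50/100/150 mm) and renders
each at 15 Hz for 20 s (300 frames) with three independent noise
realizations, seeded from one master seed.  Frames are rendered at
512 px rather than the detector's native 1062 px: the largest motion
spans ~130 px, so the smaller canvas holds every pattern with ample
margin while keeping the full suite to a few minutes on one CPU.
Tracking starts from the known frame-0 position with the default
configuration; each configured motion component is scored as
|measured − predetermined| in mm.  Typical results: overall mean error
≈ 0.05 mm, maximum ≈ 0.10 mm with noise; ≤ 0.08 mm noiseless.

## Numerical choices and edge cases

- NCC values are clamped to [−1, 1] against floating-point overshoot;
  equality with a brute-force Pearson loop is asserted to 1e−9.
- Quadratic refinement returns 0 at map borders or for a degenerate
  (zero-curvature) triple; a flat map yields the tie-break origin.
- 8-bit conversion uses one global window over the whole stack (per-
  frame windows would corrupt inter-frame correlation) with half-up
  rounding; a constant stack requires an explicit window.
- Trajectory CSVs store positions to 3 decimals (≈ 0.4 µm at native
  pitch), UTF-8, LF, "." decimal; writers are byte-deterministic.
- Exact-test thresholds (n ≤ 9 permutations, m ≤ 20 sign patterns)
  keep worst-case enumeration below a second.

## Known limitations

- Template-update drift: with `on_accept` the reference point is
  re-anchored at each refresh, so sub-pixel biases can accumulate on
  long sequences over strongly textured static backgrounds.
- The tracker assumes a translating, appearance-stable target; rotating
  or deforming targets degrade the correlation peak.
- Backward tracking from a mid-sequence seed is not implemented; frames
  before the seed are reported lost (seed in the first frame for full
  coverage).
- The breathing generator's hysteresis is a pure phase lag; real
  hysteresis can be asymmetric between inhale and exhale.
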