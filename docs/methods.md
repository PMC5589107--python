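# Methods

This note records the models, conventions and numerical choices behind
`interpmotion`, and what the synthetic data can and cannot say about real
scans.

## Coordinate and motion conventions

World coordinates are RAS millimetres with the origin at the spatial
center of the volume. Rotations are degrees, right-handed: pitch about +X
(nose up positive), roll about +Y (tilt right positive), yaw about +Z
(nose left positive). A rigid transform maps a material point `p` to
`R p + t` with `R = Rz(yaw) · Rx(pitch) · Ry(roll)`; packages in this
field disagree on rotation ordering and origin conventions, so one
ordering is fixed and stated rather than many supported. The motion-file
dialect is likewise fixed: six whitespace-delimited columns
`tx ty tz pitch roll yaw` (mm, degrees), one row per volume.

Framewise displacement at volume `t` is the sum of absolute backward
differences of the six parameters, rotations converted to arc length at a
50 mm head radius; FD = 0 at the first volume by convention, as is DVARS.
Censoring uses strict inequality (FD > threshold).

## The synthetic scan

**Phantom.** Concentric ellipsoids — background 0, CSF ring 500, gray
shell 1000, white core 700 (arbitrary units) — on a 32 × 32 × 16 grid of
3 mm voxels. Two departures from naive geometry matter:

- *Asymmetry.* The in-plane semi-axes differ (scales 0.80 / 1.00 / 0.95)
  and the white core sits off-center. A rotationally symmetric phantom
  leaves rotations invisible to intensity-based registration; heads are
  not symmetric either.
- *Texture.* A static Gaussian random field (σ = 1.2 voxels, RMS 80
  units, ~8 % of gray intensity) is added within tissue, standing in for
  gyral/sulcal structure. Without internal structure, only the few tissue
  boundaries constrain registration, and rotation estimates drown in BOLD
  noise; with it, the estimation noise floor drops to a realistic
  ~0.05–0.1 mm of FD.

A final 0.8-voxel blur gives tissue boundaries intermediate intensities,
as in real EPI. The label map (background/CSF/gray/white) stays crisp and
is carried as ground truth.

**Signal.** Per voxel: phantom intensity + latent components + linear
drift + AR(1) noise. Three latent timeseries (AR(1), φ = 0.5, unit
variance) load on spatially smooth maps restricted to tissue
(σ ≈ 6 % of the grid extent, RMS amplitude 3 units ≈ 0.3 % of gray).
The latent scale was chosen with registration in mind: spatially smooth
signal changes are partially absorbed by rigid-body parameters, and
amplitudes much above ~0.5 % give the desk-scale phantom an FD noise
floor far above what real scans show. Noise defaults: white σ = 10
(1 %), AR(1) φ = 0.3, drift slope SD 5 over the run.

**Motion.** Each subject receives a Poisson number (mean 6, floor 2) of
non-overlapping transient events over 150 volumes (TR 2.5 s, interleaved
'alt+z2'), plus 0.01 mm baseline jitter per volume. An event has a
trapezoidal time course: constant-velocity ramp up over 1 volume, hold
for 1 volume, ramp down over 1 volume — a brief nod spanning ~3 volumes,
the shape of typical transient head motions. The event amplitude is its
FD-equivalent displacement (|translations| + arc length of rotations),
drawn per subject from 0.5–2 mm and split across the six parameters by a
Dirichlet draw with random signs.

Injection is slice-wise: every acquired slice samples the continuously
positioned volume (cubic interpolation; nearest-neighbour available for
exact integer-shift tests) at that slice's acquisition time,
`t = volume_onset + rank · TR / n_slices`. Ramped and mid-volume events
therefore produce volumes whose slices come from different true
positions. Ground truth records both the per-slice positions and a
per-volume position defined as the position holding at the median
acquisition rank (the majority of the volume) — a volume acquired partly
at two positions has no single true position, and this convention makes
the per-volume truth the one a perfect volume-wise realigner should
report.

**Artifact.** Optionally, `gain × trueFD(t) × profile(x)` is added, with
`profile` = 0.5 · (uniform over tissue) + 0.5 · (Gaussian random field
with correlation length about a quarter of the grid extent, RMS 1 in
tissue). The uniform part inflates correlations at all distances; the
smooth field inflates nearby ROI pairs more than distant ones — the two
signatures of motion artifact in functional connectivity. The default
gain in artifact cohorts is 20 units per mm of FD (2 % signal change per
mm), a moderate artifact level; no attempt is made to match any real
cohort's artifact magnitude, only its qualitative distance structure.

**Cohorts.** Subject `i` of a cohort with seed `s` is generated with seed
`s + i`, so the canonical 20-subject cohort at seed 1 uses seeds 1–20.
All generators are bit-reproducible under a fixed seed.

## Despiking

Per voxel: a quadratic trend is fitted by iteratively reweighted least
squares (2 Huber reweights, k = 1.345, scale = √(π/2) · median
absolute residual). With σ the final robust scale, residual ratios
r = (y − fit)/σ are left alone when |r| ≤ c1 and otherwise replaced by
`fit + σ · sign(r) · (c1 + (c2 − c1) · tanh((|r| − c1)/(c2 − c1)))`,
with defaults c1 = 2.5, c2 = 4. The replacement is monotone in the spike
amplitude and capped at c2 σ. Constant-in-time voxels (σ = 0) are never
touched. The whole volume is despiked; the brain mask only scopes the
despike trace, defined as the percent of in-mask voxels whose value moved
by more than 1e-9 units at each volume. The robust-polynomial trend is
this package's own choice of trend family; it is simpler than the
polynomial + sinusoid bases some tools use and adequate at 150-volume
runs.

## Slice-time correction

Each slice's timeseries, nominally sampled at its acquisition offset τ
within the TR, is resampled at volume onsets (reference time zero). The
shift is a constant fraction τ/TR of one sample, so kernels act uniformly
along time: linear, Catmull–Rom cubic (default), or Fourier phase shift.
Polynomial kernels use clamped one-sided interpolation at run boundaries.
The Fourier method removes the line through the first and last samples,
phase-shifts the remainder exactly (energy-preserving by Parseval), and
restores the line evaluated at the shifted positions; the endpoint-based
trend is used rather than a least-squares line because it vanishes on
centered periodic signals (keeping the shift exact there) while still
removing the drift that causes FFT edge ringing. Quintic/heptic Lagrange
kernels are out of scope.

## Realignment

Each volume is registered to the reference (default: first retained
volume; middle and temporal-mean references available) by minimizing the
sum of squared intensity differences over the brain mask — the classical
least-squares cost for same-modality frames. Numerics:

- images presmoothed with a Gaussian of FWHM 1.5 voxels;
- Gauss–Newton with a finite-difference Jacobian (step 0.2 mm / 0.2°),
  refreshed sparingly (iterations 0, 3, 8, 15) since it changes slowly in
  the small-motion regime; backtracking line search (halving, 4 tries);
- the optimizer interpolates cubically at exactly the in-mask voxel
  positions, with spline coefficients precomputed once per volume; linear
  interpolation in the optimizer was found to bias rotation estimates;
- convergence when the parameter step norm (translations in voxels,
  rotations in degrees) falls below 1e-4; at most 25 iterations, with
  non-converged volumes kept at their best iterate and flagged in the
  log;
- successive volumes warm-start each other; no multi-resolution pyramid
  is used, so the documented capture range is ~3 voxels / 5°.

Output resampling (for the optional realigned image) uses cubic
interpolation by default. On noise-free phantoms the estimator recovers
injected between-volume motions to ~0.005 voxels / 0.005°; under the
default noise model the per-volume error is ~0.005 voxels RMS for
translations and ~0.06° RMS for rotations.

## Analyses

ROIs are a regular world-space grid of spheres (default radius 4 mm,
spacing 9 mm) wholly inside the brain mask — a synthetic analog of a
published whole-brain ROI set, which is out of scope. Edge tables hold
Pearson correlations per ROI pair over kept volumes, attached to the
Euclidean distance between centers; edges touching a constant timeseries
are flagged invalid rather than zeroed.

Scrubbing reports, per edge, the mean over subjects of
Δr = r_all − r_kept (positive = censoring lowers the correlation);
subjects retaining fewer than 3 volumes at a threshold are dropped and
listed. QC:RSFC reports, per edge, the across-subject correlation of
edge r with mean FD. Both are summarized by a centered moving mean over
2000 points sorted by distance (the window shrinks symmetrically at the
ends; a window ≥ n collapses to the global mean — the moving mean is
isolated behind one function so another smoother could be swapped in) and
by the OLS slope of the smoothed values on distance. The slope, reported
per mm, is this package's quantitative proxy for the visual slope of a
distance plot; distances span the phantom rather than a human head, which
is why slopes rather than raw curves are compared across processing
states.

## The missampling audit

For a mid-volume event, the onset volume's slices divide into pre- and
post-motion acquisition groups. Every tissue voxel is projected into
acquired-slice coordinates under each group's true position; it is
sampled by a group exactly when its nearest slice index belongs to that
group. Tissue sampled by neither group was never scanned; tissue sampled
by both was scanned twice. The audit events used in tests draw
through-plane translations of 0.8–1.8 slice thicknesses plus a 2–3°
pitch. Shifts near an even whole number of slices are excluded by that
range deliberately: at the slice lattice's resolution an interleave's
second pass then exactly retiles the displaced tissue and no voxel-level
missampling exists to detect — a degenerate alignment of the motion with
the sampling lattice, not a counterexample to the mechanism.

## Problem sizes used by the tests and the reproduction script

The default geometry (32 × 32 × 16 × 150, 20 subjects) keeps a full
four-state cohort study within minutes on one CPU. The scrubbing and
QC:RSFC checks use 6–12-subject cohorts of 100 volumes with artifact gain
20; parameter-recovery checks use 30 8-volume scans; the missampling
audit uses 50 seeded events on a static phantom. These sizes are the
package's chosen desk scale: large enough for the directional effects to
be stable across seeds, small enough to iterate on.

## What passing tests do and do not show

The generator reproduces the *mechanisms* — temporal interpolation
dampening motion-coupled intensity changes, despiking concentrating at
motion, missampling during mid-volume motion, and distance-dependent
artifact detection — under a controlled model with known truth. It does
not emulate cardiac/respiratory pseudo-motion, spin-history effects, B0
distortion, multi-echo acquisition, or any real cohort's artifact
magnitudes; quantitative results on this phantom (e.g. the ~25–30 % mean
FD reduction under DS+TS, which sits at the high end of the ~10–20 %
reductions typical of real cohorts, reflecting the phantom's sharp
boundaries and clean noise model) transfer to real data only in sign and
rough scale, not in precise magnitude.

## Known limitations

- Rigid-body truth is volume-wise by convention; for mid-volume events
  no single per-volume truth exists and the median-rank convention is
  one defensible choice among several.
- The brain-masking rule (mean image at 0.25 × the 98th percentile,
  largest component, hole-filled) is a stand-in adequate for phantoms,
  not a skull-stripper.
- The capture range of the single-resolution optimizer (~3 voxels / 5°)
  is smaller than pyramid-based tools; the injected regimes stay inside
  it.
- QC:RSFC stability across processing states is assessed at desk scale
  with 12 subjects; across-subject correlations at that n are noisy, and
  the slope comparison leans on the many-edge average.
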