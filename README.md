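# interpmotion

Head motion in fMRI is almost never measured — it is estimated, by rigidly
realigning each volume of the scan to a reference volume. Two common early
processing steps, voxel-signal **despiking** and **slice-time correction**,
interpolate each voxel's timeseries before realignment ever runs. Because
both steps replace signal at one timepoint partly with signal from
neighbouring timepoints, they dampen exactly the intensity changes that
motion leaves in the image — and the motion estimated afterwards shrinks.
Analyses that use those estimates to find motion artifact (scrubbing,
QC:RSFC) then under-detect artifact that is still in the data.

`interpmotion` implements that whole chain as a tested pipeline on
synthetic resting-state scans with *known* injected motion, for
methods-minded fMRI researchers who want to quantify the effect or stress
their own QC pipelines:

- **synthetic data** — ellipsoidal tissue phantoms with gyral-like texture,
  BOLD-like signal (latent components, AR(1) noise, drift), slice-by-slice
  rigid-motion injection with per-slice ground truth, and an optional
  motion-coupled, distance-dependent artifact;
- **temporal interpolation** — despiking (robust per-voxel trend, tanh
  spike squashing with thresholds c1 = 2.5, c2 = 4 robust-sigma) and
  slice-time correction to volume onset (linear / cubic / Fourier kernels),
  composable in the orders raw, DS, TS, DS+TS, TS+DS;
- **realignment** — 6-parameter rigid-body estimation by Gauss–Newton
  least squares on presmoothed images, cubic resampling;
- **quality control** — framewise displacement
  `FD(t) = Σ|Δd_i| + 50 mm · (π/180) · Σ|Δθ_j|`, DVARS, censor masks,
  matched-fraction thresholds, paired reduction summaries;
- **artifact detection** — ROI grids, edge correlation tables, scrubbing
  (Δr = r_all − r_censored vs inter-ROI distance) and QC:RSFC
  (across-subject correlation of each edge with mean FD vs distance), with
  2000-point smoothing curves and per-mm slope summaries.

## A worked example

```bash
python examples/02_interpolation_shrinks_motion.py
```

```
subject with 8 transient motions, amplitude scale 1.27 mm, true mean FD 0.183 mm

 state  mean FD (mm)    vs raw
   raw        0.2632      0.0%
    DS        0.2400      8.8%
    TS        0.2169     17.6%
 DS+TS        0.1993     24.3%

corr(raw FD, percent voxels despiked) = 0.66
```

The scan is the same in all four rows; only the processing applied before
motion estimation differs. Despiking alone lowers the reported mean FD by
~9 %, slice-time correction by ~18 %, and the combination by ~24 % — the
motion did not go away, the interpolation blurred it. The despike trace
(percent of in-mask voxels changed per volume) correlates at 0.66 with the
raw FD trace: despiking is, in effect, targeting times of motion, much
like a censoring strategy.

The other examples show parameter recovery against injected ground truth
(`01`), the scrubbing false negative — the same artifact produces a
scrubbing slope of −2.24 × 10⁻³/mm when volumes are censored by raw FD but
only −0.60 × 10⁻³/mm when censored by post-interpolation FD (`03`) — and
the slice-missampling audit for mid-volume motions (`04`).

A thin CLI mirrors the stages for shell use:

```bash
interpmotion simulate --subjects 4 --seed 1 --out cohort/
interpmotion preprocess --order DS+TS cohort/sub-000_bold.nii.gz dsts.nii.gz
interpmotion realign dsts.nii.gz dsts_motion.par
interpmotion qc cohort/sub-000_bold.nii.gz dsts_motion.par qc.csv
interpmotion analyze --threshold 0.2 --out analysis/ cohort/
```

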