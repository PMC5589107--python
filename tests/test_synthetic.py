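"""Generators: phantom, BOLD simulation, motion injection, artifact, cohorts."""

import numpy as np
import pytest
from scipy import stats

from interpmotion import (
    CohortSpec,
    MotionEvent,
    NoiseSpec,
    PhantomSpec,
    RigidTransform,
    inject_artifact,
    inject_motion,
    make_cohort,
    make_phantom,
    missampling_audit,
    random_events,
    simulate_bold,
)


class TestPhantom:
    def test_deterministic_under_seed(self):
        v1, l1 = make_phantom(PhantomSpec(seed=7))
        v2, l2 = make_phantom(PhantomSpec(seed=7))
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(l1, l2)

    def test_zero_blur_no_texture_gives_piecewise_constant_intensities(self):
        spec = PhantomSpec(blur_vox=0.0, texture_amp=0.0)
        volume, labels = make_phantom(spec)
        for lab, intensity in zip([0, 1, 2, 3], (0.0,) + spec.intensities):
            assert np.all(volume[labels == lab] == intensity)

    def test_tissue_occupies_reasonable_fraction(self, labels):
        frac = (labels > 0).mean()
        assert 0.2 <= frac <= 0.6

    def test_blurred_boundaries_are_intermediate(self):
        spec = PhantomSpec(texture_amp=0.0)
        volume, labels = make_phantom(spec)
        # voxels at the gray/background boundary get intermediate intensity
        from scipy import ndimage

        edge = (labels == 0) & ndimage.binary_dilation(labels == 1)
        assert np.all(volume[edge] > 0)
        assert np.all(volume[edge] < max(spec.intensities))

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_phantom(PhantomSpec(shape=(16, 16, 8), axis_scales=(2.0, 1.0, 1.0)))


class TestSimulateBold:
    def test_noise_free_series_repeats_phantom(self, phantom):
        scan = simulate_bold(
            phantom, 12, 2.5, noise=NoiseSpec(0.0, 0.0, 0.0),
            n_latents=0, latent_amp=0.0, seed=0,
        )
        for t in range(12):
            np.testing.assert_allclose(scan.data[..., t], phantom, atol=1e-3)

    def test_shared_latent_gives_unit_correlation(self, phantom):
        loadings = np.zeros((1,) + phantom.shape)
        loadings[0, 5, 5, 5] = 1.0
        loadings[0, 10, 10, 10] = 1.0
        scan = simulate_bold(
            phantom, 50, 2.5, noise=NoiseSpec(0.0, 0.0, 0.0),
            loadings=loadings, seed=0,
        )
        a = scan.data[5, 5, 5, :].astype(float)
        b = scan.data[10, 10, 10, :].astype(float)
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0, abs=1e-4)

    def test_sample_mean_tracks_phantom_within_standard_error(self, phantom):
        sigma = 10.0  # ~1 percent of gray-matter intensity
        scan = simulate_bold(
            phantom, 200, 2.5, noise=NoiseSpec(sigma, 0.0, 0.0),
            n_latents=0, latent_amp=0.0, seed=5,
        )
        mean_img = scan.data.mean(axis=3)
        dev = np.abs(mean_img - phantom)
        tol = 3.0 * sigma / np.sqrt(200)
        assert (dev <= tol).mean() > 0.99  # 3-sigma bound holds for ~all voxels

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(sigma=-1.0)


class TestInjectMotion:
    def test_empty_schedule_is_identity(self, static_scan):
        moved, gt = inject_motion(static_scan, [])
        np.testing.assert_array_equal(moved.data, static_scan.data)
        assert np.all(gt.volume_params == 0)
        assert np.all(gt.slice_params == 0)

    def test_between_volume_integer_shift_with_nearest_kernel(self, static_scan):
        ev = MotionEvent(
            onset_volume=5, displacement=RigidTransform(tx=3.0),  # one 3 mm voxel
            duration_volumes=1,
        )
        moved, gt = inject_motion(static_scan, [ev], kernel="nearest")
        expected = np.zeros_like(static_scan.data[..., 5])
        expected[1:, :, :] = static_scan.data[:-1, :, :, 5]
        np.testing.assert_allclose(moved.data[..., 5], expected, atol=1e-5)
        # untouched volumes stay untouched
        np.testing.assert_array_equal(moved.data[..., 4], static_scan.data[..., 4])
        assert gt.volume_params[5, 0] == pytest.approx(3.0)

    def test_in_brain_intensity_conserved_under_within_grid_motion(
        self, static_scan, labels
    ):
        ev = MotionEvent(
            onset_volume=5,
            displacement=RigidTransform(tx=2.0, ty=-1.5, yaw=2.0),
            duration_volumes=1,
        )
        moved, _ = inject_motion(static_scan, [ev])
        total_ref = static_scan.data[..., 4].sum()
        total_moved = moved.data[..., 5].sum()
        assert abs(total_moved - total_ref) / total_ref < 0.01

    def test_overlapping_events_rejected(self, static_scan):
        evs = [
            MotionEvent(5, RigidTransform(tx=1.0), duration_volumes=2),
            MotionEvent(6, RigidTransform(ty=1.0), duration_volumes=1),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            inject_motion(static_scan, evs)

    def test_event_outside_scan_rejected(self, static_scan):
        ev = MotionEvent(11, RigidTransform(tx=1.0), duration_volumes=3)
        with pytest.raises(ValueError, match="outside"):
            inject_motion(static_scan, [ev])

    def test_ramped_event_spreads_position_across_slices(self, static_scan):
        ev = MotionEvent(
            onset_volume=5, displacement=RigidTransform(tx=2.0),
            duration_volumes=1, ramp_volumes=1.0,
        )
        _, gt = inject_motion(static_scan, [ev])
        ramp_positions = gt.slice_params[5, :, 0]
        assert ramp_positions.min() >= 0.0
        assert ramp_positions.max() <= 2.0
        assert len(np.unique(ramp_positions)) > 4  # slices see distinct positions

    def test_per_volume_equals_per_slice_without_midvolume_event(self, static_scan):
        ev = MotionEvent(5, RigidTransform(tx=1.0, pitch=1.0), duration_volumes=2)
        _, gt = inject_motion(static_scan, [ev])
        for t in range(static_scan.n_volumes):
            for z in range(static_scan.n_slices):
                np.testing.assert_allclose(
                    gt.slice_params[t, z], gt.volume_params[t], atol=1e-12
                )


class TestMissamplingAudit:
    def test_midvolume_through_plane_event_misses_and_duplicates(
        self, static_scan, labels
    ):
        ev = MotionEvent(
            onset_volume=5, displacement=RigidTransform(tz=4.2, pitch=2.5),
            duration_volumes=2, onset_slice_acq=8,
        )
        _, gt = inject_motion(static_scan, [ev], labels=labels)
        missing, duplicated = missampling_audit(gt, ev)
        assert len(missing) > 0
        assert len(duplicated) > 0

    def test_audit_requires_midvolume_event(self, static_scan, labels):
        ev = MotionEvent(5, RigidTransform(tz=4.0), duration_volumes=1)
        _, gt = inject_motion(static_scan, [ev], labels=labels)
        with pytest.raises(ValueError, match="mid-volume"):
            missampling_audit(gt, ev)


class TestInjectArtifact:
    def test_zero_gain_is_identity(self, static_scan, labels):
        ev = MotionEvent(5, RigidTransform(tx=1.0))
        moved, gt = inject_motion(static_scan, [ev], labels=labels)
        out = inject_artifact(moved, gt, gain=0.0)
        np.testing.assert_array_equal(out.data, moved.data)

    def test_motionless_subject_unchanged(self, static_scan, labels):
        _, gt = inject_motion(static_scan, [], labels=labels)
        out = inject_artifact(static_scan, gt, gain=50.0, seed=3)
        np.testing.assert_allclose(out.data, static_scan.data, atol=1e-4)

    def test_artifact_scales_with_true_fd(self, static_scan, labels):
        ev = MotionEvent(5, RigidTransform(tx=1.0), duration_volumes=1)
        moved, gt = inject_motion(static_scan, [ev], labels=labels)
        out = inject_artifact(moved, gt, gain=20.0, seed=3)
        fd = gt.true_fd().fd
        delta = np.abs(out.data.astype(float) - moved.data.astype(float))
        per_vol = delta[labels > 0].mean(axis=0)
        assert per_vol[fd > 0].min() > 0
        assert np.all(per_vol[fd == 0] < 1e-6)


class TestCohort:
    def test_reproducible_under_seed(self):
        spec = CohortSpec(n_subjects=2, n_volumes=40, seed=9)
        (s1, g1), _ = make_cohort(spec)[0][0], None
        (s2, g2), _ = make_cohort(spec)[0][0], None
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(g1.volume_params, g2.volume_params)

    def test_still_regime_has_zero_true_fd(self):
        spec = CohortSpec(n_subjects=2, n_volumes=40, regime="still", seed=9)
        subjects, manifest = make_cohort(spec)
        for _, gt in subjects:
            assert np.all(gt.true_fd().fd == 0)
        assert np.all(manifest["true_mean_fd"] == 0)

    def test_mean_fd_tracks_assigned_amplitude(self):
        # amplitude spans the requested range and drives true mean FD
        spec = CohortSpec(
            n_subjects=20, n_volumes=150, amplitude_range=(0.2, 2.0), seed=1
        )
        _, manifest = make_cohort(spec)
        rho = stats.spearmanr(
            manifest["amplitude_mm"], manifest["true_mean_fd"]
        ).statistic
        assert rho > 0.8

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            CohortSpec(n_subjects=1)


class TestRandomEvents:
    def test_events_respect_amplitude_and_spacing(self, rng):
        events = random_events(rng, 150, 6, amplitude_mm=1.0, ramp_volumes=1.0)
        onsets = [e.onset_volume for e in events]
        assert len(events) == 6
        assert min(np.diff(sorted(onsets))) >= 4
        from interpmotion import ARC_MM_PER_DEG

        for ev in events:
            p = ev.displacement.params
            amp = np.abs(p[:3]).sum() + ARC_MM_PER_DEG * np.abs(p[3:]).sum()
            assert 0.8 <= amp <= 1.2
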