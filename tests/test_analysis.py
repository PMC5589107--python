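"""ROI grids, edge correlations, smoothing curves, scrubbing and QC:RSFC."""

import numpy as np
import pytest

from interpmotion import (
    FDTrace,
    Mask,
    ROISet,
    Scan,
    distance_smooth,
    edge_correlations,
    extract_roi_timeseries,
    make_roi_grid,
    qcrsfc_analysis,
    scrubbing_analysis,
)


@pytest.fixture(scope="module")
def full_mask():
    return Mask(np.ones((20, 20, 10), bool))


@pytest.fixture(scope="module")
def grid_rois(full_mask):
    return make_roi_grid(full_mask, spacing_mm=9.0, radius_mm=4.0, voxel_mm=(3, 3, 3))


class TestRoiGrid:
    def test_spacing_must_exceed_diameter(self, full_mask):
        with pytest.raises(ValueError, match="spacing"):
            make_roi_grid(full_mask, spacing_mm=8.0, radius_mm=4.0)

    def test_all_pairwise_distances_at_least_spacing(self, grid_rois):
        assert grid_rois.distances().min() >= 9.0 - 1e-9

    def test_phantom_mask_holds_many_rois(self, phantom, labels):
        scan = Scan(
            np.repeat(phantom[..., None], 4, axis=3), tr_s=2.0, n_ignore=0
        )
        from interpmotion import compute_brain_mask

        rois = make_roi_grid(
            compute_brain_mask(scan), spacing_mm=9.0, radius_mm=4.0, voxel_mm=(3, 3, 3)
        )
        assert len(rois) >= 20

    def test_no_fit_raises(self):
        mask = Mask(np.zeros((8, 8, 8), bool))
        with pytest.raises(ValueError, match="no ROI"):
            make_roi_grid(mask, spacing_mm=20.0, radius_mm=4.0)

    def test_spheres_lie_wholly_inside_mask(self, phantom):
        from interpmotion import compute_brain_mask

        scan = Scan(np.repeat(phantom[..., None], 4, axis=3), tr_s=2.0, n_ignore=0)
        mask = compute_brain_mask(scan)
        rois = make_roi_grid(mask, 9.0, 4.0, (3, 3, 3))
        center = (np.array(mask.grid.shape) - 1) / 2
        for c in rois.centers:
            idx = np.round(c / 3.0 + center).astype(int)
            assert mask.grid[tuple(idx)]


class TestExtractTimeseries:
    def test_single_voxel_roi_returns_that_series(self, rng):
        data = rng.normal(size=(9, 9, 5, 12)).astype(np.float32)
        scan = Scan(data, tr_s=2.0, n_ignore=0)
        rois = ROISet(np.array([[0.0, 0.0, 0.0]]), radius_mm=1.0)
        ts = extract_roi_timeseries(scan, rois)
        np.testing.assert_allclose(ts[:, 0], data[4, 4, 2, :], atol=1e-6)

    def test_constant_scan_gives_constant_series(self, grid_rois):
        scan = Scan(np.full((20, 20, 10, 6), 3.0, np.float32), tr_s=2.0, n_ignore=0)
        ts = extract_roi_timeseries(scan, grid_rois)
        assert np.allclose(ts, 3.0)

    def test_matches_brute_force_membership_loop(self, rng, grid_rois):
        data = rng.normal(size=(20, 20, 10, 8))
        scan = Scan(data, tr_s=2.0, n_ignore=0)
        ts = extract_roi_timeseries(scan, grid_rois)
        center = (np.array([20, 20, 10]) - 1) / 2
        for r, c in enumerate(grid_rois.centers):
            vals = []
            for i in range(20):
                for j in range(20):
                    for k in range(10):
                        w = (np.array([i, j, k]) - center) * 3.0
                        if np.sum((w - c) ** 2) <= 4.0**2:
                            vals.append(data[i, j, k, :])
            np.testing.assert_allclose(ts[:, r], np.mean(vals, axis=0), atol=1e-10)


class TestEdgeCorrelations:
    def rois_for(self, n):
        centers = np.zeros((n, 3))
        centers[:, 0] = np.arange(n) * 10.0
        return ROISet(centers, radius_mm=4.0)

    def test_identical_series_correlate_at_one(self, rng):
        s = rng.normal(size=20)
        ts = np.stack([s, s], axis=1)
        table = edge_correlations(ts, self.rois_for(2))
        assert table["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_series_correlate_at_minus_one(self, rng):
        s = rng.normal(size=20)
        table = edge_correlations(np.stack([s, -s], 1), self.rois_for(2))
        assert table["r"].iloc[0] == pytest.approx(-1.0)

    def test_constant_series_flagged_not_zeroed(self, rng):
        ts = np.stack([rng.normal(size=20), np.full(20, 5.0)], 1)
        table = edge_correlations(ts, self.rois_for(2))
        assert not table["valid"].iloc[0]
        assert np.isnan(table["r"].iloc[0])

    def test_censoring_removes_shared_artifact_correlation(self, rng):
        # a large common additive burst at two volumes inflates r; censoring
        # exactly those volumes removes the inflation
        n, T = 2, 60
        base = rng.normal(size=(T, n))
        burst = np.zeros(T)
        burst[[20, 40]] = 10.0
        ts = base + burst[:, None]
        rois = self.rois_for(n)
        r_all = edge_correlations(ts, rois)["r"].iloc[0]
        kept = burst == 0
        r_kept = edge_correlations(ts, rois, kept=kept)["r"].iloc[0]
        assert r_all > r_kept

    def test_too_few_kept_volumes_rejected(self, rng):
        ts = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="3 kept"):
            edge_correlations(ts, self.rois_for(3), kept=np.arange(10) < 2)


class TestDistanceSmooth:
    def test_constant_values_give_constant_curve(self, rng):
        d = rng.uniform(0, 100, 500)
        curve = distance_smooth(d, np.full(500, 2.5), window=101)
        assert np.allclose(curve.value, 2.5)

    def test_window_at_least_n_collapses_to_global_mean(self, rng):
        d = rng.uniform(0, 100, 50)
        v = rng.normal(size=50)
        curve = distance_smooth(d, v, window=2000)
        assert np.allclose(curve.value, v.mean())

    def test_linear_trend_tracked_within_window_span(self, rng):
        d = np.sort(rng.uniform(0, 100, 2000))
        a = 0.03
        curve = distance_smooth(d, a * d, window=200)
        # moving-average bias is bounded by the local window span
        interior = slice(150, -150)
        span = np.ptp(d) * (200 / 2000)
        assert np.all(np.abs(curve.value[interior] - a * curve.distance[interior])
                      <= a * span)

    def test_output_sorted_by_distance(self, rng):
        d = rng.uniform(0, 100, 300)
        curve = distance_smooth(d, rng.normal(size=300), window=50)
        assert np.all(np.diff(curve.distance) >= 0)


class TestScrubbing:
    def build_cohort(self, rng, n_subj=4, n_roi=6, T=60):
        centers = np.zeros((n_roi, 3))
        centers[:, 0] = np.arange(n_roi) * 10.0
        rois = ROISet(centers, radius_mm=4.0)
        ts_list, fd_list = [], []
        for s in range(n_subj):
            ts = rng.normal(size=(T, n_roi))
            fd = np.abs(rng.normal(0.2, 0.1, T))
            fd[0] = 0.0
            ts_list.append(ts)
            fd_list.append(FDTrace(fd))
        return ts_list, fd_list, rois

    def test_threshold_above_all_fd_gives_exact_zero(self, rng):
        ts_list, fd_list, rois = self.build_cohort(rng)
        res = scrubbing_analysis(ts_list, fd_list, rois, threshold_mm=10.0)
        assert np.all(res.delta_r == 0)
        assert res.slope == 0.0

    def test_subject_permutation_changes_nothing(self, rng):
        ts_list, fd_list, rois = self.build_cohort(rng)
        res1 = scrubbing_analysis(ts_list, fd_list, rois, 0.25)
        perm = [2, 0, 3, 1]
        res2 = scrubbing_analysis(
            [ts_list[i] for i in perm], [fd_list[i] for i in perm], rois, 0.25
        )
        np.testing.assert_allclose(res1.delta_r, res2.delta_r, atol=1e-12)
        assert res1.slope == pytest.approx(res2.slope, abs=1e-12)

    def test_subjects_with_too_few_kept_volumes_are_excluded(self, rng):
        ts_list, fd_list, rois = self.build_cohort(rng)
        fd_list[1] = FDTrace(np.full(60, 5.0))  # censored everywhere
        res = scrubbing_analysis(ts_list, fd_list, rois, 0.25)
        assert res.excluded_subjects == [1]
        assert res.n_subjects_used == 3

    def test_no_usable_subject_rejected(self, rng):
        ts_list, fd_list, rois = self.build_cohort(rng, n_subj=2)
        bad = [FDTrace(np.full(60, 5.0))] * 2
        with pytest.raises(ValueError, match="no subject"):
            scrubbing_analysis(ts_list, bad, rois, 0.25)


class TestQCRSFC:
    def rois_for(self, n):
        centers = np.zeros((n, 3))
        centers[:, 0] = np.arange(n) * 10.0
        return ROISet(centers, radius_mm=4.0)

    def test_edge_proportional_to_mean_fd_gives_unit_correlation(self):
        rois = self.rois_for(3)
        mean_fd = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        edge_r = np.stack([0.5 * mean_fd, -0.2 * mean_fd, 0.1 + 0.3 * mean_fd], 1)
        res = qcrsfc_analysis(edge_r, mean_fd, rois)
        np.testing.assert_allclose(res.qc_rsfc, [1.0, -1.0, 1.0], atol=1e-12)

    def test_constant_qc_vector_rejected(self, rng):
        rois = self.rois_for(3)
        edge_r = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="constant QC"):
            qcrsfc_analysis(edge_r, np.full(5, 0.2), rois)

    def test_too_few_subjects_rejected(self, rng):
        rois = self.rois_for(3)
        with pytest.raises(ValueError, match="4 subjects"):
            qcrsfc_analysis(rng.normal(size=(3, 3)), [0.1, 0.2, 0.3], rois)
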