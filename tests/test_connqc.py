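"""Seed maps, FC matrices, similarity, QC-FC and the threshold sweep."""

import numpy as np
import pytest
from scipy import stats

from restqc.connqc import (
    FCMatrix,
    SeedSpec,
    fc_matrix,
    fc_similarity,
    group_mean_fc,
    qcfc,
    seed_map,
)
from restqc.phantom import PhantomSpec, simulate_cohort, simulate_subject
from restqc.volio import BrainMask, Volume4D, VolumeGrid


def fcm(values, fisher_z=True):
    values = np.asarray(values, dtype=float)
    return FCMatrix(values=values, region_ids=list(range(1, len(values) + 1)), fisher_z=fisher_z)


def random_z_matrix(rng, n=6):
    a = rng.normal(scale=0.4, size=(n, n))
    z = (a + a.T) / 2
    np.fill_diagonal(z, 0.0)
    return fcm(z)


class TestSeedMap:
    def test_sphere_membership_seven_voxels(self):
        # a 4 mm radius sphere centered on a voxel of a 3 mm grid contains
        # the center and its six face neighbors
        g = VolumeGrid(dims=(9, 9, 9), affine=np.diag([3.0, 3, 3, 1]))
        center_world = g.world_coords([[4, 4, 4]])[0]
        rng = np.random.default_rng(0)
        vol = Volume4D(grid=g, values=rng.normal(size=(9, 9, 9, 10)))
        mask = BrainMask(grid=g, member=np.ones((9, 9, 9), bool))
        seed = SeedSpec("test", tuple(center_world), 4.0)
        ijk = np.indices(g.dims).reshape(3, -1).T
        world = g.world_coords(ijk)
        n_in = (np.linalg.norm(world - center_world, axis=1) <= 4.0).sum()
        assert n_in == 7
        r_map = seed_map(vol, mask, seed)
        assert np.isfinite(r_map[mask.member]).all()

    def test_noiseless_network_map(self):
        spec = PhantomSpec(thermal_sigma=0.0, region_signal_amp=0.0, seed=3)
        sub = simulate_subject(spec)
        labels = sub.truth["network_labels"]
        target = 1
        vox = np.argwhere(labels == target)
        center = sub.volume.grid.world_coords(vox[len(vox) // 2][None, :])[0]
        r_map = seed_map(sub.volume, sub.brain_mask, SeedSpec("net", tuple(center), 3.1))
        in_net = r_map[labels == target]
        np.testing.assert_allclose(in_net, 1.0, atol=1e-6)
        other = r_map[(labels != target) & (labels > 0)]
        assert np.nanmax(np.abs(other)) < 0.9

    def test_seed_outside_mask_rejected(self, small_grid, noise_volume, cube_mask):
        far = SeedSpec("far", (500.0, 500.0, 500.0), 4.0)
        with pytest.raises(ValueError, match="does not intersect"):
            seed_map(noise_volume, cube_mask, far)


class TestFcMatrix:
    def test_matches_per_pair_pearson(self, rng):
        series = rng.normal(size=(30, 4))
        m = fc_matrix(series)
        for i in range(4):
            for j in range(4):
                expected = stats.pearsonr(series[:, i], series[:, j])[0]
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_shared_timecourse_and_fisher(self, rng):
        tc = rng.normal(size=30)
        series = np.column_stack([tc, tc + 0.0, rng.normal(size=30)])
        m = fc_matrix(series, fisher_z=True)
        assert np.isfinite(m.values[0, 1])
        assert m.values[0, 1] > 8.0  # atanh of the clipped r=1

    def test_orthogonal_series_zero(self):
        t = np.arange(32)
        series = np.column_stack([np.sin(2 * np.pi * t / 32), np.cos(2 * np.pi * t / 32)])
        m = fc_matrix(series, fisher_z=True)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_region_reported(self, rng):
        series = rng.normal(size=(20, 3))
        series[:, 1] = 7.0
        m = fc_matrix(series)
        assert m.undefined_regions == [2]
        assert np.isnan(m.values[0, 1])
        assert np.isfinite(m.values[0, 2])

    def test_recovers_truth_fc_from_phantom(self):
        spec = PhantomSpec(n_timepoints=300, thermal_sigma=0.3, region_signal_amp=0.0, seed=8)
        sub = simulate_subject(spec)
        labels = sub.truth["network_labels"]
        tcs = sub.truth["network_timecourses"]
        T = spec.n_timepoints
        flat = sub.volume.values.reshape(-1, T)
        roi = np.column_stack(
            [flat[(labels == n + 1).ravel()].mean(axis=0) for n in range(spec.n_networks)]
        )
        est = fc_matrix(roi)
        truth = np.corrcoef(tcs, rowvar=False)
        assert np.max(np.abs(est.values - truth)) < 0.15

    def test_retained_rows_only(self, rng):
        series = rng.normal(size=(40, 3))
        keep = np.ones(40, bool)
        keep[10:20] = False
        m = fc_matrix(series, retained=keep)
        direct = np.corrcoef(series[keep], rowvar=False)
        np.testing.assert_allclose(m.values, direct, atol=1e-12)


class TestGroupMeanAndSimilarity:
    def test_identical_matrices_mean_is_each(self, rng):
        m = random_z_matrix(rng)
        g = group_mean_fc([m, m, m])
        np.testing.assert_allclose(g.values, m.values, atol=1e-12)

    def test_opposite_edges_cancel(self, rng):
        m = random_z_matrix(rng)
        neg = fcm(-m.values)
        g = group_mean_fc([m, neg])
        np.testing.assert_allclose(g.values, 0.0, atol=1e-12)

    def test_subject_equal_to_group(self, rng):
        m = random_z_matrix(rng)
        s = fc_similarity(m, m)
        assert s.pearson == pytest.approx(1.0)
        assert s.euclidean_dissimilarity == 0.0

    def test_constant_offset_closed_form(self, rng):
        m = random_z_matrix(rng)
        offset = 0.25
        shifted = fcm(m.values + offset - np.diag([offset] * m.n_regions))
        s = fc_similarity(shifted, m)
        n_edges = m.n_regions * (m.n_regions - 1) // 2
        assert s.pearson == pytest.approx(1.0)
        assert s.euclidean_dissimilarity == pytest.approx(offset * np.sqrt(n_edges))

    def test_noise_degrades_similarity_monotonically(self, rng):
        m = random_z_matrix(rng, n=12)
        sims, dissims = [], []
        for sd in (0.05, 0.2, 0.8):
            noise = rng.normal(scale=sd, size=m.values.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            s = fc_similarity(fcm(m.values + noise), m)
            sims.append(s.pearson)
            dissims.append(s.euclidean_dissimilarity)
        assert sims[0] > sims[1] > sims[2]
        assert dissims[0] < dissims[1] < dissims[2]

    def test_leave_one_out_insensitive_at_cohort_size(self, rng):
        mats = [random_z_matrix(rng, n=10) for _ in range(40)]
        include_all = group_mean_fc(mats)
        sims_all = [fc_similarity(m, include_all).pearson for m in mats]
        sims_loo = [
            fc_similarity(m, group_mean_fc(mats, leave_out=i)).pearson
            for i, m in enumerate(mats)
        ]
        r = np.corrcoef(sims_all, sims_loo)[0, 1]
        assert r > 0.99

    def test_fewer_than_two_rejected(self, rng):
        with pytest.raises(ValueError):
            group_mean_fc([random_z_matrix(rng)])


class TestFisherTransform:
    def test_odd_and_order_preserving(self):
        r = np.array([[1, -0.5, 0.5], [-0.5, 1, 0.2], [0.5, 0.2, 1]])
        m = FCMatrix(values=r, region_ids=[1, 2, 3], fisher_z=False)
        z = m.to_fisher_z()
        assert z.values[0, 1] == pytest.approx(-z.values[0, 2])
        assert z.values[0, 2] > z.values[1, 2]


class TestQcFc:
    def test_two_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            qcfc([random_z_matrix(rng)] * 2, [0.1, 0.2])

    def test_constant_enorm_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            qcfc([random_z_matrix(rng) for _ in range(4)], [0.1] * 4)

    def test_invariant_to_enorm_offset(self, rng):
        mats = [random_z_matrix(rng) for _ in range(10)]
        en = rng.uniform(0.02, 0.3, size=10)
        a = qcfc(mats, en)
        b = qcfc(mats, en + 5.0)
        np.testing.assert_allclose(a.edge_r, b.edge_r, atol=1e-12)

    def test_histogram_counts_sum_to_edges(self, rng):
        mats = [random_z_matrix(rng, n=8) for _ in range(10)]
        q = qcfc(mats, rng.uniform(0.02, 0.3, size=10))
        n_edges = 8 * 7 // 2
        assert q.hist_counts.sum() == n_edges - q.n_excluded_edges
        assert len(q.hist_edges) == 102  # 101 bins on [-1, 1]

    def test_ci_contains_point_estimate(self, rng):
        mats = [random_z_matrix(rng, n=8) for _ in range(12)]
        cents = rng.normal(scale=40, size=(8, 3))
        q = qcfc(mats, rng.uniform(0.02, 0.3, size=12), cents)
        lo, hi = q.distance_ci95
        assert lo <= q.distance_dependence_r <= hi

    def test_coupled_edges_detected(self):
        # inject motion-coupled FC at network edge (0, 3) and verify those
        # region edges' QC-FC values sit in the extreme upper tail
        bundles, _ = simulate_cohort(
            40, qcfc_coupling={"edges": [(0, 3)], "slope": 3.0}, seed=21
        )
        from restqc.connqc import subject_cell

        cells = [subject_cell(b, 0.4, (0.01, 0.1), 2, True) for b in bundles]
        mats = [c["fc"] for c in cells]
        en = np.array([c["mean_enorm"] for c in cells])
        q = qcfc(mats, en, bundles[0].parcellation.centroids_mm())
        rpn = bundles[0].truth["spec"]["regions_per_network"]
        R = bundles[0].parcellation.n_regions
        iu = np.triu_indices(R, k=1)
        coupled = np.array(
            [
                {a // rpn, b // rpn} == {0, 3}
                for a, b in zip(iu[0], iu[1])
            ]
        )
        assert np.nanmean(q.edge_r[coupled]) > np.nanpercentile(q.edge_r[~coupled], 95)

    def test_slope_recovered_from_coupled_cohort(self):
        # regressing the coupled edge's true z on mean Enorm recovers the
        # injected mixing slope within 2 standard errors (small-alpha regime)
        slope = 1.5
        bundles, _ = simulate_cohort(
            40,
            motion_levels=np.linspace(0.02, 0.2, 40),
            qcfc_coupling={"edges": [(0, 3)], "slope": slope},
            seed=13,
        )
        z = np.array([np.arctanh(b.truth["true_fc"][0, 3]) for b in bundles])
        en = np.array([b.truth["spec"]["motion_mean_enorm_mm"] for b in bundles])
        fit = stats.linregress(en, z)
        assert abs(fit.slope - slope) < 2 * fit.stderr + 0.2 * slope


class TestThresholdSweep:
    def test_median_dof_increases_with_threshold(self, mechanism_cohort):
        from restqc.connqc import threshold_sweep

        bundles, _ = mechanism_cohort
        rows, summ = threshold_sweep(bundles[:12], [0.2, 0.4, 1.0], [(0.01, 0.1)])
        med = summ.sort_values("threshold_mm")["median_dof"].to_numpy()
        assert med[0] <= med[1] <= med[2]
        assert med[2] > med[0]

    def test_removing_bandpass_adds_stopband_dof(self, mechanism_cohort):
        from restqc.connqc import threshold_sweep

        bundles, _ = mechanism_cohort
        rows, _ = threshold_sweep(bundles[:4], [0.4], [(0.01, 0.1), None])
        bp = rows[rows.band != "none"].set_index("subject")["dof"]
        nb = rows[rows.band == "none"].set_index("subject")["dof"]
        # every subject gains exactly the number of independent stop-band
        # columns on its retained rows; at minimal censoring this is large
        assert (nb - bp > 0).all()
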