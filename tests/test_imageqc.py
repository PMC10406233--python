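"""TSNR, smoothness estimation, blur-to-target, Dice, FCS, and flip checks."""

import numpy as np
import pytest
from scipy import ndimage

from restqc.imageqc import (
    GAUSS_FWHM_PER_SIGMA,
    blur_to_fwhm,
    check_lr_flip,
    dice,
    estimate_fwhm,
    fcs,
    tsnr,
)
from restqc.volio import BrainMask, Volume4D, VolumeGrid


def grid(dims, vox=3.0):
    return VolumeGrid(dims=dims, affine=np.diag([vox, vox, vox, 1.0]))


def full_mask(g):
    return BrainMask(grid=g, member=np.ones(g.dims, dtype=bool))


class TestTsnr:
    def test_known_mean_over_std(self, small_grid, cube_mask, rng):
        # every voxel gets the same series with mean 100 and sd 10
        base = rng.normal(size=50)
        series = 100.0 + 10.0 * (base - base.mean()) / base.std(ddof=1)
        data = np.broadcast_to(series, small_grid.dims + (50,)).copy()
        res = tsnr(Volume4D(grid=small_grid, values=data), cube_mask)
        assert res.mean_in_mask == pytest.approx(10.0, rel=1e-9)

    def test_constant_voxel_undefined(self, small_grid, cube_mask, rng):
        data = rng.normal(100, 5, size=small_grid.dims + (20,))
        data[0, 0, 0, :] = 42.0
        res = tsnr(Volume4D(grid=small_grid, values=data), cube_mask)
        assert res.n_undefined == 1
        assert np.isnan(res.map[0, 0, 0])

    def test_scale_invariance(self, noise_volume, cube_mask):
        a = tsnr(noise_volume, cube_mask)
        doubled = Volume4D(grid=noise_volume.grid, values=noise_volume.values * 3.7)
        b = tsnr(doubled, cube_mask)
        assert b.mean_in_mask == pytest.approx(a.mean_in_mask, rel=1e-12)

    def test_doubled_noise_halves_tsnr(self):
        from restqc.phantom import PhantomSpec, simulate_subject

        lo = simulate_subject(PhantomSpec(thermal_sigma=0.5, seed=3))
        hi = simulate_subject(PhantomSpec(thermal_sigma=1.0, seed=3))
        r_lo = tsnr(lo.volume, lo.brain_mask).mean_in_mask
        r_hi = tsnr(hi.volume, hi.brain_mask).mean_in_mask
        assert 0.4 <= r_hi / r_lo <= 0.6

    def test_single_timepoint_rejected(self, small_grid, cube_mask):
        vol = Volume4D(grid=small_grid, values=np.zeros(small_grid.dims + (1,)))
        with pytest.raises(ValueError):
            tsnr(vol, cube_mask)


class TestFwhm:
    def test_known_gaussian_blur_recovered(self):
        # white noise blurred with an 8 mm kernel has a Gaussian spatial ACF
        # whose width the first-difference estimator must recover
        g = grid((64, 64, 64), vox=3.0)
        rng = np.random.default_rng(42)
        sigma_vox = 8.0 / GAUSS_FWHM_PER_SIGMA / 3.0
        data = ndimage.gaussian_filter(rng.normal(size=g.dims), sigma_vox)
        res = estimate_fwhm(data, full_mask(g), detrend=False)
        assert res.combined_mm == pytest.approx(8.0, rel=0.10)
        for f in res.fwhm_mm:
            assert f == pytest.approx(8.0, rel=0.10)

    def test_white_noise_measured_rough(self):
        # spatially independent voxels: the Gaussian-ACF estimate collapses
        # toward zero (the field is as rough as the estimator can express)
        g = grid((48, 48, 48), vox=3.0)
        rng = np.random.default_rng(7)
        res = estimate_fwhm(rng.normal(size=g.dims), full_mask(g), detrend=False)
        assert res.combined_mm < 3.0

    def test_matches_direct_autocorrelation_fit(self):
        # independent oracle: fit the Gaussian ACF to empirical lag-1..3
        # correlations by least squares and compare widths
        g = grid((96, 96, 32), vox=3.0)
        rng = np.random.default_rng(3)
        sigma_vox = 6.0 / GAUSS_FWHM_PER_SIGMA / 3.0
        data = ndimage.gaussian_filter(rng.normal(size=g.dims), (sigma_vox, sigma_vox, sigma_vox))
        res = estimate_fwhm(data, full_mask(g), detrend=False)

        x = data - data.mean()
        var = x.var()
        lags = np.arange(1, 4)
        acf = np.array([np.mean(x[s:, :, :] * x[:-s, :, :]) / var for s in lags])
        # ACF model exp(-d^2/(4 sigma_b^2)) => linear fit of -log(acf) on d^2
        coef = np.sum(-np.log(acf) * lags**2) / np.sum(lags**4)
        sigma_fit_vox = np.sqrt(1.0 / (4.0 * coef))
        fwhm_fit = sigma_fit_vox * GAUSS_FWHM_PER_SIGMA * 3.0
        assert res.fwhm_mm[0] == pytest.approx(fwhm_fit, rel=0.05)

    def test_uniform_image_rejected(self, small_grid, cube_mask):
        with pytest.raises(ValueError, match="variance"):
            estimate_fwhm(np.ones(small_grid.dims), cube_mask, detrend=False)


class TestBlurToFwhm:
    def make_noise(self, dims=(48, 48, 48), vox=3.0, seed=0):
        g = grid(dims, vox)
        rng = np.random.default_rng(seed)
        return Volume4D(grid=g, values=rng.normal(size=dims + (1,))), full_mask(g)

    def test_converges_to_8mm(self):
        vol, mask = self.make_noise()
        out = blur_to_fwhm(vol, mask, target_mm=8.0, tol_frac=0.05)
        final = estimate_fwhm(out, mask, detrend=False).combined_mm
        assert 7.6 <= final <= 8.4

    def test_already_at_target_unchanged(self):
        vol, mask = self.make_noise()
        pre = blur_to_fwhm(vol, mask, target_mm=8.0)
        est = estimate_fwhm(pre, mask, detrend=False).combined_mm
        out = blur_to_fwhm(pre, mask, target_mm=est, tol_frac=0.05)
        np.testing.assert_array_equal(out.values, pre.values)

    def test_estimate_increases_monotonically(self):
        vol, mask = self.make_noise(seed=5)
        ests = [estimate_fwhm(vol, mask, detrend=False).combined_mm]
        data = vol
        for target in (5.0, 8.0, 11.0):
            data = blur_to_fwhm(data, mask, target_mm=target)
            ests.append(estimate_fwhm(data, mask, detrend=False).combined_mm)
        assert all(b > a for a, b in zip(ests, ests[1:]))

    def test_target_below_current_refused(self):
        vol, mask = self.make_noise(seed=2)
        blurred = blur_to_fwhm(vol, mask, target_mm=9.0)
        with pytest.raises(ValueError, match="smoother"):
            blur_to_fwhm(blurred, mask, target_mm=4.0)


class TestDice:
    def make(self, g, coords):
        m = np.zeros(g.dims, dtype=bool)
        for c in coords:
            m[c] = True
        return BrainMask(grid=g, member=m)

    def test_identity_symmetry_disjoint(self, small_grid, rng):
        a = BrainMask(grid=small_grid, member=rng.random(small_grid.dims) > 0.5)
        b = BrainMask(grid=small_grid, member=rng.random(small_grid.dims) > 0.5)
        assert dice(a, a) == 1.0
        assert dice(a, b) == dice(b, a)
        disjoint = BrainMask(grid=small_grid, member=~a.member)
        assert dice(a, disjoint) == 0.0

    def test_known_overlap_value(self):
        g = grid((10, 10, 10), vox=1.0)
        flat_a = np.zeros(1000, dtype=bool)
        flat_a[:100] = True
        flat_b = np.zeros(1000, dtype=bool)
        flat_b[40:120] = True  # |B|=80, overlap=60
        a = BrainMask(grid=g, member=flat_a.reshape(g.dims))
        b = BrainMask(grid=g, member=flat_b.reshape(g.dims))
        assert dice(a, b) == pytest.approx(120.0 / 180.0)

    def test_monotone_in_overlap(self, small_grid):
        base = np.zeros(small_grid.dims, dtype=bool)
        base.ravel()[:60] = True
        a = BrainMask(grid=small_grid, member=base)
        prev = 1.0
        for removed in (10, 30, 50):
            other = base.copy().ravel()
            other[:removed] = False
            d = dice(a, BrainMask(grid=small_grid, member=other.reshape(small_grid.dims)))
            assert d < prev
            prev = d

    def test_both_empty_rejected(self, small_grid):
        empty = BrainMask(grid=small_grid, member=np.zeros(small_grid.dims, bool))
        with pytest.raises(ValueError):
            dice(empty, empty)


class TestFcs:
    def test_shared_timecourse_gives_unity(self, small_grid, cube_mask):
        f = np.sin(np.arange(24) * 0.7)
        data = np.broadcast_to(f, small_grid.dims + (24,)).copy()
        res = fcs(Volume4D(grid=small_grid, values=data), cube_mask)
        np.testing.assert_allclose(res.map[cube_mask.member], 1.0, atol=1e-10)

    def test_matches_bruteforce_pairwise_mean(self, rng):
        # oracle: mean over j of corr(v, j), self included, equals the
        # scaled-global correlation divided by the norm of the mean of the
        # unit-normalized series
        g = grid((8, 1, 1), vox=3.0)
        data = rng.normal(size=(8, 20))
        mask = full_mask(g)
        res = fcs(data, mask)
        C = np.corrcoef(data)
        brute = C.mean(axis=1)
        centered = data - data.mean(axis=1, keepdims=True)
        unit = centered / np.linalg.norm(centered, axis=1, keepdims=True)
        scale = np.linalg.norm(unit.mean(axis=0))
        vals = res.map[mask.member]
        np.testing.assert_allclose(vals, brute / scale, rtol=1e-10)
        # identical ranking as the brute-force vector
        assert np.array_equal(np.argsort(vals), np.argsort(brute))

    def test_global_spikes_raise_fcs(self):
        from restqc.phantom import PhantomSpec, simulate_subject

        base = dict(n_networks=1, region_signal_amp=0.0, thermal_sigma=1.0, seed=9)
        clean = simulate_subject(PhantomSpec(**base))
        spiky = simulate_subject(PhantomSpec(**base, spike_times=(30, 80, 140), spike_gain=0.05))
        f_clean = fcs(clean.volume, clean.brain_mask).mean_in_mask
        f_spiky = fcs(spiky.volume, spiky.brain_mask).mean_in_mask
        assert f_spiky > f_clean

    def test_zero_variance_voxels_counted(self, small_grid, cube_mask, rng):
        data = rng.normal(size=small_grid.dims + (20,))
        data[0, 0, 0, :] = 5.0
        res = fcs(Volume4D(grid=small_grid, values=data), cube_mask)
        assert res.n_undefined == 1


class TestFlipCheck:
    def asym_volume(self, g, rng):
        x = np.indices(g.dims)[0].astype(float)
        return rng.normal(size=g.dims) + 3.0 * x / g.dims[0]

    def test_identical_volumes_not_flipped(self, rng):
        g = grid((12, 12, 8), vox=3.0)
        vol = self.asym_volume(g, rng)
        res = check_lr_flip(vol, vol, full_mask(g))
        assert not res.flipped
        assert res.cost_original <= res.cost_flipped

    def test_mirrored_anatomy_detected(self, rng):
        g = grid((12, 12, 8), vox=3.0)
        vol = self.asym_volume(g, rng)
        lr_axis = g.axis_for("L")
        mirrored = np.flip(vol, axis=lr_axis)
        res = check_lr_flip(vol, mirrored, full_mask(g), margin=0.01)
        assert res.flipped

    def test_symmetric_input_ties_to_not_flipped(self, rng):
        g = grid((12, 12, 8), vox=3.0)
        half = rng.normal(size=(6, 12, 8))
        sym = np.concatenate([half, np.flip(half, axis=0)], axis=0)
        res = check_lr_flip(sym, sym, full_mask(g), margin=1e-6)
        assert not res.flipped

    def test_grid_mismatch_rejected(self, rng):
        g = grid((12, 12, 8))
        with pytest.raises(ValueError):
            check_lr_flip(rng.normal(size=(10, 12, 8)), rng.normal(size=g.dims), full_mask(g))
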