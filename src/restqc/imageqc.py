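"""Scalar and voxelwise image-quality metrics.

TSNR is computed on the original (pre-regression) series; FCS on
post-regression residuals.  Spatial smoothness uses the classical
Gaussian-autocorrelation first-difference estimator: if the data are a
Gaussian random field with autocorrelation exp(-d^2 / (4 sigma_b^2)), the
variance of first spatial differences at spacing D satisfies
    var(diff) = 2 sigma^2 (1 - rho(D)),   rho(D) = 1 - var(diff)/(2 sigma^2),
and the kernel full-width at half maximum along that direction is
    FWHM = D * sqrt(-2 ln 2 / ln rho(D)).
For spatially uncorrelated noise rho -> 0 and the estimate goes to zero
("rougher than white noise" is clamped to 0); for data blurred with a known
Gaussian kernel the estimator returns the kernel FWHM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volio import BrainMask, Volume4D

__all__ = [
    "TsnrResult",
    "FwhmResult",
    "FcsResult",
    "FlipResult",
    "tsnr",
    "estimate_fwhm",
    "blur_to_fwhm",
    "dice",
    "fcs",
    "check_lr_flip",
]

GAUSS_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass
class TsnrResult:
    map: np.ndarray  # 3D; NaN where undefined or out of mask
    mean_in_mask: float
    n_undefined: int


@dataclass
class FwhmResult:
    fwhm_mm: tuple[float, float, float]

    @property
    def combined_mm(self) -> float:
        fx, fy, fz = self.fwhm_mm
        return float((fx * fy * fz) ** (1.0 / 3.0))


@dataclass
class FcsResult:
    map: np.ndarray  # 3D; NaN where undefined or out of mask
    mean_in_mask: float
    scaled_global: np.ndarray
    n_undefined: int = 0


@dataclass
class FlipResult:
    cost_original: float
    cost_flipped: float
    flipped: bool
    margin: float


def tsnr(volume: Volume4D, mask: BrainMask) -> TsnrResult:
    """Per-voxel temporal mean / temporal standard deviation (ddof=1).

    Zero-variance voxels are undefined: counted, excluded from the in-mask
    summary, NaN in the map.
    """
    if volume.n_timepoints < 2:
        raise ValueError("TSNR requires at least 2 time points")
    if not mask.grid.matches(volume.grid):
        raise ValueError("mask grid does not match volume grid")
    mask.require_nonempty()
    mean = volume.values.mean(axis=3)
    std = volume.values.std(axis=3, ddof=1)
    out = np.full(volume.grid.dims, np.nan)
    member = mask.member
    defined = member & (std > 0)
    out[defined] = np.abs(mean[defined]) / std[defined]
    n_undef = int(member.sum() - defined.sum())
    if not defined.any():
        raise ValueError("all in-mask voxels have zero temporal variance")
    return TsnrResult(map=out, mean_in_mask=float(out[defined].mean()), n_undefined=n_undef)


def _fwhm_from_ratio(ratio: float, spacing: float) -> float:
    """Gaussian-ACF FWHM from sigma_diff^2 / (2 sigma^2); clamped to 0 when
    the field is as rough as (or rougher than) white noise."""
    if ratio >= 1.0:
        return 0.0
    rho = 1.0 - ratio
    if rho >= 1.0:  # no roughness measured: effectively infinite smoothness
        return float("inf")
    return float(spacing * np.sqrt(-2.0 * np.log(2.0) / np.log(rho)))


def estimate_fwhm(volume, mask: BrainMask, detrend: bool = True) -> FwhmResult:
    """Per-direction smoothness of the data via first spatial differences.

    ``volume`` is a Volume4D or a 3D array on the mask's grid.  For 4D input
    each voxel's time series is detrended (mean + linear, when ``detrend``)
    so anatomy does not masquerade as smoothness, the per-direction estimate
    is formed at each time point and averaged.  Only voxel pairs fully inside
    the mask contribute.
    """
    if isinstance(volume, Volume4D):
        data = volume.values
        grid = volume.grid
    else:
        data = np.asarray(volume, dtype=float)
        grid = mask.grid
        if data.ndim == 3:
            data = data[..., None]
    if data.shape[:3] != mask.grid.dims:
        raise ValueError("volume shape does not match mask grid")
    mask.require_nonempty()
    T = data.shape[3]

    if detrend and T >= 3:
        t = np.linspace(-1.0, 1.0, T)
        X = np.column_stack([np.ones(T), t])
        flat = data.reshape(-1, T).T  # (T, V)
        beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
        data = (flat - X @ beta).T.reshape(data.shape)
    elif T >= 2:
        data = data - data.mean(axis=3, keepdims=True)

    member = mask.member
    spacing = mask.grid.voxel_size_mm
    fwhm_dirs = []
    for axis in range(3):
        if member.shape[axis] < 2:
            raise ValueError(f"mask too thin along axis {axis} for FWHM estimation")
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        pair = member[tuple(sl_lo)] & member[tuple(sl_hi)]
        if pair.sum() < 2:
            raise ValueError(f"not enough in-mask voxel pairs along axis {axis}")
        per_t = []
        for ti in range(T):
            vol = data[..., ti]
            vox = vol[member]
            var = vox.var(ddof=1)
            if var <= 0:
                continue
            d = vol[tuple(sl_hi)] - vol[tuple(sl_lo)]
            var_d = d[pair].var(ddof=1)
            per_t.append(_fwhm_from_ratio(var_d / (2.0 * var), spacing[axis]))
        if not per_t:
            raise ValueError("zero spatial variance at every time point")
        fwhm_dirs.append(float(np.mean(per_t)))
    return FwhmResult(fwhm_mm=tuple(fwhm_dirs))


def _masked_blur(data3d: np.ndarray, member: np.ndarray, sigma_vox) -> np.ndarray:
    """Gaussian blur restricted to the mask (normalized convolution)."""
    w = member.astype(float)
    num = ndimage.gaussian_filter(data3d * w, sigma_vox)
    den = ndimage.gaussian_filter(w, sigma_vox)
    out = np.zeros_like(data3d)
    inside = den > 1e-12
    out[inside] = num[inside] / den[inside]
    out[~member] = 0.0
    return out


def blur_to_fwhm(
    volume: Volume4D,
    mask: BrainMask,
    target_mm: float,
    tol_frac: float = 0.05,
    max_iter: int = 10,
) -> Volume4D:
    """Iteratively smooth the data inside the mask until the estimated
    combined FWHM reaches ``target_mm``.

    Each iteration estimates the current smoothness and applies an in-mask
    Gaussian blur whose width closes the quadrature gap
    sigma_step^2 = sigma_target^2 - sigma_current^2.  Refuses when the data
    are already smoother than the target (beyond tolerance).
    """
    if target_mm <= 0:
        raise ValueError("target FWHM must be positive")
    est = estimate_fwhm(volume, mask).combined_mm
    if est > target_mm * (1.0 + tol_frac):
        raise ValueError(
            f"data already smoother ({est:.2f} mm) than target {target_mm:.2f} mm"
        )
    data = volume.values.copy()
    spacing = volume.grid.voxel_size_mm
    for _ in range(max_iter):
        if abs(est - target_mm) <= tol_frac * target_mm:
            break
        sigma_target = target_mm / GAUSS_FWHM_PER_SIGMA
        sigma_current = est / GAUSS_FWHM_PER_SIGMA
        gap = sigma_target**2 - sigma_current**2
        if gap <= 0:
            break
        # cap the step: large single blurs overshoot inside a bounded mask
        sigma_step_mm = min(np.sqrt(gap), sigma_target)
        sigma_vox = sigma_step_mm / spacing
        for ti in range(data.shape[3]):
            data[..., ti] = _masked_blur(data[..., ti], mask.member, sigma_vox)
        est = estimate_fwhm(Volume4D(grid=volume.grid, values=data), mask).combined_mm
    else:
        if abs(est - target_mm) > tol_frac * target_mm:
            warnings.warn(
                f"blur_to_fwhm: reached max_iter with FWHM {est:.2f} mm "
                f"(target {target_mm:.2f} mm)",
                stacklevel=2,
            )
    return Volume4D(grid=volume.grid, values=data)


def dice(a: BrainMask, b: BrainMask) -> float:
    """Sorensen-Dice overlap 2|A∩B| / (|A| + |B|) of two masks on one grid."""
    if not a.grid.matches(b.grid):
        raise ValueError("masks are on different grids")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("both masks are empty")
    inter = int((a.member & b.member).sum())
    return 2.0 * inter / (na + nb)


def fcs(series, mask: BrainMask, retained: np.ndarray | None = None) -> FcsResult:
    """Functional connectivity strength: each voxel's correlation with the
    scaled global signal.

    The scaled global signal is the average of variance-normalized voxel time
    courses over the brain; correlating voxel v with it equals the average
    pairwise correlation of v with every brain voxel (self included) up to
    one positive per-dataset scalar, so the map ranks voxels exactly as the
    brute-force all-pairs average does.  Input should be post-regression
    residuals; pass ``retained`` to restrict to uncensored rows.
    """
    if isinstance(series, Volume4D):
        if not mask.grid.matches(series.grid):
            raise ValueError("mask grid does not match volume grid")
        data = series.values.reshape(-1, series.n_timepoints)[mask.member.ravel()]
    else:
        data = np.asarray(series, dtype=float)
        if data.ndim != 2:
            raise ValueError("series must be (V, T)")
        if data.shape[0] != mask.n_voxels:
            raise ValueError("series row count must equal in-mask voxel count")
    if retained is not None:
        data = data[:, np.asarray(retained, dtype=bool)]
    T = data.shape[1]
    if T < 3:
        raise ValueError("FCS requires at least 3 time points")
    std = data.std(axis=1, ddof=1)
    ok = std > 0
    n_undef = int((~ok).sum())
    if not ok.any():
        raise ValueError("all in-mask voxels have zero variance")
    scaled = data[ok] / std[ok, None]
    g = scaled.mean(axis=0)
    centered = data[ok] - data[ok].mean(axis=1, keepdims=True)
    gc = g - g.mean()
    gn = np.linalg.norm(gc)
    vals = centered @ gc / (np.linalg.norm(centered, axis=1) * gn)
    out_map = np.full(mask.grid.dims, np.nan)
    idx = np.flatnonzero(mask.member.ravel())[ok]
    out_map.ravel()[idx] = vals
    return FcsResult(
        map=out_map,
        mean_in_mask=float(vals.mean()),
        scaled_global=g,
        n_undefined=n_undef,
    )


def _overlap_views(a: np.ndarray, b: np.ndarray, m: np.ndarray, shift):
    """Aligned sub-views of a, b, mask for an integer voxel shift of b."""
    sl_a, sl_b = [], []
    for ax, s in enumerate(shift):
        n = a.shape[ax]
        if s >= 0:
            sl_a.append(slice(s, n))
            sl_b.append(slice(0, n - s))
        else:
            sl_a.append(slice(0, n + s))
            sl_b.append(slice(-s, n))
    return a[tuple(sl_a)], b[tuple(sl_b)], m[tuple(sl_a)]


def _match_cost(a: np.ndarray, b: np.ndarray, member: np.ndarray, shifts, cost_name: str) -> float:
    best = np.inf
    for shift in shifts:
        av, bv, mv = _overlap_views(a, b, member, shift)
        if mv.sum() < 10:
            continue
        x = av[mv]
        y = bv[mv]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        c = -abs(r) if cost_name == "neg_abs_corr" else -r
        best = min(best, c)
    if not np.isfinite(best):
        raise ValueError("no usable overlap between the two volumes")
    return best


def check_lr_flip(
    epi: np.ndarray,
    t1: np.ndarray,
    mask: BrainMask,
    cost_name: str = "neg_corr",
    margin: float = 0.0,
    search_mm: float = 10.0,
) -> FlipResult:
    """Compare EPI-to-T1 match cost against the left-right mirrored T1.

    Both 3D volumes must already share the mask's grid (alignment is
    upstream); only an exhaustive integer-voxel translation search within
    +/- ``search_mm`` is performed for each candidate.  The mirror plane is
    the mid-sagittal grid plane of the axis mapped to L-R by the orientation
    code.  ``flipped`` is True when the mirrored cost is better by more than
    ``margin`` (ties go to "not flipped").
    """
    if cost_name not in ("neg_corr", "neg_abs_corr"):
        raise ValueError(f"unknown cost {cost_name!r}")
    epi = np.asarray(epi, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if epi.shape != mask.grid.dims or t1.shape != mask.grid.dims:
        raise ValueError("EPI/T1 volumes must be on the mask grid")
    mask.require_nonempty()
    lr_axis = mask.grid.axis_for("L")
    t1_flipped = np.flip(t1, axis=lr_axis)

    spacing = mask.grid.voxel_size_mm
    ranges = [
        np.arange(-int(search_mm // spacing[ax]), int(search_mm // spacing[ax]) + 1)
        for ax in range(3)
    ]
    shifts = [(i, j, k) for i in ranges[0] for j in ranges[1] for k in ranges[2]]
    cost_orig = _match_cost(epi, t1, mask.member, shifts, cost_name)
    cost_flip = _match_cost(epi, t1_flipped, mask.member, shifts, cost_name)
    return FlipResult(
        cost_original=cost_orig,
        cost_flipped=cost_flip,
        flipped=bool(cost_flip < cost_orig - margin),
        margin=margin,
    )
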