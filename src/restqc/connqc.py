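"""Connectivity-level quality control.

Builds seed correlation maps and parcellated functional-connectivity (FC)
matrices from residual time series, summarizes each subject against the
group (Pearson similarity and Euclidean "dissimilarity" over the vectorized
edges), and computes the cohort-level motion diagnostics: QC-FC (per-edge
correlation across subjects between connectivity and mean Enorm), its
histogram, and its distance dependence.  Group averaging and QC-FC operate
in Fisher-Z space, the variance-stabilizing companion to edgewise averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .denoise import ResidualSeries, build_design, extract_nuisance_series, project_nuisance
from .motionqc import censor_mask, compute_enorm, motion_summary
from .volio import BrainMask, Parcellation, Volume4D

__all__ = [
    "FCMatrix",
    "SeedSpec",
    "QcFcResult",
    "SimilarityResult",
    "DEFAULT_SEEDS",
    "seed_map",
    "fc_matrix",
    "group_mean_fc",
    "fc_similarity",
    "qcfc",
    "threshold_sweep",
]

#: reference seed spheres (4 mm radius) for the canonical resting networks,
#: in the template world frame as printed by the source protocol
DEFAULT_SEEDS = {
    "default_mode": ((0.0, 50.0, 31.0), 4.0),
    "motor": ((36.0, 20.0, 60.0), 4.0),
    "auditory": ((43.0, 25.0, 14.0), 4.0),
    "visual": ((30.0, 87.0, 9.0), 4.0),
}

R_CLIP = 1.0 - 1e-7


@dataclass
class SeedSpec:
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("seed radius must be positive")


@dataclass
class FCMatrix:
    """Symmetric region-by-region connectivity matrix.

    In r-space the diagonal is 1; in Fisher-Z space it is stored as 0 and in
    both cases the diagonal is excluded from every vectorization.  Undefined
    edges (zero-variance regions) are NaN.
    """

    values: np.ndarray
    region_ids: list[int]
    fisher_z: bool
    undefined_regions: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.region_ids)
        if self.values.shape != (n, n):
            raise ValueError("FC matrix shape does not match region count")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("FC matrix must be symmetric")
        if not self.fisher_z:
            finite = np.isfinite(self.values)
            if np.any(np.abs(self.values[finite]) > 1 + 1e-12):
                raise ValueError("r-space FC values must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def edges(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) edge vector."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]

    def to_fisher_z(self) -> "FCMatrix":
        if self.fisher_z:
            return self
        z = np.arctanh(np.clip(self.values, -R_CLIP, R_CLIP))
        np.fill_diagonal(z, 0.0)
        return FCMatrix(
            values=z,
            region_ids=list(self.region_ids),
            fisher_z=True,
            undefined_regions=list(self.undefined_regions),
        )

    def to_csv(self, path):
        pd.DataFrame(self.values, index=self.region_ids, columns=self.region_ids).to_csv(path)


@dataclass
class QcFcResult:
    edge_r: np.ndarray
    mean_r: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    distance_dependence_r: float
    distance_ci95: tuple[float, float]
    n_excluded_edges: int = 0


@dataclass
class SimilarityResult:
    pearson: float
    euclidean_dissimilarity: float


def seed_map(
    residuals: Volume4D,
    mask: BrainMask,
    seed: SeedSpec,
    retained: np.ndarray | None = None,
) -> np.ndarray:
    """Pearson correlation of every in-mask voxel with the mean seed series.

    Seed membership is decided by the Euclidean distance (mm) from the voxel
    center to the seed center in world coordinates.
    """
    if not mask.grid.matches(residuals.grid):
        raise ValueError("mask grid does not match volume grid")
    grid = residuals.grid
    ijk = np.indices(grid.dims).reshape(3, -1).T
    world = grid.world_coords(ijk)
    dist = np.linalg.norm(world - np.asarray(seed.center_mm), axis=1)
    in_seed = (dist <= seed.radius_mm).reshape(grid.dims)
    seed_vox = in_seed & mask.member
    if not seed_vox.any():
        raise ValueError(
            f"seed {seed.name!r} at {seed.center_mm} does not intersect the mask"
        )
    T = residuals.n_timepoints
    keep = np.ones(T, dtype=bool) if retained is None else np.asarray(retained, dtype=bool)
    flat = residuals.values.reshape(-1, T)[:, keep]
    seed_series = flat[seed_vox.ravel()].mean(axis=0)
    ss = seed_series - seed_series.mean()
    ssn = np.linalg.norm(ss)
    if ssn == 0:
        raise ValueError("seed time course has zero variance")
    vox = flat[mask.member.ravel()]
    centered = vox - vox.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    vals = np.full(norms.shape, np.nan)
    ok = norms > 0
    vals[ok] = centered[ok] @ ss / (norms[ok] * ssn)
    out = np.full(grid.dims, np.nan)
    out.ravel()[np.flatnonzero(mask.member.ravel())] = vals
    return out


def _roi_series(data, parcellation: Parcellation) -> np.ndarray:
    """(T, R) mean region series from a Volume4D, ResidualSeries or array."""
    if isinstance(data, Volume4D):
        if not data.grid.matches(parcellation.grid):
            raise ValueError("volume grid does not match parcellation grid")
        return parcellation.region_means(data.values)
    raise TypeError("expected Volume4D when a parcellation is supplied")


def fc_matrix(
    data,
    parcellation: Parcellation | None = None,
    fisher_z: bool = False,
    retained: np.ndarray | None = None,
    region_ids: list[int] | None = None,
) -> FCMatrix:
    """Pairwise Pearson correlations among region mean time courses.

    ``data`` may be a Volume4D (reduced over ``parcellation``), a
    ResidualSeries of ROI columns, or a (T, R) array.  Correlations use
    retained time points only.  Regions whose mean series has zero variance
    produce NaN (undefined) edges and are reported.
    """
    if isinstance(data, ResidualSeries):
        series = data.values
        if retained is None:
            retained = data.retained.keep
    elif isinstance(data, Volume4D):
        if parcellation is None:
            raise ValueError("parcellation required for volume input")
        series = _roi_series(data, parcellation)
    else:
        series = np.asarray(data, dtype=float)
        if series.ndim != 2:
            raise ValueError("ROI series must be (T, R)")
    if parcellation is not None and isinstance(data, Volume4D):
        ids = parcellation.region_ids
    elif region_ids is not None:
        ids = list(region_ids)
    else:
        ids = list(range(1, series.shape[1] + 1))
    R = series.shape[1]
    if R < 2:
        raise ValueError("need at least 2 regions")
    keep = np.ones(series.shape[0], dtype=bool) if retained is None else np.asarray(retained, bool)
    sub = series[keep]
    if sub.shape[0] < 3:
        raise ValueError("fewer than 3 retained time points: FC undefined")
    std = sub.std(axis=0, ddof=1)
    ok = std > 0
    undefined = [ids[i] for i in np.flatnonzero(~ok)]
    vals = np.full((R, R), np.nan)
    if ok.sum() >= 1:
        r_ok = np.corrcoef(sub[:, ok], rowvar=False)
        r_ok = np.atleast_2d(r_ok)
        idx = np.flatnonzero(ok)
        vals[np.ix_(idx, idx)] = np.clip(r_ok, -1.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    out = FCMatrix(values=vals, region_ids=ids, fisher_z=False, undefined_regions=undefined)
    return out.to_fisher_z() if fisher_z else out


def group_mean_fc(matrices: list[FCMatrix], leave_out: int | None = None) -> FCMatrix:
    """Edgewise mean over subjects, in Fisher-Z space.

    Undefined edges are excluded per edge (NaN-aware mean).  ``leave_out``
    drops one subject index, for leave-one-out similarity.
    """
    if leave_out is not None:
        matrices = [m for i, m in enumerate(matrices) if i != leave_out]
    if len(matrices) < 2:
        raise ValueError("group mean requires at least 2 matrices")
    ref = matrices[0]
    zs = []
    for m in matrices:
        if m.region_ids != ref.region_ids:
            raise ValueError("matrices have mismatched regions")
        zs.append(m.to_fisher_z().values)
    stack = np.stack(zs)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    mean[np.all(np.isnan(stack), axis=0)] = np.nan
    np.fill_diagonal(mean, 0.0)
    return FCMatrix(values=mean, region_ids=list(ref.region_ids), fisher_z=True)


def fc_similarity(subject: FCMatrix, group: FCMatrix) -> SimilarityResult:
    """Pearson similarity and Euclidean dissimilarity over the edge vector."""
    if subject.region_ids != group.region_ids:
        raise ValueError("subject and group matrices have mismatched regions")
    a = subject.to_fisher_z().edges()
    b = group.to_fisher_z().edges()
    finite = np.isfinite(a) & np.isfinite(b)
    if finite.sum() < 3:
        raise ValueError("fewer than 3 jointly defined edges")
    a, b = a[finite], b[finite]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance edge vector")
    r = float(np.corrcoef(a, b)[0, 1])
    return SimilarityResult(
        pearson=r, euclidean_dissimilarity=float(np.linalg.norm(a - b))
    )


def qcfc(
    matrices: list[FCMatrix],
    mean_enorms,
    centroids_mm: np.ndarray | None = None,
    n_bins: int = 101,
) -> QcFcResult:
    """QC-FC: per-edge correlation across subjects between connectivity
    (Fisher-Z) and mean Enorm, with histogram and distance dependence.

    The distance dependence is the Pearson correlation between the per-edge
    QC-FC values and the inter-centroid Euclidean distances, with a 95%
    Fisher-interval treating edges as independent (anti-conservative, as in
    the usual reporting convention).
    """
    mean_enorms = np.asarray(mean_enorms, dtype=float)
    usable = [i for i, m in enumerate(matrices) if m is not None]
    if len(usable) < 3:
        raise ValueError("QC-FC requires at least 3 subjects")
    if len(matrices) != mean_enorms.shape[0]:
        raise ValueError("one mean Enorm per subject required")
    if not np.all(np.isfinite(mean_enorms[usable])):
        raise ValueError("mean Enorm values must be finite")
    if np.std(mean_enorms[usable]) == 0:
        raise ValueError("mean Enorm has zero variance across subjects")
    ref = matrices[usable[0]]
    edges = np.stack([matrices[i].to_fisher_z().edges() for i in usable])  # (S, E)
    qc = mean_enorms[usable]
    S, E = edges.shape
    edge_r = np.full(E, np.nan)
    n_excl = 0
    for e in range(E):
        col = edges[:, e]
        fin = np.isfinite(col)
        if fin.sum() < 3 or np.std(col[fin]) == 0 or np.std(qc[fin]) == 0:
            n_excl += 1
            continue
        edge_r[e] = np.corrcoef(col[fin], qc[fin])[0, 1]
    valid = np.isfinite(edge_r)
    if not valid.any():
        raise ValueError("no edge has enough defined values for QC-FC")
    hist_edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(edge_r[valid], bins=hist_edges)

    dd_r = np.nan
    ci = (np.nan, np.nan)
    if centroids_mm is not None:
        centroids_mm = np.asarray(centroids_mm, dtype=float)
        if centroids_mm.shape != (ref.n_regions, 3):
            raise ValueError("centroids must be (R, 3)")
        iu = np.triu_indices(ref.n_regions, k=1)
        dists = np.linalg.norm(centroids_mm[iu[0]] - centroids_mm[iu[1]], axis=1)
        d = dists[valid]
        r_v = edge_r[valid]
        if d.std() > 0 and r_v.std() > 0:
            dd_r = float(np.corrcoef(r_v, d)[0, 1])
            n = valid.sum()
            if n > 3:
                z = np.arctanh(np.clip(dd_r, -R_CLIP, R_CLIP))
                half = 1.959963984540054 / np.sqrt(n - 3)
                ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return QcFcResult(
        edge_r=edge_r,
        mean_r=float(np.nanmean(edge_r)),
        hist_edges=hist_edges,
        hist_counts=counts,
        distance_dependence_r=dd_r,
        distance_ci95=ci,
        n_excluded_edges=n_excl,
    )


def subject_cell(bundle, threshold_mm, band_hz, poly_order, include_global):
    """Censor -> design -> projection -> FC for one subject at one setting."""
    enorm = compute_enorm(bundle.motion)
    cmask = censor_mask(enorm, threshold_mm)
    summ = motion_summary(enorm, cmask, bundle.motion.tr_s)
    nuis = extract_nuisance_series(
        bundle.volume,
        masks={"global": bundle.brain_mask, "wm": bundle.wm_mask, "csf": bundle.csf_mask},
        motion=bundle.motion,
        include_global=include_global,
    )
    design = build_design(
        T=bundle.volume.n_timepoints,
        tr_s=bundle.motion.tr_s,
        nuisance_series=nuis,
        poly_order=poly_order,
        band_hz=band_hz,
        mask=cmask,
    )
    roi = bundle.parcellation.region_means(bundle.volume.values)
    resid = project_nuisance(roi, design)
    fc = None
    if resid.dof > 0:
        try:
            fc = fc_matrix(resid.values, fisher_z=True, retained=cmask.keep)
        except ValueError:
            fc = None
    return {
        "mean_enorm": summ.mean_enorm_mm,
        "max_enorm": summ.max_enorm_mm,
        "n_good": summ.n_good,
        "good_seconds": summ.good_seconds,
        "dof": resid.dof,
        "fc": fc,
    }


def threshold_sweep(
    bundles: list,
    thresholds,
    bands,
    poly_order: int = 2,
    include_global: bool = True,
    dof_cutoff: int = 15,
    min_good_seconds: float = 240.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run censoring -> design -> projection -> FC -> similarity for every
    (censoring threshold, band option) cell of a cohort.

    Returns ``(rows, summary)``: per-subject rows with dof, n_good,
    similarity and mean Enorm, and a per-cell summary with the R^2 of
    similarity on mean Enorm, the mean QC-FC, and exclusion counts under the
    supplied cutoffs.  ``bands`` entries are (f_lo, f_hi) or None.
    """
    rows = []
    summaries = []
    centroids = bundles[0].parcellation.centroids_mm() if bundles else None
    for thr in thresholds:
        for band in bands:
            band_label = "none" if band is None else f"{band[0]:g}-{band[1]:g}"
            cell = [
                subject_cell(b, thr, band, poly_order, include_global) for b in bundles
            ]
            fcs_list = [c["fc"] for c in cell]
            defined = [f for f in fcs_list if f is not None]
            group = group_mean_fc(defined) if len(defined) >= 2 else None
            for i, c in enumerate(cell):
                sim = np.nan
                dissim = np.nan
                if c["fc"] is not None and group is not None:
                    try:
                        s = fc_similarity(c["fc"], group)
                        sim, dissim = s.pearson, s.euclidean_dissimilarity
                    except ValueError:
                        pass
                rows.append(
                    {
                        "threshold_mm": thr,
                        "band": band_label,
                        "subject": getattr(bundles[i], "subject_id", i),
                        "mean_enorm": c["mean_enorm"],
                        "max_enorm": c["max_enorm"],
                        "n_good": c["n_good"],
                        "good_seconds": c["good_seconds"],
                        "dof": c["dof"],
                        "similarity": sim,
                        "dissimilarity": dissim,
                    }
                )
            cell_rows = [r for r in rows if r["threshold_mm"] == thr and r["band"] == band_label]
            sims = np.array([r["similarity"] for r in cell_rows])
            enorms = np.array([r["mean_enorm"] for r in cell_rows])
            fin = np.isfinite(sims)
            r2 = np.nan
            if fin.sum() >= 3 and np.std(enorms[fin]) > 0 and np.std(sims[fin]) > 0:
                r2 = float(np.corrcoef(sims[fin], enorms[fin])[0, 1] ** 2)
            mean_qcfc = np.nan
            dd_r = np.nan
            if len(defined) >= 3:
                try:
                    q = qcfc(fcs_list, enorms, centroids)
                    mean_qcfc = q.mean_r
                    dd_r = q.distance_dependence_r
                except ValueError:
                    pass
            summaries.append(
                {
                    "threshold_mm": thr,
                    "band": band_label,
                    "similarity_motion_r2": r2,
                    "mean_qcfc": mean_qcfc,
                    "qcfc_distance_r": dd_r,
                    "median_dof": float(np.median([c["dof"] for c in cell])),
                    "n_dof_zero": int(sum(c["dof"] == 0 for c in cell)),
                    "n_dof_below_cutoff": int(sum(c["dof"] < dof_cutoff for c in cell)),
                    "n_short_good_time": int(
                        sum(c["good_seconds"] < min_good_seconds for c in cell)
                    ),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(summaries)
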