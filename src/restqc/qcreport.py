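"""Per-subject and cohort QC records, inclusion criteria, and review montages.

The inclusion criteria mirror the study's summary table:

  A  fail when residual degrees of freedom < cutoff (default 15)
  B  fail when < min_good_seconds (default 240 s) of data survive censoring
  C  *uncertain* (flag for review, not auto-exclusion) when the maximum
     volume-to-volume Enorm exceeds the cutoff (default 3 mm); a config
     switch makes it exclusionary
  D  uncertain when the left-right flip check prefers the mirrored anatomy
  E  fail when mean TSNR or mean FCS is a robust within-site outlier
     (|value - site median| > k * MAD, default k = 4) — the coil-artifact
     screen, which has no absolute cutoff
  F-H qualitative (field-of-view, anatomy, alignment): emitted as
     "not-evaluable" placeholders for manual entry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volio import RunConfig, write_subject_qc_json

__all__ = [
    "SubjectQC",
    "CRITERIA",
    "FLAG_VALUES",
    "evaluate_criteria",
    "site_robust_stats",
    "cohort_summary",
    "export_montage",
    "mask_overlap_scores",
]

CRITERIA = ("A", "B", "C", "D", "E", "F", "G", "H")
FLAG_VALUES = ("pass", "fail", "uncertain", "not-evaluable")
QUANT_METRICS = ("tsnr_mean", "fcs_mean")


@dataclass
class SubjectQC:
    """Machine-readable per-subject QC record; missing metrics stay None."""

    subject_id: str
    site: str = "site-1"
    matrix_size: int | None = None
    voxel_size_mm: tuple | None = None
    tr_s: float | None = None
    oblique: bool | None = None
    n_timepoints: int | None = None
    mean_enorm_mm: float | None = None
    max_enorm_mm: float | None = None
    n_good: int | None = None
    good_seconds: float | None = None
    dof: int | None = None
    tsnr_mean: float | None = None
    fwhm_mm: tuple | None = None
    dice_e2a: float | None = None
    dice_a2t: float | None = None
    fcs_mean: float | None = None
    flip_flag: bool | None = None
    similarity_pearson: float | None = None
    dissimilarity: float | None = None
    criteria_flags: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = dataclasses.asdict(self)
        flags = rec.pop("criteria_flags")
        for c in CRITERIA:
            rec[f"criterion_{c}"] = flags.get(c, "not-evaluable")
        return rec


def site_robust_stats(qcs: list[SubjectQC]) -> dict:
    """Per-site median and MAD of the coil-artifact screen metrics."""
    stats: dict = {}
    df = pd.DataFrame([{**{"site": q.site}, **{m: getattr(q, m) for m in QUANT_METRICS}} for q in qcs])
    for site, group in df.groupby("site"):
        for metric in QUANT_METRICS:
            vals = group[metric].dropna().to_numpy(dtype=float)
            if len(vals) >= 3:
                med = float(np.median(vals))
                mad = float(np.median(np.abs(vals - med)))
                stats[(site, metric)] = (med, mad)
    return stats


def evaluate_criteria(
    qc: SubjectQC, config: RunConfig, site_stats: dict | None = None
) -> dict:
    """Evaluate criteria A-H for one subject; missing inputs give
    "not-evaluable"."""
    flags: dict[str, str] = {}

    if qc.dof is None:
        flags["A"] = "not-evaluable"
    else:
        flags["A"] = "fail" if qc.dof < config.dof_cutoff else "pass"

    if qc.good_seconds is None:
        flags["B"] = "not-evaluable"
    else:
        flags["B"] = "fail" if qc.good_seconds < config.min_good_seconds else "pass"

    if qc.max_enorm_mm is None:
        flags["C"] = "not-evaluable"
    elif qc.max_enorm_mm > config.max_enorm_mm:
        flags["C"] = "fail" if config.strict_max_enorm else "uncertain"
    else:
        flags["C"] = "pass"

    if qc.flip_flag is None:
        flags["D"] = "not-evaluable"
    else:
        flags["D"] = "uncertain" if qc.flip_flag else "pass"

    flags["E"] = "not-evaluable"
    if site_stats is not None:
        verdicts = []
        for metric in QUANT_METRICS:
            value = getattr(qc, metric)
            key = (qc.site, metric)
            if value is None or key not in site_stats:
                continue
            med, mad = site_stats[key]
            if mad == 0:
                verdicts.append(value != med)
            else:
                verdicts.append(abs(value - med) > config.outlier_mad_k * mad)
        if verdicts:
            flags["E"] = "fail" if any(verdicts) else "pass"

    for c in ("F", "G", "H"):
        flags[c] = "not-evaluable"
    return flags


def cohort_summary(
    qcs: list[SubjectQC], config: RunConfig
) -> tuple[pd.DataFrame, dict]:
    """Evaluate every subject under one config and tally exclusions.

    Returns the per-subject flag table (deterministic subject order) and a
    summary dict with per-criterion fail/uncertain counts; the counts are by
    construction the column sums of the table.
    """
    if not qcs:
        raise ValueError("empty cohort")
    stats = site_robust_stats(qcs)
    rows = []
    for qc in sorted(qcs, key=lambda q: q.subject_id):
        qc.criteria_flags = evaluate_criteria(qc, config, stats)
        rows.append(qc.to_record())
    table = pd.DataFrame(rows)
    counts = {}
    for c in CRITERIA:
        col = table[f"criterion_{c}"]
        counts[c] = {
            "fail": int((col == "fail").sum()),
            "uncertain": int((col == "uncertain").sum()),
            "not_evaluable": int((col == "not-evaluable").sum()),
        }
    counts["n_subjects"] = len(qcs)
    counts["n_excluded"] = int(
        (table[[f"criterion_{c}" for c in CRITERIA]] == "fail").any(axis=1).sum()
    )
    return table, counts


def write_cohort_report(table: pd.DataFrame, counts: dict, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "cohort_qc.csv", index=False)
    write_subject_qc_json(counts, outdir / "exclusion_summary.json")


def mask_overlap_scores(masks: list) -> np.ndarray:
    """Dice of each subject's mask against the cohort majority mask — an
    advisory misalignment smoke metric (lowest score = most offset)."""
    stack = np.stack([np.asarray(m.member, dtype=bool) for m in masks])
    majority = stack.mean(axis=0) >= 0.5
    out = np.empty(len(masks))
    for i, m in enumerate(stack):
        inter = np.logical_and(m, majority).sum()
        out[i] = 2.0 * inter / (m.sum() + majority.sum())
    return out


def export_montage(volumes: list, outdir, subject_ids=None, dpi: int = 80) -> list[Path]:
    """Write one static per-subject panel (3 orthogonal mid-slices) per
    volume, with a display window fixed across subjects by cohort-wide
    robust (2nd/98th) percentiles, for flip-book style review.

    ``volumes`` are 3D arrays on a shared grid.  Returns the written paths in
    deterministic subject order.
    """
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    arrays = [np.asarray(v, dtype=float) for v in volumes]
    if not arrays:
        raise ValueError("no volumes to export")
    shape = arrays[0].shape
    for a in arrays:
        if a.shape != shape:
            raise ValueError("all volumes must share one grid")
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(len(arrays))]
    pooled = np.concatenate([a.ravel() for a in arrays])
    vmin, vmax = np.percentile(pooled, [2.0, 98.0])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    order = np.argsort(subject_ids)
    for idx in order:
        a = arrays[idx]
        fig = Figure(figsize=(6, 2.2))
        FigureCanvasAgg(fig)
        mids = [s // 2 for s in a.shape]
        slices = [a[mids[0], :, :], a[:, mids[1], :], a[:, :, mids[2]]]
        for k, sl in enumerate(slices):
            ax = fig.add_subplot(1, 3, k + 1)
            ax.imshow(sl.T, origin="lower", cmap="gray", vmin=vmin, vmax=vmax)
            ax.set_axis_off()
        fig.suptitle(str(subject_ids[idx]), fontsize=9)
        path = outdir / f"montage_{subject_ids[idx]}.png"
        fig.savefig(path, dpi=dpi)
        written.append(path)
    return written
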