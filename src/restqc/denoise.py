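"""Nuisance regression with exact degrees-of-freedom accounting.

The nuisance model is a single general linear model containing polynomial
drift terms, nuisance time courses (mean whole-brain / eroded white-matter /
CSF signals and the six realignment parameters) plus their backward-difference
temporal derivatives, and — when a pass band is requested — sine/cosine pairs
at every DFT frequency *outside* the band.  Regressing those stop-band
sinusoids out of the data is algebraically a band-pass filter, and unlike a
frequency-domain filter it composes exactly with motion censoring: the model
is fit on retained rows only, and the residual degrees of freedom are
    dof = (#retained rows) - rank(design restricted to retained rows),
which is the quantity the 15-dof inclusion criterion refers to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motionqc import CensorMask, MotionTrace

__all__ = [
    "DesignMatrix",
    "ResidualSeries",
    "build_design",
    "residual_dof",
    "project_nuisance",
    "extract_nuisance_series",
]

CATEGORIES = ("polynomial", "nuisance", "derivative", "bandpass_stop")


@dataclass
class DesignMatrix:
    """Categorized regressor bank with a retained-row mask."""

    n_timepoints: int
    names: list[str]
    categories: list[str]
    matrix: np.ndarray  # (T, P)
    retained: CensorMask

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.n_timepoints, len(self.names)):
            raise ValueError("design matrix shape inconsistent with names")
        if len(self.categories) != len(self.names):
            raise ValueError("one category per column required")
        if len(set(self.names)) != len(self.names):
            dupes = {n for n in self.names if self.names.count(n) > 1}
            raise ValueError(f"duplicate column names: {sorted(dupes)}")
        if self.retained.n_timepoints != self.n_timepoints:
            raise ValueError("retained mask length does not match design")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def category_counts(self) -> dict[str, int]:
        return {c: self.categories.count(c) for c in CATEGORIES}

    def retained_matrix(self) -> np.ndarray:
        return self.matrix[self.retained.keep]

    def rank(self) -> int:
        rows = self.retained_matrix()
        if rows.size == 0:
            return 0
        return int(np.linalg.matrix_rank(rows))


@dataclass
class ResidualSeries:
    """Residual time courses after projection, with DOF bookkeeping.

    ``values`` has the input shape (T, N); censored rows are zero-filled and
    must be excluded (via ``retained``) from all downstream correlations.
    """

    values: np.ndarray
    retained: CensorMask
    dof: int
    effective_rank: int
    over_determined: bool
    meta: dict = field(default_factory=dict)

    def retained_values(self) -> np.ndarray:
        return self.values[self.retained.keep]


def stopband_frequencies(T: int, tr_s: float, band_hz: tuple[float, float]) -> list[float]:
    """DFT frequencies k/(T*tr), 1 <= k <= T/2, outside the (inclusive) band."""
    f_lo, f_hi = band_hz
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0.0 < f_lo < f_hi <= nyquist * (1 + 1e-9)):
        raise ValueError(
            f"band ({f_lo}, {f_hi}) must satisfy 0 < low < high <= Nyquist={nyquist:g}"
        )
    freqs = []
    for k in range(1, T // 2 + 1):
        f = k / (T * tr_s)
        if f < f_lo or f > f_hi:
            freqs.append(f)
    return freqs


def build_design(
    T: int,
    tr_s: float,
    nuisance_series: dict[str, np.ndarray] | None = None,
    poly_order: int = 2,
    band_hz: tuple[float, float] | None = None,
    mask: CensorMask | None = None,
) -> DesignMatrix:
    """Assemble the polynomial + nuisance + derivative + stop-band design.

    Polynomial drift terms are Legendre polynomials of degree 0..poly_order
    on [-1, 1] (poly_order + 1 columns).  Every nuisance series contributes
    itself plus its backward-difference derivative (first element 0).  For a
    band (f_lo, f_hi), sine and cosine columns are added at each DFT
    frequency k/(T*tr_s) lying strictly outside the inclusive band; the
    Nyquist frequency (k = T/2, even T) contributes a cosine only, and the
    zero frequency is covered by the constant polynomial.
    """
    if T < 2:
        raise ValueError("need at least 2 time points")
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    if mask is None:
        mask = CensorMask.all_retained(T)

    names: list[str] = []
    categories: list[str] = []
    columns: list[np.ndarray] = []

    x = np.linspace(-1.0, 1.0, T)
    for d in range(poly_order + 1):
        coef = np.zeros(d + 1)
        coef[d] = 1.0
        names.append(f"poly_{d}")
        categories.append("polynomial")
        columns.append(np.polynomial.legendre.legval(x, coef))

    nuisance_series = nuisance_series or {}
    for name, series in nuisance_series.items():
        series = np.asarray(series, dtype=float)
        if series.shape != (T,):
            raise ValueError(f"nuisance series {name!r} must have length {T}")
        if not np.all(np.isfinite(series)):
            raise ValueError(f"nuisance series {name!r} contains non-finite values")
        names.append(name)
        categories.append("nuisance")
        columns.append(series)
    for name, series in nuisance_series.items():
        deriv = np.concatenate([[0.0], np.diff(np.asarray(series, dtype=float))])
        names.append(f"{name}_deriv")
        categories.append("derivative")
        columns.append(deriv)

    if band_hz is not None:
        t_idx = np.arange(T)
        for f in stopband_frequencies(T, tr_s, band_hz):
            k = f * T * tr_s
            phase = 2.0 * np.pi * f * tr_s * t_idx
            if abs(k - T / 2.0) > 1e-9:  # sine at Nyquist is identically 0
                names.append(f"sin_{f:.6g}Hz")
                categories.append("bandpass_stop")
                columns.append(np.sin(phase))
            names.append(f"cos_{f:.6g}Hz")
            categories.append("bandpass_stop")
            columns.append(np.cos(phase))

    matrix = np.column_stack(columns) if columns else np.empty((T, 0))
    return DesignMatrix(
        n_timepoints=T, names=names, categories=categories, matrix=matrix, retained=mask
    )


def residual_dof(mask: CensorMask, design: DesignMatrix) -> int:
    """Residual degrees of freedom: retained rows minus design rank on them.

    The result is never negative; when the design saturates the retained rows
    (rank == #rows) there are no degrees of freedom left for estimating
    anything — the "not enough degrees of freedom" condition.
    """
    if mask.n_timepoints != design.n_timepoints:
        raise ValueError("censor mask length does not match design")
    rows = design.matrix[mask.keep]
    rank = int(np.linalg.matrix_rank(rows)) if rows.size else 0
    return max(int(mask.n_good) - rank, 0)


def project_nuisance(series: np.ndarray, design: DesignMatrix) -> ResidualSeries:
    """Project the design out of time courses by least squares on retained rows.

    ``series`` is (T,) or (T, N).  The fit uses retained rows only
    (numpy's minimum-norm solution under rank deficiency); residuals are
    reported on retained rows and zero elsewhere, and are orthogonal to every
    design column on the retained rows.
    """
    Y = np.asarray(series, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    if Y.shape[0] != design.n_timepoints:
        raise ValueError("series length does not match design")
    keep = design.retained.keep
    Xk = design.matrix[keep]
    Yk = Y[keep]
    resid = np.zeros_like(Y)
    if Xk.shape[1] == 0:
        resid[keep] = Yk
        rank = 0
    else:
        beta, _, rank, _ = np.linalg.lstsq(Xk, Yk, rcond=None)
        resid[keep] = Yk - Xk @ beta
        rank = int(rank)
    n_ret = int(keep.sum())
    dof = max(n_ret - rank, 0)
    if squeeze:
        resid = resid[:, 0]
    return ResidualSeries(
        values=resid,
        retained=design.retained,
        dof=dof,
        effective_rank=rank,
        over_determined=(rank >= n_ret and design.n_columns > 0),
        meta={
            "threshold_mm": design.retained.threshold_mm,
            "category_counts": design.category_counts(),
        },
    )


def extract_nuisance_series(
    volume,
    masks: dict,
    motion: MotionTrace | None = None,
    include_global: bool = True,
    include_wm: bool = True,
    include_csf: bool = True,
    include_motion: bool = True,
) -> dict[str, np.ndarray]:
    """Mean-signal and motion nuisance time courses, keyed by name.

    ``masks`` maps any of 'global', 'wm', 'csf' to a BrainMask on the
    volume's grid ('global' = whole brain, 'wm' = eroded white matter).  The
    global column is omitted when ``include_global`` is False (the no-GSR
    variant).  Derivatives are added later, at design-build time.
    """
    out: dict[str, np.ndarray] = {}
    T = volume.n_timepoints
    wanted = [
        ("global", include_global),
        ("wm", include_wm),
        ("csf", include_csf),
    ]
    flat = volume.values.reshape(-1, T)
    for name, enabled in wanted:
        if not enabled:
            continue
        if name not in masks:
            raise ValueError(f"mask {name!r} required but not provided")
        m = masks[name]
        if not m.grid.matches(volume.grid):
            raise ValueError(f"mask {name!r} is not on the volume grid")
        m.require_nonempty()
        out[name] = flat[m.member.ravel()].mean(axis=0)
    if include_motion:
        if motion is None:
            raise ValueError("motion trace required when include_motion=True")
        if motion.n_timepoints != T:
            raise ValueError("motion trace length does not match volume")
        for i, name in enumerate(("rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z")):
            out[name] = motion.params[:, i].copy()
    return out
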