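"""Head-motion quantification: Enorm, censoring, and motion summary statistics.

The motion measure is the Euclidean norm (Enorm) of the volume-to-volume
differences of the six rigid-body realignment parameters, with translations in
millimeters and rotations in degrees combined at unit weight.  The degree/mm
equivalence rests on the geometry of the head: a 1 degree rotation displaces
tissue by about 1 mm at a radius of 57 mm (arc length 57*pi/180 = 0.995 mm),
roughly the distance from the center of mass to the edge of the brain.

Censoring removes every time point whose Enorm exceeds a threshold *and* the
point immediately preceding it (the difference straddles both volumes); the
comparison is strict, so a point exactly at threshold is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotionTrace",
    "EnormSeries",
    "CensorMask",
    "MotionQC",
    "compute_enorm",
    "censor_mask",
    "motion_summary",
]


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters.

    ``params`` is (T, 6): columns 0-2 rotations in degrees, columns 3-5
    translations in mm.
    """

    params: np.ndarray
    tr_s: float

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"params must be (T, 6), got {self.params.shape}")
        if self.params.shape[0] < 2:
            raise ValueError("motion trace needs at least 2 time points")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]


@dataclass
class EnormSeries:
    """Volume-to-volume Enorm values in mm-equivalents; values[0] is 0."""

    values: np.ndarray
    tr_s: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Enorm series must be 1D")
        if self.values[0] != 0.0:
            raise ValueError("Enorm at the first time point is 0 by definition")
        if np.any(self.values < 0):
            raise ValueError("Enorm values are nonnegative")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass
class CensorMask:
    """Per-time-point keep flags (True = retained)."""

    keep: np.ndarray
    threshold_mm: float | None = None

    def __post_init__(self):
        self.keep = np.asarray(self.keep).astype(bool)
        if self.keep.ndim != 1:
            raise ValueError("censor mask must be 1D")

    @property
    def n_timepoints(self) -> int:
        return self.keep.shape[0]

    @property
    def n_good(self) -> int:
        return int(self.keep.sum())

    @classmethod
    def all_retained(cls, n_timepoints: int) -> "CensorMask":
        return cls(keep=np.ones(n_timepoints, dtype=bool))


@dataclass
class MotionQC:
    mean_enorm_mm: float
    max_enorm_mm: float
    n_good: int
    good_seconds: float


def compute_enorm(trace: MotionTrace) -> EnormSeries:
    """Euclidean norm of the temporal parameter differences at each point.

    values[t] = sqrt(sum_i (p[t,i] - p[t-1,i])^2) for t >= 1, values[0] = 0;
    degrees and millimeters enter at unit weight, with no rescaling.
    """
    diffs = np.diff(trace.params, axis=0)
    values = np.concatenate([[0.0], np.linalg.norm(diffs, axis=1)])
    return EnormSeries(values=values, tr_s=trace.tr_s)


def censor_mask(enorm: EnormSeries, threshold_mm: float) -> CensorMask:
    """Censor points whose Enorm strictly exceeds the threshold, plus the
    immediately preceding point of each violation."""
    if threshold_mm <= 0:
        raise ValueError("censoring threshold must be positive")
    keep = np.ones(enorm.n_timepoints, dtype=bool)
    viol = np.flatnonzero(enorm.values > threshold_mm)
    keep[viol] = False
    prev = viol[viol > 0] - 1
    keep[prev] = False
    return CensorMask(keep=keep, threshold_mm=threshold_mm)


def motion_summary(enorm: EnormSeries, mask: CensorMask, tr_s: float | None = None) -> MotionQC:
    """Mean/max Enorm over the defined differences (t >= 1) plus good-data
    counts.  Mean and max are computed over all differences, not only the
    retained ones, so they summarize the subject independent of the censoring
    choice."""
    if mask.n_timepoints != enorm.n_timepoints:
        raise ValueError("censor mask length does not match Enorm series")
    tr = enorm.tr_s if tr_s is None else tr_s
    diffs = enorm.values[1:]
    return MotionQC(
        mean_enorm_mm=float(diffs.mean()),
        max_enorm_mm=float(diffs.max()),
        n_good=mask.n_good,
        good_seconds=float(mask.n_good * tr),
    )
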