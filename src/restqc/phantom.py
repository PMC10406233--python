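"""Synthetic resting-state subjects and cohorts with known ground truth.

A phantom subject is a 4D volume built as

    baseline anatomy + sum_n (network map x network time course) + noise,

where the network time courses are sums of sinusoids confined to the low
frequencies where resting-state fluctuations live (default 0.01-0.08 Hz, so
they survive a 0.01-0.1 Hz pass band), the thermal noise is white Gaussian,
and optional global artifacts multiply every in-mask voxel by (1 + gain) at
chosen time points (the signature of an RF coil spike).  Motion traces have a
controllable mean Enorm, optional exact spike excursions, and an optional
heavy-tailed per-frame amplitude modulation so that the censored fraction
varies smoothly with the subject's motion level across thresholds.

Cohorts assign each subject a motion level and can couple designated true-FC
edges linearly to the subject's mean Enorm, giving an analytic target for
QC-FC recovery.  Everything is reproducible from one integer seed; subject
substreams are derived with numpy's SeedSequence spawn keys.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gamma as _gamma

from . import volio
from .motionqc import MotionTrace
from .volio import BrainMask, Parcellation, Volume4D, VolumeGrid

__all__ = [
    "PhantomSpec",
    "SubjectBundle",
    "simulate_motion_trace",
    "simulate_subject",
    "simulate_cohort",
    "write_bundle",
]

#: E[chi_6] = sqrt(2) Gamma(3.5) / Gamma(3): mean of the Euclidean norm of a
#: 6-vector of unit-variance Gaussians; used to normalize E[Enorm].
CHI6_MEAN = float(np.sqrt(2.0) * _gamma(3.5) / _gamma(3.0))


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Defaults describe a small multi-site-style resting run: a 16x16x12 grid
    of 3 mm voxels, 200 volumes at TR 2.5 s, six networks carrying
    0.01-0.08 Hz fluctuations of unit amplitude against thermal noise of
    standard deviation 0.5 on a baseline of 100 signal units, and a
    low-motion trace (mean Enorm 0.05 mm) with a lognormal heavy tail.
    Each parcel region additionally carries its own independent in-band
    fluctuation of amplitude ``region_signal_amp`` (regional heterogeneity,
    which keeps FC edges from being degenerate copies of one another).
    """

    grid_dims: tuple[int, int, int] = (16, 16, 12)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_timepoints: int = 200
    tr_s: float = 2.5
    n_networks: int = 6
    network_freq_band_hz: tuple[float, float] = (0.01, 0.08)
    thermal_sigma: float = 0.5
    spike_times: tuple[int, ...] = ()
    spike_gain: float = 0.0
    motion_mean_enorm_mm: float = 0.05
    motion_spike_times: tuple[int, ...] = ()
    motion_spike_amp_mm: float = 0.0
    motion_tail_weight: float = 0.8
    regions_per_network: int = 4
    region_signal_amp: float = 0.6
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if any(int(d) <= 0 for d in self.grid_dims) or len(self.grid_dims) != 3:
            raise ValueError("grid_dims must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.n_timepoints <= 0 or self.tr_s <= 0 or self.n_networks <= 0:
            raise ValueError("n_timepoints, tr_s and n_networks must be positive")
        nyq = 1.0 / (2.0 * self.tr_s)
        lo, hi = self.network_freq_band_hz
        if not (0.0 < lo < hi < nyq):
            raise ValueError(
                f"network band ({lo}, {hi}) must lie within (0, Nyquist={nyq:g})"
            )
        for t in tuple(self.spike_times) + tuple(self.motion_spike_times):
            if not (0 <= int(t) < self.n_timepoints):
                raise ValueError(f"spike index {t} out of range [0, {self.n_timepoints})")
        if self.thermal_sigma < 0 or self.spike_gain < 0:
            raise ValueError("thermal_sigma and spike_gain must be nonnegative")
        if self.motion_mean_enorm_mm < 0 or self.motion_spike_amp_mm < 0:
            raise ValueError("motion amplitudes must be nonnegative")

    @property
    def grid(self) -> VolumeGrid:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        # center the grid on the world origin
        aff[:3, 3] = -(np.asarray(self.grid_dims) - 1) / 2.0 * np.asarray(self.voxel_size_mm)
        return VolumeGrid(dims=tuple(self.grid_dims), affine=aff)


@dataclass
class SubjectBundle:
    """One synthetic subject: data, masks, parcellation and ground truth."""

    subject_id: str
    volume: Volume4D
    motion: MotionTrace
    brain_mask: BrainMask
    wm_mask: BrainMask
    csf_mask: BrainMask
    parcellation: Parcellation
    t1: np.ndarray  # 3D structural-contrast image on the same grid
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        for m in (self.brain_mask, self.wm_mask, self.csf_mask):
            if not m.grid.matches(self.volume.grid):
                raise ValueError("bundle masks must share the volume grid")
        if not self.parcellation.grid.matches(self.volume.grid):
            raise ValueError("parcellation must share the volume grid")
        if self.motion.n_timepoints != self.volume.n_timepoints:
            raise ValueError("motion trace must have one row per volume")


def _child_seed(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))


def simulate_motion_trace(
    n_timepoints: int,
    tr_s: float,
    baseline_sigma_mm: float,
    spike_times=(),
    spike_amp_mm: float = 0.0,
    seed: int = 0,
    tail_weight: float = 0.0,
) -> MotionTrace:
    """Generate a 6-parameter trace with E[Enorm] = ``baseline_sigma_mm``.

    Parameter increments are iid Gaussian (integrated to a random walk), so
    the volume-to-volume Enorm is chi-distributed with 6 degrees of freedom;
    the per-parameter scale is chosen so its expectation equals
    ``baseline_sigma_mm`` exactly.  ``tail_weight`` > 0 modulates each
    frame's increment by a shared lognormal amplitude (unit mean), producing
    the occasional large excursions real traces show without changing the
    expected Enorm.  At each ``spike_times`` index t (1 <= t < T) the frame's
    increments are replaced by a single-axis translation step of
    ``spike_amp_mm``, so the Enorm excursion there is exactly that amplitude.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    if baseline_sigma_mm < 0 or spike_amp_mm < 0:
        raise ValueError("amplitudes must be nonnegative")
    for t in spike_times:
        if not (1 <= int(t) < n_timepoints):
            raise ValueError(
                f"motion spike index {t} out of range [1, {n_timepoints}) "
                "(index 0 has no preceding volume)"
            )
    rng = np.random.default_rng(_child_seed(seed, 0))
    scale = baseline_sigma_mm / CHI6_MEAN
    diffs = rng.normal(0.0, 1.0, size=(n_timepoints - 1, 6)) * scale
    if tail_weight > 0:
        w = np.exp(tail_weight * rng.normal(size=n_timepoints - 1) - tail_weight**2 / 2.0)
        diffs *= w[:, None]
    for t in spike_times:
        diffs[int(t) - 1] = 0.0
        diffs[int(t) - 1, 3] = spike_amp_mm  # translation x
    params = np.vstack([np.zeros(6), np.cumsum(diffs, axis=0)])
    return MotionTrace(params=params, tr_s=tr_s)


def _ellipsoid_mask(dims) -> np.ndarray:
    semi = (np.asarray(dims) - 1) / 2.0
    idx = np.indices(dims)
    norm = sum(((idx[a] - semi[a]) / max(semi[a], 0.5)) ** 2 for a in range(3))
    return norm <= 1.0


def _geometry(spec: PhantomSpec):
    """Deterministic brain geometry: mask, tissue masks, network labels.

    Networks tile the superior half of the ellipsoid (slabs along x, split
    along y into parcel regions); eroded "white matter" occupies the inferior
    core with a small central "CSF" block carved out.
    """
    dims = spec.grid_dims
    brain = _ellipsoid_mask(dims)
    z_mid = dims[2] // 2
    zidx = np.indices(dims)[2]
    cortex = brain & (zidx >= z_mid)
    lower = brain & (zidx < z_mid)

    vox = np.argwhere(cortex)
    if len(vox) < spec.n_networks * spec.regions_per_network:
        raise ValueError("grid too small for the requested networks/regions")
    order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))  # sort by x, then y, z
    vox = vox[order]
    net_labels = np.zeros(dims, dtype=np.int32)  # 0 = none, 1..N = network
    parcel = np.zeros(dims, dtype=np.int32)
    chunks = np.array_split(np.arange(len(vox)), spec.n_networks)
    for n, chunk in enumerate(chunks):
        sub = vox[chunk]
        net_labels[tuple(sub.T)] = n + 1
        sub_order = np.lexsort((sub[:, 2], sub[:, 0], sub[:, 1]))  # by y within slab
        sub = sub[sub_order]
        for r, rchunk in enumerate(np.array_split(np.arange(len(sub)), spec.regions_per_network)):
            rv = sub[rchunk]
            parcel[tuple(rv.T)] = n * spec.regions_per_network + r + 1

    core = _ellipsoid_mask(dims)
    # erode by shrinking the ellipsoid: voxels well inside the boundary
    semi = (np.asarray(dims) - 1) / 2.0
    idx = np.indices(dims)
    norm = sum(((idx[a] - semi[a]) / max(semi[a], 0.5)) ** 2 for a in range(3))
    wm = lower & (norm <= 0.55)
    center = tuple(int(c) for c in semi)
    csf = np.zeros(dims, dtype=bool)
    cz = max(z_mid - 2, 0)
    csf[center[0] - 1 : center[0] + 1, center[1] - 1 : center[1] + 1, cz : cz + 2] = True
    csf &= brain
    wm &= ~csf
    if not wm.any() or not csf.any():
        raise ValueError("grid too small to carve tissue masks")
    return brain, wm, csf, net_labels, parcel


def _network_timecourses(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """(T, N) unit-variance sums of in-band sinusoids."""
    T, N = spec.n_timepoints, spec.n_networks
    t = np.arange(T) * spec.tr_s
    lo, hi = spec.network_freq_band_hz
    K = 5  # sinusoids per network
    tcs = np.empty((T, N))
    for n in range(N):
        freqs = rng.uniform(lo, hi, size=K)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=K)
        amps = rng.uniform(0.5, 1.0, size=K)
        tc = np.sum(amps[None, :] * np.sin(2 * np.pi * freqs[None, :] * t[:, None] + phases), axis=1)
        tc -= tc.mean()
        tcs[:, n] = tc / tc.std(ddof=0)
    return tcs


def _apply_coupling(tcs: np.ndarray, edges, alpha: float) -> np.ndarray:
    """Mix tc_j into tc_i for each coupled edge (i, j); keeps unit variance
    approximately for weakly correlated sources."""
    out = tcs.copy()
    for (i, j) in edges:
        mixed = out[:, i] + alpha * out[:, j]
        out[:, i] = mixed / np.sqrt(1.0 + alpha**2)
    return out


def simulate_subject(
    spec: PhantomSpec,
    subject_id: str = "sub-001",
    _coupling_edges=None,
    _coupling_alpha: float = 0.0,
) -> SubjectBundle:
    """Generate one synthetic subject (volume, motion, masks, truth)."""
    grid = spec.grid
    brain, wm, csf, net_labels, parcel = _geometry(spec)

    rng = np.random.default_rng(_child_seed(spec.seed, 1))
    tcs = _network_timecourses(spec, rng)
    if _coupling_edges:
        tcs = _apply_coupling(tcs, _coupling_edges, _coupling_alpha)

    dims = spec.grid_dims
    T = spec.n_timepoints
    # anatomical baseline with a left-right ramp so flip checks have contrast
    xnorm = np.indices(dims)[0] / max(dims[0] - 1, 1)
    znorm = np.indices(dims)[2] / max(dims[2] - 1, 1)
    anat = spec.baseline * (1.0 + 0.3 * xnorm + 0.1 * znorm)
    data = np.zeros(dims + (T,))
    data += (anat * brain)[..., None]
    for n in range(spec.n_networks):
        member = net_labels == n + 1
        data[member] += tcs[:, n]
    region_tcs = None
    if spec.region_signal_amp > 0:
        n_regions = spec.n_networks * spec.regions_per_network
        region_tcs = np.empty((T, n_regions))
        t_s = np.arange(T) * spec.tr_s
        lo, hi = spec.network_freq_band_hz
        for r in range(n_regions):
            freqs = rng.uniform(lo, hi, size=3)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
            tc = np.sin(2 * np.pi * freqs[None, :] * t_s[:, None] + phases).sum(axis=1)
            tc -= tc.mean()
            region_tcs[:, r] = spec.region_signal_amp * tc / tc.std(ddof=0)
            data[parcel == r + 1] += region_tcs[:, r]
    if spec.thermal_sigma > 0:
        noise = rng.normal(0.0, spec.thermal_sigma, size=data.shape)
        noise[~brain] = 0.0
        data += noise
    for t in spec.spike_times:
        frame = data[..., int(t)]
        frame[brain] *= 1.0 + spec.spike_gain

    motion_seed = _child_seed(spec.seed, 2).generate_state(1)[0] % (2**31)
    motion = simulate_motion_trace(
        T,
        spec.tr_s,
        spec.motion_mean_enorm_mm,
        spike_times=spec.motion_spike_times,
        spike_amp_mm=spec.motion_spike_amp_mm,
        seed=int(motion_seed),
        tail_weight=spec.motion_tail_weight,
    )

    t1 = (anat * brain) * 1.4  # same anatomy, structural-like contrast scale

    true_fc = np.corrcoef(tcs, rowvar=False)
    truth = {
        "network_labels": net_labels,
        "network_timecourses": tcs,
        "region_timecourses": region_tcs,
        "spike_times": list(spec.spike_times),
        "motion_spike_times": list(spec.motion_spike_times),
        "true_fc": true_fc,
        "coupling_edges": list(_coupling_edges or []),
        "coupling_alpha": _coupling_alpha,
        "spec": dataclasses.asdict(spec),
    }
    return SubjectBundle(
        subject_id=subject_id,
        volume=Volume4D(grid=grid, values=data),
        motion=motion,
        brain_mask=BrainMask(grid=grid, member=brain),
        wm_mask=BrainMask(grid=grid, member=wm),
        csf_mask=BrainMask(grid=grid, member=csf),
        parcellation=Parcellation(grid=grid, labels=parcel),
        t1=t1,
        truth=truth,
    )


def default_motion_levels(n_subjects: int) -> np.ndarray:
    """Cohort motion levels (mean Enorm, mm): log-spaced from a very still
    0.02 mm to a restless 0.25 mm, the range over which censoring at
    0.2/0.4/1.0 mm thresholds removes from none to most of a run."""
    return np.geomspace(0.02, 0.25, n_subjects)


def simulate_cohort(
    n_subjects: int,
    base_spec: PhantomSpec | None = None,
    motion_levels=None,
    qcfc_coupling: dict | None = None,
    seed: int = 0,
) -> tuple[list[SubjectBundle], dict]:
    """Generate a cohort with per-subject motion levels and optional
    motion-coupled FC edges.

    ``qcfc_coupling`` is ``{"edges": [(i, j), ...], "slope": s}`` with
    0-based network indices; for each subject the designated edges' true
    coupling strength is ``alpha = s * mean_enorm`` (time-course mixing), so
    true FC at those edges varies monotonically — approximately linearly for
    small alpha — with the subject's motion level.
    """
    if base_spec is None:
        base_spec = PhantomSpec()
    if motion_levels is None:
        motion_levels = default_motion_levels(n_subjects)
    motion_levels = np.asarray(motion_levels, dtype=float)
    if motion_levels.shape != (n_subjects,):
        raise ValueError("motion_levels must have one entry per subject")
    edges = []
    slope = 0.0
    if qcfc_coupling is not None:
        edges = [tuple(int(v) for v in e) for e in qcfc_coupling["edges"]]
        slope = float(qcfc_coupling["slope"])
        for (i, j) in edges:
            if not (0 <= i < base_spec.n_networks and 0 <= j < base_spec.n_networks):
                raise ValueError(
                    f"coupling edge ({i}, {j}) references a nonexistent network "
                    f"(n_networks={base_spec.n_networks})"
                )
            if i == j:
                raise ValueError("coupling edges must join two distinct networks")
    bundles = []
    for i in range(n_subjects):
        sub_seed = int(_child_seed(seed, i).generate_state(1)[0] % (2**31))
        spec_i = replace(base_spec, motion_mean_enorm_mm=float(motion_levels[i]), seed=sub_seed)
        bundles.append(
            simulate_subject(
                spec_i,
                subject_id=f"sub-{i + 1:03d}",
                _coupling_edges=edges,
                _coupling_alpha=slope * float(motion_levels[i]),
            )
        )
    cohort_truth = {
        "motion_levels": motion_levels.tolist(),
        "coupling_edges": edges,
        "coupling_slope": slope,
        "seed": int(seed),
    }
    return bundles, cohort_truth


def write_bundle(bundle: SubjectBundle, outdir):
    """Write a SubjectBundle to disk: NIfTI volumes/masks/parcellation, a
    6-column motion text file, and a JSON truth record."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    volio.write_volume4d(bundle.volume, outdir / "bold.nii.gz")
    volio.write_mask(bundle.brain_mask, outdir / "mask_brain.nii.gz")
    volio.write_mask(bundle.wm_mask, outdir / "mask_wm.nii.gz")
    volio.write_mask(bundle.csf_mask, outdir / "mask_csf.nii.gz")
    volio.write_parcellation(bundle.parcellation, outdir / "parcellation.nii.gz")
    volio.write_volume3d(bundle.volume.grid, bundle.t1, outdir / "t1.nii.gz")
    volio.write_motion(bundle.motion, outdir / "motion.txt")
    truth = {
        k: v
        for k, v in bundle.truth.items()
        if k not in ("network_labels", "network_timecourses", "true_fc")
    }
    truth["true_fc"] = np.asarray(bundle.truth["true_fc"]).tolist()
    volio.write_subject_qc_json(truth, outdir / "truth.json")
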