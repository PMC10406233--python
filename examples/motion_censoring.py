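"""Motion quantification and censoring on a synthetic realignment trace.

Builds a 200-volume trace with a mean volume-to-volume Enorm of 0.15 mm and
one deliberate 6.5 mm excursion, then shows how the censoring threshold
controls how much data survives.
"""

from restqc import motionqc, phantom

trace = phantom.simulate_motion_trace(
    n_timepoints=200, tr_s=2.5, baseline_sigma_mm=0.15,
    spike_times=[120], spike_amp_mm=6.5, seed=42, tail_weight=0.8,
)
enorm = motionqc.compute_enorm(trace)

print("Volume-to-volume motion (Enorm, mm): rotations in degrees and")
print("translations in mm combined at unit weight (1 deg ~ 1 mm at 57 mm).")
for thr in (0.2, 0.4, 1.0):
    mask = motionqc.censor_mask(enorm, thr)
    qc = motionqc.motion_summary(enorm, mask)
    print(
        f"  threshold {thr:>4.1f} mm: mean Enorm {qc.mean_enorm_mm:.3f} mm, "
        f"max {qc.max_enorm_mm:.2f} mm, good volumes {qc.n_good}/{trace.n_timepoints} "
        f"({qc.good_seconds:.0f} s retained)"
    )
print("Each threshold removes the offending volume AND the one before it;")
print("the 6.5 mm spike alone costs 2 volumes, the baseline jitter the rest.")
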