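"""Censoring-threshold x band-pass sweep on a small synthetic cohort.

Re-runs censoring -> design -> projection -> FC -> similarity for each cell
and prints the cohort summary: how strongly each subject's similarity to the
group-mean connectivity depends on their motion (R^2), the mean QC-FC, and
the exclusion counts.  On a cohort whose high movers lose most of their
degrees of freedom at a 0.2 mm threshold, the similarity-motion dependence
collapses as the threshold is relaxed -- censoring-induced dof loss, not
motion artifact, drives the dissimilarity.
"""

from restqc import connqc, phantom

bundles, _ = phantom.simulate_cohort(20, seed=11)
rows, summary = connqc.threshold_sweep(
    bundles, thresholds=[0.2, 0.4, 1.0], bands=[(0.01, 0.1), None]
)
cols = ["threshold_mm", "band", "similarity_motion_r2", "mean_qcfc",
        "median_dof", "n_dof_below_cutoff", "n_short_good_time"]
print(summary[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("similarity_motion_r2: variance in subject-to-group FC similarity")
print("explained by mean Enorm; large at 0.2 mm with band-pass, near zero at")
print("1.0 mm.  mean_qcfc stays ~0 throughout: no motion-FC coupling exists")
print("in this cohort, the similarity losses are a degrees-of-freedom effect.")
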