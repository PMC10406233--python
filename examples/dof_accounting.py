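"""Exact degrees-of-freedom accounting for the nuisance + band-pass model.

The residual degrees of freedom are (#retained time points) minus the rank
of the design restricted to those points.  With 9 nuisance series, their 9
derivatives and an order-2 polynomial (21 columns) and no band-pass, runs of
140 and 720 volumes leave 119 and 699 degrees of freedom; adding the
0.01-0.1 Hz stop-band regressors costs two per excluded frequency.
"""

import numpy as np

from restqc import denoise
from restqc.motionqc import CensorMask

rng = np.random.default_rng(0)
for T in (140, 720):
    nuis = {f"n{i}": rng.normal(size=T) for i in range(9)}
    mask = CensorMask.all_retained(T)
    no_band = denoise.build_design(T, 2.0, nuis, poly_order=2, band_hz=None)
    with_band = denoise.build_design(T, 2.0, nuis, poly_order=2, band_hz=(0.01, 0.1))
    print(
        f"T={T:>3}: design {no_band.n_columns} columns -> "
        f"dof {denoise.residual_dof(mask, no_band)} without band-pass; "
        f"{with_band.n_columns} columns -> "
        f"dof {denoise.residual_dof(mask, with_band)} with 0.01-0.1 Hz band-pass"
    )
print("A subject needs at least 15 residual dof to stay in the analysis;")
print("band-pass regression and censoring both eat directly into that budget.")
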