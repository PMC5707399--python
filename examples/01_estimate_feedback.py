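"""Estimate a feedback matrix from lagged covariances on synthetic data.

Builds a two-forcing scenario with known coefficients (0.5 and -0.3 response
units per forcing standard deviation), generates 50 years of monthly data,
and recovers the coefficients at a one-month lag with bootstrap p-values.
"""

import numpy as np

import gefa

truth = gefa.SyntheticTruth(
    B_true=[[0.5, -0.3]],
    forcing_ar1=[0.85, 0.85],
    forcing_crosscov=np.eye(2),
    noise_sd=[1.0],
    seed=42,
)
O_vals = gefa.generate_forcings(truth, 600)
A = gefa.generate_atmosphere(truth, O_vals)[:, 0]

O = gefa.ForcingMatrix.from_series({"sst_mode": O_vals[:, 0], "ndvi": O_vals[:, 1]},
                                   {"sst_mode": "oceanic", "ndvi": "terrestrial"})
fb = gefa.bootstrap_significance(A, O, tau=1, n_iter=1000, seed=0)

for name, b, p in zip(fb.forcing_names, fb.B[0], fb.p_values[0]):
    print(f"{name:10s} feedback = {b:+.3f} per sigma   p = {p:.3f}")
print(f"(truth: +0.500 and -0.300; L = {fb.L_effective} months at lag {fb.tau})")
# Each coefficient is the response change per one-standard-deviation forcing
# anomaly; p < 0.1 marks feedbacks distinguishable from scrambled noise.
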