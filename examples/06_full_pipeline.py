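"""End-to-end attribution run from a single declarative config.

Runs the bundled scenario (17 ocean-like + 3 land-like candidate forcings,
3 truly coupled; 30 years pooled over SON): simulate -> anomalies -> AIC
selection -> feedback + bootstrap -> variance split -> 4-dataset combination.
Outputs (feedback CSVs, selection trace, provenance log) land in ./gefa_run.
"""

import gefa

config = gefa.RunConfig(seed=1, season="SON", tau=1, n_bootstrap=1000,
                        outdir="gefa_run")
bundle = gefa.run_attribution(config)

fb = bundle["feedback"]
print("retained forcings and feedbacks (response units per sigma):")
for name, b, p in zip(fb.forcing_names, fb.B[0], fb.p_values[0]):
    print(f"  {name:18s} {b:+.3f}  p={p:.3f}")

att = bundle["attribution"]
print(f"V_ocean = {100 * att.V_ocean:.1f}%, V_land = {100 * att.V_land:.1f}%")

s = bundle["multidataset"]
print("multi-dataset mean [p10, p90] per retained forcing:")
for name, m, lo, hi in zip(fb.forcing_names, s.mean, s.p10, s.p90):
    print(f"  {name:18s} {m:+.3f} [{lo:+.3f}, {hi:+.3f}]")
# The three true forcings (sst_basin1_eof1/eof2, ndvi_sahel; truth +0.387
# each) should appear with positive significant coefficients; occasional
# null survivors carry small coefficients and wide bands.
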