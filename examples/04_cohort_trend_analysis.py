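"""End-to-end cohort analysis: simulate four severity groups and test
for a severity trend in posterior lower-alpha connectivity.

Uses a small cohort (8 subjects per group) with the generator's
posterior lower-alpha coupling declining with severity, runs the full
pipeline, and prints the group means and p-for-trend values.
"""

import tempfile

from hubshift import RunConfig, SimulationSpec, run_pipeline

# Posterior coupling sits in the responsive part of the kappa -> PLI map
# (around 0.7, where the study-level calibration lands) and declines by
# 0.04 per severity step; other cells stay flat.
coupling = {("lower_alpha", r): 0.35 for r in ("anterior", "central", "posterior")}
coupling[("lower_alpha", "posterior")] = 0.72
spec = SimulationSpec(
    group_sizes=(8, 8, 8, 8),
    bands=("lower_alpha",),
    base_coupling=coupling,
    severity_slope={("lower_alpha", "posterior"): -0.04},
    seed=0,
)
with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(
        spec=spec,
        bands=("lower_alpha",),
        outdir=tmp,
        seed=0,
        save_intermediates=False,
    )
    result = run_pipeline(config)

table = result.cohort_table
post = table[table["region"] == "posterior"]
print("posterior lower-alpha PLI by group:")
print(
    post.groupby("group_name", sort=False)["pli"]
    .agg(["mean", "std"])
    .round(3)
    .to_string()
)

summary = result.summary
row = summary[
    (summary["band"] == "lower_alpha") & (summary["region"] == "posterior")
].iloc[0]
print(
    f"\np for trend (PLI, posterior): raw={row['pli_p_raw']:.2e}, "
    f"Bonferroni x{row['correction_factor']:.0f} -> "
    f"{row['pli_p_corrected']:.2e}, slope={row['pli_slope']:+.3f}"
)
com = summary[summary["region"] == "mass_center"]
ys = com["com_y_slope"].dropna()
print(f"center-of-mass y slope per severity step: {float(ys.iloc[0]):+.4f}")
print(
    "\nA negative PLI slope with a small corrected p reproduces the "
    "severity-dependent posterior connectivity decline; a positive "
    "com_y slope means hubs shift forward as severity increases."
)
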