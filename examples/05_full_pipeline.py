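"""The whole analysis in one call: synth -> solve -> sweep -> report.

Runs every activity at a coarse five-level weakness grid (quarter steps
for speed; the default is 10% steps), writes the CSV reports to
./capgap_demo_out/, and prints the weakness tolerances.
Equivalent shell command:  capgap report --levels 0:1:0.25 --out capgap_demo_out
"""

import capgap as cg

config = cg.RunConfig(
    levels=[0.0, 0.25, 0.5, 0.75, 1.0], out_dir="capgap_demo_out", seed=0
)
report, tolerances = cg.run_pipeline(config)

print("\nweakness tolerance per activity/DOF/direction (NaN = never impaired):")
print(
    tolerances[["activity", "dof", "direction", "tolerance_weakness", "max_task_moment"]]
    .to_string(index=False)
)
print("\nfull tables written to capgap_demo_out/ (report.csv, tolerances.csv)")
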