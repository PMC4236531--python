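"""Weakness sweep of a synthetic stair-ascent trial.

Generates a dynamically consistent stair-ascent trial on the shipped
planar model, re-solves the muscle redundancy at 0-100% uniform loss of
maximal isometric force, and prints the peak ankle plantarflexion
capability gap per level and the weakness tolerance — the lowest level
at which the task first becomes impossible by muscle force alone.
"""

import numpy as np

import capgap as cg

model = cg.planar9()
trial = cg.generate_trial(cg.default_profile("stair_ascent", seed=1), model)
sweep = cg.weakness_sweep(model, trial)

print("stair ascent, ankle plantarflexion (peak task "
      f"{np.max(trial.net_moments[:, 2]) / model.body_mass:.2f} Nm/kg):")
for w in sweep.levels:
    series = sweep.get(w.fraction, "ankle")
    peak = np.max(np.maximum(series.gap_moment, 0.0))
    print(f"  weakness {w.fraction:4.0%}: peak gap {peak:6.3f} Nm/kg")

tol = cg.tolerance_level(sweep, "ankle", "positive")
print(f"weakness tolerance (first detected gap > 0.01 Nm/kg): {tol.fraction:.0%}")
print("below that level the intact plantarflexors still cover the task; "
      "above it an exoskeleton must make up the printed gap.")
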