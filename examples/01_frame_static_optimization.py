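"""One frame of static optimization: muscles versus a costly reserve.

A single DOF demands 50 Nm.  One muscle can deliver up to 100 Nm; the
ideal moment actuator (reserve) delivers 1 Nm per unit activation.  The
quadratic objective splits the load by gain ratio, so the reserve carries
almost nothing — until the muscle saturates, when the reserve bridges
exactly the capability gap.
"""

import capgap as cg

strong = cg.FrameProblem(
    required_moments=[50.0], gains=[[100.0]], reserves=[cg.ReserveActuator("ankle")]
)
sol = cg.solve_frame(strong)
print("strong muscle (gain 100 Nm), demand 50 Nm:")
print(f"  muscle activation  {sol.muscle_activations[0]:.6f}  (closed form 5000/10001)")
print(f"  reserve activation {sol.reserve_activations[0]:.6f}  -> reserve moment "
      f"{sol.reserve_activations[0] * 1.0:.4f} Nm (negligible: muscles are preferred)")

weak = cg.FrameProblem(
    required_moments=[50.0], gains=[[30.0]], reserves=[cg.ReserveActuator("ankle")]
)
sol = cg.solve_frame(weak)
print("weakened muscle (gain 30 Nm), demand 50 Nm:")
print(f"  muscle activation  {sol.muscle_activations[0]:.6f}  (saturated)")
print(f"  reserve moment     {sol.reserve_activations[0] * 1.0:.4f} Nm "
      "(the capability gap: assistance an exoskeleton must supply)")
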