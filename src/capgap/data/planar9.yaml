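# Default planar sagittal lower-limb model: 3 DOFs, 9 lumped muscle groups.
#
# Conventions: extension moments positive at hip and knee, plantarflexion
# positive at ankle; joint angles share the positive direction of their
# moments; angles in radians, forces in N, lengths in m.
#
# Maximal isometric forces are lumped-group values of standard lower-limb
# model magnitudes for a healthy adult; optimal fiber lengths are effective
# rigid-tendon constants chosen so normalized fiber length stays near 1
# over activities-of-daily-living joint excursions.  Body mass and segment
# inertial properties (fractions of body mass/stature) describe a 61 kg,
# 1.72 m adult.
name: planar9
body_mass: 61.0
dofs:
  - {name: hip, positive_direction_label: extension}
  - {name: knee, positive_direction_label: extension}
  - {name: ankle, positive_direction_label: plantarflexion}
segments:
  - {name: thigh, mass: 6.10, length: 0.42, com: 0.181, inertia: 0.1123}
  - {name: shank, mass: 2.84, length: 0.43, com: 0.185, inertia: 0.0479}
  - {name: foot,  mass: 0.88, length: 0.26, com: 0.130, inertia: 0.0134}
muscles:
  - name: iliopsoas
    max_isometric_force: 1500.0
    optimal_fiber_length: 0.16
    moment_arm_coeffs: {hip: [-0.050]}
  - name: gluteus_maximus
    max_isometric_force: 3000.0
    optimal_fiber_length: 0.20
    moment_arm_coeffs: {hip: [0.062]}
  - name: hamstrings
    max_isometric_force: 2500.0
    optimal_fiber_length: 0.25
    moment_arm_coeffs: {hip: [0.060], knee: [-0.035]}
  - name: rectus_femoris
    max_isometric_force: 1200.0
    optimal_fiber_length: 0.22
    moment_arm_coeffs: {hip: [-0.045], knee: [0.042]}
  - name: vasti
    max_isometric_force: 4500.0
    optimal_fiber_length: 0.18
    moment_arm_coeffs: {knee: [0.042, 0.008]}
  - name: biceps_femoris_short
    max_isometric_force: 900.0
    optimal_fiber_length: 0.16
    moment_arm_coeffs: {knee: [-0.032]}
  - name: gastrocnemius
    max_isometric_force: 2400.0
    optimal_fiber_length: 0.30
    moment_arm_coeffs: {knee: [-0.020], ankle: [0.050]}
  - name: soleus
    max_isometric_force: 3600.0
    optimal_fiber_length: 0.22
    moment_arm_coeffs: {ankle: [0.048, 0.012]}
  - name: tibialis_anterior
    max_isometric_force: 1400.0
    optimal_fiber_length: 0.18
    moment_arm_coeffs: {ankle: [-0.040]}
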