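# Shipped fixture profiles for the five activities of daily living.
#
# Angles in radians (hip/knee extension positive, ankle plantarflexion
# positive; knee is kept at least slightly flexed so the leg never
# straightens into a singular posture for the ground-reaction solve).
# Moment scales are peak mass-normalized targets in Nm/kg, ordered per
# the usual ADL demand hierarchy: stair tasks >= gait >= chair tasks at
# the ankle, with plantarflexion the single largest demand (~1.7 Nm/kg
# during stair ascent) and gait dorsiflexion the smallest (~0.11 Nm/kg).
gait:
  duration: 1.1
  sampling_rate: 100
  cyclic: true
  angles:
    hip:   {type: fourier, a0: -0.12, an: [-0.28, 0.02], bn: [0.10, -0.03]}
    knee:  {type: fourier, a0: -0.50, an: [0.15, 0.10], bn: [0.06, 0.08]}
    ankle: {type: fourier, a0: 0.02, an: [-0.0175, 0.0496], bn: [-0.1153, 0.0604]}
  moments:
    hip:   {scale: 0.90, bumps: [[0.12, 0.10, 1.0], [0.55, 0.14, -0.70]]}
    knee:  {scale: 0.60, bumps: [[0.15, 0.08, 1.0], [0.65, 0.12, -0.70]]}
    ankle: {scale: 1.40, bumps: [[0.45, 0.11, 1.0], [0.06, 0.05, -0.08]]}
stair_ascent:
  duration: 1.4
  sampling_rate: 100
  cyclic: true
  angles:
    hip:   {type: fourier, a0: -0.35, an: [-0.30, 0.04], bn: [0.12, -0.02]}
    knee:  {type: fourier, a0: -0.60, an: [0.25, 0.10], bn: [0.10, 0.06]}
    ankle: {type: fourier, a0: 0.00, an: [0.1137, -0.0389], bn: [-0.1777, 0.0657]}
  moments:
    hip:   {scale: 0.91, bumps: [[0.20, 0.14, 1.0], [0.70, 0.12, -0.35]]}
    knee:  {scale: 1.30, bumps: [[0.18, 0.12, 1.0], [0.65, 0.10, -0.30]]}
    ankle: {scale: 1.70, bumps: [[0.55, 0.10, 1.0], [0.08, 0.06, -0.05]]}
stair_descent:
  duration: 1.3
  sampling_rate: 100
  cyclic: true
  angles:
    hip:   {type: fourier, a0: -0.20, an: [-0.18, 0.03], bn: [0.08, -0.02]}
    knee:  {type: fourier, a0: -0.55, an: [0.22, 0.10], bn: [0.08, 0.06]}
    ankle: {type: fourier, a0: 0.05, an: [0.057, 0.0154], bn: [-0.1454, 0.069]}
  moments:
    hip:   {scale: 0.50, bumps: [[0.15, 0.12, 1.0], [0.60, 0.15, -0.50]]}
    knee:  {scale: 1.31, bumps: [[0.30, 0.15, 1.0], [0.80, 0.10, -0.25]]}
    ankle: {scale: 1.60, bumps: [[0.20, 0.12, 1.0], [0.75, 0.08, -0.06]]}
sit_to_stand:
  duration: 2.0
  sampling_rate: 100
  cyclic: false
  angles:
    hip:   {type: logistic, start: -1.30, end: -0.05, center: 0.5, steepness: 9.0}
    knee:  {type: logistic, start: -1.45, end: -0.15, center: 0.5, steepness: 9.0}
    ankle: {type: logistic, start: -0.10, end: 0.02, center: 0.45, steepness: 9.0}
  moments:
    hip:   {scale: 0.70, bumps: [[0.45, 0.18, 1.0], [0.05, 0.10, -0.15]]}
    knee:  {scale: 1.00, bumps: [[0.50, 0.16, 1.0], [0.05, 0.10, -0.10]]}
    ankle: {scale: 0.35, bumps: [[0.55, 0.20, 1.0], [0.10, 0.10, -0.20]]}
stand_to_sit:
  duration: 2.2
  sampling_rate: 100
  cyclic: false
  angles:
    hip:   {type: logistic, start: -0.05, end: -1.30, center: 0.5, steepness: 9.0}
    knee:  {type: logistic, start: -0.15, end: -1.45, center: 0.5, steepness: 9.0}
    ankle: {type: logistic, start: 0.02, end: -0.10, center: 0.55, steepness: 9.0}
  moments:
    hip:   {scale: 0.60, bumps: [[0.55, 0.18, 1.0], [0.05, 0.10, -0.10]]}
    knee:  {scale: 0.90, bumps: [[0.50, 0.18, 1.0], [0.95, 0.08, -0.10]]}
    ankle: {scale: 0.30, bumps: [[0.45, 0.20, 1.0], [0.90, 0.10, -0.20]]}
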