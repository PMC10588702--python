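# Default simulation: pressurized icosphere under the hybrid
# force + constraint loop.  All physics defaults live here, none are
# hard-coded in the driver.
fixture:
  kind: icosphere
  subdivision: 3
  radius: 1.0
forces:
  k_spring: 200.0      # N/m, edge spring stiffness
  damping: 20.0        # 1/s, velocity rescale rate (damping*dt <= 1)
  pressure: 5.0        # N/m^2, positive inflates
  offset_magnitude: 0.0
  offset_mode: inward-normal
  dt: 0.01             # s
solver:
  iterations: 5
  dt: 0.01
  k_str: 0.9
  k_bend: 0.5
constraints:
  breakable: false
  break_threshold: 0.4
colliders: []
interaction_script: null
steps: 200
seed: 0
frame_stride: 0
output_dir: out
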