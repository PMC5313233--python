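# End-to-end demo: synthetic two-state loop, zero-temperature string on the
# Müller-Brown surface, finite-temperature string with PMF, 1D well-tempered
# metadynamics with free-energy reconstruction, and ensemble analysis.
seed: 2026
output_dir: pathcv_demo
stages: [synth, zts, string, metad, fes, cluster, network, density]

system:
  kind: mueller-brown
  params: {scale: 0.1}
  temperature: 150.0
  friction: 20.0
  timestep: 0.001

synth:
  n_beads: 20
  n_frames: 150
  noise_amplitude: 0.3
  basin_depths: [0.0, 0.0]

zts:
  descent_steps: 20
  iterations: 100
  start_images: 4
  final_images: 256
  extract_count: 32
  extract_start: 7
  descent_step: 1.0e-4

string:
  force_constant: 400.0
  stride: 60
  dt: 0.005
  fixed_endpoints: true
  max_updates: 120
  conv_window: 40
  conv_tolerance: 0.02
  pmf_steps: 2000

metad:
  system:
    kind: double-well-1d
    params: {barrier: 2.5, half_width: 1.0, tilt: 1.2}
    temperature: 300.0
    friction: 2.0
    timestep: 0.002
  n_walkers: 10
  n_steps: 12000
  stride: 500
  height: 0.7
  sigma: 0.1
  bias_temperature: 4200.0
  grid_min: [-2.2]
  grid_max: [2.2]
  grid_spacing: 0.002

fes: {}

cluster:
  threshold: 3.0

network:
  link_threshold: 3.8

density:
  bins: 30
  contour_interval: 0.005
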