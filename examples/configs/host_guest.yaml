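# 3D host-guest LV-MetaD run for the `lvmetad simulate` CLI.
# Omitting system.host_guest uses the package's default toy host
# (apolar core + two polar flanks forming one surface pocket on +x).
seed: 1
output_prefix: hg_run
system:
  kind: host_guest
langevin:
  timestep: 0.004
  friction: 1.0
  temperature: 298.0
  mass: 40.0
  n_steps: 250000     # 1 ns demo; the canonical study run is longer
metad:
  h0: 0.1
  stride: 1.0
  widths: [0.4, 0.12, 0.7854]
  gamma: 6.0
volume:
  origin: [0.0, 0.0, 0.0]
  axis: [1.0, 0.0, 0.0]
  steepness: 1.5      # Å; paraboloid r_perp^2 = k (a - a0)
  a0: -0.5
  a_min: 0.0          # axial safety wall
  rho_max: 6.0
  tau_max: 1.0
  wall_k: 10.0
contacts:
  pairs: [[guest, host1], [guest, host2]]   # the two polar sites
  params: {n: 8, m: 12, d0: 0.0, r0: 2.5}
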