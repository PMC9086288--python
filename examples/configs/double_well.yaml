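# Confined 1D double-well run for the `lvmetad simulate` CLI.
# A quick, scaled-down version of the canonical study conditions
# (see lvmetad.fixtures / docs/methods.md for the full-length ones).
seed: 1
output_prefix: dw_run
system:
  kind: double_well
  barrier: 2.961      # kcal/mol (5 kT at 298 K)
  asymmetry: 0.592    # kcal/mol (1 kT)
  separation: 4.0     # Å between minima
langevin:
  timestep: 0.004     # ps
  friction: 1.0       # 1/ps
  temperature: 298.0  # K
  mass: 40.0          # amu
  n_steps: 250000     # 1 ns; 2000 hills at the stride below
metad:
  h0: 0.1             # kcal/mol
  stride: 0.5         # ps between hills
  widths: [0.2, 0.04, 0.3927]   # (sigma_rho Å, sigma_tau, sigma_theta rad)
  gamma: 6.0
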