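"""Reweight externally produced HILLS/COLVAR files.

The analysis half of the package is format-compatible with PLUMED
text output, so a real all-atom localized-volume run can be
post-processed without the toy simulator: read HILLS and COLVAR,
compute c(t), weight the final window, project onto (d, N) and report
basins and ΔG.  Here we first generate a small toy pair of files so
the example is self-contained — point the paths at real files to use
your own data.
"""

import numpy as np

from lvmetad import (
    compute_ct,
    delta_g,
    frame_weights,
    grid_from_hills,
    kt,
    read_colvar,
    read_hills,
    run_lv_metad,
    write_colvar,
    write_hills,
)
from lvmetad.fixtures import (
    TEMPERATURE,
    double_well_langevin,
    double_well_metad,
    double_well_system,
)

# --- stand-in for "your simulation": write HILLS/COLVAR to disk -----------
pot = double_well_system()
colvar, bias = run_lv_metad(pot, None, double_well_metad(),
                            double_well_langevin(seed=7, n_hills=1500),
                            start=np.array([-2.0]))
write_colvar(colvar, "toy.colvar")
write_hills(bias.to_frame(), "toy.hills")

# --- the part you would run on real files ---------------------------------
hills = read_hills("toy.hills")
table = read_colvar("toy.colvar")
beta = 1.0 / kt(TEMPERATURE)
gamma = float(hills["biasf"].iloc[0])

grid = grid_from_hills(hills, dims=(0,))          # 1D run: bias lives on rho
ct = compute_ct(hills, grid, gamma=gamma, beta=beta)
t_end = table["time"][-1]
w = frame_weights(table, ct, beta, t_start=0.5 * t_end)

dg, err = delta_g(w, table, {"rho": (-4.0, 0.0)}, {"rho": (0.0, 4.0)},
                  kT=kt(TEMPERATURE), n_blocks=5)
print(f"read {len(hills)} hills (bias factor {gamma:g}), {len(table)} frames")
print(f"ΔG(left vs right well) = {dg:+.3f} ± {err:.3f} kcal/mol")
print("negative means the left region is the favoured state")
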