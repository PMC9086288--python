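"""Well-tempered metadynamics on a confined 1D double well.

Runs Langevin dynamics with hill deposition on the asymmetric double
well (5 kT barrier, 1 kT asymmetry), reweights the trajectory with the
time-dependent bias estimator, and compares the left/right well
free-energy difference with deterministic quadrature of e^(-U/kT).
The two numbers should agree to within a few hundredths of kcal/mol;
the quadrature value is exact up to grid resolution.

Takes well under a minute (a scaled-down version of the full study run).
"""

import numpy as np

from lvmetad import (
    BoxRegion,
    CVTriple,
    compute_ct,
    frame_weights,
    grid_from_hills,
    kt,
    reference_free_energy,
    run_lv_metad,
)
from lvmetad.fixtures import (
    TEMPERATURE,
    double_well_langevin,
    double_well_metad,
    double_well_system,
)

pot = double_well_system()
kT = kt(TEMPERATURE)
beta = 1.0 / kT

oracle = reference_free_energy(pot, BoxRegion([-6], [0]), BoxRegion([0], [6]), TEMPERATURE)
print(f"quadrature oracle  ΔF(left-right) = {oracle:+.4f} kcal/mol")

metad = double_well_metad()
lang = double_well_langevin(seed=2026, n_hills=4000)
print(f"running {lang.n_steps} Langevin steps, depositing {4000} hills ...")
colvar, bias = run_lv_metad(pot, None, metad, lang, start=np.array([-2.0]))

hills = bias.to_frame()
grid = grid_from_hills(hills, dims=(0,))
ct = compute_ct(hills, grid, gamma=metad.gamma, beta=beta)
w = frame_weights(colvar, ct, beta, t_start=0.5 * colvar["time"][-1])
x = colvar["rho"]
df = -kT * np.log(w[x < 0].sum() / w[x >= 0].sum())
print(f"reweighted metadynamics ΔF       = {df:+.4f} kcal/mol")
print(f"difference = {abs(df - oracle) / kT:.3f} kT "
      "(statistical; shrinks with longer runs)")
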