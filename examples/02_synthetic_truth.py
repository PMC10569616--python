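"""Hybrid-scale synthetic truth: vessel trees + continuum + observations.

Generates a desk-scale phantom dataset: seeded arterial and venous binary
trees coupled to a Darcy continuum, implicit tracer advection, 2x2 upscaled
noisy observations at greedily selected time points.
"""

import numpy as np

import perfusim as pf

cfg = pf.twin_config()          # 64 x 80 fine grid, 2 x 2 upscaling
ds = pf.run_truth_experiment(cfg, seed=1)

m = ds.fine_mesh
print("fine grid %dx%d (%.1f x %.1f mm), estimation grid %dx%d"
      % (m.nx, m.ny, 1e3 * m.nx * m.cell_size, 1e3 * m.ny * m.cell_size,
         ds.est_mesh.nx, ds.est_mesh.ny))
print("terminals: %d arterial, %d venous"
      % (ds.arterial.n_terminals, ds.venous.n_terminals))

hf = ds.hflow
print("root inflow %.3e m^3/s = exchange %.3e m^3/s (conservation)"
      % (hf.total_root_inflow, hf.total_exchange))

tissue = m.active & (m.vessel_label == 0)
P = ds.true_perfusion_fine
print("true perfusion in tissue: mean %.1f, range %.1f..%.1f mL/min/100mL"
      % (np.nanmean(P[tissue]), np.nanmin(P[tissue]), np.nanmax(P[tissue])))

obs = ds.observations
print("observations: %d of %d time points (D-optimal), sigma = %.3f mmol/L"
      % (obs.time_indices.size, ds.times.size, obs.sigma))
print("selected time indices:", obs.time_indices.tolist())
# The selected times cluster around the bolus passage where the image-to-
# image covariance is largest, then thin out along the washout tail.
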