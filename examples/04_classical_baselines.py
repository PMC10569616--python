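"""Classical estimators on constructed voxels with known perfusion.

Max slope: tissue curve built as P0 * cumulative integral of the AIF (no
venous outflow), so the peak slope over the peak AIF recovers P0 exactly.
Deconvolution: curve built by convolving a known flow-scaled exponential
residue with the AIF; TSVD deconvolution recovers the flow F.
"""

import numpy as np

import perfusim as pf
from perfusim.porous import PERFUSION_UNIT

times = np.arange(0.0, 90.0, 1.0)
aif = pf.gamma_variate_aif(5.0, 5.0, 3.0, 6.0, times)

P0 = 15.0  # mL/min/100mL
curve = (P0 / PERFUSION_UNIT) * np.cumsum(aif)
est = pf.max_slope_perfusion(curve, aif, 1.0)
print("max slope: truth %.1f -> estimate %.2f mL/min/100mL (err %.2f%%)"
      % (P0, est, 100 * abs(est - P0) / P0))

F = 10.0
R = np.exp(-times / 4.0)   # exponential residue, MTT 4 s
conv = np.convolve(aif, (F / PERFUSION_UNIT) * R)[: times.size]
est = pf.svd_deconvolution(conv, aif, 1.0, threshold=0.01)
print("deconvolution: truth %.1f -> estimate %.2f mL/min/100mL (err %.2f%%)"
      % (F, est, 100 * abs(est - F) / F))
# Both are voxel-at-a-time tracer-kinetic methods: they see one curve and
# one AIF, with no spatial coupling — the gap the flow-model inversion closes.
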