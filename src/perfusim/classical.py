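"""Classical voxelwise perfusion estimators: maximum slope and SVD deconvolution.

Both operate on a single tissue concentration curve C(t) with a global
arterial input function; the same AIF (the injection function) is used for
every voxel.  Perfusion is returned in mL/min/100mL (1/s times 6000).
Hematocrit/density correction constants default to 1.
"""

from __future__ import annotations

import numpy as np

from .porous import PERFUSION_UNIT


def max_slope_perfusion(curve: np.ndarray, aif: np.ndarray, dt: float,
                        constant: float = 1.0) -> float:
    """Maximum-slope perfusion estimate.

    P = max_t dC/dt / max_t AIF(t), with forward differences and no
    smoothing.  Valid under the no-venous-outflow assumption (the peak slope
    occurs before tracer starts leaving the voxel).
    """
    aif = np.asarray(aif, dtype=float)
    curve = np.asarray(curve, dtype=float)
    amax = aif.max()
    if amax <= 0:
        raise ValueError("AIF must be nonzero")
    slope = np.diff(curve).max(initial=0.0) / dt
    return constant * max(slope, 0.0) / amax * PERFUSION_UNIT


def svd_deconvolution(curve: np.ndarray, aif: np.ndarray, dt: float,
                      threshold: float = 0.1, constant: float = 1.0) -> float:
    """TSVD deconvolution perfusion estimate.

    Solves C = A (F R) for the flow-scaled residue function, where A is the
    lower-triangular convolution matrix A_ik = dt * AIF(t_{i-k}); singular
    values below ``threshold`` times the largest are zeroed in the
    pseudo-inverse; P is the recovered peak of F R.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    aif = np.asarray(aif, dtype=float)
    curve = np.asarray(curve, dtype=float)
    n = aif.size
    A = np.zeros((n, n))
    for k in range(n):
        A[k:, k] = dt * aif[: n - k]
    U, w, Vt = np.linalg.svd(A)
    keep = w >= threshold * w[0]
    if not keep.any():
        raise ValueError("all singular values fall below the truncation threshold")
    winv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    fr = Vt.T @ (winv * (U.T @ curve))
    return constant * max(fr.max(initial=0.0), 0.0) * PERFUSION_UNIT


def perfusion_map_classical(series: np.ndarray, aif: np.ndarray, dt: float,
                            method: str = "max_slope",
                            threshold: float = 0.1) -> np.ndarray:
    """Apply one classical estimator voxelwise to an (nt, nx, ny) series.

    Inactive voxels (all-zero curves) return 0.  For the deconvolution
    method, the SVD of the convolution matrix is factored once and reused
    across voxels.
    """
    series = np.asarray(series, dtype=float)
    nt, nx, ny = series.shape
    out = np.zeros((nx, ny))
    if method == "max_slope":
        amax = np.asarray(aif).max()
        if amax <= 0:
            raise ValueError("AIF must be nonzero")
        slopes = np.diff(series, axis=0).max(axis=0) / dt
        return np.maximum(slopes, 0.0) / amax * PERFUSION_UNIT
    if method != "deconvolution":
        raise ValueError(f"unknown method '{method}'")
    aif = np.asarray(aif, dtype=float)
    n = aif.size
    A = np.zeros((n, n))
    for k in range(n):
        A[k:, k] = dt * aif[: n - k]
    U, w, Vt = np.linalg.svd(A)
    keep = w >= threshold * w[0]
    winv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    flat = series.reshape(nt, -1)
    fr = Vt.T @ (winv[:, None] * (U.T @ flat))
    return np.maximum(fr.max(axis=0), 0.0).reshape(nx, ny) * PERFUSION_UNIT
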