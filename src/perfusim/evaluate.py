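"""Evaluation metrics and report bundles for perfusion comparisons.

Estimates are scored against the true perfusion map over a hierarchy of
region-of-interest partitions: signed relative error maps, per-region mean
perfusion with the >50%-vessel zeroing rule, and the mean absolute error

    MAE_s = (1/s) sum_q |P_T,q - P_E,q|

per partition level.  Method labels follow the comparison convention:
MS (maximum slope), DC (deconvolution), PR (prior model), PO (posterior).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Mesh, RegionPartition, partition_regions, TISSUE

log = logging.getLogger(__name__)

METHOD_LABELS = ("MS", "DC", "PR", "PO")


def relative_error_map(P_T: np.ndarray, P_E: np.ndarray) -> np.ndarray:
    """Signed relative error 100 (P_T - P_E) / P_T in percent.

    Overestimation is negative by this sign convention.  Cells where the
    true perfusion is zero (or undefined) are masked with NaN.
    """
    P_T = np.asarray(P_T, dtype=float)
    P_E = np.asarray(P_E, dtype=float)
    out = np.full(P_T.shape, np.nan)
    ok = np.isfinite(P_T) & (P_T > 0) & np.isfinite(P_E)
    out[ok] = 100.0 * (P_T[ok] - P_E[ok]) / P_T[ok]
    return out


def region_mean_perfusion(P: np.ndarray, partition: RegionPartition,
                          vessel_label: np.ndarray,
                          vessel_rule: float = 0.5) -> np.ndarray:
    """Mean perfusion per region over active cells, forced to zero in
    regions whose vessel (artery + vein) cell fraction exceeds ``vessel_rule``.

    Regions containing no active cells return NaN and are excluded
    downstream.
    """
    rid = partition.region_id
    nreg = partition.n_regions
    out = np.full(nreg, np.nan)
    act = rid >= 0
    vals = np.nan_to_num(np.asarray(P, dtype=float))
    sums = np.bincount(rid[act], weights=vals[act], minlength=nreg)
    cnts = np.bincount(rid[act], minlength=nreg)
    vess = np.bincount(rid[act], weights=(vessel_label[act] != TISSUE).astype(float),
                       minlength=nreg)
    nonempty = cnts > 0
    out[nonempty] = sums[nonempty] / cnts[nonempty]
    frac = np.zeros(nreg)
    frac[nonempty] = vess[nonempty] / cnts[nonempty]
    out[nonempty & (frac > vessel_rule)] = 0.0
    return out


def mae_by_partition(P_T: np.ndarray, P_E: np.ndarray, mesh: Mesh,
                     levels) -> pd.DataFrame:
    """Mean absolute error of region-mean perfusion per partition level.

    ``levels`` is an iterable of (rows, cols); region means use the
    >50%-vessel rule.  Returns a DataFrame with columns level, n_regions,
    mae.
    """
    rows = []
    for (r, c) in levels:
        part = partition_regions(mesh, r, c)
        vt = region_mean_perfusion(P_T, part, mesh.vessel_label)
        ve = region_mean_perfusion(P_E, part, mesh.vessel_label)
        ok = np.isfinite(vt) & np.isfinite(ve)
        mae = float(np.abs(vt[ok] - ve[ok]).mean()) if ok.any() else np.nan
        rows.append(dict(level=f"{r}x{c}", n_regions=int(ok.sum()), mae=mae))
    return pd.DataFrame(rows)


def default_levels(mesh: Mesh):
    """Partition hierarchy from the whole domain down to single cells,
    halving region size per level (1x1, 2x2, ... up to the full grid)."""
    levels = []
    r, c = 1, 1
    while r < mesh.nx and c < mesh.ny:
        levels.append((r, c))
        r = min(2 * r, mesh.nx)
        c = min(2 * c, mesh.ny)
    levels.append((mesh.nx, mesh.ny))
    return levels


def report(outdir, mesh: Mesh, P_T: np.ndarray, estimates: dict,
           mismatch_history=None, levels=None, curves_at=(),
           series=None, times=None) -> dict:
    """Write a report bundle: MAE-vs-regions table, relative-error maps,
    per-iteration mismatch table and optional concentration curves.

    ``estimates`` maps method labels (MS/DC/PR/PO) to perfusion maps.
    Returns a manifest dict (also written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"tables": [], "figures": []}
    if levels is None:
        levels = default_levels(mesh)

    if estimates:
        frames = []
        for label, P_E in estimates.items():
            df = mae_by_partition(P_T, P_E, mesh, levels)
            df.insert(0, "method", label)
            frames.append(df)
        mae = pd.concat(frames, ignore_index=True)
        p = outdir / "mae_by_regions.csv"
        mae.to_csv(p, index=False)
        manifest["tables"].append(p.name)

        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(np.asarray(P_T).T, origin="lower", cmap="viridis")
        fig.colorbar(im, ax=ax, label="true perfusion (mL/min/100mL)")
        fig.savefig(outdir / "true_perfusion.png", dpi=120)
        plt.close(fig)
        manifest["figures"].append("true_perfusion.png")
        for label, P_E in estimates.items():
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(relative_error_map(P_T, P_E).T, origin="lower",
                           cmap="coolwarm")
            fig.colorbar(im, ax=ax, label=f"relative error {label} (%)")
            fig.savefig(outdir / f"relative_error_{label}.png", dpi=120)
            plt.close(fig)
            manifest["figures"].append(f"relative_error_{label}.png")

    if mismatch_history is not None:
        df = pd.DataFrame({"iteration": np.arange(len(mismatch_history)),
                           "avg_mismatch": mismatch_history})
        p = outdir / "mismatch_history.csv"
        df.to_csv(p, index=False)
        manifest["tables"].append(p.name)

    if series is not None and curves_at:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(curves_at), figsize=(3 * len(curves_at), 3),
                                 squeeze=False)
        for ax, (i, j) in zip(axes[0], curves_at):
            ax.plot(times, series[:, i, j])
            ax.set_title(f"cell ({i}, {j})")
            ax.set_xlabel("time (s)")
        fig.tight_layout()
        fig.savefig(outdir / "concentration_curves.png", dpi=120)
        plt.close(fig)
        manifest["figures"].append("concentration_curves.png")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
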