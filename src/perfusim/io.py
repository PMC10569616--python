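"""HDF5 containers and CSV exports for datasets, ensembles and results."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd

from . import geometry, hybrid, prior


def save_dataset(path, ds: "hybrid.SyntheticDataset") -> None:
    """Write a synthetic dataset (meshes, truth, observations, AIF) plus a
    JSON manifest of the generating configuration and seed."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = ds.seed
        f.attrs["config"] = json.dumps(dataclasses.asdict(ds.config))
        geometry.save_mesh(f.create_group("fine_mesh"), ds.fine_mesh)
        geometry.save_mesh(f.create_group("est_mesh"), ds.est_mesh)
        f.create_dataset("times", data=ds.times)
        f.create_dataset("aif", data=ds.aif)
        f.create_dataset("true_perfusion_fine", data=ds.true_perfusion_fine)
        f.create_dataset("true_perfusion_coarse", data=ds.true_perfusion_coarse)
        f.create_dataset("c_total_fine", data=ds.advect["c_total"])
        g = f.create_group("observations")
        o = ds.observations
        g.attrs.update(sigma=o.sigma, noise_fraction=o.noise_fraction,
                       seed=o.seed, factor=o.factor)
        g.create_dataset("time_indices", data=o.time_indices)
        g.create_dataset("values", data=o.values)
        g.create_dataset("clean", data=o.clean)
        g.create_dataset("coarse_active", data=o.coarse_active)


def load_observations(path) -> "hybrid.ObservationSet":
    with h5py.File(path, "r") as f:
        g = f["observations"]
        return hybrid.ObservationSet(
            g["time_indices"][...], g["values"][...], g["clean"][...],
            float(g.attrs["sigma"]), float(g.attrs["noise_fraction"]),
            int(g.attrs["seed"]), int(g.attrs["factor"]),
            g["coarse_active"][...].astype(bool))


def load_dataset_arrays(path) -> dict:
    """Load the array content of a saved dataset (no network objects)."""
    out = {}
    with h5py.File(path, "r") as f:
        out["seed"] = int(f.attrs["seed"])
        out["config"] = json.loads(f.attrs["config"])
        out["est_mesh"] = geometry.load_mesh(f["est_mesh"])
        out["fine_mesh"] = geometry.load_mesh(f["fine_mesh"])
        for k in ("times", "aif", "true_perfusion_fine", "true_perfusion_coarse",
                  "c_total_fine"):
            out[k] = f[k][...]
    out["observations"] = load_observations(path)
    return out


def save_ensemble(path, ens: "prior.Ensemble") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = ens.seed
        f.attrs["field_names"] = ",".join(prior.FIELD_NAMES)
        f.create_dataset("members", data=ens.members)
        geometry.save_mesh(f.create_group("mesh"), ens.mesh)


def load_ensemble(path, prior_spec=None) -> "prior.Ensemble":
    with h5py.File(path, "r") as f:
        mesh = geometry.load_mesh(f["mesh"])
        return prior.Ensemble(f["members"][...], mesh,
                              prior_spec or prior.default_prior_spec(),
                              int(f.attrs["seed"]))


def save_posterior(path, result, mesh) -> None:
    """Posterior container: mean, sd, members, mismatch history."""
    with h5py.File(path, "w") as f:
        f.create_dataset("mean", data=result.posterior_mean())
        f.create_dataset("sd", data=result.posterior_sd())
        f.create_dataset("members", data=result.members)
        f.create_dataset("mismatch_history", data=np.asarray(result.mismatch_history))
        f.create_dataset("gamma_history", data=np.asarray(result.gamma_history))
        f.attrs["stop_reason"] = result.stop_reason
        f.attrs["n_forward_runs"] = result.n_forward_runs
        geometry.save_mesh(f.create_group("mesh"), mesh)


def observations_to_csv(path, obs: "hybrid.ObservationSet") -> None:
    """Long-format export: time_index, cell_i, cell_j, value, sigma."""
    ti, ci, cj = np.meshgrid(obs.time_indices,
                             np.arange(obs.values.shape[1]),
                             np.arange(obs.values.shape[2]), indexing="ij")
    keep = np.broadcast_to(obs.coarse_active, obs.values.shape)
    df = pd.DataFrame({
        "time_index": ti[keep], "cell_i": ci[keep], "cell_j": cj[keep],
        "value": obs.values[keep], "sigma": obs.sigma,
    })
    df.to_csv(path, index=False)
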