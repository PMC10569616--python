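"""Initial-ensemble generation: Gaussian random fields with Gaussian variograms.

Each ensemble member stacks eight parameter fields over the active cells —
three porosities (linear scale) and five log-transmissibilities ln T with
T = K / mu.  Fields are stationary Gaussian random fields with a Gaussian
(squared-exponential) variogram whose anisotropic ranges are themselves drawn
per member from Gaussian distributions.  Values are clipped to loose physical
bounds, and vessel cells receive the known Hagen-Poiseuille transmissibility
T = D^2/(32 mu) in the compartment matching their label.

The correlation model is parameterized by the practical range: the
correlation at lag = range is exp(-3) ~ 0.05, i.e.
rho(h) = exp(-3 ((hx/rx)^2 + (hy/ry)^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Mesh, ARTERY, VEIN, vessel_transmissibility
from .porous import ParameterFields

#: canonical field order in the stacked parameter vector
FIELD_NAMES = ("phi_a", "phi_v", "phi_c",
               "lnT_ax", "lnT_ay", "lnT_vx", "lnT_vy", "lnT_c")


@dataclass
class FieldPrior:
    """Mean, spread and bounds for one parameter field (Gaussian scale)."""

    mean: float
    sd: float
    lb: float
    ub: float
    transform: str = "linear"  # "linear" | "log" (log-transmissibility)

    def __post_init__(self):
        if not self.lb < self.ub:
            raise ValueError("lower bound must be below upper bound")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def default_prior_spec(range_x: float = 74.0, range_y: float = 60.0,
                       range_sd: float = 1.0) -> "PriorSpec":
    """Prior statistics for the eight fields.

    Porosities: mean 0.1, sd 0.1, bounds [0.001, 0.999] (phi_c: mean 1e-4,
    sd 1e-5, bounds [1e-6, 0.1]).  Log-transmissibilities: arterial/venous
    mean -24.1, capillary mean -10.3, sd 1, bounds [-26, -10] and [-26, -8].
    Variogram range means default to 74 and 60 grid blocks (x and y) with
    sd one block.
    """
    fields = {
        "phi_a": FieldPrior(0.1, 0.1, 0.001, 0.999),
        "phi_v": FieldPrior(0.1, 0.1, 0.001, 0.999),
        "phi_c": FieldPrior(1e-4, 1e-5, 1e-6, 0.1),
        "lnT_ax": FieldPrior(-24.1, 1.0, -26.0, -10.0, "log"),
        "lnT_ay": FieldPrior(-24.1, 1.0, -26.0, -10.0, "log"),
        "lnT_vx": FieldPrior(-24.1, 1.0, -26.0, -10.0, "log"),
        "lnT_vy": FieldPrior(-24.1, 1.0, -26.0, -10.0, "log"),
        "lnT_c": FieldPrior(-10.3, 1.0, -26.0, -8.0, "log"),
    }
    return PriorSpec(fields, range_x, range_y, range_sd)


@dataclass
class PriorSpec:
    """Per-field priors plus the variogram-range distribution (in cells)."""

    fields: dict
    range_mean_x: float = 74.0
    range_mean_y: float = 60.0
    range_sd: float = 1.0

    def scaled_ranges(self, fx: float, fy: float) -> "PriorSpec":
        """Copy with range means multiplied by (fx, fy) — used when the
        estimation grid is coarser/finer than the reference grid."""
        return replace(self, range_mean_x=self.range_mean_x * fx,
                       range_mean_y=self.range_mean_y * fy)


@dataclass
class Ensemble:
    """N parameter vectors stacked column-wise: ``members`` is (N_m, N)."""

    members: np.ndarray
    mesh: Mesh
    prior: PriorSpec
    seed: int

    @property
    def size(self) -> int:
        return self.members.shape[1]

    @property
    def n_params(self) -> int:
        return self.members.shape[0]

    def mean(self) -> np.ndarray:
        return self.members.mean(axis=1)


def gaussian_random_field(mesh_or_shape, mean: float, sd: float,
                          range_x: float, range_y: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian field with squared-exponential correlation.

    Ranges are practical ranges in cell units.  Sampling uses circulant
    embedding on a padded torus (FFT); if the embedding produces negative
    eigenvalues they are clipped — for the smooth Gaussian variogram with
    ample padding the clipped mass is negligible — with a dense-Cholesky
    fallback for very small grids.
    """
    if range_x <= 0 or range_y <= 0:
        raise ValueError("variogram ranges must be positive")
    shape = (mesh_or_shape.nx, mesh_or_shape.ny) if isinstance(mesh_or_shape, Mesh) \
        else tuple(mesh_or_shape)
    nx, ny = shape
    if sd == 0:
        return np.full(shape, float(mean))
    if nx * ny <= 1024:
        return _grf_dense(shape, mean, sd, range_x, range_y, rng)
    from scipy.fft import next_fast_len

    Mx = next_fast_len(2 * nx)
    My = next_fast_len(2 * ny)
    dx = np.minimum(np.arange(Mx), Mx - np.arange(Mx))
    dy = np.minimum(np.arange(My), My - np.arange(My))
    rho = np.exp(-3.0 * ((dx[:, None] / range_x) ** 2 + (dy[None, :] / range_y) ** 2))
    lam = np.fft.fft2(rho).real
    lam = np.maximum(lam, 0.0)
    A = np.sqrt(lam / (Mx * My))
    z = rng.standard_normal((Mx, My)) + 1j * rng.standard_normal((Mx, My))
    f = np.fft.fft2(A * z).real[:nx, :ny]
    # renormalize for the (tiny) clipped mass
    f *= sd / np.sqrt(lam.sum() / (Mx * My))
    return mean + f


def _grf_dense(shape, mean, sd, range_x, range_y, rng):
    nx, ny = shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    dxx = (pts[:, None, 0] - pts[None, :, 0]) / range_x
    dyy = (pts[:, None, 1] - pts[None, :, 1]) / range_y
    C = np.exp(-3.0 * (dxx**2 + dyy**2))
    C[np.diag_indices_from(C)] += 1e-10
    L = np.linalg.cholesky(C)
    return mean + sd * (L @ rng.standard_normal(nx * ny)).reshape(shape)


def apply_bounds(vector: np.ndarray, prior: PriorSpec, mesh: Mesh) -> np.ndarray:
    """Componentwise clip of a stacked parameter vector to the prior bounds."""
    n = mesh.n_active
    out = vector.copy()
    for k, name in enumerate(FIELD_NAMES):
        f = prior.fields[name]
        out[k * n:(k + 1) * n] = np.clip(out[k * n:(k + 1) * n], f.lb, f.ub)
    return out


def vessel_overrides(mesh: Mesh, mu: float) -> tuple[np.ndarray, np.ndarray]:
    """(indices, values) overriding log-transmissibilities in vessel cells
    with ln(D^2 / 32 mu) from the per-cell vessel diameter."""
    n = mesh.n_active
    act = mesh.active
    label = mesh.vessel_label[act]
    if mesh.vessel_diameter is None:
        return np.empty(0, dtype=np.int64), np.empty(0)
    diam = mesh.vessel_diameter[act]
    idx_list, val_list = [], []
    for code, fields in ((ARTERY, ("lnT_ax", "lnT_ay")), (VEIN, ("lnT_vx", "lnT_vy"))):
        cells = np.nonzero((label == code) & (diam > 0))[0]
        if cells.size == 0:
            continue
        lnT = np.log(diam[cells] ** 2 / (32.0 * mu))
        for name in fields:
            k = FIELD_NAMES.index(name)
            idx_list.append(k * n + cells)
            val_list.append(lnT)
    if not idx_list:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return np.concatenate(idx_list), np.concatenate(val_list)


def draw_member(mesh: Mesh, prior: PriorSpec, rng: np.random.Generator,
                mu: float = 3e-3) -> np.ndarray:
    n = mesh.n_active
    act = mesh.active
    rx = max(rng.normal(prior.range_mean_x, prior.range_sd), 1.0)
    ry = max(rng.normal(prior.range_mean_y, prior.range_sd), 1.0)
    vec = np.empty(8 * n)
    for k, name in enumerate(FIELD_NAMES):
        f = prior.fields[name]
        fld = gaussian_random_field((mesh.nx, mesh.ny), f.mean, f.sd, rx, ry, rng)
        vec[k * n:(k + 1) * n] = fld[act]
    oi, ov = vessel_overrides(mesh, mu)
    vec[oi] = ov
    return apply_bounds(vec, prior, mesh)


def draw_ensemble(mesh: Mesh, prior: PriorSpec, N: int, seed: int,
                  mu: float = 3e-3) -> Ensemble:
    """Draw N members with independent per-member random streams.

    Variogram ranges are redrawn per member (shared across the 8 fields of
    that member); log-transmissibilities in vessel cells are overridden by
    the Hagen-Poiseuille value; everything is clipped to the prior bounds.
    Member j is identical regardless of N (stream-per-member seeding).
    """
    if N < 2:
        raise ValueError("ensemble size must be >= 2")
    n = mesh.n_active
    members = np.empty((8 * n, N))
    streams = np.random.SeedSequence(seed).spawn(N)
    for j in range(N):
        members[:, j] = draw_member(mesh, prior, np.random.default_rng(streams[j]), mu)
    return Ensemble(members, mesh, prior, seed)


def params_from_vector(vector: np.ndarray, mesh: Mesh,
                       mu: float = 3e-3) -> ParameterFields:
    """Unpack a stacked parameter vector into :class:`ParameterFields`,
    mapping log-transmissibilities back to permeabilities K = mu e^{ln T}."""
    n = mesh.n_active
    act = mesh.active

    def grid(k):
        g = np.zeros((mesh.nx, mesh.ny))
        g[act] = vector[k * n:(k + 1) * n]
        return g

    phi_a, phi_v, phi_c = grid(0), grid(1), grid(2)
    K = [mu * np.exp(grid(k)) for k in range(3, 8)]
    for Kf in K:
        Kf[~act] = 0.0
    return ParameterFields(phi_a, phi_v, phi_c, K[0], K[1], K[2], K[3], K[4], mu)
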