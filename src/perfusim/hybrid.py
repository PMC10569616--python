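"""Hybrid vessel-network / continuum truth generator ("hybrid-lite").

The synthetic-truth model couples one-dimensional Poiseuille flow on binary
arterial and venous vessel trees to two Darcy continuum compartments.  Root
nodes carry Dirichlet pressures; terminal nodes exchange with the continuum
through a finite-support (uniform disc) kernel; the arterial and venous
continuums exchange through a conductivity field whose flux defines the TRUE
perfusion map.  Tracer transport is a fully implicit (backward Euler) upwind
advection over network edges and continuum cells.

The module also provides the observation pipeline: gamma-variate arterial
input function, block upscaling, Gaussian noising, and greedy D-optimal
selection of observation time points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import solve_triangular

from . import geometry as geo
from .geometry import Mesh, BoundaryConditions, ARTERY, VEIN
from .porous import PERFUSION_UNIT


# ---------------------------------------------------------------------------
# arterial input function

def gamma_variate_aif(amplitude: float, t0: float, alpha: float, beta: float,
                      times: np.ndarray) -> np.ndarray:
    """Peak-normalized gamma-variate bolus curve.

    c(t) = A ((t - t0)/(alpha beta))^alpha exp(alpha - (t - t0)/beta) for
    t > t0, else 0; the maximum equals ``amplitude`` and occurs at
    t = t0 + alpha beta.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    t = np.asarray(times, dtype=float)
    tau = t - t0
    out = np.zeros_like(t)
    pos = tau > 0
    x = tau[pos] / (alpha * beta)
    out[pos] = amplitude * np.power(x, alpha) * np.exp(alpha - tau[pos] / beta)
    return out


# ---------------------------------------------------------------------------
# vessel networks

@dataclass
class VesselNetwork:
    """Tree of vessel segments on one side of the circulation.

    nodes: (n, 2) positions in meters; edges: (m, 2) node-index pairs with
    per-edge radius and length; ``is_root`` nodes sit on the domain boundary
    and carry pressure boundary conditions, ``is_terminal`` nodes couple to
    the continuum.
    """

    side: str  # "artery" | "vein"
    nodes: np.ndarray
    edges: np.ndarray
    radius: np.ndarray
    length: np.ndarray
    is_root: np.ndarray
    is_terminal: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_terminals(self) -> int:
        return int(self.is_terminal.sum())


def generate_phantom_network(mesh: Mesh, seed: int, depth: int,
                             root_position, side: str = "artery",
                             root_radius: float = 1.5e-4,
                             trunk_length: float = 8e-3,
                             length_ratio: float = 0.75,
                             spread_deg: float = 32.0,
                             jitter_deg: float = 6.0) -> VesselNetwork:
    """Seeded binary branching tree growing from the lower domain edge.

    ``depth`` bifurcation generations follow a trunk segment, giving
    2**depth terminal leaves; radii taper by Murray's law
    (r_child = r_parent * 2**(-1/3)).  Arterial and venous trees generated
    with different roots/seeds interdigitate naturally.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if 2 ** depth > mesh.n_active:
        raise ValueError(f"depth {depth} gives more terminals than active cells")
    rng = np.random.default_rng(seed)
    Lx = mesh.nx * mesh.cell_size
    Ly = mesh.ny * mesh.cell_size
    margin = 1.2 * mesh.cell_size

    nodes = [np.asarray(root_position, dtype=float)]
    edges, radii, lengths = [], [], []
    # (node index, direction angle from +y, radius, segment length)
    frontier = [(0, 0.0, root_radius, trunk_length)]
    # trunk
    for gen in range(depth + 1):
        new_frontier = []
        for (ni, ang, r, L) in frontier:
            if gen == 0:
                branches = [(ang, r, L)]
            else:
                da = math.radians(spread_deg) + math.radians(jitter_deg) * rng.standard_normal()
                db = math.radians(spread_deg) + math.radians(jitter_deg) * rng.standard_normal()
                rc = r * 2.0 ** (-1.0 / 3.0)
                branches = [(ang + da, rc, L), (ang - db, rc, L)]
            for (a2, r2, L2) in branches:
                p = nodes[ni]
                d = np.array([math.sin(a2), math.cos(a2)])  # +y is "up"
                child = p + L2 * d
                child[0] = np.clip(child[0], margin, Lx - margin)
                child[1] = np.clip(child[1], margin, Ly - margin)
                ci = len(nodes)
                nodes.append(child)
                edges.append((ni, ci))
                radii.append(r2)
                lengths.append(float(np.linalg.norm(child - p)))
                new_frontier.append((ci, a2, r2, L2 * length_ratio))
        frontier = new_frontier

    nodes = np.asarray(nodes)
    edges = np.asarray(edges, dtype=np.int64)
    n = nodes.shape[0]
    is_root = np.zeros(n, dtype=bool)
    is_root[0] = True
    deg = np.zeros(n, dtype=np.int64)
    np.add.at(deg, edges.ravel(), 1)
    is_terminal = (deg == 1) & ~is_root
    return VesselNetwork(side, nodes, edges, np.asarray(radii),
                         np.asarray(lengths), is_root, is_terminal)


def rasterize_networks(mesh: Mesh, networks) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map vessel segments onto mesh cells.

    Returns (vessel_label, vessel_diameter, vessel_volume) arrays of shape
    (nx, ny): label per the dominant side, the largest crossing diameter, and
    the approximate intravascular blood volume (m^3) per cell.
    """
    h = mesh.cell_size
    label = np.zeros((mesh.nx, mesh.ny), dtype=np.int8)
    diam = np.zeros((mesh.nx, mesh.ny))
    vol = np.zeros((mesh.nx, mesh.ny))
    for net in networks:
        code = ARTERY if net.side == "artery" else VEIN
        for e, (n1, n2) in enumerate(net.edges):
            p1, p2 = net.nodes[n1], net.nodes[n2]
            L = net.length[e]
            nsmp = max(int(L / (0.4 * h)), 2)
            ts = (np.arange(nsmp) + 0.5) / nsmp
            pts = p1[None, :] + ts[:, None] * (p2 - p1)[None, :]
            ii = np.clip((pts[:, 0] / h).astype(int), 0, mesh.nx - 1)
            jj = np.clip((pts[:, 1] / h).astype(int), 0, mesh.ny - 1)
            seg_vol = math.pi * net.radius[e] ** 2 * L / nsmp
            for i, j in zip(ii, jj):
                if label[i, j] == 0 or diam[i, j] < 2 * net.radius[e]:
                    label[i, j] = code
                diam[i, j] = max(diam[i, j], 2 * net.radius[e])
                vol[i, j] += seg_vol
    label[~mesh.active] = 0
    return label, diam, vol


# ---------------------------------------------------------------------------
# hybrid flow

@dataclass
class TerminalKernel:
    """Uniform finite-support disc kernel distributing terminal fluxes."""

    eps: float  # support radius, m

    def weights(self, mesh: Mesh, position: np.ndarray):
        """(cell dense indices, weights summing to 1) for active cells within
        the support; falls back to the nearest active cell for tiny eps."""
        ij = mesh.active_ij
        centers = (ij + 0.5) * mesh.cell_size
        d2 = ((centers - position[None, :]) ** 2).sum(axis=1)
        inside = np.nonzero(d2 <= self.eps ** 2)[0]
        if inside.size == 0:
            inside = np.array([int(np.argmin(d2))])
        w = np.full(inside.size, 1.0 / inside.size)
        return inside, w


@dataclass
class HybridFlow:
    """Pressures and fluxes of the coupled network/continuum truth model."""

    mesh: Mesh
    p_cont_a: np.ndarray      # (nx, ny), Pa
    p_cont_v: np.ndarray
    q: np.ndarray             # exchange rate, 1/s per bulk volume
    node_pressure: dict       # side -> array over nodes
    edge_flux: dict           # side -> signed flux along edge orientation, m^3/s
    terminal_flux: dict       # side -> list of (node, cell_idx array, flux array)
    root_flux: dict           # side -> {root node: signed outgoing flux, m^3/s}
    cell_volume: float
    faces: tuple = None       # (lo, hi) dense-index face arrays
    face_T: dict = None       # side -> face transmissibility array

    @property
    def total_exchange(self) -> float:
        act = self.mesh.active
        return float(np.nansum(self.q[act]) * self.cell_volume)

    @property
    def total_root_inflow(self) -> float:
        return float(sum(self.root_flux["artery"].values()))

    @property
    def total_root_outflow(self) -> float:
        return float(-sum(self.root_flux["vein"].values()))

    def true_perfusion(self) -> np.ndarray:
        """True perfusion map, mL/min/100mL (NaN outside the active domain)."""
        return self.q * PERFUSION_UNIT


def solve_hybrid_flow(arterial: VesselNetwork, venous: VesselNetwork,
                      mesh: Mesh, K_a: float, K_v: float, K_c: np.ndarray,
                      bc: BoundaryConditions, kernel: TerminalKernel,
                      coupling: float, mu: float = 3e-3,
                      thickness: float = 5e-4) -> HybridFlow:
    """Monolithic solve for continuum cell and network node pressures.

    Edge fluxes follow Poiseuille, Q = pi r^4 dp / (8 mu L); terminal fluxes
    are ``coupling`` times the node-to-continuum pressure difference,
    distributed by the kernel; the continuums exchange with per-cell
    conductance (K_c/mu) V.
    """
    n = mesh.n_active
    h = mesh.cell_size
    V = h * h * thickness
    na, nv = arterial.n_nodes, venous.n_nodes
    NU = 2 * n + na + nv
    off_a, off_v = 2 * n, 2 * n + na

    K_c = np.asarray(K_c, dtype=float)
    E = (K_c[mesh.active] / mu) * V

    rows, cols, vals = [], [], []
    b = np.zeros(NU)

    def add(r, c, v):
        r, c, v = np.broadcast_arrays(np.atleast_1d(r), np.atleast_1d(c),
                                      np.atleast_1d(v))
        rows.append(r); cols.append(c); vals.append(v.astype(float))

    # continuum Darcy faces (scalar permeabilities)
    lo, hi, axis, _ = _faces(mesh)
    Tf_a = thickness * (K_a / mu) * np.ones(lo.size)
    Tf_v = thickness * (K_v / mu) * np.ones(lo.size)
    for T, off in ((Tf_a, 0), (Tf_v, n)):
        add(lo + off, lo + off, T); add(lo + off, hi + off, -T)
        add(hi + off, hi + off, T); add(hi + off, lo + off, -T)
    # exchange
    cells = np.arange(n)
    add(cells, cells, E); add(cells, cells + n, -E)
    add(cells + n, cells + n, E); add(cells + n, cells, -E)

    term_maps = {"artery": [], "vein": []}
    for net, off_net, off_cont in ((arterial, off_a, 0), (venous, off_v, n)):
        g = math.pi * net.radius ** 4 / (8.0 * mu * np.maximum(net.length, 1e-12))
        for e, (n1, n2) in enumerate(net.edges):
            if not net.is_root[n1]:
                add(off_net + n1, off_net + n1, g[e]); add(off_net + n1, off_net + n2, -g[e])
            if not net.is_root[n2]:
                add(off_net + n2, off_net + n2, g[e]); add(off_net + n2, off_net + n1, -g[e])
        for k in np.nonzero(net.is_terminal)[0]:
            cidx, w = kernel.weights(mesh, net.nodes[k])
            lam = coupling * w
            term_maps[net.side].append((int(k), cidx, lam))
            if not net.is_root[k]:
                add(off_net + k, off_net + k, lam.sum())
                add(off_net + k, off_cont + cidx, -lam)
            add(off_cont + cidx, off_cont + cidx, lam)
            add(off_cont + cidx, np.full(cidx.size, off_net + k), -lam)
        # root Dirichlet
        for k in np.nonzero(net.is_root)[0]:
            add(off_net + k, off_net + k, 1.0)
            b[off_net + k] = bc.p_a0 if net.side == "artery" else bc.p_v0

    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(NU, NU))
    # detect isolated unknowns (no couplings at all)
    diag = A.diagonal()
    if np.any(diag == 0):
        k = int(np.nonzero(diag == 0)[0][0])
        raise RuntimeError(f"singular hybrid system: unknown #{k} is isolated")
    x = spla.spsolve(A.tocsc(), b)

    pca, pcv = x[:n], x[n:2 * n]
    pna, pnv = x[off_a:off_a + na], x[off_v:]
    qcell = E * (pca - pcv) / V

    edge_flux = {}
    terminal_flux = {}
    root_flux = {}
    for net, pn, side in ((arterial, pna, "artery"), (venous, pnv, "vein")):
        g = math.pi * net.radius ** 4 / (8.0 * mu * np.maximum(net.length, 1e-12))
        edge_flux[side] = g * (pn[net.edges[:, 0]] - pn[net.edges[:, 1]])
        pc = pca if side == "artery" else pcv
        tf = []
        for (k, cidx, lam) in term_maps[side]:
            tf.append((k, cidx, lam * (pn[k] - pc[cidx])))
        terminal_flux[side] = tf
        # per-root signed outgoing (into the tree) flux
        rf = {}
        for k in np.nonzero(net.is_root)[0]:
            tot = 0.0
            for e, (n1, n2) in enumerate(net.edges):
                if n1 == k:
                    tot += edge_flux[side][e]
                elif n2 == k:
                    tot -= edge_flux[side][e]
            rf[int(k)] = float(tot)
        root_flux[side] = rf

    sc = lambda v: _scatter(mesh, v)
    return HybridFlow(mesh, sc(pca), sc(pcv), sc(qcell),
                      {"artery": pna, "vein": pnv}, edge_flux, terminal_flux,
                      root_flux, V, faces=(lo, hi),
                      face_T={"artery": Tf_a, "vein": Tf_v})


def _faces(mesh: Mesh):
    idx = mesh.cell_index
    a = mesh.active
    mx = a[:-1, :] & a[1:, :]
    ii, jj = np.nonzero(mx)
    lo = [idx[ii, jj]]; hi = [idx[ii + 1, jj]]; ax = [np.zeros(ii.size, dtype=np.int8)]
    my = a[:, :-1] & a[:, 1:]
    ii, jj = np.nonzero(my)
    lo.append(idx[ii, jj]); hi.append(idx[ii, jj + 1]); ax.append(np.ones(ii.size, dtype=np.int8))
    return np.concatenate(lo), np.concatenate(hi), np.concatenate(ax), None


def _scatter(mesh: Mesh, vec: np.ndarray) -> np.ndarray:
    out = np.full((mesh.nx, mesh.ny), np.nan)
    out[mesh.active] = vec
    return out


# ---------------------------------------------------------------------------
# implicit tracer advection

def hybrid_advect(hflow: HybridFlow, arterial: VesselNetwork,
                  venous: VesselNetwork, aif: np.ndarray, times: np.ndarray,
                  phi_a: float = 0.05, phi_v: float = 0.1,
                  vessel_volume: np.ndarray | None = None):
    """Backward-Euler upwind advection of contrast over the hybrid model.

    Control volumes: network edges (blood volume pi r^2 L), network nodes
    (zero volume, pure mixing), and continuum cells (blood volumes
    phi_a V and phi_v V).  Root inflow carries the AIF concentration.

    Returns a dict with per-time concentration grids ``c_total`` (nt, nx, ny)
    — the porosity-weighted continuum concentrations plus the intravascular
    contribution of rasterized vessel segments — and the advection state
    arrays plus a mass-balance audit (inflow, outflow, stored).
    """
    mesh = hflow.mesh
    n = mesh.n_active
    ma, mv = arterial.edges.shape[0], venous.edges.shape[0]
    na, nv = arterial.n_nodes, venous.n_nodes
    # unknown layout: [a-nodes, a-edges, cont-a, cont-v, v-edges, v-nodes]
    off = {}
    off["an"] = 0
    off["ae"] = na
    off["ca"] = na + ma
    off["cv"] = na + ma + n
    off["ve"] = na + ma + 2 * n
    off["vn"] = na + ma + 2 * n + mv
    NU = off["vn"] + nv

    vol = np.zeros(NU)
    V = hflow.cell_volume
    vol[off["ae"]:off["ae"] + ma] = math.pi * arterial.radius ** 2 * arterial.length
    vol[off["ve"]:off["ve"] + mv] = math.pi * venous.radius ** 2 * venous.length
    vol[off["ca"]:off["ca"] + n] = phi_a * V
    vol[off["cv"]:off["cv"] + n] = phi_v * V

    conns = []      # (src, dst, flux) directed, internal
    ext_in = []     # (dst, flux) carrying AIF concentration
    ext_out = []    # (src, flux)

    for net, oe, onode, side in ((arterial, off["ae"], off["an"], "artery"),
                                 (venous, off["ve"], off["vn"], "vein")):
        ef = hflow.edge_flux[side]
        for e, (n1, n2) in enumerate(net.edges):
            f = ef[e]
            if f >= 0:
                conns.append((onode + n1, oe + e, f))
                conns.append((oe + e, onode + n2, f))
            else:
                conns.append((onode + n2, oe + e, -f))
                conns.append((oe + e, onode + n1, -f))
        ocont = off["ca"] if side == "artery" else off["cv"]
        for (k, cidx, fl) in hflow.terminal_flux[side]:
            for c, f in zip(cidx, fl):
                if f >= 0:
                    conns.append((onode + k, ocont + c, f))
                else:
                    conns.append((ocont + c, onode + k, -f))
        for k, rf in hflow.root_flux[side].items():
            if rf >= 0:   # flow enters the tree at this root
                ext_in.append((onode + k, rf))
            else:         # flow leaves the system at this root
                ext_out.append((onode + k, -rf))

    # continuum faces and exchange
    lo, hi = hflow.faces
    act = mesh.active
    qvol = hflow.q[act] * V
    for c in range(n):
        f = qvol[c]
        if f >= 0:
            conns.append((off["ca"] + c, off["cv"] + c, f))
        else:
            conns.append((off["cv"] + c, off["ca"] + c, -f))

    conns_faces = _continuum_face_conns(hflow, lo, hi, off)
    conns.extend(conns_faces)

    src = np.array([c[0] for c in conns], dtype=np.int64)
    dst = np.array([c[1] for c in conns], dtype=np.int64)
    f = np.array([c[2] for c in conns])

    times = np.asarray(times, dtype=float)
    dt = times[1] - times[0]
    diag = vol / dt
    np.add.at(diag, src, f)
    for (s, fo) in ext_out:
        diag[s] += fo
    rowsum = diag.copy()
    A = sp.csr_matrix((np.concatenate([diag, -f]),
                       (np.concatenate([np.arange(NU), dst]),
                        np.concatenate([np.arange(NU), src]))),
                      shape=(NU, NU))
    # zero-throughput zero-volume rows: pin to zero concentration
    dead = np.asarray(A.diagonal() <= 0).ravel()
    if dead.any():
        d2 = A.diagonal(); d2[dead] = 1.0
        A = A.tolil()
        for k in np.nonzero(dead)[0]:
            A.rows[k] = [int(k)]; A.data[k] = [1.0]
        A = A.tocsr()
    lu = spla.splu(A.tocsc())

    nt = times.size
    c = np.zeros(NU)
    c_cont_a = np.zeros((nt, n))
    c_cont_v = np.zeros((nt, n))
    c_edges = {"artery": np.zeros((nt, ma)), "vein": np.zeros((nt, mv))}
    inflow_mass = 0.0
    outflow_mass = 0.0
    for it in range(1, nt):
        b = vol / dt * c
        for (d, fi) in ext_in:
            b[d] += fi * aif[it]
        c = lu.solve(b)
        c_cont_a[it] = c[off["ca"]:off["ca"] + n]
        c_cont_v[it] = c[off["cv"]:off["cv"] + n]
        c_edges["artery"][it] = c[off["ae"]:off["ae"] + ma]
        c_edges["vein"][it] = c[off["ve"]:off["ve"] + mv]
        for (d, fi) in ext_in:
            inflow_mass += fi * aif[it] * dt
        for (s, fo) in ext_out:
            outflow_mass += fo * c[s] * dt
    stored = float((vol * c).sum())

    # total observable concentration on the fine grid
    c_total = np.zeros((nt, mesh.nx, mesh.ny))
    phi_tot = np.zeros((mesh.nx, mesh.ny))
    c_total[:, act] = phi_a * c_cont_a + phi_v * c_cont_v
    if vessel_volume is not None:
        frac = np.minimum(vessel_volume / V, 0.8)
        vgrid = np.zeros((nt, mesh.nx, mesh.ny))
        # deposit edge concentrations weighted by local vessel volume share
        for net, side in ((arterial, "artery"), (venous, "vein")):
            for e, (n1, n2) in enumerate(net.edges):
                p1, p2 = net.nodes[n1], net.nodes[n2]
                h = mesh.cell_size
                nsmp = max(int(net.length[e] / (0.4 * h)), 2)
                ts = (np.arange(nsmp) + 0.5) / nsmp
                pts = p1[None, :] + ts[:, None] * (p2 - p1)[None, :]
                ii = np.clip((pts[:, 0] / h).astype(int), 0, mesh.nx - 1)
                jj = np.clip((pts[:, 1] / h).astype(int), 0, mesh.ny - 1)
                cells = np.unique(ii * mesh.ny + jj)
                ci, cj = cells // mesh.ny, cells % mesh.ny
                vgrid[:, ci, cj] = np.maximum(vgrid[:, ci, cj],
                                              c_edges[side][:, e][:, None])
        c_total = c_total + frac[None, :, :] * vgrid
    c_total[:, ~act] = 0.0

    return dict(c_total=c_total, c_cont_a=c_cont_a, c_cont_v=c_cont_v,
                c_edges=c_edges, inflow_mass=inflow_mass,
                outflow_mass=outflow_mass, stored_mass=stored)


def _continuum_face_conns(hflow: HybridFlow, lo, hi, off):
    """Directed upwind connections for continuum face fluxes."""
    conns = []
    act = hflow.mesh.active
    for pvec, T, o in ((hflow.p_cont_a[act], hflow.face_T["artery"], off["ca"]),
                       (hflow.p_cont_v[act], hflow.face_T["vein"], off["cv"])):
        fl = T * (pvec[lo] - pvec[hi])
        for k in range(lo.size):
            f = fl[k]
            if f > 0:
                conns.append((o + lo[k], o + hi[k], f))
            elif f < 0:
                conns.append((o + hi[k], o + lo[k], -f))
    return conns


# ---------------------------------------------------------------------------
# observations

@dataclass
class ObservationSet:
    """Noisy, upscaled, time-subsampled concentration observations.

    ``values`` has shape (n_selected_times, cnx, cny); ``sigma`` is the
    measurement-error standard deviation (a fixed fraction of the maximum
    observed concentration); noise is independent Gaussian, clipped at zero.
    """

    time_indices: np.ndarray
    values: np.ndarray
    clean: np.ndarray
    sigma: float
    noise_fraction: float
    seed: int
    factor: int
    coarse_active: np.ndarray

    def vector(self) -> np.ndarray:
        """Time-major observation vector over active coarse cells."""
        return self.values[:, self.coarse_active].ravel()


def make_observations(series: np.ndarray, factor: int, noise_fraction: float,
                      seed: int, active: np.ndarray | None = None,
                      time_indices=None) -> ObservationSet:
    """Upscale a fine (nt, nx, ny) series by block averaging, subsample the
    given time indices and add clipped Gaussian noise with standard deviation
    ``noise_fraction`` times the maximum coarse concentration."""
    if factor < 1:
        raise ValueError("upscaling factor must be >= 1")
    if noise_fraction < 0:
        raise ValueError("noise fraction must be >= 0")
    coarse, cact = geo.coarsen_series(series, factor, active)
    nt = coarse.shape[0]
    if time_indices is None:
        time_indices = np.arange(nt)
    time_indices = np.asarray(sorted(time_indices), dtype=np.int64)
    clean = coarse[time_indices]
    sigma = float(noise_fraction * coarse.max())
    rng = np.random.default_rng(seed)
    if sigma > 0:
        noisy = np.clip(clean + sigma * rng.standard_normal(clean.shape), 0.0, None)
    else:
        noisy = clean.copy()
    noisy[:, ~cact] = 0.0
    return ObservationSet(time_indices, noisy, clean, sigma, noise_fraction,
                          seed, factor, cact)


def greedy_doptimal_times(series: np.ndarray, n_p: int,
                          psd_tol: float = 1e-8) -> np.ndarray:
    """Greedy D-optimal selection of observation time points.

    ``series`` has shape (n_cells, n_t); each time point's image is one
    vector of a stochastic variable, and C = Cov(x_i, x_j) is the time-point
    covariance.  The first index maximizes the diagonal of C; each further
    index maximizes det C_II.  Determinant growth is tracked through a
    rank-one Cholesky extension.  Returns the sorted index set.
    """
    X = np.asarray(series, dtype=float)
    C = np.atleast_2d(np.cov(X, rowvar=False))
    return greedy_doptimal_from_cov(C, n_p, psd_tol)


def greedy_doptimal_from_cov(C: np.ndarray, n_p: int,
                             psd_tol: float = 1e-8) -> np.ndarray:
    """Greedy D-optimal subset selection from an explicit covariance matrix."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n_t = C.shape[0]
    if not (1 <= n_p <= n_t):
        raise ValueError("n_p must satisfy 1 <= n_p <= n_t")
    scale = np.abs(np.diag(C)).max()
    if scale > 0:
        w = np.linalg.eigvalsh(C)
        if w.min() < -psd_tol * scale:
            raise ValueError(f"covariance is not PSD within tolerance (min eig {w.min():.3e})")
    chosen = [int(np.argmax(np.diag(C)))]
    L = np.array([[math.sqrt(max(C[chosen[0], chosen[0]], 0.0))]])
    eps = 1e-300
    while len(chosen) < n_p:
        best, best_s, best_v = -1, -np.inf, None
        rows = np.array(chosen)
        for k in range(n_t):
            if k in chosen:
                continue
            v = solve_triangular(L, C[rows, k], lower=True)
            s = C[k, k] - v @ v  # det ratio (Schur complement)
            if s > best_s:
                best, best_s, best_v = k, s, v
        chosen.append(best)
        m = L.shape[0]
        L2 = np.zeros((m + 1, m + 1))
        L2[:m, :m] = L
        L2[m, :m] = best_v
        L2[m, m] = math.sqrt(max(best_s, eps))
        L = L2
    return np.array(sorted(chosen), dtype=np.int64)


# ---------------------------------------------------------------------------
# end-to-end synthetic-truth experiment

@dataclass
class TruthConfig:
    """Study conditions of the synthetic-truth experiment.

    Defaults mirror the hybrid-model experimental setup: porosities
    phi_a = 0.05, phi_v = 0.1, permeabilities K_a = 1e-13, K_v = 5e-13 m^2,
    true capillary conductivity 3e-9 m^2, boundary pressures 10.6/1.60 kPa,
    150 s horizon sampled every second with one-tenth of the time points
    selected greedily, and 10% observation noise.
    """

    fine_nx: int = 256
    fine_ny: int = 316
    domain_x: float = 0.032   # m
    domain_y: float = 0.040   # m
    upscale: int = 2
    phi_a: float = 0.05
    phi_v: float = 0.1
    K_a: float = 1e-13
    K_v: float = 5e-13
    K_c_true: float = 3e-9
    mu: float = 3e-3
    p_a0: float = 10600.0
    p_v0: float = 1600.0
    thickness: float = 5e-4
    horizon: float = 150.0
    dt: float = 1.0
    time_fraction: int = 10   # keep floor(n_t / time_fraction) time points
    noise_fraction: float = 0.1
    aif_amplitude: float = 5.0
    aif_t0: float = 5.0
    aif_alpha: float = 3.0
    aif_beta: float = 6.0
    network_depth: int = 6
    root_radius: float = 1.5e-4
    trunk_length: float = 8e-3
    length_ratio: float = 0.75
    kernel_eps: float = 2e-3
    terminal_coupling: float = 4e-15
    artery_root_x: float = 0.375  # fraction of domain width
    vein_root_x: float = 0.625


def twin_config(**overrides) -> TruthConfig:
    """Desk-scale configuration: 64x80 fine grid with 2x2 upscaling."""
    kw = dict(fine_nx=64, fine_ny=80, network_depth=5)
    kw.update(overrides)
    return TruthConfig(**kw)


@dataclass
class SyntheticDataset:
    """Everything the assimilation exercise needs, generated from one seed."""

    config: TruthConfig
    seed: int
    fine_mesh: Mesh
    est_mesh: Mesh
    arterial: VesselNetwork
    venous: VesselNetwork
    hflow: HybridFlow
    times: np.ndarray
    aif: np.ndarray
    true_perfusion_fine: np.ndarray
    true_perfusion_coarse: np.ndarray
    observations: ObservationSet
    advect: dict


def _estimation_mesh(fine: Mesh, factor: int, diam: np.ndarray,
                     arterial: VesselNetwork, venous: VesselNetwork) -> Mesh:
    """Derive the coarse estimation mesh (labels, diameters, inlets/outlets)
    from the fine truth mesh."""
    cact = geo.coarsen_field(np.ones((fine.nx, fine.ny)), factor, fine.active)[1]
    cnx, cny = cact.shape
    h = fine.cell_size * factor
    label = np.zeros((cnx, cny), dtype=np.int8)
    cdiam = np.zeros((cnx, cny))
    for code in (ARTERY, VEIN):
        cnt, _ = geo.coarsen_field((fine.vessel_label == code).astype(float),
                                   factor, fine.active)
        take = (cnt > 0) & ((label == 0) | (cnt > 0.5))
        label[take & (label == 0)] = code
    dmax = np.zeros((cnx, cny))
    for bi in range(factor):
        for bj in range(factor):
            blk = diam[bi::factor, bj::factor]
            dmax[:blk.shape[0], :blk.shape[1]] = np.maximum(
                dmax[:blk.shape[0], :blk.shape[1]], blk)
    inlets, outlets = [], []
    for net, code, bucket in ((arterial, ARTERY, inlets), (venous, VEIN, outlets)):
        for k in np.nonzero(net.is_root)[0]:
            i = int(np.clip(net.nodes[k][0] / h, 0, cnx - 1))
            j = int(np.clip(net.nodes[k][1] / h, 0, cny - 1))
            label[i, j] = code
            if dmax[i, j] == 0:
                dmax[i, j] = 2 * net.radius[0]
            bucket.append((i, j))
    return geo.build_mesh(cnx, cny, h, cact, label, inlets, outlets,
                          vessel_diameter=dmax)


def run_truth_experiment(config: TruthConfig | None = None,
                         seed: int = 0) -> SyntheticDataset:
    """Generate the full synthetic dataset: phantom vasculature, hybrid flow,
    implicit tracer transport, true perfusion maps, and the noisy upscaled
    observation set at greedily selected time points."""
    cfg = config or TruthConfig()
    h = cfg.domain_x / cfg.fine_nx
    ny = cfg.fine_ny
    fine = Mesh(cfg.fine_nx, ny, h,
                np.ones((cfg.fine_nx, ny), dtype=bool),
                np.zeros((cfg.fine_nx, ny), dtype=np.int8))
    ss = np.random.SeedSequence(seed)
    s_art, s_vein, s_noise = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    arterial = generate_phantom_network(
        fine, s_art, cfg.network_depth,
        (cfg.artery_root_x * cfg.domain_x, 0.0), "artery",
        root_radius=cfg.root_radius, trunk_length=cfg.trunk_length,
        length_ratio=cfg.length_ratio)
    venous = generate_phantom_network(
        fine, s_vein, cfg.network_depth,
        (cfg.vein_root_x * cfg.domain_x, 0.0), "vein",
        root_radius=1.3 * cfg.root_radius, trunk_length=cfg.trunk_length,
        length_ratio=cfg.length_ratio)

    label, diam, vvol = rasterize_networks(fine, (arterial, venous))
    fine.vessel_label = label
    fine.vessel_diameter = diam

    # true capillary conductivity: uniform in tissue, zero in the large
    # vessels so the true perfusion map vanishes there
    K_c = np.full((fine.nx, fine.ny), cfg.K_c_true)
    K_c[label != 0] = 0.0

    bc = BoundaryConditions(cfg.p_a0, cfg.p_v0)
    kernel = TerminalKernel(cfg.kernel_eps)
    hflow = solve_hybrid_flow(arterial, venous, fine, cfg.K_a, cfg.K_v, K_c,
                              bc, kernel, cfg.terminal_coupling, cfg.mu,
                              cfg.thickness)

    times = np.arange(0.0, cfg.horizon, cfg.dt)
    aif = gamma_variate_aif(cfg.aif_amplitude, cfg.aif_t0, cfg.aif_alpha,
                            cfg.aif_beta, times)
    adv = hybrid_advect(hflow, arterial, venous, aif, times,
                        cfg.phi_a, cfg.phi_v, vessel_volume=vvol)

    coarse_all, cact = geo.coarsen_series(adv["c_total"], cfg.upscale, fine.active)
    n_p = times.size // cfg.time_fraction
    sel = greedy_doptimal_times(coarse_all[:, cact].T, n_p)
    obs = make_observations(adv["c_total"], cfg.upscale, cfg.noise_fraction,
                            s_noise, fine.active, time_indices=sel)

    est_mesh = _estimation_mesh(fine, cfg.upscale, diam, arterial, venous)

    P_fine = hflow.true_perfusion()
    P_fine = np.where(fine.active, np.nan_to_num(P_fine), np.nan)
    Pc, _ = geo.coarsen_field(np.nan_to_num(P_fine), cfg.upscale, fine.active)
    Pc = np.where(est_mesh.active, Pc, np.nan)

    return SyntheticDataset(cfg, seed, fine, est_mesh, arterial, venous,
                            hflow, times, aif, P_fine, Pc, obs, adv)
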