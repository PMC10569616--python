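"""Dual-compartment porous-media blood-flow model used for parameter estimation.

Arterial and venous compartments each obey Darcy's law on the active cells of
a Cartesian mesh; a capillary compartment with throughput conductivity K_c
couples them through the exchange flux

    q(x) = (K_c(x) / mu) * (p_a(x) - p_v(x))      [1/s, per bulk volume]

which is interpreted directly as the local perfusion.  Pressures are obtained
from a five-point finite-volume discretization assembled monolithically over
both compartments.  Contrast-agent transport is advective: because the
discretization obeys a discrete maximum principle, the flux graph of each
compartment is acyclic and concentrations can be propagated cell by cell from
the most upstream cell, using per-cell lumped transit times
dtau_a = V phi_a / F_a_up, dtau_c = phi_c / q, dtau_v = V phi_v / F_v_dn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh, BoundaryConditions

#: unit conversion: a volumetric exchange rate of 1 (m^3 blood / m^3 tissue / s)
#: equals 6000 mL blood / min / 100 mL tissue.
PERFUSION_UNIT = 6000.0

_FLUX_TOL = 1e-13  # relative flux pruning threshold for the upstream graph


class SingularSystemError(RuntimeError):
    """Pressure system is singular (a connected component lacks a Dirichlet cell)."""


@dataclass
class ParameterFields:
    """The eight spatial parameter fields of the estimation model.

    Porosities are dimensionless; permeabilities in m^2; ``K_c`` carries a
    nominal m^2 label, the exchange flux (K_c/mu)(p_a - p_v) being read
    directly as a rate per bulk volume (1/s).  All arrays are (nx, ny);
    values on inactive cells are ignored.
    """

    phi_a: np.ndarray
    phi_v: np.ndarray
    phi_c: np.ndarray
    K_ax: np.ndarray
    K_ay: np.ndarray
    K_vx: np.ndarray
    K_vy: np.ndarray
    K_c: np.ndarray
    mu: float = 3e-3  # blood viscosity, Pa s

    def validate(self, active: np.ndarray) -> None:
        for name in ("phi_a", "phi_v", "phi_c"):
            v = getattr(self, name)[active]
            if np.any(v <= 0) or np.any(v >= 1):
                raise ValueError(f"{name} must lie in (0, 1) on active cells")
        for name in ("K_ax", "K_ay", "K_vx", "K_vy", "K_c"):
            if np.any(getattr(self, name)[active] < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.mu <= 0:
            raise ValueError("viscosity must be positive")

    @classmethod
    def uniform(cls, mesh: Mesh, phi_a=0.05, phi_v=0.1, phi_c=1e-4,
                K_a=1e-13, K_v=5e-13, K_c=3e-9, mu=3e-3) -> "ParameterFields":
        full = lambda v: np.full((mesh.nx, mesh.ny), float(v))
        return cls(full(phi_a), full(phi_v), full(phi_c),
                   full(K_a), full(K_a), full(K_v), full(K_v), full(K_c), mu)


@dataclass
class FlowSolution:
    """Pressures, face fluxes and exchange rates from a pressure solve.

    ``q`` is in 1/s (rate per bulk volume).  ``faces`` is a dict with arrays
    ``cell_lo``/``cell_hi`` (dense active indices; the face normal points
    lo -> hi along +x or +y), ``flux_a``/``flux_v`` (m^3/s, positive lo->hi).
    ``boundary_in_a`` / ``boundary_out_v`` hold the Dirichlet-cell boundary
    fluxes (m^3/s, >= 0 expected under valid boundary conditions).
    """

    mesh: Mesh
    p_a: np.ndarray
    p_v: np.ndarray
    q: np.ndarray
    faces: dict
    boundary_in_a: np.ndarray   # per active cell, nonzero only on inlets
    boundary_out_v: np.ndarray  # per active cell, nonzero only on outlets
    cell_volume: float
    mass_residual: float        # max per-cell imbalance / total inflow

    @property
    def total_inflow(self) -> float:
        return float(self.boundary_in_a.sum())

    @property
    def total_outflow(self) -> float:
        return float(self.boundary_out_v.sum())

    @property
    def total_exchange(self) -> float:
        act = self.mesh.active
        return float(np.sum(self.q[act]) * self.cell_volume)


def capillary_exchange(K_c: np.ndarray, mu: float, p_a: np.ndarray,
                       p_v: np.ndarray) -> np.ndarray:
    """Exchange rate q = (K_c / mu) (p_a - p_v), in 1/s per bulk volume."""
    return (K_c / mu) * (p_a - p_v)


def _face_arrays(mesh: Mesh):
    """Internal faces between pairs of active cells, as dense-index arrays."""
    idx = mesh.cell_index
    lo, hi, axis = [], [], []
    a = mesh.active
    # x-faces
    mx = a[:-1, :] & a[1:, :]
    ii, jj = np.nonzero(mx)
    lo.append(idx[ii, jj]); hi.append(idx[ii + 1, jj]); axis.append(np.zeros(ii.size, dtype=np.int8))
    # y-faces
    my = a[:, :-1] & a[:, 1:]
    ii, jj = np.nonzero(my)
    lo.append(idx[ii, jj]); hi.append(idx[ii, jj + 1]); axis.append(np.ones(ii.size, dtype=np.int8))
    return (np.concatenate(lo), np.concatenate(hi), np.concatenate(axis),
            (np.nonzero(mx), np.nonzero(my)))


def _harmonic(a, b):
    s = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(s > 0, 2.0 * a * b / np.where(s > 0, s, 1.0), 0.0)
    return h


def solve_pressure(mesh: Mesh, params: ParameterFields, bc: BoundaryConditions,
                   thickness: float = 1.0) -> FlowSolution:
    """Solve the coupled (p_a, p_v) finite-volume system monolithically.

    Face transmissibilities are harmonic means of the neighboring cells'
    directional K/mu times the face geometric factor (slab ``thickness`` for
    square cells).  Dirichlet pressures are imposed on inlet (arterial) and
    outlet (venous) cells; all other external faces are no-flow.

    Raises
    ------
    SingularSystemError
        If a connected component of the coupled system contains no
        Dirichlet cell.
    """
    n = mesh.n_active
    idx = mesh.cell_index
    act = mesh.active
    mu = params.mu
    h = mesh.cell_size
    V = h * h * thickness

    lo, hi, axis, _ = _face_arrays(mesh)
    ij = mesh.active_ij
    Tax = (params.K_ax[act] / mu)
    Tay = (params.K_ay[act] / mu)
    Tvx = (params.K_vx[act] / mu)
    Tvy = (params.K_vy[act] / mu)

    Ta_face = thickness * np.where(axis == 0,
                                   _harmonic(Tax[lo], Tax[hi]),
                                   _harmonic(Tay[lo], Tay[hi]))
    Tv_face = thickness * np.where(axis == 0,
                                   _harmonic(Tvx[lo], Tvx[hi]),
                                   _harmonic(Tvy[lo], Tvy[hi]))
    E = (params.K_c[act] / mu) * V  # exchange conductance per cell, m^3/(Pa s)

    inlet_idx = np.array([idx[i, j] for (i, j) in mesh.inlet_cells], dtype=np.int64)
    outlet_idx = np.array([idx[i, j] for (i, j) in mesh.outlet_cells], dtype=np.int64)
    dir_a = np.zeros(n, dtype=bool); dir_a[inlet_idx] = True
    dir_v = np.zeros(n, dtype=bool); dir_v[outlet_idx] = True

    # singularity diagnosis on the coupled graph
    g_r = np.concatenate([lo, lo + n, np.nonzero(E > 0)[0]])
    g_c = np.concatenate([hi, hi + n, np.nonzero(E > 0)[0] + n])
    g = sp.coo_matrix((np.ones(g_r.size), (g_r, g_c)), shape=(2 * n, 2 * n))
    ncomp, labels = sp.csgraph.connected_components(g, directed=False)
    has_dir = np.zeros(ncomp, dtype=bool)
    has_dir[labels[inlet_idx]] = True
    has_dir[labels[outlet_idx + n]] = True
    if not has_dir.all():
        bad = int(np.nonzero(~has_dir)[0][0])
        members = np.nonzero(labels == bad)[0]
        comp = "arterial" if members[0] < n else "venous"
        raise SingularSystemError(
            f"connected component #{bad} ({comp} side, {members.size} unknowns) "
            "has no Dirichlet pressure cell"
        )

    # assemble: rows for free unknowns; Dirichlet rows are identity
    R, C, Vv = [], [], []
    b = np.zeros(2 * n)

    def add(r, c, v):
        R.append(r); C.append(c); Vv.append(v)

    # face couplings, skipping rows of Dirichlet cells
    for T, off, dmask in ((Ta_face, 0, dir_a), (Tv_face, n, dir_v)):
        for (u, w) in ((lo, hi), (hi, lo)):
            m = ~dmask[u]
            add(u[m] + off, u[m] + off, T[m])
            add(u[m] + off, w[m] + off, -T[m])
    # exchange coupling
    cells = np.arange(n)
    ma = ~dir_a
    add(cells[ma], cells[ma], E[ma])
    add(cells[ma], cells[ma] + n, -E[ma])
    mv = ~dir_v
    add(cells[mv] + n, cells[mv] + n, E[mv])
    add(cells[mv] + n, cells[mv], -E[mv])
    # Dirichlet rows
    add(inlet_idx, inlet_idx, np.ones(inlet_idx.size))
    b[inlet_idx] = bc.p_a0
    add(outlet_idx + n, outlet_idx + n, np.ones(outlet_idx.size))
    b[outlet_idx + n] = bc.p_v0

    A = sp.csr_matrix((np.concatenate([np.atleast_1d(v) for v in Vv]),
                       (np.concatenate([np.atleast_1d(r) for r in R]),
                        np.concatenate([np.atleast_1d(c) for c in C]))),
                      shape=(2 * n, 2 * n))
    try:
        x = spla.spsolve(A.tocsc(), b)
    except RuntimeError as e:  # pragma: no cover - spsolve failure path
        raise SingularSystemError(str(e)) from e
    pa = x[:n]
    pv = x[n:]

    flux_a = Ta_face * (pa[lo] - pa[hi])
    flux_v = Tv_face * (pv[lo] - pv[hi])
    qcell = E * (pa - pv) / V  # 1/s
    # clean round-off fluxes (exact no-flow systems otherwise leave noise)
    scale = max(np.abs(flux_a).max(initial=0.0), np.abs(flux_v).max(initial=0.0))
    inflow_scale = np.abs(E * (pa - pv)).sum()
    ref = max(inflow_scale, 0.0)
    if ref > 0 and scale > 0:
        flux_a[np.abs(flux_a) < 1e-13 * scale] = 0.0
        flux_v[np.abs(flux_v) < 1e-13 * scale] = 0.0
    elif ref == 0.0:
        # no exchange anywhere: the compartments are stationary
        flux_a[:] = 0.0
        flux_v[:] = 0.0

    # net face divergence per cell
    div_a = np.zeros(n); div_v = np.zeros(n)
    np.add.at(div_a, lo, flux_a); np.add.at(div_a, hi, -flux_a)
    np.add.at(div_v, lo, flux_v); np.add.at(div_v, hi, -flux_v)
    # boundary fluxes close the balance on Dirichlet cells
    boundary_in_a = np.zeros(n)
    boundary_in_a[inlet_idx] = (div_a + E * (pa - pv))[inlet_idx]
    boundary_out_v = np.zeros(n)
    boundary_out_v[outlet_idx] = (-div_v + E * (pa - pv))[outlet_idx]

    resid_a = div_a + E * (pa - pv) - boundary_in_a
    resid_v = div_v - E * (pa - pv) + boundary_out_v
    total_in = max(boundary_in_a.sum(), 1e-300)
    mass_residual = float(max(np.abs(resid_a).max(initial=0.0),
                              np.abs(resid_v).max(initial=0.0)) / total_in)

    to2d = lambda v: _scatter(mesh, v)
    faces = dict(cell_lo=lo, cell_hi=hi, axis=axis, flux_a=flux_a, flux_v=flux_v)
    return FlowSolution(mesh, to2d(pa), to2d(pv), to2d(qcell), faces,
                        boundary_in_a, boundary_out_v, V, mass_residual)


def _scatter(mesh: Mesh, vec: np.ndarray) -> np.ndarray:
    out = np.full((mesh.nx, mesh.ny), np.nan)
    out[mesh.active] = vec
    return out


def perfusion_map(flow: FlowSolution) -> np.ndarray:
    """Perfusion P = q * 6000, in mL/min/100mL (NaN on inactive cells)."""
    return flow.q * PERFUSION_UNIT


# ---------------------------------------------------------------------------
# transit times and tracer advection

@dataclass
class TransitTimes:
    """Per-cell lumped compartment transit times (s), on active-cell vectors.

    Cells with zero throughput in a compartment get dtau = +inf and are
    flagged stagnant for that compartment.
    """

    dtau_a: np.ndarray
    dtau_c: np.ndarray
    dtau_v: np.ndarray
    F_a_up: np.ndarray
    F_v_dn: np.ndarray
    stagnant_a: np.ndarray
    stagnant_c: np.ndarray
    stagnant_v: np.ndarray


def _cell_in_out(flow: FlowSolution, which: str):
    """Per-cell face inflow and outflow sums for one compartment."""
    n = flow.mesh.n_active
    f = flow.faces["flux_" + which]
    lo, hi = flow.faces["cell_lo"], flow.faces["cell_hi"]
    fin = np.zeros(n); fout = np.zeros(n)
    pos = f > 0
    np.add.at(fout, lo[pos], f[pos]); np.add.at(fin, hi[pos], f[pos])
    neg = ~pos
    np.add.at(fout, hi[neg], -f[neg]); np.add.at(fin, lo[neg], -f[neg])
    return fin, fout


def transit_times(mesh: Mesh, params: ParameterFields,
                  flow: FlowSolution) -> TransitTimes:
    """Lumped transit times: dtau_a = V phi_a / F_a_up, dtau_c = phi_c / q,
    dtau_v = V phi_v / F_v_dn."""
    act = mesh.active
    V = flow.cell_volume
    fin_a, _ = _cell_in_out(flow, "a")
    _, fout_v = _cell_in_out(flow, "v")
    F_a_up = fin_a + np.maximum(flow.boundary_in_a, 0.0)
    F_v_dn = fout_v + np.maximum(flow.boundary_out_v, 0.0)
    qv = flow.q[act]

    ref = max(flow.total_inflow, np.abs(qv).max(initial=0.0) * V, 1e-300)
    tol = _FLUX_TOL * ref
    stag_a = F_a_up <= tol
    stag_v = F_v_dn <= tol
    stag_c = qv * V <= tol

    with np.errstate(divide="ignore"):
        dtau_a = np.where(stag_a, np.inf, V * params.phi_a[act] / np.where(stag_a, 1, F_a_up))
        dtau_v = np.where(stag_v, np.inf, V * params.phi_v[act] / np.where(stag_v, 1, F_v_dn))
        dtau_c = np.where(stag_c, np.inf, params.phi_c[act] / np.where(stag_c, 1, qv))
    if np.any(params.phi_a[act] < 0) or np.any(params.phi_v[act] < 0) or np.any(params.phi_c[act] < 0):
        raise ValueError("negative porosity")
    return TransitTimes(dtau_a, dtau_c, dtau_v, F_a_up, F_v_dn, stag_a, stag_c, stag_v)


def topological_order(flow: FlowSolution, which: str = "a",
                      tol_rel: float = _FLUX_TOL) -> np.ndarray:
    """Upstream-to-downstream cell ordering for one compartment's flux graph.

    Fluxes below ``tol_rel`` times the maximum magnitude are pruned before
    ordering; a remaining cycle (possible only through numerical round-off)
    raises ``RuntimeError`` after one stricter pruning retry.
    """
    n = flow.mesh.n_active
    f = flow.faces["flux_" + which]
    lo, hi = flow.faces["cell_lo"], flow.faces["cell_hi"]
    fmax = np.abs(f).max(initial=0.0)
    if fmax == 0.0:
        return np.arange(n)
    for tol in (tol_rel * fmax, 1e-9 * fmax):
        src = np.where(f > tol, lo, hi)
        dst = np.where(f > tol, hi, lo)
        keep = np.abs(f) > tol
        order = _kahn(n, src[keep], dst[keep])
        if order is not None:
            return order
    raise RuntimeError(f"flux graph of compartment '{which}' is cyclic after pruning")


def _kahn(n, src, dst):
    indeg = np.zeros(n, dtype=np.int64)
    np.add.at(indeg, dst, 1)
    order_dst = np.argsort(src, kind="stable")
    sdst = dst[order_dst]
    starts = np.searchsorted(src[order_dst], np.arange(n + 1))
    stack = list(np.nonzero(indeg == 0)[0])
    out = []
    while stack:
        u = stack.pop()
        out.append(u)
        for w in sdst[starts[u]:starts[u + 1]]:
            indeg[w] -= 1
            if indeg[w] == 0:
                stack.append(w)
    if len(out) != n:
        return None
    return np.asarray(out)


def shift_series(series: np.ndarray, shift: float, dt: float) -> np.ndarray:
    """Delay a sampled series: c_out(t) = c_in(t - shift), linear interpolation,
    zero before the first sample."""
    if shift < 0:
        raise ValueError("shift must be nonnegative")
    return _shift_samples(np.asarray(series, dtype=float), shift / dt)


def _shift_samples(c: np.ndarray, w: float) -> np.ndarray:
    n = c.size
    if w == 0.0:
        return c.copy()
    if not np.isfinite(w) or w >= n:
        return np.zeros_like(c)
    return np.interp(np.arange(n, dtype=float) - w, np.arange(n, dtype=float), c, left=0.0)


def _window_average(c: np.ndarray, w: float) -> np.ndarray:
    """Trailing moving average over a window of ``w`` samples (trapezoidal),
    treating the series as zero before the first sample.  w = 0 returns the
    series itself; an infinite window returns zeros."""
    n = c.size
    if w == 0.0:
        return c.copy()
    if not np.isfinite(w):
        return np.zeros_like(c)
    I = np.empty(n)
    I[0] = 0.0
    np.cumsum(0.5 * (c[1:] + c[:-1]), out=I[1:])
    xs = np.arange(n, dtype=float) - w
    np.clip(xs, 0.0, float(n - 1), out=xs)
    f0 = np.minimum(xs.astype(np.int64), n - 2)
    fr = xs - f0
    Ix = I[f0] + c[f0] * fr + 0.5 * (c[f0 + 1] - c[f0]) * fr * fr
    return (I - Ix) / w


@dataclass
class TracerSeries:
    """Sampled compartment concentrations per active cell.

    Arrays are (nt, n_active); ``c_total_vol`` is the porosity-weighted total
    volume concentration phi_a c_a + phi_c c_c + phi_v c_v.
    """

    times: np.ndarray
    c_a_vol: np.ndarray
    c_c_vol: np.ndarray
    c_v_vol: np.ndarray
    c_total_vol: np.ndarray
    c_v_dn: np.ndarray
    stagnant: np.ndarray
    mesh: Mesh = None

    def to_grid(self, name: str = "c_total_vol") -> np.ndarray:
        """(nt, nx, ny) grid view of one concentration field (0 on inactive)."""
        arr = getattr(self, name)
        out = np.zeros((arr.shape[0], self.mesh.nx, self.mesh.ny))
        out[:, self.mesh.active] = arr
        return out


def advect_tracer(mesh: Mesh, params: ParameterFields, flow: FlowSolution,
                  tt: TransitTimes, aif: np.ndarray,
                  times: np.ndarray) -> TracerSeries:
    """Streamline-ordered three-step tracer advection.

    Arterial sweep: flux-weighted upstream mixing (inlets receive the AIF),
    shift by dtau_a, volume average.  Capillary: shift/average of c_a_vol by
    dtau_c.  Venous sweep: mixing of upstream-vein inflow and capillary
    outflow, shift by dtau_v.  Stagnant cells receive zero concentration and
    are flagged.
    """
    times = np.asarray(times, dtype=float)
    aif = np.asarray(aif, dtype=float)
    nt = times.size
    dt = times[1] - times[0]
    n = mesh.n_active
    act = mesh.active
    V = flow.cell_volume
    qvol = flow.q[act] * V  # m^3/s extracted from artery into capillary

    lo, hi = flow.faces["cell_lo"], flow.faces["cell_hi"]

    def upstream_lists(which):
        f = flow.faces["flux_" + which]
        fmax = np.abs(f).max(initial=0.0)
        tol = _FLUX_TOL * fmax
        src = np.where(f > 0, lo, hi)
        dst = np.where(f > 0, hi, lo)
        mag = np.abs(f)
        keep = mag > tol
        src, dst, mag = src[keep], dst[keep], mag[keep]
        o = np.argsort(dst, kind="stable")
        src, dst, mag = src[o], dst[o], mag[o]
        starts = np.searchsorted(dst, np.arange(n + 1))
        return src, mag, starts

    src_a, w_a, st_a = upstream_lists("a")
    src_v, w_v, st_v = upstream_lists("v")
    order_a = topological_order(flow, "a")
    order_v = topological_order(flow, "v")

    c_a_dn = np.zeros((n, nt))
    c_a_vol = np.zeros((n, nt))
    c_c_dn = np.zeros((n, nt))
    c_c_vol = np.zeros((n, nt))
    c_v_dn = np.zeros((n, nt))
    c_v_vol = np.zeros((n, nt))

    bin_a = np.maximum(flow.boundary_in_a, 0.0)

    # arterial sweep
    for u in order_a:
        F = tt.F_a_up[u]
        if tt.stagnant_a[u]:
            continue
        acc = bin_a[u] * aif if bin_a[u] > 0 else None
        s, e = st_a[u], st_a[u + 1]
        if e > s:
            mix = w_a[s:e] @ c_a_dn[src_a[s:e]]
            acc = mix if acc is None else acc + mix
        if acc is None:
            continue
        c_up = acc / F
        wsmp = tt.dtau_a[u] / dt
        c_a_dn[u] = _shift_samples(c_up, wsmp)
        c_a_vol[u] = _window_average(c_up, wsmp)

    # capillary step
    okc = ~tt.stagnant_c
    for u in np.nonzero(okc)[0]:
        wsmp = tt.dtau_c[u] / dt
        c_c_dn[u] = _shift_samples(c_a_vol[u], wsmp)
        c_c_vol[u] = _window_average(c_a_vol[u], wsmp)

    # venous sweep
    for u in order_v:
        if tt.stagnant_v[u]:
            continue
        qin = qvol[u]
        acc = qin * c_c_dn[u] if qin > 0 else None
        Ftot = max(qin, 0.0)
        s, e = st_v[u], st_v[u + 1]
        if e > s:
            mix = w_v[s:e] @ c_v_dn[src_v[s:e]]
            Fin = w_v[s:e].sum()
            acc = mix if acc is None else acc + mix
            Ftot += Fin
        if acc is None or Ftot <= 0:
            continue
        c_up = acc / Ftot
        wsmp = tt.dtau_v[u] / dt
        c_v_dn[u] = _shift_samples(c_up, wsmp)
        c_v_vol[u] = _window_average(c_up, wsmp)

    pa_ = params.phi_a[act][:, None]
    pc_ = params.phi_c[act][:, None]
    pv_ = params.phi_v[act][:, None]
    c_total = pa_ * c_a_vol + pc_ * c_c_vol + pv_ * c_v_vol
    stagnant = tt.stagnant_a & tt.stagnant_v
    return TracerSeries(times, c_a_vol.T.copy(), c_c_vol.T.copy(),
                        c_v_vol.T.copy(), c_total.T.copy(), c_v_dn.T.copy(),
                        stagnant, mesh)


def run_forward(mesh: Mesh, params: ParameterFields, bc: BoundaryConditions,
                aif: np.ndarray, times: np.ndarray,
                thickness: float = 1.0):
    """Full forward model: pressure solve, transit times, tracer advection.

    Returns (flow, transit_times, tracer_series).
    """
    flow = solve_pressure(mesh, params, bc, thickness=thickness)
    tt = transit_times(mesh, params, flow)
    tracer = advect_tracer(mesh, params, flow, tt, aif, times)
    return flow, tt, tracer
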