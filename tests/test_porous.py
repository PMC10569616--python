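import numpy as np
import pytest

import perfusim as pf
from perfusim import porous
from perfusim.geometry import ARTERY, VEIN


def _two_cell_mesh():
    label = np.zeros((2, 1), dtype=np.int8)
    label[0, 0] = ARTERY
    label[1, 0] = VEIN
    return pf.build_mesh(2, 1, 1e-3, None, label, [(0, 0)], [(1, 0)])


class TestSolvePressure:
    def test_two_cell_matches_dense_oracle(self, bc):
        """1x2 coupled system against a hand-assembled dense 4x4 solve."""
        mesh = _two_cell_mesh()
        params = pf.ParameterFields.uniform(mesh, K_a=2e-13, K_v=7e-13, K_c=4e-9)
        flow = pf.solve_pressure(mesh, params, bc)

        mu, h, t = params.mu, mesh.cell_size, 1.0
        Tfa = t * (2e-13 / mu)      # harmonic mean of equal values
        Tfv = t * (7e-13 / mu)
        E = (4e-9 / mu) * h * h * t
        # unknowns [pa0, pa1, pv0, pv1]
        A = np.array([
            [1.0, 0.0, 0.0, 0.0],                       # Dirichlet inlet
            [-Tfa, Tfa + E, 0.0, -E],                   # arterial cell 1
            [0.0, -0.0, 0.0, 0.0],                      # placeholder
            [0.0, 0.0, 0.0, 1.0],                       # Dirichlet outlet
        ])
        A[2] = [-E, 0.0, Tfv + E, -Tfv]                 # venous cell 0
        b = np.array([bc.p_a0, 0.0, 0.0, bc.p_v0])
        pa0, pa1, pv0, pv1 = np.linalg.solve(A, b)
        assert flow.p_a[0, 0] == pytest.approx(pa0, rel=1e-12)
        assert flow.p_a[1, 0] == pytest.approx(pa1, rel=1e-12)
        assert flow.p_v[0, 0] == pytest.approx(pv0, rel=1e-12)
        assert flow.p_v[1, 0] == pytest.approx(pv1, rel=1e-12)

    def test_zero_exchange_gives_inlet_pressure_everywhere(self, bc, chain_mesh):
        params = pf.ParameterFields.uniform(chain_mesh, K_c=0.0)
        flow = pf.solve_pressure(chain_mesh, params, bc)
        assert np.allclose(flow.q[chain_mesh.active], 0.0)
        assert np.allclose(flow.p_a[chain_mesh.active], bc.p_a0)
        assert np.allclose(flow.p_v[chain_mesh.active], bc.p_v0)

    def test_flux_linearity_in_permeability(self, bc, grid_mesh):
        p1 = pf.ParameterFields.uniform(grid_mesh)
        p2 = pf.ParameterFields.uniform(grid_mesh, K_a=2e-13, K_v=1e-12, K_c=6e-9)
        f1 = pf.solve_pressure(grid_mesh, p1, bc)
        f2 = pf.solve_pressure(grid_mesh, p2, bc)
        assert np.allclose(f2.p_a[grid_mesh.active], f1.p_a[grid_mesh.active])
        assert np.allclose(f2.p_v[grid_mesh.active], f1.p_v[grid_mesh.active])
        assert np.allclose(f2.faces["flux_a"], 2 * f1.faces["flux_a"])
        assert np.allclose(f2.faces["flux_v"], 2 * f1.faces["flux_v"])

    def test_mass_conservation(self, bc, grid_mesh, uniform_params):
        flow = pf.solve_pressure(grid_mesh, uniform_params(grid_mesh), bc)
        assert flow.mass_residual < 1e-8
        assert flow.total_inflow == pytest.approx(flow.total_outflow, rel=1e-10)
        assert flow.total_inflow == pytest.approx(flow.total_exchange, rel=1e-10)

    def test_maximum_principle(self, bc, grid_mesh):
        rng = np.random.default_rng(5)
        params = pf.ParameterFields.uniform(grid_mesh)
        params.K_ax = params.K_ax * np.exp(rng.normal(0, 1, params.K_ax.shape))
        params.K_vy = params.K_vy * np.exp(rng.normal(0, 1, params.K_vy.shape))
        flow = pf.solve_pressure(grid_mesh, params, bc)
        act = grid_mesh.active
        for p in (flow.p_a[act], flow.p_v[act]):
            assert p.min() >= bc.p_v0 - 1e-6
            assert p.max() <= bc.p_a0 + 1e-6

    def test_disconnected_component_raises(self, bc):
        # two islands; the right one has no outlet and K_c = 0 decouples it
        mask = np.ones((5, 1), dtype=bool)
        mask[2, 0] = False
        label = np.zeros((5, 1), dtype=np.int8)
        label[0, 0] = ARTERY
        label[1, 0] = VEIN
        mesh = pf.build_mesh(5, 1, 1e-3, mask, label, [(0, 0)], [(1, 0)])
        params = pf.ParameterFields.uniform(mesh)
        with pytest.raises(porous.SingularSystemError, match="component"):
            pf.solve_pressure(mesh, params, bc)


class TestExchangeAndTransit:
    def test_exchange_formula(self):
        q = pf.capillary_exchange(np.array(3e-9), 3e-3, np.array(10000.0),
                                  np.array(1000.0))
        assert q == pytest.approx(9e-3)
        assert pf.capillary_exchange(np.array(1.0), 1.0, np.array(5.0),
                                     np.array(5.0)) == 0.0
        q2 = pf.capillary_exchange(np.array(6e-9), 3e-3, np.array(10000.0),
                                   np.array(1000.0))
        assert q2 == pytest.approx(2 * q)

    def test_capillary_transit_time(self, bc):
        mesh = _two_cell_mesh()
        params = pf.ParameterFields.uniform(mesh, phi_c=1e-4)
        flow = pf.solve_pressure(mesh, params, bc)
        tt = pf.transit_times(mesh, params, flow)
        q = flow.q[mesh.active]
        assert np.allclose(tt.dtau_c, 1e-4 / q)
        # direct example: phi_c = 1e-4, q = 9e-3 -> 0.0111 s
        assert 1e-4 / 9e-3 == pytest.approx(0.0111, rel=1e-2)

    def test_zero_porosity_and_stagnant_contract(self, bc):
        mesh = _two_cell_mesh()
        params = pf.ParameterFields.uniform(mesh, phi_a=1e-12, K_c=0.0)
        flow = pf.solve_pressure(mesh, params, bc)
        tt = pf.transit_times(mesh, params, flow)
        # no exchange -> no flow at all: stagnant everywhere, dtau_c infinite
        assert np.isinf(tt.dtau_c).all()
        assert tt.stagnant_c.all()

    def test_perfusion_unit_conversion(self, bc, chain_mesh, uniform_params):
        flow = pf.solve_pressure(chain_mesh, uniform_params(chain_mesh), bc)
        P = pf.perfusion_map(flow)
        act = chain_mesh.active
        assert np.allclose(P[act], flow.q[act] * 6000.0)
        assert porous.PERFUSION_UNIT * (1.0 / 6000.0) == pytest.approx(1.0)


class TestTopologicalOrder:
    def test_chain_order(self, bc, chain_mesh, uniform_params):
        flow = pf.solve_pressure(chain_mesh, uniform_params(chain_mesh), bc)
        order = pf.topological_order(flow, "a")
        assert order.tolist() == [0, 1, 2, 3]

    def test_no_back_edges_on_random_grid(self, bc, grid_mesh):
        rng = np.random.default_rng(11)
        params = pf.ParameterFields.uniform(grid_mesh)
        for name in ("K_ax", "K_ay"):
            setattr(params, name,
                    getattr(params, name) * np.exp(rng.normal(0, 1.5, (5, 5))))
        flow = pf.solve_pressure(grid_mesh, params, bc)
        order = pf.topological_order(flow, "a")
        pos = np.empty_like(order)
        pos[order] = np.arange(order.size)
        f = flow.faces["flux_a"]
        lo, hi = flow.faces["cell_lo"], flow.faces["cell_hi"]
        tol = 1e-12 * np.abs(f).max()
        for k in range(f.size):
            if f[k] > tol:
                assert pos[lo[k]] < pos[hi[k]]
            elif f[k] < -tol:
                assert pos[hi[k]] < pos[lo[k]]

    def test_zero_flow_returns_index_order(self, bc, chain_mesh):
        params = pf.ParameterFields.uniform(chain_mesh, K_c=0.0)
        flow = pf.solve_pressure(chain_mesh, params, bc)
        order = pf.topological_order(flow, "a")
        assert order.tolist() == list(range(chain_mesh.n_active))


class TestShiftSeries:
    def test_zero_shift_identity(self):
        c = np.array([0.0, 1.0, 0.5, 0.2])
        assert np.array_equal(pf.shift_series(c, 0.0, 1.0), c)

    def test_integer_shift(self):
        c = np.array([0.0, 1.0, 0.0, 0.0])
        assert np.allclose(pf.shift_series(c, 1.0, 1.0), [0, 0, 1, 0])

    def test_half_sample_shift(self):
        assert np.allclose(pf.shift_series(np.array([0.0, 1.0, 0.0]), 0.5, 1.0),
                           [0.0, 0.5, 0.5])

    def test_against_fine_grid_oracle(self):
        """Linear-interpolation shift agrees with shifting a 10x-resolved series."""
        rng = np.random.default_rng(2)
        t = np.arange(20.0)
        c = np.maximum(rng.normal(1.0, 0.5, 20), 0.0)
        shift = 3.7
        coarse = pf.shift_series(c, shift, 1.0)
        tf = np.arange(0.0, 19.0 + 1e-9, 0.1)
        cf = np.interp(tf, t, c)
        fine_shift = np.interp(tf - shift, tf, cf, left=0.0)
        oracle = np.interp(t, tf, fine_shift)
        assert np.allclose(coarse, oracle, atol=1e-9)

    def test_negative_shift_raises(self):
        with pytest.raises(ValueError):
            pf.shift_series(np.zeros(3), -1.0, 1.0)


class TestAdvection:
    times = np.arange(0.0, 120.0, 1.0)

    def _aif(self):
        return pf.gamma_variate_aif(5.0, 5.0, 3.0, 6.0, self.times)

    def test_single_cell_passthrough(self, bc):
        """With negligible transit times c_total -> (phi_a+phi_c+phi_v) AIF."""
        label = np.zeros((2, 1), dtype=np.int8)
        label[0, 0] = ARTERY
        label[1, 0] = VEIN
        mesh = pf.build_mesh(2, 1, 1e-3, None, label, [(0, 0)], [(1, 0)])
        params = pf.ParameterFields.uniform(mesh, phi_a=1e-6, phi_v=1e-6,
                                            phi_c=1e-8, K_a=1e-10, K_v=1e-10,
                                            K_c=1e-6)
        flow, tt, tr = pf.run_forward(mesh, params, bc, self._aif(), self.times)
        assert tt.dtau_a.max() < 1e-3
        phis = 1e-6 + 1e-8 + 1e-6
        assert np.allclose(tr.c_total_vol[:, 0], phis * self._aif(), rtol=1e-3,
                           atol=phis * 1e-3)

    def test_two_cell_chain_delay(self, bc):
        """Unit transit in each cell delays the downstream series by 2 dt."""
        mesh = _two_cell_mesh()
        params = pf.ParameterFields.uniform(mesh, K_c=1e-11)  # weak extraction
        flow = pf.solve_pressure(mesh, params, bc)
        tt = pf.transit_times(mesh, params, flow)
        tt.dtau_a[:] = 1.0  # force unit transits
        aif = self._aif()
        tr = pf.advect_tracer(mesh, params, flow, tt, aif, self.times)
        # downstream arterial output of cell 1 = AIF shifted by 2 dt
        expect = pf.shift_series(aif, 2.0, 1.0)
        # reconstruct cell-1 downstream from internals: shift its c_a_vol window
        # is tested indirectly; compare volume averages instead
        v1 = tr.c_a_vol[:, 1]
        expect_vol = porous._window_average(pf.shift_series(aif, 1.0, 1.0), 1.0)
        assert np.allclose(v1, expect_vol, rtol=1e-6, atol=1e-9)

    def test_tracer_mass_audit(self, bc, grid_mesh):
        """Inflow - outflow - stored balances within 1% after full transit."""
        params = pf.ParameterFields.uniform(grid_mesh, phi_a=0.02, phi_v=0.04,
                                            phi_c=1e-4)
        times = np.arange(0.0, 400.0, 1.0)
        aif = pf.gamma_variate_aif(5.0, 5.0, 3.0, 6.0, times)
        flow, tt, tr = pf.run_forward(grid_mesh, params, bc, aif, times)
        dt = 1.0
        m_in = flow.total_inflow * np.sum(aif) * dt
        act = grid_mesh.active
        out_cells = np.nonzero(flow.boundary_out_v > 0)[0]
        m_out = sum(flow.boundary_out_v[c] * np.sum(tr.c_v_dn[:, c]) * dt
                    for c in out_cells)
        V = flow.cell_volume
        phis = np.stack([params.phi_a[act], params.phi_c[act], params.phi_v[act]])
        stored = V * np.sum(phis[0] * tr.c_a_vol[-1] + phis[1] * tr.c_c_vol[-1]
                            + phis[2] * tr.c_v_vol[-1])
        assert abs(m_in - m_out - stored) / m_in < 0.01

    def test_bounded_by_aif_and_total_identity(self, bc, grid_mesh, uniform_params):
        aif = self._aif()
        params = uniform_params(grid_mesh)
        flow, tt, tr = pf.run_forward(grid_mesh, params, bc, aif, self.times)
        for arr in (tr.c_a_vol, tr.c_c_vol, tr.c_v_vol):
            assert arr.min() >= -1e-12
            assert arr.max() <= aif.max() + 1e-9
        act = grid_mesh.active
        recon = (params.phi_a[act] * tr.c_a_vol + params.phi_c[act] * tr.c_c_vol
                 + params.phi_v[act] * tr.c_v_vol)
        assert np.allclose(recon, tr.c_total_vol, rtol=0, atol=1e-15)

    def test_linearity_in_aif(self, bc, grid_mesh, uniform_params):
        params = uniform_params(grid_mesh)
        aif = self._aif()
        _, _, t1 = pf.run_forward(grid_mesh, params, bc, aif, self.times)
        _, _, t2 = pf.run_forward(grid_mesh, params, bc, 3.0 * aif, self.times)
        assert np.allclose(t2.c_total_vol, 3.0 * t1.c_total_vol, rtol=1e-9,
                           atol=1e-10)
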