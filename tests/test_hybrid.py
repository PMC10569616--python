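import itertools
import math

import numpy as np
import pytest

import perfusim as pf
from perfusim import hybrid
from perfusim.geometry import ARTERY, VEIN


def _plain_mesh(nx=16, ny=20, h=2e-3):
    return hybrid.Mesh(nx, ny, h, np.ones((nx, ny), dtype=bool),
                       np.zeros((nx, ny), dtype=np.int8))


class TestGammaVariate:
    times = np.linspace(0.0, 100.0, 20001)

    def test_zero_before_onset(self):
        c = pf.gamma_variate_aif(5.0, 10.0, 3.0, 6.0, self.times)
        assert np.all(c[self.times <= 10.0] == 0.0)

    def test_peak_location_and_value(self):
        # calculus: argmax of x^a exp(a - x a ... ) occurs at t0 + alpha*beta
        amp, t0, a, b = 4.2, 5.0, 3.0, 6.0
        c = pf.gamma_variate_aif(amp, t0, a, b, self.times)
        k = np.argmax(c)
        assert self.times[k] == pytest.approx(t0 + a * b, abs=0.01)
        assert c[k] == pytest.approx(amp, rel=1e-6)

    def test_zero_amplitude(self):
        assert np.all(pf.gamma_variate_aif(0.0, 5.0, 3.0, 6.0, self.times) == 0.0)

    def test_invalid_shape(self):
        with pytest.raises(ValueError):
            pf.gamma_variate_aif(1.0, 0.0, -1.0, 6.0, self.times)


class TestPhantomNetwork:
    def test_depth_zero_single_edge(self):
        mesh = _plain_mesh()
        net = pf.generate_phantom_network(mesh, 0, 0, (0.016, 0.0))
        assert net.edges.shape[0] == 1
        assert net.is_root.sum() == 1
        assert net.n_terminals == 1

    def test_terminal_count_doubles_per_generation(self):
        mesh = _plain_mesh()
        for depth in (1, 2, 4):
            net = pf.generate_phantom_network(mesh, 3, depth, (0.016, 0.0))
            assert net.n_terminals == 2 ** depth

    def test_seed_determinism(self):
        mesh = _plain_mesh()
        n1 = pf.generate_phantom_network(mesh, 42, 4, (0.016, 0.0))
        n2 = pf.generate_phantom_network(mesh, 42, 4, (0.016, 0.0))
        assert np.array_equal(n1.nodes, n2.nodes)
        assert np.array_equal(n1.radius, n2.radius)

    def test_murray_tapering(self):
        mesh = _plain_mesh()
        net = pf.generate_phantom_network(mesh, 0, 2, (0.016, 0.0),
                                          root_radius=1e-4)
        assert net.radius.min() == pytest.approx(1e-4 * 2 ** (-2 / 3), rel=1e-9)

    def test_excessive_depth_raises(self):
        mesh = _plain_mesh(4, 4)
        with pytest.raises(ValueError):
            pf.generate_phantom_network(mesh, 0, 10, (0.004, 0.0))


class TestHybridFlow:
    def _single_edge_setup(self, coupling):
        mesh = _plain_mesh(8, 8, 2e-3)
        r, L = 1e-4, 6e-3
        nodes = np.array([[0.008, 0.0], [0.008, L]])
        art = hybrid.VesselNetwork("artery", nodes, np.array([[0, 1]]),
                                   np.array([r]), np.array([L]),
                                   np.array([True, False]),
                                   np.array([False, True]))
        vnodes = np.array([[0.012, 0.0], [0.012, L]])
        ven = hybrid.VesselNetwork("vein", vnodes, np.array([[0, 1]]),
                                   np.array([r]), np.array([L]),
                                   np.array([True, False]),
                                   np.array([False, True]))
        bc = pf.BoundaryConditions(10600.0, 1600.0)
        K_c = np.full((8, 8), 3e-9)
        kern = hybrid.TerminalKernel(3e-3)
        return mesh, art, ven, bc, K_c, kern, r, L

    def test_poiseuille_closed_form(self):
        """Edge flux matches Q = pi r^4 dp / (8 mu L) for the solved dp."""
        mesh, art, ven, bc, K_c, kern, r, L = self._single_edge_setup(1e-13)
        hf = hybrid.solve_hybrid_flow(art, ven, mesh, 1e-13, 5e-13, K_c, bc,
                                      kern, 1e-13, mu=3e-3)
        pn = hf.node_pressure["artery"]
        expect = math.pi * r**4 * (pn[0] - pn[1]) / (8 * 3e-3 * L)
        assert hf.edge_flux["artery"][0] == pytest.approx(expect, rel=1e-10)
        # with a strong terminal coupling nearly the full 9 kPa drop is
        # available; flux stays below the open-pipe bound
        qmax = math.pi * r**4 * 9000.0 / (8 * 3e-3 * L)
        assert 0 < hf.edge_flux["artery"][0] < qmax

    def test_zero_coupling_uniform_tree_pressure(self):
        mesh, art, ven, bc, K_c, kern, _, _ = self._single_edge_setup(0.0)
        hf = hybrid.solve_hybrid_flow(art, ven, mesh, 1e-13, 5e-13,
                                      np.zeros((8, 8)), bc, kern, 0.0)
        assert hf.edge_flux["artery"][0] == pytest.approx(0.0, abs=1e-20)
        assert hf.node_pressure["artery"] == pytest.approx(10600.0)
        assert hf.node_pressure["vein"] == pytest.approx(1600.0)

    def test_global_conservation(self, twin_dataset):
        hf = twin_dataset.hflow
        qin, qout, qx = hf.total_root_inflow, hf.total_root_outflow, hf.total_exchange
        assert qin == pytest.approx(qout, rel=1e-8)
        assert qin == pytest.approx(qx, rel=1e-8)

    def test_true_perfusion_zero_in_vessels(self, twin_dataset):
        mesh = twin_dataset.fine_mesh
        P = twin_dataset.true_perfusion_fine
        vessels = mesh.vessel_label != 0
        assert np.allclose(P[vessels & mesh.active], 0.0)


class TestHybridAdvect:
    def test_zero_aif_gives_zero(self, twin_dataset):
        hf = twin_dataset.hflow
        times = np.arange(0.0, 20.0, 1.0)
        adv = hybrid.hybrid_advect(hf, twin_dataset.arterial, twin_dataset.venous,
                                   np.zeros(times.size), times)
        assert adv["c_total"].max() == 0.0

    def test_monotone_bound(self, twin_dataset):
        adv = twin_dataset.advect
        assert adv["c_total"].min() >= -1e-12
        amax = twin_dataset.aif.max()
        assert adv["c_cont_a"].max() <= amax + 1e-9
        assert adv["c_cont_v"].max() <= amax + 1e-9

    def test_mass_audit(self, twin_dataset):
        adv = twin_dataset.advect
        imbalance = abs(adv["inflow_mass"] - adv["outflow_mass"]
                        - adv["stored_mass"]) / adv["inflow_mass"]
        assert imbalance < 0.01


class TestObservations:
    def _series(self, seed=0, nt=8, nx=6, ny=6):
        rng = np.random.default_rng(seed)
        return rng.random((nt, nx, ny))

    def test_noiseless_equals_coarse(self):
        s = self._series()
        obs = pf.make_observations(s, 2, 0.0, seed=1)
        coarse, _ = pf.coarsen_series(s, 2)
        assert np.array_equal(obs.values, coarse)

    def test_seed_reproducibility(self):
        s = self._series()
        o1 = pf.make_observations(s, 2, 0.1, seed=7)
        o2 = pf.make_observations(s, 2, 0.1, seed=7)
        assert np.array_equal(o1.values, o2.values)

    def test_noise_standard_deviation(self):
        """Empirical sd of the added noise matches sigma within 2%."""
        s = np.full((10, 100, 100), 10.0)  # 1e5 data
        obs = pf.make_observations(s, 1, 0.1, seed=3)
        noise = obs.values - obs.clean
        # clipping at zero is inactive here (values >> sigma)
        assert np.std(noise) == pytest.approx(obs.sigma, rel=0.02)
        assert obs.sigma == pytest.approx(1.0)


class TestGreedyDOptimal:
    def _brute_force(self, C, n_p):
        best, bestdet = None, -np.inf
        for I in itertools.combinations(range(C.shape[0]), n_p):
            d = np.linalg.det(C[np.ix_(I, I)])
            if d > bestdet:
                best, bestdet = I, d
        return np.array(best), bestdet

    def test_single_point_is_diag_argmax(self):
        rng = np.random.default_rng(0)
        X = rng.random((50, 6))
        C = np.cov(X, rowvar=False)
        sel = pf.greedy_doptimal_times(X, 1)
        assert sel[0] == np.argmax(np.diag(C))

    def test_diagonal_case_matches_brute_force(self):
        # independent time points with variances 3, 1, 2
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20000, 3)) * np.sqrt([3.0, 1.0, 2.0])
        sel = pf.greedy_doptimal_times(X, 2)
        brute, _ = self._brute_force(np.cov(X, rowvar=False), 2)
        assert set(sel) == set(brute) == {0, 2}

    def test_all_points(self):
        X = np.random.default_rng(2).random((30, 5))
        assert pf.greedy_doptimal_times(X, 5).tolist() == [0, 1, 2, 3, 4]

    def test_greedy_vs_exhaustive_on_random_psd(self):
        """Greedy det is within the exhaustive optimum (ratio logged, <= 1)."""
        rng = np.random.default_rng(9)
        ratios = []
        for _ in range(5):
            A = rng.standard_normal((8, 30))
            X = A.T  # 30 samples of an 8-dim variable -> random 8x8 PSD cov
            C = np.cov(X, rowvar=False)
            sel = pf.greedy_doptimal_times(X, 3)
            dg = np.linalg.det(C[np.ix_(sel, sel)])
            _, dopt = self._brute_force(C, 3)
            ratios.append(dg / dopt)
        # greedy can be suboptimal but never better than the optimum
        assert all(r <= 1.0 + 1e-9 for r in ratios)
        print("greedy/optimal det ratios:", ratios)

    def test_non_psd_raises(self):
        C_bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            hybrid.greedy_doptimal_from_cov(C_bad, 2)

    def test_invalid_np(self):
        X = np.random.default_rng(3).random((10, 4))
        with pytest.raises(ValueError):
            pf.greedy_doptimal_times(X, 0)


class TestTruthExperiment:
    def test_time_point_budget(self, twin_dataset):
        assert twin_dataset.observations.time_indices.size == 150 // 10

    def test_seed_determinism(self):
        cfg = pf.twin_config(fine_nx=32, fine_ny=40, network_depth=4)
        d1 = pf.run_truth_experiment(cfg, seed=5)
        d2 = pf.run_truth_experiment(cfg, seed=5)
        assert np.array_equal(d1.observations.values, d2.observations.values)
        assert np.array_equal(d1.true_perfusion_coarse, d2.true_perfusion_coarse,
                              equal_nan=True)

    def test_estimation_mesh_consistency(self, twin_dataset):
        est = twin_dataset.est_mesh
        obs = twin_dataset.observations
        assert est.nx == obs.values.shape[1] and est.ny == obs.values.shape[2]
        assert np.array_equal(est.active, obs.coarse_active)
        assert len(est.inlet_cells) >= 1 and len(est.outlet_cells) >= 1
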