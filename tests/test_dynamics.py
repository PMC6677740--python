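"""Single-cell dynamics, signal composition and the seeded integrator."""

import dataclasses

import numpy as np
import pytest
from scipy import sparse

from bristlesim.dynamics import (
    CellStateField,
    GradientParams,
    ModelParams,
    SpatialProfile,
    activation,
    bistability_window,
    extrinsic_signal,
    ligand_activity,
    resolve_fate_threshold,
    simulate,
    single_cell_fixed_points,
    total_signal,
)
from bristlesim.geometry import CellLattice, CouplingMatrix, build_disordered_lattice, compute_coupling

from conftest import uniform_gradient


class TestActivation:
    def test_limits_zero_and_one(self, params):
        assert activation(-1e6, params) == pytest.approx(0.0, abs=1e-9)
        assert activation(+1e6, params) == pytest.approx(1.0, abs=1e-9)

    def test_midpoint_value(self):
        p = ModelParams(f_threshold=0.3)
        assert activation(0.3, p) == pytest.approx(0.5)

    def test_midpoint_slope_matches_logistic(self, params):
        h = 1e-6
        slope = (activation(params.f_threshold + h, params) - activation(params.f_threshold - h, params)) / (2 * h)
        assert slope == pytest.approx(1.0 / (4 * params.f_steepness), rel=1e-5)

    def test_monotone_increasing(self, params):
        v = np.linspace(-2, 2, 500)
        f = activation(v, params)
        assert np.all(np.diff(f) >= 0)
        # strict away from floating-point saturation of the tails
        core = (v[:-1] > -0.4) & (v[1:] < 0.4)
        assert np.all(np.diff(f)[core] > 0)


class TestLigand:
    def test_endpoints(self, params):
        assert ligand_activity(0.0, params) == pytest.approx(0.0, abs=1e-12)
        assert ligand_activity(1.0, params) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_and_bounded_on_grid(self, params):
        u = np.linspace(-0.5, 1.5, 100)
        d = ligand_activity(u, params)
        assert np.all(np.diff(d) >= 0)
        assert np.all((d >= 0) & (d <= 1))


class TestExtrinsicGradient:
    def setup_method(self):
        early = SpatialProfile(baseline=1.0, bumps=((5.0, -1.0, 1.0),), period=10.0)
        late = SpatialProfile(baseline=0.0, bumps=((2.0, 0.8, 1.5),), period=10.0)
        self.g = GradientParams(early=early, late=late, t_start=4.0, t_end=8.0)

    def test_boundary_times_return_pure_profiles(self):
        x = np.linspace(0, 10, 33)
        assert np.array_equal(extrinsic_signal(x, 4.0, self.g), self.g.early.value(x))
        assert np.array_equal(extrinsic_signal(x, 8.0, self.g), self.g.late.value(x))
        assert np.array_equal(extrinsic_signal(x, 0.0, self.g), self.g.early.value(x))

    def test_midpoint_is_arithmetic_mean(self):
        x = np.linspace(0, 10, 17)
        mid = extrinsic_signal(x, 6.0, self.g)
        assert np.allclose(mid, 0.5 * (self.g.early.value(x) + self.g.late.value(x)))

    def test_profile_periodic_in_x(self):
        assert self.g.early.value(0.0) == pytest.approx(self.g.early.value(10.0))

    def test_invalid_time_order_rejected(self):
        with pytest.raises(ValueError):
            GradientParams(early=self.g.early, late=self.g.late, t_start=5.0, t_end=1.0)


class TestTotalSignal:
    def _chain(self):
        lat = CellLattice(
            positions=np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]]),
            box_width=6.0,
            box_height=2.0,
            areas=np.full(3, 4.0),
            neighbor_pairs=frozenset({(0, 1), (1, 2)}),
        )
        w = np.array([[0.0, 0.7, 0.0], [0.7, 0.0, 0.4], [0.0, 0.4, 0.0]])
        coup = CouplingMatrix(
            weights=sparse.csr_matrix(w),
            signaling_range=1.0,
            cutoff_radius=3.0,
            strength=1.0,
        )
        return lat, coup, w

    def test_null_cell_cell_term_leaves_extrinsic(self, params):
        lat, coup, _ = self._chain()
        g = uniform_gradient(0.4, period=6.0)
        sf = total_signal(CellStateField(u=np.zeros(3)), lat, coup, g, params)
        assert np.allclose(sf.s, 0.4)
        assert np.allclose(sf.cell_cell, 0.0)

    def test_three_cell_chain_matches_hand_sum(self, params):
        lat, coup, w = self._chain()
        g = uniform_gradient(0.1, period=6.0)
        u = np.array([0.9, 0.2, 0.6])
        sf = total_signal(CellStateField(u=u), lat, coup, g, params)
        expected = np.empty(3)
        for i in range(3):
            acc = 0.0
            for j in range(3):
                if j != i:
                    acc += w[i, j] * float(ligand_activity(u[j], params))
            expected[i] = 0.1 + acc
        assert np.allclose(sf.s, expected, atol=1e-12)
        assert np.allclose(sf.s, sf.extrinsic + sf.cell_cell)

    def test_cell_cell_part_linear_in_strength(self, params):
        lat, coup, w = self._chain()
        doubled = dataclasses.replace(coup, weights=sparse.csr_matrix(2 * w))
        g = uniform_gradient(0.25, period=6.0)
        u = np.array([0.5, 0.8, 0.1])
        a = total_signal(CellStateField(u=u), lat, coup, g, params)
        b = total_signal(CellStateField(u=u), lat, doubled, g, params)
        assert np.allclose(b.cell_cell, 2 * a.cell_cell)
        assert np.allclose(b.extrinsic, a.extrinsic)

    def test_size_mismatch_rejected(self, params):
        lat, coup, _ = self._chain()
        with pytest.raises(ValueError):
            total_signal(CellStateField(u=np.zeros(5)), lat, coup, uniform_gradient(0.0, 6.0), params)


def _one_cell_lattice():
    return build_disordered_lattice(1, 3.0, 3.0, disorder=0.0, seed=0)


class TestFixedPoints:
    def test_two_stable_one_unstable_at_intermediate_signal(self, params):
        fps = single_cell_fixed_points(0.5, params)
        assert [st for _, st in fps] == [True, False, True]

    def test_single_low_root_at_large_signal(self, params):
        fps = single_cell_fixed_points(5.0, params)
        assert len(fps) == 1
        u, st = fps[0]
        assert st and abs(u) < 1e-6

    def test_matches_brute_force_sign_scan(self, params):
        for s in (0.0, 0.3, 0.5, 0.7, 1.2):
            grid = np.linspace(-0.5, 1.5, 100_000)
            vals = activation(grid - s, params) - grid
            brute = [
                0.5 * (grid[k] + grid[k + 1])
                for k in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
            ]
            fps = single_cell_fixed_points(s, params)
            assert len(fps) == len(brute)
            for (u, _), ub in zip(fps, brute):
                assert u == pytest.approx(ub, abs=2e-5)

    def test_bistability_window_is_an_interval(self, params):
        s_lo, s_hi = bistability_window(params)
        assert s_lo < s_hi
        ss = np.linspace(-0.5, 1.5, 201)
        bist = np.array(
            [sum(st for _, st in single_cell_fixed_points(s, params)) == 2 for s in ss]
        )
        idx = np.flatnonzero(bist)
        assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))

    def test_fate_threshold_between_branches(self, params):
        thr = resolve_fate_threshold(params)
        s_lo, s_hi = bistability_window(params)
        stable = [u for u, st in single_cell_fixed_points(0.5 * (s_lo + s_hi), params) if st]
        assert stable[0] < thr < stable[-1]
        assert resolve_fate_threshold(ModelParams(fate_threshold=0.42)) == 0.42


class TestSimulate:
    def test_equilibrium_is_invariant(self, quiet_params):
        lat = _one_cell_lattice()
        coup = compute_coupling(lat, 1.0, strength=0.0)
        g = uniform_gradient(0.5, period=3.0)
        u_star = single_cell_fixed_points(0.5, quiet_params)[0][0]
        traj = simulate(lat, coup, quiet_params, g, u0=np.array([u_star]), t_end=5.0, dt=0.01)
        assert np.all(np.abs(traj.u - u_star) < 1e-9)

    def test_converges_to_fixed_point_from_arbitrary_start(self, quiet_params):
        lat = _one_cell_lattice()
        coup = compute_coupling(lat, 1.0, strength=0.0)
        for s0, u_init in [(0.5, 0.9), (0.5, 0.05), (1.5, 0.7), (0.0, 0.2)]:
            g = uniform_gradient(s0, period=3.0)
            traj = simulate(lat, coup, quiet_params, g, u0=np.array([u_init]), t_end=40.0, dt=0.01)
            stable_us = [u for u, st in single_cell_fixed_points(s0, quiet_params) if st]
            assert min(abs(traj.u[-1, 0] - u) for u in stable_us) < 1e-6

    def test_two_coupled_cells_resolve_anticorrelated(self, quiet_params):
        lat = CellLattice(
            positions=np.array([[1.0, 1.0], [2.0, 1.0]]),
            box_width=6.0,
            box_height=2.0,
            areas=np.full(2, 6.0),
            neighbor_pairs=frozenset({(0, 1)}),
        )
        coup = compute_coupling(lat, 1.0, strength=2.0)
        g = uniform_gradient(0.0, period=6.0)
        u0 = np.array([0.51, 0.49])
        traj = simulate(lat, coup, quiet_params, g, u0=u0, t_end=40.0, dt=0.01)
        fine = simulate(lat, coup, quiet_params, g, u0=u0, t_end=40.0, dt=0.001)
        for t in (traj, fine):
            assert t.u[-1, 0] > 0.8 and t.u[-1, 1] < 0.2
        assert np.allclose(traj.u[-1], fine.u[-1], atol=1e-3)

    def test_noiseless_states_stay_in_unit_interval(self, quiet_params, small_lattice):
        coup = compute_coupling(small_lattice, 1.0, strength=2.0)
        g = uniform_gradient(0.3, period=small_lattice.box_width)
        rng = np.random.default_rng(2)
        traj = simulate(
            small_lattice, coup, quiet_params, g,
            u0=rng.uniform(0, 1, small_lattice.n_cells), t_end=10.0, dt=0.02,
        )
        assert np.all((traj.u >= 0.0) & (traj.u <= 1.0))

    def test_raising_uniform_inhibition_never_raises_terminal_state(self, quiet_params, small_lattice):
        # pointwise monotonicity holds cell-autonomously (zero coupling);
        # with coupling, losing an inhibited neighbor can disinhibit a cell,
        # so there the monotone quantity is the precursor count, not u itself
        rng = np.random.default_rng(3)
        u0 = rng.uniform(0, 0.1, small_lattice.n_cells)
        uncoupled = compute_coupling(small_lattice, 1.0, strength=0.0)
        finals = []
        for level in (0.1, 0.3, 0.6):
            g = uniform_gradient(level, period=small_lattice.box_width)
            traj = simulate(small_lattice, uncoupled, quiet_params, g, u0=u0, t_end=20.0, dt=0.02)
            finals.append(traj.u[-1])
        assert np.all(finals[1] <= finals[0] + 1e-9)
        assert np.all(finals[2] <= finals[1] + 1e-9)

        coup = compute_coupling(small_lattice, 1.0, strength=1.0)
        counts = []
        for level in (0.0, 0.3, 0.6):
            g = uniform_gradient(level, period=small_lattice.box_width)
            traj = simulate(small_lattice, coup, quiet_params, g, u0=u0, t_end=20.0, dt=0.02)
            counts.append(int((traj.u[-1] > 0.5).sum()))
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[0] > 0

    def test_euler_step_convergence(self, quiet_params, small_lattice):
        coup = compute_coupling(small_lattice, 1.0, strength=1.5)
        g = uniform_gradient(0.4, period=small_lattice.box_width)
        rng = np.random.default_rng(4)
        u0 = rng.uniform(0, 0.1, small_lattice.n_cells)
        t_probe = 2.0
        sols = {}
        for dt in (0.05, 0.005):
            traj = simulate(
                small_lattice, coup, quiet_params, g, u0=u0,
                t_end=t_probe, dt=dt, record_every=int(round(t_probe / dt)),
            )
            sols[dt] = traj.u[-1]
        ref = simulate(
            small_lattice, coup, quiet_params, g, u0=u0,
            t_end=t_probe, dt=0.0005, record_every=4000,
        ).u[-1]
        err_coarse = np.max(np.abs(sols[0.05] - ref))
        err_fine = np.max(np.abs(sols[0.005] - ref))
        assert err_coarse < 2 * 0.05  # O(dt) accuracy
        assert err_fine < err_coarse / 3  # error shrinks with dt

    def test_seeded_reproducibility_bit_identical(self, params, small_lattice):
        coup = compute_coupling(small_lattice, 1.0, strength=2.0)
        g = uniform_gradient(0.2, period=small_lattice.box_width)
        a = simulate(small_lattice, coup, params, g, t_end=3.0, dt=0.02, seed=9)
        b = simulate(small_lattice, coup, params, g, t_end=3.0, dt=0.02, seed=9)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.s, b.s)
        c = simulate(small_lattice, coup, params, g, t_end=3.0, dt=0.02, seed=10)
        assert not np.array_equal(a.u, c.u)

    def test_rejects_coarse_dt(self, params, small_lattice):
        coup = compute_coupling(small_lattice, 1.0, strength=1.0)
        g = uniform_gradient(0.0, period=small_lattice.box_width)
        with pytest.raises(ValueError, match="dt"):
            simulate(small_lattice, coup, params, g, t_end=1.0, dt=0.5)
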