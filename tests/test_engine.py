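import numpy as np
import pytest

import polyphase as pp
from polyphase.engine import (
    BlowUpError,
    bend_energy,
    bend_forces,
    build_forcefield,
    forces,
    kinetic_temperature,
    langevin_step,
    pair_energy,
    pair_forces,
    run,
    stretch_energy,
    stretch_forces,
)
from polyphase.model import K_B_KCAL, BeadRole

from conftest import min_image, random_state


def make_state(positions, roles=None, chain_id=None, box=200.0):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return pp.SystemState(
        positions=np.mod(positions, box),
        velocities=np.zeros((n, 3)),
        roles=np.zeros(n, dtype=int) if roles is None else np.asarray(roles),
        chain_id=np.zeros(n, dtype=int) if chain_id is None else np.asarray(chain_id),
        box_edge=box,
    )


def ff_for(state, params, eps_sp=1.2, eps_ns=0.5):
    table = pp.build_interaction_table(eps_sp, eps_ns)
    return build_forcefield(state.roles, state.chain_id, table, params)


def numerical_gradient(state, ff, energy_fn, h=1e-5):
    grad = np.zeros_like(state.positions)
    for i in range(state.n_beads):
        for k in range(3):
            sp = state.copy()
            sp.positions[i, k] += h
            sm = state.copy()
            sm.positions[i, k] -= h
            grad[i, k] = (energy_fn(sp, ff) - energy_fn(sm, ff)) / (2 * h)
    return grad


class TestStretchEnergy:
    def test_zero_at_equilibrium(self, params):
        pos = [[10 + 4.5 * i, 10, 10] for i in range(5)]
        state = make_state(pos)
        assert stretch_energy(state, ff_for(state, params)) == pytest.approx(0.0, abs=1e-12)

    def test_single_stretched_bond_literal_formula(self, params):
        state = make_state([[10, 10, 10], [15.5, 10, 10]])
        # k_s (r - r0)^2 with no 1/2 prefactor: 10 * 1.0^2
        assert stretch_energy(state, ff_for(state, params)) == pytest.approx(10.0)

    def test_force_matches_numerical_gradient(self, params):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(scale=3.0, size=(6, 3)), axis=0) + 50
        state = make_state(pos)
        ff = ff_for(state, params)
        f, _ = stretch_forces(state, ff)
        num = numerical_gradient(state, ff, stretch_energy)
        assert np.allclose(f, -num, atol=1e-6)


class TestBendEnergy:
    def test_straight_chain_zero(self, params):
        pos = [[10 + 4.5 * i, 10, 10] for i in range(6)]
        state = make_state(pos)
        assert bend_energy(state, ff_for(state, params)) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle(self, params):
        state = make_state([[10, 10, 10], [14.5, 10, 10], [14.5, 14.5, 10]])
        # kappa (1 - cos 90deg) = 2 * 1
        assert bend_energy(state, ff_for(state, params)) == pytest.approx(2.0)

    def test_folded_bond_pair(self, params):
        state = make_state([[10, 10, 10], [14.5, 10, 10], [10.0, 10, 10 + 1e-9]])
        # theta ~ pi -> 2 kappa per angle
        assert bend_energy(state, ff_for(state, params)) == pytest.approx(4.0, rel=1e-3)

    def test_zero_length_bond_rejected(self, params):
        state = make_state([[10, 10, 10], [10, 10, 10], [14.5, 10, 10]])
        with pytest.raises(ValueError, match="zero-length"):
            bend_energy(state, ff_for(state, params))

    def test_force_matches_numerical_gradient(self, params):
        rng = np.random.default_rng(1)
        pos = np.cumsum(4.5 * _unit_rows(rng, 7), axis=0) + 60
        state = make_state(pos)
        ff = ff_for(state, params)
        f, _ = bend_forces(state, ff)
        num = numerical_gradient(state, ff, bend_energy)
        assert np.allclose(f, -num, atol=1e-6)


def _unit_rows(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestPairEnergy:
    def test_zero_crossing_at_sigma(self, params):
        state = make_state([[10, 10, 10], [14.5, 10, 10]], chain_id=[0, 1])
        assert pair_energy(state, ff_for(state, params)) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth_at_rmin(self, params):
        rmin = 2 ** (1 / 6) * 4.5
        state = make_state([[10, 10, 10], [10 + rmin, 10, 10]], chain_id=[0, 1])
        eps_kcal = pp.kBT_to_kcal(1.2, 310.0)  # both specific
        assert pair_energy(state, ff_for(state, params)) == pytest.approx(-eps_kcal, rel=1e-12)

    def test_beyond_cutoff_exactly_zero(self, params):
        state = make_state([[10, 10, 10], [10 + 2.5 * 4.5 + 1e-9, 10, 10]], chain_id=[0, 1])
        ff = ff_for(state, params)
        assert pair_energy(state, ff) == 0.0
        f, _ = pair_forces(state, ff)
        assert np.all(f == 0.0)

    def test_repulsive_only_pair_cut_at_rmin(self, params):
        roles = [int(BeadRole.INERT), int(BeadRole.INERT)]
        rmin = 2 ** (1 / 6) * 4.5
        state = make_state([[10, 10, 10], [10 + rmin + 1e-9, 10, 10]], roles=roles, chain_id=[0, 1])
        assert pair_energy(state, ff_for(state, params)) == 0.0
        closer = make_state([[10, 10, 10], [14.2, 10, 10]], roles=roles, chain_id=[0, 1])
        assert pair_energy(closer, ff_for(closer, params)) > 0.0

    def test_bonded_pair_excluded(self, params):
        state = make_state([[10, 10, 10], [13.0, 10, 10]])  # bonded, deep overlap range
        ff = ff_for(state, params)
        f, e = pair_forces(state, ff)
        assert e == 0.0 and np.all(f == 0.0)

    def test_matches_brute_force_oracle(self, params):
        # independent all-pairs numpy oracle with minimum image
        state = random_state(n_chains=5, chain_len=10, box=50.0, seed=3, spread=6.0)
        ff = ff_for(state, params)
        got = pair_energy(state, ff)
        expect = 0.0
        n = state.n_beads
        for i in range(n):
            for j in range(i + 1, n):
                if state.chain_id[i] == state.chain_id[j] and j == i + 1:
                    continue
                d = min_image(state.positions[i] - state.positions[j], state.box_edge)
                r2 = float(d @ d)
                rc2 = ff.rcut2[state.roles[i], state.roles[j]]
                if r2 >= rc2:
                    continue
                eps = ff.eps_kcal[state.roles[i], state.roles[j]]
                sr6 = (params.sigma**2 / r2) ** 3
                expect += 4 * eps * (sr6**2 - sr6)
        assert got == pytest.approx(expect, rel=1e-8)

    def test_overlap_logs_warning_but_returns(self, params, caplog):
        import logging

        state = make_state([[10, 10, 10], [10.5, 10, 10]], chain_id=[0, 1])
        with caplog.at_level(logging.WARNING, logger="polyphase.engine"):
            e = pair_energy(state, ff_for(state, params))
        assert np.isfinite(e) and e > 0
        assert any("overlap" in rec.message for rec in caplog.records)

    def test_force_matches_numerical_gradient(self, params):
        state = random_state(n_chains=3, chain_len=8, box=40.0, seed=7, spread=5.0)
        ff = ff_for(state, params)
        f, _ = pair_forces(state, ff)
        num = numerical_gradient(state, ff, pair_energy)
        assert np.allclose(f, -num, atol=1e-6)


class TestForceInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_total_force_matches_gradient_on_random_states(self, seed, params):
        state = random_state(n_chains=2, chain_len=6, box=45.0, seed=seed, spread=5.0)
        ff = ff_for(state, params)
        f, _ = forces(state, ff)

        def total_energy(s, ff):
            return stretch_energy(s, ff) + bend_energy(s, ff) + pair_energy(s, ff)

        num = numerical_gradient(state, ff, total_energy)
        assert np.allclose(f, -num, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_newtons_third_law(self, seed, params):
        # overlap-free states: forces are moderate, so pairwise cancellation
        # leaves only clean rounding noise
        spec = pp.default_system_spec(n_chains=3, seed=seed + 10, box_edge=120.0, M=20, patch_len=3)
        state = pp.build_system(spec, params)
        ff = ff_for(state, params)
        f, _ = forces(state, ff)
        assert np.abs(f.sum(axis=0)).max() < 1e-9


class TestLangevinStep:
    def test_ballistic_limit(self):
        # no forces, (numerically) infinite damping: x(t) = x0 + v0 t
        params = pp.EngineParams(damping_time=1e30)
        state = make_state([[50.0, 50.0, 50.0]])
        state.velocities[0] = [1e-3, -2e-3, 5e-4]
        ff = ff_for(state, params)
        rng = np.random.default_rng(0)
        out = state.copy()
        for _ in range(100):
            out = langevin_step(out, ff, params, rng)
        expect = np.array([50.0, 50.0, 50.0]) + np.array([1e-3, -2e-3, 5e-4]) * 30.0 * 100
        assert np.allclose(out.positions[0], expect, atol=1e-9)

    def test_same_rng_state_identical_output(self, params, dimer_state, dimer_ff):
        out1 = langevin_step(dimer_state, dimer_ff, params, np.random.default_rng(9))
        out2 = langevin_step(dimer_state, dimer_ff, params, np.random.default_rng(9))
        assert np.array_equal(out1.positions, out2.positions)
        assert np.array_equal(out1.velocities, out2.velocities)

    def test_blow_up_reports_bead(self, params):
        # exactly coincident beads -> 0/0 in the pair force -> NaN coordinates
        state = make_state([[10, 10, 10], [10, 10, 10]], chain_id=[0, 1])
        ff = ff_for(state, params)
        with pytest.raises(BlowUpError, match="bead"):
            out = state
            rng = np.random.default_rng(0)
            for _ in range(50):
                out = langevin_step(out, ff, params, rng)

    def test_single_bond_equipartition(self, params):
        # bond-length variance ~ kT / (2 k_s): printed bond formula lacks the
        # conventional 1/2, so the effective stiffness is 2 k_s
        chain = pp.ChainSpec(roles=(BeadRole.NONSPECIFIC, BeadRole.NONSPECIFIC))
        spec = pp.SystemSpec(chains=((chain, 1),), seed=3, box_edge=60.0)
        state = pp.build_system(spec, params)
        table = pp.build_interaction_table(1.2, 0.5)
        ff = build_forcefield(state.roles, state.chain_id, table, params)
        rng = np.random.default_rng(11)
        _, state = run(state, ff, params, 20_000, 20_000, rng)  # equilibrate
        traj, _ = run(state, ff, params, 400_000, 40, rng, use_neighbor_list=False)
        lengths = []
        for fr in traj.frames:
            d = min_image(fr.positions[1] - fr.positions[0], state.box_edge)
            lengths.append(np.linalg.norm(d))
        var = np.var(lengths)
        expect = K_B_KCAL * params.T / (2 * params.k_s)
        assert expect == pytest.approx(0.0308, abs=1e-4)
        assert var == pytest.approx(expect, rel=0.05)


class TestRun:
    def test_frame_count_contract(self, params, dimer_state, dimer_ff):
        traj, _ = run(dimer_state, dimer_ff, params, 100, 20, np.random.default_rng(0))
        assert traj.n_frames == 100 // 20 + 1
        assert traj.frames[0].time == 0.0

    def test_zero_steps_rejected(self, params, dimer_state, dimer_ff):
        with pytest.raises(ValueError):
            run(dimer_state, dimer_ff, params, 0, 10, np.random.default_rng(0))

    def test_neighbor_list_equivalence(self, params, dimer_state, dimer_ff):
        t1, _ = run(dimer_state, dimer_ff, params, 100, 10, np.random.default_rng(5),
                    use_neighbor_list=True)
        t2, _ = run(dimer_state, dimer_ff, params, 100, 10, np.random.default_rng(5),
                    use_neighbor_list=False)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.allclose(f1.positions, f2.positions, atol=1e-10)

    def test_restart_reproduces_continuation(self, params, dimer_state, dimer_ff):
        rng = np.random.default_rng(8)
        full, _ = run(dimer_state, dimer_ff, params, 200, 100, rng)
        rng2 = np.random.default_rng(8)
        half, mid = run(dimer_state, dimer_ff, params, 100, 100, rng2)
        rest, _ = run(mid, dimer_ff, params, 100, 100, rng2)
        assert np.allclose(rest.frames[-1].positions, full.frames[-1].positions, atol=1e-12)

    def test_determinism_same_seed(self, params, dimer_state, dimer_ff):
        t1, _ = run(dimer_state, dimer_ff, params, 300, 100, np.random.default_rng(4))
        t2, _ = run(dimer_state, dimer_ff, params, 300, 100, np.random.default_rng(4))
        assert np.array_equal(t1.frames[-1].positions, t2.frames[-1].positions)

    def test_frames_are_wrapped(self, params, dimer_state, dimer_ff):
        traj, _ = run(dimer_state, dimer_ff, params, 500, 100, np.random.default_rng(2))
        for fr in traj.frames:
            assert np.all(fr.positions >= 0)
            assert np.all(fr.positions < traj.box_edge)


class TestThermostat:
    def test_kinetic_temperature_long_run(self, params, default_table):
        # moderate-length calibration; the acceptance suite runs the full 1e6-step version
        spec = pp.default_system_spec(n_chains=1, seed=21, box_edge=400.0)
        state = pp.build_system(spec, params)
        ff = build_forcefield(state.roles, state.chain_id, default_table, params)
        rng = np.random.default_rng(17)
        _, state = run(state, ff, params, 20_000, 20_000, rng)
        traj, _ = run(state, ff, params, 200_000, 200, rng, store_velocities=True)
        temps = [kinetic_temperature(traj.state_at(i), params) for i in range(1, traj.n_frames)]
        assert np.mean(temps) == pytest.approx(params.T, rel=0.02)
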