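"""Langevin sampler: integrator correctness, thermostat, protocol shape."""

import numpy as np
import pytest

from evbkit.evb_core import ACC_CONVERSION, KB, DiabatsResult, EVBCoupling
from evbkit.sampler import (MDState, SimulationConfig, equilibrate,
                            kinetic_temperature, langevin_step,
                            maxwell_velocities, run_fep_protocol, run_window,
                            window_lambdas)
from evbkit.synthetic import make_oracle_1d, make_toy_reaction


class HarmonicWell:
    """Isotropic 3D harmonic well, identical diabats (plain MD test system)."""

    dim = 3
    restraint = None

    def __init__(self, k=100.0, mass=12.0):
        self.k = k
        self.masses = np.array([mass])
        self.coupling = EVBCoupling(0.0, 0.0)

    def initial_coords(self):
        return np.zeros((1, 3))

    def evaluate(self, coords):
        e = 0.5 * self.k * float(np.sum(coords**2))
        f = -self.k * coords
        return DiabatsResult(e1=e, e2=e, f1=f, f2=f)


def _free_potential(coords):
    return 0.0, np.zeros_like(coords), None


class TestIntegrator:
    def test_free_particle_uniform_motion(self):
        masses = np.array([10.0])
        v0 = np.array([[0.01, -0.02, 0.0]])
        state = MDState(coords=np.zeros((1, 3)), velocities=v0.copy(),
                        forces=np.zeros((1, 3)), potential=0.0)
        rng = np.random.default_rng(0)
        for _ in range(100):
            state = langevin_step(state, _free_potential, 1.0, 0.0, 298.0,
                                  masses, rng)
        np.testing.assert_allclose(state.coords, v0 * 100.0, rtol=1e-12)
        np.testing.assert_allclose(state.velocities, v0, rtol=1e-12)

    def test_identical_seeds_bit_identical(self):
        system = make_oracle_1d("reference")
        cfg = SimulationConfig(seed=3, n_prod_steps=200,
                               n_window_equil_steps=50)
        runs = []
        for _ in range(2):
            rep = equilibrate(system, cfg,
                              rng=np.random.default_rng(99))
            traj, _ = run_window(system, 0.4, 298.0, cfg, rep.state,
                                 np.random.default_rng(7))
            runs.append(traj)
        np.testing.assert_array_equal(runs[0].e1, runs[1].e1)
        np.testing.assert_array_equal(runs[0].coords, runs[1].coords)

    def test_equipartition_position_variance(self):
        """Sampled variance of a harmonic coordinate equals kB*T/k."""
        well = HarmonicWell(k=50.0)
        cfg = SimulationConfig(seed=1, timestep_fs=1.0, friction_ps=50.0,
                               n_prod_steps=40000, sample_stride=5,
                               n_window_equil_steps=1000)
        rep = equilibrate(well, cfg, rng=np.random.default_rng(11))
        traj, _ = run_window(well, 0.0, 298.0, cfg, rep.state,
                             np.random.default_rng(12))
        var = np.var(traj.coords.reshape(-1, 3), axis=0).mean()
        expected = KB * 298.0 / well.k
        n_eff = traj.coords.size / 10  # correlated samples, conservative
        se = expected * np.sqrt(2.0 / n_eff)
        assert abs(var - expected) < 3 * se

    def test_energy_drift_without_thermostat(self):
        """gamma = 0 reduces to velocity Verlet; bonded toy drifts
        < 0.01 kcal/mol per ps over 10^4 steps at 0.5 fs."""
        from evbkit.synthetic import ToyReactionSpec
        system = make_toy_reaction(ToyReactionSpec(n_solvent=0), seed=0)
        masses = system.masses
        from evbkit.sampler import _init_state, _mapping_potential
        pot = _mapping_potential(system, 0.0)
        rng = np.random.default_rng(4)
        state = _init_state(system, pot, 150.0, rng)
        energies = []
        dt = 0.5
        for step in range(10000):
            state = langevin_step(state, pot, dt, 0.0, 0.0, masses, rng)
            if step % 50 == 0:
                ke = 0.5 * np.sum(masses[:, None] * state.velocities**2) \
                    / ACC_CONVERSION
                energies.append(state.potential + ke)
        t_ps = np.arange(len(energies)) * 50 * dt * 1e-3
        drift_per_ps = abs(np.polyfit(t_ps, energies, 1)[0])
        assert drift_per_ps < 0.01

    def test_non_finite_force_raises(self):
        def bad_potential(coords):
            return np.nan, np.full_like(coords, np.nan), None

        state = MDState(coords=np.zeros((1, 3)), velocities=np.zeros((1, 3)),
                        forces=np.zeros((1, 3)), potential=0.0)
        from evbkit.sampler import IntegrationError
        with pytest.raises(IntegrationError):
            langevin_step(state, bad_potential, 1.0, 0.0, 298.0,
                          np.array([1.0]), np.random.default_rng(0))


class TestEquilibration:
    def test_six_stages_logged_and_target_reached(self):
        well = HarmonicWell(k=50.0)
        cfg = SimulationConfig(
            seed=0, temperature=298.0,
            n_equil_steps=(500, 500, 500, 500, 500, 20000),
            equil_relax_fs=(10.0,) * 6)
        report = equilibrate(well, cfg, rng=np.random.default_rng(5))
        assert len(report.stages) == 6
        assert report.stages[0].target_T == pytest.approx(1.0)
        assert report.stages[-1].target_T == pytest.approx(298.0)
        trailing = report.stages[-1].mean_kinetic_T
        assert 268.0 <= trailing <= 328.0
        assert report.reached_target

    def test_one_kelvin_target_gives_tiny_velocities(self):
        well = HarmonicWell(k=50.0)
        cfg = SimulationConfig(seed=0, temperature=1.0,
                               n_equil_steps=(100,) * 6,
                               equil_relax_fs=(10.0,) * 6)
        report = equilibrate(well, cfg, rng=np.random.default_rng(5))
        speed = np.abs(report.state.velocities).max()
        # thermal velocity at 1 K for 12 amu is ~2.6e-4 A/fs
        assert speed < 2e-3

    def test_maxwell_velocities_temperature(self, rng):
        masses = np.full(2000, 12.0)
        v = maxwell_velocities(masses, 298.0, 3, rng)
        assert kinetic_temperature(v, masses) == pytest.approx(298.0,
                                                               rel=0.05)


class TestProtocol:
    def test_window_lambda_spacing(self):
        lam51 = window_lambdas(51)
        assert np.allclose(np.diff(lam51), 0.02)
        assert np.allclose(window_lambdas(3), [0.0, 0.5, 1.0])
        with pytest.raises(ValueError):
            window_lambdas(2)

    def test_frame_mapping_invariant(self, reference_trajectories):
        """eps_m = (1-lam)*eps1 + lam*eps2' holds for every stored frame."""
        for w in reference_trajectories[:8]:
            expected = (1.0 - w.lam) * w.e1 + w.lam * w.e2s
            np.testing.assert_allclose(w.em, expected, atol=1e-9)

    def test_replicates_differ_but_share_config_hash(
            self, reference_trajectories):
        by_rep = {}
        for w in reference_trajectories:
            if w.lam == 0.5:
                by_rep[w.replicate] = w
        assert len(by_rep) == 10
        w0, w1 = by_rep[0], by_rep[1]
        assert w0.config_hash == w1.config_hash
        assert not np.array_equal(w0.e1, w1.e1)

    def test_same_master_seed_reproduces_protocol(self):
        system = make_oracle_1d("reference")
        cfg = SimulationConfig(seed=17, n_prod_steps=120,
                               n_window_equil_steps=30,
                               n_equil_steps=(30,) * 6)
        a = run_fep_protocol(system, 298.0, 5, 2, cfg)
        b = run_fep_protocol(system, 298.0, 5, 2, cfg)
        assert len(a) == len(b) == 10
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.e1, wb.e1)

    def test_kinetic_temperature_near_target(self, reference_trajectories):
        kin = np.concatenate([w.kin_t for w in reference_trajectories])
        assert np.mean(kin) == pytest.approx(298.0, rel=0.02)
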