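"""Dynamics and sampling: thermostats, cluster MC, umbrella reweighting."""

import math

import numpy as np
import pytest
from scipy import integrate

from hybkin import (
    BiasSpec,
    IntegrationError,
    MoveSet,
    StrandTopology,
    ThermostatSettings,
    UsageError,
    draw_velocities,
    evolve,
    kinetic_energy,
    load_parameters,
    make_configuration,
    run_umbrella,
    total_energy,
    vmmc_sweep,
)
from hybkin.dynamics import MCStats, profile_from_counts
from hybkin.fixtures import FixtureSpec, build_configuration
from hybkin.structure import detect_base_pairs


def _free_gas(n_particles, box=120.0, temperature=300.0, seed=0):
    topo = StrandTopology(tuple("A" for _ in range(n_particles)))
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box, (n_particles, 3))
    a1 = np.tile([1.0, 0, 0], (n_particles, 1))
    a3 = np.tile([0, 0, 1.0], (n_particles, 1))
    return make_configuration(topo, pos, a1, a3, box, temperature)


def _dimer(box=8.0, r0=1.5, temperature=300.0):
    topo = StrandTopology(("A", "A"))
    pos = np.array([[0.0, 0, 0], [r0, 0, 0]])
    a1 = np.tile([1.0, 0, 0], (2, 1))
    a3 = np.tile([0, 0, 1.0], (2, 1))
    return make_configuration(topo, pos, a1, a3, box, temperature)


class TestLangevin:
    def test_free_diffusion_recovers_input_coefficient(self, params_avg):
        """Einstein relation: MSD slope / 6 equals the input D within 5%."""
        D_in = 0.05
        dt = 0.01
        cfg = _free_gas(64, seed=1)
        thermo = ThermostatSettings(
            translational_diffusion=D_in, rotational_diffusion=D_in,
            timestep=dt, seed=1,
        )
        rng = np.random.default_rng(1)
        draw_velocities(cfg, params_avg, rng)
        frames = evolve(cfg, params_avg, thermo, 60_000, stride=500, rng=rng)
        traj = np.array([f.pos for f in frames])  # (T, N, 3), unwrapped
        # lag of 30 time units >> velocity relaxation time (m D / kT = 0.5),
        # with every frame as a time origin for variance reduction
        lag = 6
        frame_t = 500 * dt
        d = traj[lag:] - traj[:-lag]
        msd = np.mean(np.sum(d * d, axis=2))
        D_est = msd / (6.0 * lag * frame_t)
        assert D_est == pytest.approx(D_in, rel=0.05)

    def test_equipartition_on_interacting_system(self, params_avg):
        """Mean kinetic energy per translational DOF is kT/2 within 3%."""
        spec = FixtureSpec(strands=("AC", "GT"), mode="native_duplex", relax_steps=100)
        cfg = build_configuration(spec, params_avg)
        rng = np.random.default_rng(5)
        draw_velocities(cfg, params_avg, rng)
        thermo = ThermostatSettings(
            translational_diffusion=0.01, rotational_diffusion=0.01,
            timestep=0.003, seed=5,
        )
        evolve(cfg, params_avg, thermo, 3000, rng=rng)  # equilibrate
        samples_t, samples_r = [], []
        for _ in range(600):
            evolve(cfg, params_avg, thermo, 15, rng=rng)
            samples_t.append(0.5 * np.sum(cfg.vel**2) / cfg.n / 3)
            samples_r.append(0.5 * np.sum(cfg.angmom**2) / cfg.n / 3)
        half_kT = cfg.kT / 2
        assert np.mean(samples_t) == pytest.approx(half_kT, rel=0.03)
        assert np.mean(samples_r) == pytest.approx(half_kT, rel=0.03)

    def test_zero_temperature_drag_decays_velocity(self, params_avg):
        cfg = _free_gas(1, temperature=0.0, seed=2)
        cfg.vel[0] = [1.0, 0.0, 0.0]
        thermo = ThermostatSettings(
            friction_translational=2.0, friction_rotational=2.0,
            timestep=0.01, seed=2,
        )
        speeds = [1.0]
        for _ in range(20):
            evolve(cfg, params_avg, thermo, 10, rng=np.random.default_rng(2))
            speeds.append(float(np.linalg.norm(cfg.vel[0])))
        assert all(b < a for a, b in zip(speeds, speeds[1:]))
        assert speeds[-1] < 0.05

    def test_nve_conserves_energy(self, params_avg):
        """Symplectic zero-friction integration: drift < 1e-4 per 1e4 steps."""
        spec = FixtureSpec(strands=("AC", "GT"), mode="native_duplex", relax_steps=100)
        cfg = build_configuration(spec, params_avg)
        rng = np.random.default_rng(1)
        draw_velocities(cfg, params_avg, rng)
        e0 = total_energy(cfg, params_avg).total + kinetic_energy(cfg, params_avg)
        thermo = ThermostatSettings(scheme="nve", timestep=0.003, seed=1)
        evolve(cfg, params_avg, thermo, 10_000, rng=rng)
        e1 = total_energy(cfg, params_avg).total + kinetic_energy(cfg, params_avg)
        assert abs(e1 - e0) < 1e-4

    def test_blow_up_raises_integration_error_with_step(self, params_avg):
        cfg = _dimer(r0=0.02)  # deep inside the excluded-volume core
        cfg.temperature = 300.0
        thermo = ThermostatSettings(timestep=0.05, seed=0)
        with pytest.raises(IntegrationError) as err:
            evolve(cfg, params_avg, thermo, 1000)
        assert err.value.step >= 1

    def test_trajectory_stride_and_reproducibility(self, params_avg):
        def run():
            cfg = _free_gas(4, seed=3)
            rng = np.random.default_rng(7)
            draw_velocities(cfg, params_avg, rng)
            thermo = ThermostatSettings(timestep=0.01, seed=7)
            frames = evolve(cfg, params_avg, thermo, 100, stride=20, rng=rng)
            return frames

        f1, f2 = run(), run()
        assert len(f1) == 5
        for a, b in zip(f1, f2):
            assert np.array_equal(a.pos, b.pos)
            assert np.array_equal(a.vel, b.vel)

    def test_brownian_free_diffusion(self, params_avg):
        D_in = 0.3
        cfg = _free_gas(48, seed=9)
        thermo = ThermostatSettings(
            scheme="brownian", translational_diffusion=D_in,
            rotational_diffusion=D_in, timestep=0.01, seed=9,
        )
        start = cfg.pos.copy()
        rng = np.random.default_rng(9)
        evolve(cfg, params_avg, thermo, 4000, rng=rng)
        t = 4000 * 0.01
        D_est = np.mean(np.sum((cfg.pos - start) ** 2, axis=1)) / (6 * t)
        assert D_est == pytest.approx(D_in, rel=0.15)

    def test_n_steps_must_be_positive(self, params_avg):
        cfg = _free_gas(1)
        with pytest.raises(UsageError):
            evolve(cfg, params_avg, ThermostatSettings(), 0)


def _double_well_energy_fn(box, barrier=8.0, tilt=0.3):
    def U(r):
        return barrier * ((r - 1.5) ** 2 - 0.25) ** 2 + tilt * (r - 1.0)

    def efn(c):
        d = c.pos[1] - c.pos[0]
        d -= box * np.round(d / box)
        return U(float(np.linalg.norm(d)))

    return U, efn


def _radial_partition(U, beta, lo, hi):
    z, _ = integrate.quad(lambda r: 4 * math.pi * r * r * math.exp(-beta * U(r)), lo, hi)
    return z


class TestClusterMC:
    def test_boltzmann_occupancy_matches_quadrature(self, params_avg):
        """Well occupancies of a dimer pair potential agree with quadrature."""
        box = 8.0
        kT = 0.1
        U, efn = _double_well_energy_fn(box, barrier=3.0, tilt=0.2)
        zi = _radial_partition(U, 1 / kT, 1e-9, 1.5)
        zo = _radial_partition(U, 1 / kT, 1.5, 4.0)
        ref = zi / (zi + zo)
        cfg = _dimer(r0=1.0)
        rng = np.random.default_rng(11)
        ms = MoveSet(translation=0.5, cluster_fraction=0.0)
        burn, n_sweeps, n_blocks = 1000, 14_000, 10
        block_hits = np.zeros(n_blocks)
        block_tot = np.zeros(n_blocks)
        for sweep in range(n_sweeps):
            vmmc_sweep(cfg, params_avg, ms, rng, energy_fn=efn)
            if sweep >= burn:
                d = cfg.pos[1] - cfg.pos[0]
                d -= box * np.round(d / box)
                blk = (sweep - burn) * n_blocks // (n_sweeps - burn)
                block_hits[blk] += float(np.linalg.norm(d)) < 1.5
                block_tot[blk] += 1
        block_p = block_hits / block_tot
        p = block_p.mean()
        sigma = block_p.std(ddof=1) / math.sqrt(n_blocks)
        assert abs(p - ref) < 2 * max(sigma, 0.01)

    def test_detailed_balance_identity_on_logged_moves(self, params_avg):
        """Logged acceptance ratios satisfy a(x->x')/a(x'->x) = exp(-beta dE)."""
        cfg = _dimer(r0=1.2)
        _, efn = _double_well_energy_fn(cfg.box, barrier=2.0)
        stats = MCStats()
        rng = np.random.default_rng(3)
        for _ in range(200):
            vmmc_sweep(cfg, params_avg, MoveSet(cluster_fraction=0.0), rng,
                       stats=stats, energy_fn=efn)
        assert stats.attempted > 0
        kT = cfg.kT
        for e_old, e_new, log_ratio in stats.log:
            forward = min(0.0, log_ratio)
            backward = min(0.0, -log_ratio)
            assert forward - backward == pytest.approx(-(e_new - e_old) / kT, abs=1e-10)

    def test_bound_duplex_diffuses_with_pairs_intact(self, params_avg):
        """Cluster moves let an 8-bp duplex diffuse without breaking pairs."""
        from hybkin import complement

        seq = "ACGTACGT"
        spec = FixtureSpec(strands=(seq, complement(seq)), mode="native_duplex",
                           temperature=250.0, relax_steps=150)
        cfg = build_configuration(spec, params_avg)
        rng = np.random.default_rng(3)
        com0 = cfg.pos.mean(axis=0).copy()
        msd_mid = msd_end = 0.0
        for sweep in range(120):
            vmmc_sweep(cfg, params_avg, MoveSet(), rng)
            if sweep == 59:
                msd_mid = float(np.sum((cfg.pos.mean(axis=0) - com0) ** 2))
        msd_end = float(np.sum((cfg.pos.mean(axis=0) - com0) ** 2))
        assert detect_base_pairs(cfg, params_avg).n_native == 8
        assert msd_end > msd_mid > 0.5


class TestUmbrella:
    def _op(self, box):
        def op(c):
            d = c.pos[1] - c.pos[0]
            d -= box * np.round(d / box)
            return 0 if float(np.linalg.norm(d)) < 1.5 else 1

        return op

    def test_uniform_weights_reproduce_plain_sampling(self, params_avg):
        box = 8.0
        U, efn = _double_well_energy_fn(box, barrier=2.0, tilt=0.0)
        kT = 0.1
        zi = _radial_partition(U, 1 / kT, 1e-9, 1.5)
        zo = _radial_partition(U, 1 / kT, 1.5, 4.0)
        ref = zi / (zi + zo)
        cfg = _dimer(r0=1.5)
        bias = BiasSpec("state", {0: 1.0, 1: 1.0})
        prof = run_umbrella(
            cfg, params_avg, bias, sweeps=6000, order_param=self._op(box),
            move_set=MoveSet(translation=0.4, cluster_fraction=0.0),
            seed=21, energy_fn=efn,
        )
        idx = int(np.flatnonzero(prof.n == 0)[0])
        se = max(prof.probability_se[idx], 0.02)
        assert abs(prof.probability[idx] - ref) < 2 * se

    def test_biased_sampling_recovers_analytic_delta_f(self, params_avg):
        """Strong bias toward the rare state still yields the quadrature dF."""
        box = 8.0
        U, efn = _double_well_energy_fn(box, barrier=8.0, tilt=0.3)
        kT = 0.1
        zi = _radial_partition(U, 1 / kT, 1e-9, 1.5)
        zo = _radial_partition(U, 1 / kT, 1.5, 4.0)
        dF_ref = -math.log(zi / zo)  # F(inner) - F(outer), kT units
        cfg = _dimer(r0=2.0)
        bias = BiasSpec("state", {0: 40.0, 1: 1.0})
        prof = run_umbrella(
            cfg, params_avg, bias, sweeps=12_000, order_param=self._op(box),
            move_set=MoveSet(translation=0.45, cluster_fraction=0.0),
            seed=22, energy_fn=efn,
        )
        dF_est = prof.delta_f_kT(1, 0)
        p0, p1 = prof.probability
        se0 = max(prof.probability_se[0], 1e-3)
        dF_se = se0 * (1 / p0 + 1 / p1)
        assert abs(dF_est - dF_ref) < 2 * max(dF_se, 0.15)

    def test_unsampled_bins_are_flagged_not_invented(self):
        prof = profile_from_counts(
            counts={0: 50, 2: 50}, weights={0: 1.0, 1: 1.0, 2: 1.0},
            temperature=300.0,
        )
        idx = int(np.flatnonzero(prof.n == 1)[0])
        assert not prof.sampled[idx]
        assert math.isnan(prof.free_energy_kT[idx])

    def test_weights_must_be_positive(self):
        with pytest.raises(UsageError):
            BiasSpec("n", {0: 1.0, 1: -2.0})
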