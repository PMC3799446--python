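"""Time evolution and equilibrium sampling for the rigid-nucleotide model.

Langevin dynamics uses a BAOAB-type splitting for rigid bodies: velocity
half-kicks from forces/torques, free streaming of positions and frames, and
an Ornstein-Uhlenbeck refresh whose noise amplitude satisfies the
fluctuation-dissipation relation at the configuration's temperature.  With
zero friction the scheme reduces to symplectic velocity Verlet.  A Brownian
(overdamped) first-order propagator is available for the sequence-dependent
runs, and a friction-free NVE mode supports energy-conservation checks.

Equilibrium sampling uses a Metropolis Monte Carlo scheme with
single-nucleotide rigid-body moves plus rigid cluster translations and
rotations.  Clusters are the connected components of the bond graph
(backbone links plus hydrogen bonds below the pairing threshold); a move of
a cluster is rejected outright if it would change the cluster decomposition,
which keeps the proposal symmetric and detailed balance exact while still
letting bound duplexes diffuse.  Umbrella sampling multiplies the acceptance
with a weight ratio on an integer order parameter and reweights the visited
histogram back to the unbiased distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model import (
    Configuration,
    ModelParameters,
    UsageError,
    hb_energies,
    total_energy,
    total_energy_forces_torques,
)


class IntegrationError(RuntimeError):
    """Numerical blow-up detected; carries the offending step index."""

    def __init__(self, step: int, message: str):
        super().__init__(f"step {step}: {message}")
        self.step = step


@dataclass(frozen=True)
class ThermostatSettings:
    """Integration scheme and its constants (simulation units).

    ``diffusion_scale`` multiplies both diffusion coefficients; the model's
    kinetics are routinely accelerated relative to physical DNA, so the
    scale is a logged run condition and rate comparisons require equal
    scales.  ``scheme='nve'`` disables drag and noise entirely.
    """

    scheme: str = "langevin"  # langevin | brownian | nve
    translational_diffusion: float = 1.0
    rotational_diffusion: float = 2.0
    timestep: float = 0.003
    seed: int = 0
    diffusion_scale: float = 1.0
    # explicit friction rates (per unit mass / inertia); when set they take
    # precedence over the diffusion coefficients.  Needed at T = 0, where
    # gamma = kT / (m D) would vanish while physical drag does not.
    friction_translational: Optional[float] = None
    friction_rotational: Optional[float] = None

    def __post_init__(self):
        if self.scheme not in ("langevin", "brownian", "nve"):
            raise UsageError(f"unknown thermostat scheme {self.scheme!r}")
        if self.timestep <= 0:
            raise UsageError("timestep must be positive")
        if self.translational_diffusion <= 0 or self.rotational_diffusion <= 0:
            raise UsageError("diffusion coefficients must be positive")


def _rotate_rows(a1, a3, rotvec):
    angles = np.linalg.norm(rotvec, axis=1)
    mask = angles > 1e-14
    if np.any(mask):
        R = Rotation.from_rotvec(rotvec[mask]).as_matrix()
        a1[mask] = np.einsum("nij,nj->ni", R, a1[mask])
        a3[mask] = np.einsum("nij,nj->ni", R, a3[mask])


_GUARD_ENERGY = 1e8
_GUARD_STEP = 2.0  # max per-step displacement, simulation length units


def evolve(
    config: Configuration,
    params: ModelParameters,
    thermo: ThermostatSettings,
    n_steps: int,
    stride: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Advance ``config`` in place for ``n_steps``; return emitted frames.

    Frames (copies) are emitted every ``stride`` steps when ``stride > 0``;
    the final state is always ``config`` itself.  Bitwise reproducible for a
    fixed seed.  Raises :class:`IntegrationError` on numerical blow-up.
    """
    if n_steps < 1:
        raise UsageError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(thermo.seed)
    if thermo.scheme == "brownian":
        return _evolve_brownian(config, params, thermo, n_steps, stride, rng)
    return _evolve_langevin(config, params, thermo, n_steps, stride, rng)


def _evolve_langevin(cfg, params, thermo, n_steps, stride, rng):
    dt = thermo.timestep
    m, inertia = params.mass, params.inertia
    kT = cfg.kT
    frames = []
    if thermo.scheme == "nve":
        c1t = c1r = 1.0
        s2t = s2r = 0.0
    else:
        Dt = thermo.translational_diffusion * thermo.diffusion_scale
        Dr = thermo.rotational_diffusion * thermo.diffusion_scale
        gam_t = (
            thermo.friction_translational
            if thermo.friction_translational is not None
            else kT / (m * Dt)
        )
        gam_r = (
            thermo.friction_rotational
            if thermo.friction_rotational is not None
            else kT / (inertia * Dr)
        )
        c1t = math.exp(-gam_t * dt)
        c1r = math.exp(-gam_r * dt)
        s2t = math.sqrt((1.0 - c1t**2) * kT * m)
        s2r = math.sqrt((1.0 - c1r**2) * kT * inertia)

    _, force, torque = total_energy_forces_torques(cfg, params)
    for step in range(1, n_steps + 1):
        cfg.vel += 0.5 * dt * force / m
        cfg.angmom += 0.5 * dt * torque
        # A: stream half step
        cfg.pos += 0.5 * dt * cfg.vel
        _rotate_rows(cfg.a1, cfg.a3, 0.5 * dt * cfg.angmom / inertia)
        # O: velocity refresh (drag persists even at zero temperature)
        if thermo.scheme != "nve":
            cfg.vel = c1t * cfg.vel + (s2t / m) * rng.standard_normal(cfg.vel.shape)
            cfg.angmom = c1r * cfg.angmom + s2r * rng.standard_normal(
                cfg.angmom.shape
            )
        # A
        cfg.pos += 0.5 * dt * cfg.vel
        _rotate_rows(cfg.a1, cfg.a3, 0.5 * dt * cfg.angmom / inertia)
        cfg.orthonormalize()
        rep, force, torque = total_energy_forces_torques(cfg, params, validate=False)
        cfg.vel += 0.5 * dt * force / m
        cfg.angmom += 0.5 * dt * torque
        if not np.isfinite(rep.total) or abs(rep.total) > _GUARD_ENERGY:
            raise IntegrationError(step, f"potential energy {rep.total!r}")
        if np.max(np.abs(cfg.vel)) * dt > _GUARD_STEP:
            raise IntegrationError(step, "per-step displacement beyond guard")
        if stride and step % stride == 0:
            frames.append(cfg.copy())
    return frames


def _evolve_brownian(cfg, params, thermo, n_steps, stride, rng):
    dt = thermo.timestep
    kT = cfg.kT
    Dt = thermo.translational_diffusion * thermo.diffusion_scale
    Dr = thermo.rotational_diffusion * thermo.diffusion_scale
    st = math.sqrt(2.0 * Dt * dt)
    sr = math.sqrt(2.0 * Dr * dt)
    frames = []
    for step in range(1, n_steps + 1):
        rep, force, torque = total_energy_forces_torques(cfg, params, validate=False)
        if not np.isfinite(rep.total) or abs(rep.total) > _GUARD_ENERGY:
            raise IntegrationError(step, f"potential energy {rep.total!r}")
        disp = (Dt / kT) * force * dt + st * rng.standard_normal(cfg.pos.shape)
        if np.max(np.abs(disp)) > _GUARD_STEP:
            raise IntegrationError(step, "per-step displacement beyond guard")
        cfg.pos += disp
        rot = (Dr / kT) * torque * dt + sr * rng.standard_normal(cfg.pos.shape)
        _rotate_rows(cfg.a1, cfg.a3, rot)
        cfg.orthonormalize()
        if stride and step % stride == 0:
            frames.append(cfg.copy())
    return frames


def kinetic_energy(config: Configuration, params: ModelParameters) -> float:
    """Translational plus rotational kinetic energy (isotropic inertia)."""
    v2 = float(np.sum(config.vel**2))
    l2 = float(np.sum(config.angmom**2))
    return 0.5 * params.mass * v2 + 0.5 * l2 / params.inertia


def draw_velocities(
    config: Configuration, params: ModelParameters, rng: np.random.Generator
) -> None:
    """Draw Maxwell-Boltzmann momenta at the configuration's temperature."""
    kT = config.kT
    config.vel = rng.standard_normal(config.vel.shape) * math.sqrt(kT / params.mass)
    config.angmom = rng.standard_normal(config.angmom.shape) * math.sqrt(
        kT * params.inertia
    )


# ---------------------------------------------------------------------------
# cluster-move Monte Carlo
# ---------------------------------------------------------------------------


@dataclass
class MoveSet:
    """Proposal amplitudes for the Metropolis sampler."""

    translation: float = 0.15
    rotation: float = 0.2
    cluster_translation: float = 0.3
    cluster_rotation: float = 0.15
    cluster_fraction: float = 0.25  # probability of attempting a cluster move


@dataclass
class MCStats:
    attempted: int = 0
    accepted: int = 0
    log: list = field(default_factory=list)


def _bond_clusters(cfg: Configuration, params: ModelParameters) -> list:
    """Connected components of backbone links plus detected hydrogen bonds."""
    n = cfg.n
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a, b in cfg.topology.bonded_pairs:
        union(int(a), int(b))
    thr = params.pairing_threshold
    for i, j, e in hb_energies(cfg, params):
        if e <= thr:
            union(i, j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _cluster_of(cfg, params, seed_particle) -> frozenset:
    for grp in _bond_clusters(cfg, params):
        if seed_particle in grp:
            return frozenset(grp)
    return frozenset((seed_particle,))


def vmmc_sweep(
    config: Configuration,
    params: ModelParameters,
    move_set: Optional[MoveSet] = None,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    bias: Optional["BiasSpec"] = None,
    order_param: Optional[Callable[[Configuration], int]] = None,
    stats: Optional[MCStats] = None,
    energy_fn: Optional[Callable[[Configuration], float]] = None,
) -> Configuration:
    """One Monte Carlo sweep (N move attempts); mutates and returns config.

    The chain satisfies detailed balance with respect to the Boltzmann
    distribution at ``config.temperature`` (times the umbrella weight when a
    bias is supplied).  Cluster moves translate or rotate whole bond-connected
    components so bound duplexes diffuse without artificial suppression;
    proposals that would alter the cluster decomposition are rejected to keep
    the move symmetric.
    """
    move_set = move_set or MoveSet()
    if rng is None:
        rng = np.random.default_rng(seed)
    if energy_fn is None:
        def energy_fn(c):
            return total_energy(c, params).total
    kT = config.kT
    e_old = energy_fn(config)
    n_old = order_param(config) if order_param else None
    for _ in range(config.n):
        seed_particle = int(rng.integers(config.n))
        do_cluster = rng.random() < move_set.cluster_fraction
        trial = config.copy()
        if do_cluster:
            cluster = _cluster_of(config, params, seed_particle)
            idx = np.fromiter(cluster, dtype=np.int64)
            if rng.random() < 0.5:
                shift = rng.normal(scale=move_set.cluster_translation, size=3)
                trial.pos[idx] += shift
            else:
                rotvec = rng.normal(scale=move_set.cluster_rotation, size=3)
                com = trial.pos[idx].mean(axis=0)
                R = Rotation.from_rotvec(rotvec).as_matrix()
                trial.pos[idx] = (trial.pos[idx] - com) @ R.T + com
                trial.a1[idx] = trial.a1[idx] @ R.T
                trial.a3[idx] = trial.a3[idx] @ R.T
        else:
            i = seed_particle
            trial.pos[i] += rng.normal(scale=move_set.translation, size=3)
            rotvec = rng.normal(scale=move_set.rotation, size=3)
            R = Rotation.from_rotvec(rotvec).as_matrix()
            trial.a1[i] = R @ trial.a1[i]
            trial.a3[i] = R @ trial.a3[i]
        e_new = energy_fn(trial)
        if do_cluster and _cluster_of(trial, params, seed_particle) != cluster:
            accept = False
            log_ratio = None
        else:
            log_ratio = -(e_new - e_old) / kT
            if bias is not None:
                n_new = order_param(trial)
                log_ratio += math.log(bias.weight(n_new)) - math.log(
                    bias.weight(n_old)
                )
            accept = log_ratio >= 0 or rng.random() < math.exp(log_ratio)
        if stats is not None:
            stats.attempted += 1
            stats.accepted += int(accept)
            if log_ratio is not None:
                stats.log.append((e_old, e_new, log_ratio))
        if accept:
            config.pos, config.a1, config.a3 = trial.pos, trial.a1, trial.a3
            e_old = e_new
            if bias is not None:
                n_old = n_new
    return config


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiasSpec:
    """Umbrella weights over an integer order parameter (e.g. base pairs)."""

    order_parameter: str
    weights: dict  # value -> positive weight

    def __post_init__(self):
        if any(w <= 0 for w in self.weights.values()):
            raise UsageError("umbrella weights must be positive")

    def weight(self, n) -> float:
        return self.weights.get(n, min(self.weights.values()))


@dataclass
class FreeEnergyProfile:
    """Unbiased P(n) and F(n) = -kT ln P(n), offset so min F = 0."""

    n: np.ndarray
    probability: np.ndarray
    free_energy_kT: np.ndarray
    free_energy_kcal_mol: np.ndarray
    probability_se: np.ndarray
    temperature: float
    sampled: np.ndarray  # bool mask: visited at least once

    def delta_f_kT(self, n_from: int, n_to: int) -> float:
        i_from = int(np.flatnonzero(self.n == n_from)[0])
        i_to = int(np.flatnonzero(self.n == n_to)[0])
        return float(self.free_energy_kT[i_to] - self.free_energy_kT[i_from])


def profile_from_counts(
    counts: dict,
    weights: dict,
    temperature: float,
    params: Optional[ModelParameters] = None,
    block_counts: Optional[Sequence[dict]] = None,
) -> FreeEnergyProfile:
    """Reweight biased visit counts to an unbiased free-energy profile."""
    support = np.array(sorted(set(counts) | set(weights)), dtype=int)
    raw = np.array([counts.get(int(v), 0) for v in support], dtype=float)
    w = np.array([weights.get(int(v), 1.0) for v in support], dtype=float)
    unbiased = raw / w
    total = unbiased.sum()
    if total <= 0:
        raise UsageError("no visits recorded in any order-parameter bin")
    prob = unbiased / total
    sampled = raw > 0
    with np.errstate(divide="ignore"):
        f_kT = -np.log(np.where(sampled, prob, np.nan))
    f_kT -= np.nanmin(f_kT)
    se = np.zeros_like(prob)
    if block_counts:
        probs = []
        for bc in block_counts:
            braw = np.array([bc.get(int(v), 0) for v in support], dtype=float)
            bun = braw / w
            if bun.sum() > 0:
                probs.append(bun / bun.sum())
        if len(probs) >= 2:
            se = np.std(probs, axis=0, ddof=1) / math.sqrt(len(probs))
    kcal = f_kT * (temperature / 3000.0)
    if params is not None:
        kcal = f_kT * params.kT_of(temperature) * params.energy_kcal_mol
    return FreeEnergyProfile(
        n=support,
        probability=prob,
        free_energy_kT=f_kT,
        free_energy_kcal_mol=kcal,
        probability_se=se,
        temperature=temperature,
        sampled=sampled,
    )


def run_umbrella(
    config: Configuration,
    params: ModelParameters,
    bias: BiasSpec,
    sweeps: int,
    order_param: Optional[Callable[[Configuration], int]] = None,
    move_set: Optional[MoveSet] = None,
    seed: int = 0,
    n_blocks: int = 5,
    burn_in: Optional[int] = None,
    energy_fn: Optional[Callable[[Configuration], float]] = None,
) -> FreeEnergyProfile:
    """Biased equilibrium sampling of the model along an order parameter.

    The default order parameter counts detected native base pairs.  Visits
    are reweighted by 1/weight, normalized, and offset so the minimum free
    energy is zero; uncertainties come from block averaging over
    ``n_blocks`` contiguous blocks.
    """
    from .structure import detect_base_pairs

    if order_param is None:
        def order_param(c):
            return detect_base_pairs(c, params).n_native

    rng = np.random.default_rng(seed)
    if burn_in is None:
        burn_in = max(10, sweeps // 10)
    for _ in range(burn_in):
        vmmc_sweep(config, params, move_set, rng, bias=bias,
                   order_param=order_param, energy_fn=energy_fn)
    counts: dict = {}
    block_counts = [dict() for _ in range(n_blocks)]
    for s in range(sweeps):
        vmmc_sweep(config, params, move_set, rng, bias=bias,
                   order_param=order_param, energy_fn=energy_fn)
        nv = int(order_param(config))
        counts[nv] = counts.get(nv, 0) + 1
        blk = block_counts[min(s * n_blocks // sweeps, n_blocks - 1)]
        blk[nv] = blk.get(nv, 0) + 1
    return profile_from_counts(
        counts, bias.weights, config.temperature, params, block_counts
    )


def adapt_umbrella_weights(
    counts: dict, weights: dict, damping: float = 0.6
) -> dict:
    """Multiplicative update of umbrella weights toward a flat histogram."""
    mean = np.mean([c for c in counts.values() if c > 0])
    new = {}
    for n, w in weights.items():
        c = counts.get(n, 0)
        factor = (mean / c) ** damping if c > 0 else 2.0
        new[n] = w * factor
    norm = min(new.values())
    return {n: w / norm for n, w in new.items()}
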