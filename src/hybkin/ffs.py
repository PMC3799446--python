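"""Direct forward flux sampling: initial flux, staged shooting, rates.

A rare transition A -> B is split by an ordered set of interfaces on a
progress coordinate lambda.  The rate is the flux of first crossings of the
first interface out of basin A, multiplied by the conditional probabilities
of reaching each next interface before falling back to A:

    k = Phi_0 * prod_i p_i,   p_i = P(lambda_{i+1} before lambda_A | at i).

The engine is generic over a system protocol (an object with
``initial_state(rng)``, ``propagate(state, rng)`` advancing one stride,
``order_param(state)``, ``copy_state(state)`` and ``time_per_stride``), so
the same code drives both the one-dimensional toy oracles and the DNA model.
Shots resample stored interface states uniformly with replacement; stores
are capped by reservoir sampling; errors are binomial per stage and combined
in quadrature on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from .model import Configuration, ModelParameters, UsageError
from .dynamics import ThermostatSettings, evolve, draw_velocities
from .structure import OrderParameterSpec, eval_order_parameter
from .fixtures import ToySystem, walker_step


class BudgetExhaustedError(RuntimeError):
    """No qualifying event occurred within the step budget."""


class IncompleteRunError(RuntimeError):
    """A stage required for rate composition is missing."""


@dataclass(frozen=True)
class InterfaceSet:
    """Basin definition plus strictly increasing interface values.

    ``lambda_A`` bounds the unbound basin from above; ``interfaces`` are the
    staged crossing values, the last being the full-transition target.
    """

    lambda_A: float
    interfaces: tuple
    capacity: int = 512

    def __post_init__(self):
        lam = tuple(self.interfaces)
        if len(lam) < 1:
            raise UsageError("at least one interface required")
        if any(b <= a for a, b in zip(lam, lam[1:])):
            raise UsageError("interfaces must be strictly increasing")
        if lam[0] <= self.lambda_A:
            raise UsageError("first interface must exceed lambda_A")
        object.__setattr__(self, "interfaces", lam)

    @property
    def target(self) -> float:
        return self.interfaces[-1]


@dataclass
class StageRecord:
    lambda_value: float
    n_shots: int
    n_success: int
    p: float
    p_se: float
    warning: Optional[str] = None


@dataclass
class FFSRateEstimate:
    """Composed FFS rate with per-stage diagnostics and uncertainties."""

    phi0: float
    phi0_se: float
    stages: List[StageRecord]
    k: float
    k_se: float
    seed: int
    time_unit: str = "simulation time"
    box: Optional[float] = None
    temperature: Optional[float] = None
    diffusion_scale: float = 1.0

    @property
    def p(self) -> np.ndarray:
        return np.array([s.p for s in self.stages])

    def bimolecular_rate(self, box_edge_sim: float, length_nm: float) -> float:
        """k * V * N_A for one strand pair in a periodic box, in /M/time."""
        edge_m = box_edge_sim * length_nm * 1e-9
        v_l = edge_m**3 * 1e3
        return self.k * v_l * 6.02214076e23


def _reservoir_append(store: list, item, capacity: int, count: int, rng) -> int:
    """Reservoir sampling into a capped store; returns the new item count."""
    count += 1
    if len(store) < capacity:
        store.append(item)
    else:
        j = int(rng.integers(count))
        if j < capacity:
            store[j] = item
    return count


def measure_initial_flux(
    system,
    interfaces: InterfaceSet,
    min_crossings: int = 50,
    rng: Optional[np.random.Generator] = None,
    max_strides: int = 2_000_000,
    state=None,
):
    """Count forward crossings of the first interface from basin A.

    A crossing is scored when lambda moves from below the first interface to
    at or above it, provided the trajectory has re-entered the basin
    (lambda <= lambda_A) since the previous crossing — successive crossings
    are therefore decorrelated at the basin level.  The flux clock counts
    only time during which the trajectory last visited basin A rather than
    the product state (irrelevant for genuinely rare transitions, but it
    keeps the estimator exact on toy systems where the product basin is
    visited during the flux run).  Returns (Phi_0, Phi_0_SE, stored states).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lam0 = interfaces.interfaces[0]
    lam_target = interfaces.target
    if state is None:
        state = system.initial_state(rng)
    lam = system.order_param(state)
    armed = lam <= interfaces.lambda_A
    in_a_history = True
    crossings = 0
    count_seen = 0
    store: list = []
    strides = 0
    strides_in_a = 0
    while crossings < min_crossings:
        if strides >= max_strides:
            raise BudgetExhaustedError(
                f"{crossings} crossings after {strides} strides "
                f"(lambda now {lam:.3g}, basin {interfaces.lambda_A:.3g}, "
                f"first interface {lam0:.3g})"
            )
        prev = lam
        state = system.propagate(state, rng)
        lam = system.order_param(state)
        strides += 1
        if lam >= lam_target:
            in_a_history = False
        if lam <= interfaces.lambda_A:
            armed = True
            in_a_history = True
        if in_a_history:
            strides_in_a += 1
        if in_a_history and armed and prev < lam0 <= lam:
            crossings += 1
            armed = False
            count_seen = _reservoir_append(
                store, system.copy_state(state), interfaces.capacity, count_seen, rng
            )
    total_time = strides_in_a * system.time_per_stride
    phi0 = crossings / total_time
    phi0_se = math.sqrt(crossings) / total_time  # Poisson counting error
    return phi0, phi0_se, store


def shoot_interface(
    system,
    states: Sequence,
    lambda_next: float,
    lambda_A: float,
    n_shots: int,
    rng: Optional[np.random.Generator] = None,
    max_strides: int = 200_000,
    capacity: int = 512,
):
    """Fire ``n_shots`` fresh-noise continuations from stored states.

    Success: reach ``lambda_next`` before falling back to ``lambda_A``.
    Returns (p, p_se, reached_states, warning).
    """
    if not states:
        raise UsageError("empty interface state store")
    if rng is None:
        rng = np.random.default_rng(0)
    successes = 0
    reached: list = []
    count_seen = 0
    for _ in range(n_shots):
        start = system.copy_state(states[int(rng.integers(len(states)))])
        state = system.refresh(start, rng) if hasattr(system, "refresh") else start
        for _ in range(max_strides):
            state = system.propagate(state, rng)
            lam = system.order_param(state)
            if lam >= lambda_next:
                successes += 1
                count_seen = _reservoir_append(
                    store=reached,
                    item=system.copy_state(state),
                    capacity=capacity,
                    count=count_seen,
                    rng=rng,
                )
                break
            if lam <= lambda_A:
                break
        # a shot that exhausts its stride budget counts as a failure
    p = successes / n_shots
    p_se = math.sqrt(max(p * (1 - p), 1.0 / n_shots) / n_shots)
    warning = "all shots failed" if successes == 0 else None
    return p, p_se, reached, warning


def run_ffs(
    system,
    interfaces: InterfaceSet,
    n_shots: int = 200,
    min_crossings: int = 50,
    seed: int = 0,
    max_strides_flux: int = 2_000_000,
    max_strides_shot: int = 200_000,
) -> FFSRateEstimate:
    """Full direct-FFS pipeline: flux measurement plus staged shooting."""
    rng = np.random.default_rng(seed)
    phi0, phi0_se, store = measure_initial_flux(
        system, interfaces, min_crossings, rng, max_strides_flux
    )
    stages: List[StageRecord] = []
    for lam_next in interfaces.interfaces[1:]:
        p, p_se, store, warning = shoot_interface(
            system,
            store,
            lam_next,
            interfaces.lambda_A,
            n_shots,
            rng,
            max_strides_shot,
            interfaces.capacity,
        )
        stages.append(StageRecord(lam_next, n_shots, int(round(p * n_shots)), p, p_se, warning))
        if warning:
            break
    return estimate_rate(
        phi0, phi0_se, stages, seed=seed,
        n_stages_expected=len(interfaces.interfaces) - 1,
        system=system,
    )


def estimate_rate(
    phi0: float,
    phi0_se: float,
    stages: Sequence[StageRecord],
    seed: int = 0,
    n_stages_expected: Optional[int] = None,
    system=None,
) -> FFSRateEstimate:
    """Compose k = Phi_0 * prod p_i with log-scale error propagation."""
    if n_stages_expected is not None and len(stages) < n_stages_expected:
        if not (stages and stages[-1].warning):
            raise IncompleteRunError(
                f"only {len(stages)} of {n_stages_expected} stages present"
            )
    k = phi0
    for s in stages:
        k *= s.p
    if k > 0:
        rel2 = (phi0_se / phi0) ** 2
        for s in stages:
            rel2 += (s.p_se / s.p) ** 2
        k_se = k * math.sqrt(rel2)
    else:
        k_se = float("nan")
    est = FFSRateEstimate(
        phi0=phi0, phi0_se=phi0_se, stages=list(stages), k=k, k_se=k_se, seed=seed
    )
    if system is not None:
        est.box = getattr(system, "box", None)
        est.temperature = getattr(system, "temperature", None)
        est.diffusion_scale = getattr(system, "diffusion_scale", 1.0)
    return est


def commit_probability(
    system,
    states: Sequence,
    target: float,
    lambda_A: float,
    n_shots: int,
    rng: Optional[np.random.Generator] = None,
    max_strides: int = 200_000,
):
    """Success probability of unbiased continuations to the full transition.

    The fraction of fresh-noise shots from the given interface ensemble that
    reach ``target`` before returning to the basin; (p, binomial SE).
    """
    p, p_se, _, _ = shoot_interface(
        system, states, target, lambda_A, n_shots, rng, max_strides
    )
    return p, p_se


# ---------------------------------------------------------------------------
# system adapters
# ---------------------------------------------------------------------------


class WalkerFFSSystem:
    """Adapter: 1D overdamped double-well walker as an FFS system."""

    def __init__(self, toy: ToySystem, x_init: float = -1.0, stride: int = 10):
        self.toy = toy
        self.x_init = x_init
        self.stride = stride
        self.time_per_stride = stride * toy.params["dt"]

    def initial_state(self, rng):
        return float(self.x_init)

    def propagate(self, x, rng):
        for _ in range(self.stride):
            x = float(walker_step(self.toy, x, rng))
        return x

    def order_param(self, x):
        return x

    def copy_state(self, x):
        return float(x)


class DNAFFSSystem:
    """Adapter: the coarse-grained DNA model as an FFS system.

    Propagation runs ``stride`` dynamics steps; the order parameter is the
    staged separation/contact/base-pair coordinate.  ``refresh`` redraws
    Maxwell-Boltzmann momenta so each shot carries fresh noise.
    """

    def __init__(
        self,
        initial_config: Configuration,
        params: ModelParameters,
        thermo: ThermostatSettings,
        op_spec: OrderParameterSpec,
        stride: int = 20,
    ):
        self._initial = initial_config
        self.params = params
        self.thermo = thermo
        self.op_spec = op_spec
        self.stride = stride
        self.time_per_stride = stride * thermo.timestep
        self.box = initial_config.box
        self.temperature = initial_config.temperature
        self.diffusion_scale = thermo.diffusion_scale

    def initial_state(self, rng):
        cfg = self._initial.copy()
        draw_velocities(cfg, self.params, rng)
        return cfg

    def propagate(self, cfg, rng):
        evolve(cfg, self.params, self.thermo, self.stride, rng=rng)
        return cfg

    def order_param(self, cfg):
        return eval_order_parameter(cfg, self.op_spec, self.params)

    def copy_state(self, cfg):
        return cfg.copy()

    def refresh(self, cfg, rng):
        draw_velocities(cfg, self.params, rng)
        return cfg
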