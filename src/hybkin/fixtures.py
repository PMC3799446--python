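"""Synthetic inputs: initial configurations, sequence presets, toy oracles.

Duplex blocks are built on an idealized helix whose geometry constants are
packaged with the model parameters, then optionally relaxed by a short
deterministic gradient quench.  Misaligned and pseudoknotted structures are
assembled from duplex blocks sharing a helical axis (stems stack coaxially,
as in real two-strand pseudoknots), with unpaired segments routed on an
outer radius so backbone connectivity stays within the spring's range.

Toy systems (a one-dimensional double-well walker and a two-state dimer)
ship with independently computed reference observables — quadrature for
equilibrium quantities, long direct simulation for rates — and serve as
oracles for the sampling and rare-event machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import integrate

from .model import (
    Configuration,
    ModelParameters,
    StrandTopology,
    UsageError,
    complement,
    is_watson_crick,
    make_configuration,
    total_energy_forces_torques,
)
from .structure import max_pairs_in_register


class FeasibilityError(ValueError):
    """The requested structure mode cannot be realised for these sequences."""


# ---------------------------------------------------------------------------
# sequence presets
# ---------------------------------------------------------------------------

_PRESETS = {
    # 14-mers designed to limit unintended (misaligned) base pairing
    "nonrepetitive14": ("TATCTGGCTTGTCG", "CGACAAGCCAGATA"),
    # maximally repetitive AC/GT 14-mers: many misaligned registers available
    "repeat14": ("ACACACACACACAC", "GTGTGTGTGTGTGT"),
    # 8-mers used for sequence-dependent binding-rate comparisons
    "gc8": ("CCCGCCGC", complement("CCCGCCGC")),
    "avg8": ("TCTCCATG", complement("TCTCCATG")),
    "at8": ("ATTTATTA", complement("ATTTATTA")),
}


def sequence_presets() -> dict:
    """Named strand pairs (5'->3') with provenance labels."""
    out = {}
    for name, (s1, s2) in _PRESETS.items():
        label = {
            "nonrepetitive14": "non-repetitive 14-mer pair",
            "repeat14": "repetitive AC/GT 14-mer pair",
            "gc8": "G-C-rich 8-mer and complement",
            "avg8": "average-strength 8-mer and complement",
            "at8": "A-T-rich 8-mer and complement",
        }[name]
        out[name] = {"strands": (s1, s2), "label": label}
    return out


# ---------------------------------------------------------------------------
# configuration builder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """What to build: sequences, box, structure mode, temperature, seed.

    mode is one of ``separated_strands``, ``native_duplex``,
    ``misaligned`` (with ``register``), ``pseudoknot`` (with ``registers``
    (r1, r2) and ``split``, the strand-0 position separating the two
    blocks) or ``partial_native`` (only ``paired_positions`` of strand 0
    paired with their native partners, tails free).  ``box`` fixes the
    strand concentration (one pair per box^3).
    """

    strands: tuple
    box: float = 20.0
    mode: str = "separated_strands"
    register: int = 0
    registers: tuple = (0, 0)
    split: Optional[int] = None
    paired_positions: tuple = ()
    temperature: float = 300.0
    seed: int = 0
    separation: float = 6.0
    relax_steps: int = 200


def concentration_molar(box_edge_sim: float, params: ModelParameters) -> float:
    """Concentration of one strand pair per box, in mol/L."""
    edge_m = box_edge_sim * params.length_nm * 1e-9
    volume_l = edge_m**3 * 1e3
    return 1.0 / (6.02214076e23 * volume_l)


def _helix_site(level: float, side: int, turn: float, g: dict) -> tuple:
    """COM position and frame for a nucleotide at a bp level on side 0/1."""
    R, rise, twist = g["helix_radius"], g["rise"], g["twist"]
    phi = level * twist + turn + (math.pi if side == 1 else 0.0)
    pos = np.array([R * math.cos(phi), R * math.sin(phi), level * rise])
    a1 = -np.array([math.cos(phi), math.sin(phi), 0.0])  # inward, toward axis
    a3 = np.array([0.0, 0.0, 1.0 if side == 0 else -1.0])
    return pos, a1, a3


def _relax(cfg: Configuration, params: ModelParameters, steps: int, eta: float = 2e-3):
    """Deterministic damped gradient quench of positions and orientations."""
    from scipy.spatial.transform import Rotation

    for _ in range(steps):
        _, force, torque = total_energy_forces_torques(cfg, params)
        step = np.clip(eta * force, -0.05, 0.05)
        cfg.pos += step
        rot = np.clip(eta * torque, -0.05, 0.05)
        angles = np.linalg.norm(rot, axis=1)
        mask = angles > 1e-12
        if np.any(mask):
            Rm = Rotation.from_rotvec(rot[mask]).as_matrix()
            cfg.a1[mask] = np.einsum("nij,nj->ni", Rm, cfg.a1[mask])
            cfg.a3[mask] = np.einsum("nij,nj->ni", Rm, cfg.a3[mask])
        cfg.orthonormalize()
    return cfg


def _feasible_pairs(seq1: str, seq2: str, r: int):
    """Pairs (i, j = N-1-i+r) that are WC-complementary at register r."""
    n = len(seq1)
    out = []
    for i in range(n):
        j = n - 1 - i + r
        if 0 <= j < len(seq2) and is_watson_crick(seq1[i], seq2[j]):
            out.append((i, j))
    return out


def build_configuration(spec: FixtureSpec, params: ModelParameters) -> Configuration:
    """Construct the requested structure; deterministic given the seed."""
    strands = tuple(s.upper() for s in spec.strands)
    topo = StrandTopology(strands)
    g = params.geometry
    rng = np.random.default_rng(spec.seed)

    if spec.mode == "separated_strands":
        return _build_separated(topo, spec, params, rng)
    if spec.mode == "native_duplex":
        pairs = _feasible_pairs(strands[0], strands[1], 0)
        if len(pairs) != len(strands[0]):
            raise FeasibilityError("strands are not full complements")
        return _build_from_pairs(topo, pairs, spec, params)
    if spec.mode == "misaligned":
        if max_pairs_in_register(strands[0], strands[1], spec.register) == 0:
            raise FeasibilityError(
                f"register {spec.register} admits no base pairs for these strands"
            )
        pairs = _feasible_pairs(strands[0], strands[1], spec.register)
        return _build_from_pairs(topo, pairs, spec, params)
    if spec.mode == "pseudoknot":
        return _build_pseudoknot(topo, spec, params)
    if spec.mode == "partial_native":
        n = len(strands[0])
        pairs = [
            (i, n - 1 - i)
            for i in spec.paired_positions
            if is_watson_crick(strands[0][i], strands[1][n - 1 - i])
        ]
        if len(pairs) != len(spec.paired_positions):
            raise FeasibilityError("a requested position is not natively WC")
        return _build_from_pairs(topo, pairs, spec, params)
    raise UsageError(f"unknown structure mode {spec.mode!r}")


def _build_separated(topo, spec, params, rng):
    g = params.geometry
    n_each = [len(s) for s in topo.strands]
    pos, a1, a3 = [], [], []
    turn = 0.0
    for k, n in enumerate(n_each):
        for i in range(n):
            # single strands sit on the same helical track they occupy in a
            # duplex; level ascends with position for strand 0 and descends
            # for strand 1 so both are 5'->3' consistent
            level = i if k == 0 else (n - 1 - i)
            p, u1, u3 = _helix_site(level, k % 2, turn, g)
            pos.append(p)
            a1.append(u1)
            a3.append(u3)
    pos = np.array(pos)
    # displace strand 1 by the requested separation in a seed-derived direction
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    shift = direction * (spec.separation + 2.0)
    start1 = n_each[0]
    pos[start1:] += shift
    cfg = make_configuration(topo, pos, np.array(a1), np.array(a3), spec.box, spec.temperature)
    cfg = _relax(cfg, params, spec.relax_steps)
    return cfg


def _build_from_pairs(topo, pairs, spec, params, level_of_j=None):
    """Ideal helix with the given (i, j) pairs formed.

    Paired nucleotides sit on the helix track at their base-pair level
    (``level_of_j`` maps strand-1 position to level; default: level = j).
    Unpaired interior segments are routed as outward-bulged straight links
    between their anchoring blocks; unpaired tails extend straight past the
    strand ends.  A short gradient quench then settles the geometry.
    """
    g = params.geometry
    if not pairs:
        raise FeasibilityError("no pairs to anchor the structure")
    level_j = {j: (j if level_of_j is None else level_of_j[j]) for _, j in pairs}
    level_i = {i: level_j[j] for i, j in pairs}

    n_tot = topo.n_total
    pos = np.zeros((n_tot, 3))
    a1 = np.zeros((n_tot, 3))
    a3 = np.zeros((n_tot, 3))
    assigned = np.zeros(n_tot, bool)
    strand_start = [0, len(topo.strands[0])]

    for gi in range(n_tot):
        side = int(topo.strand_id[gi])
        p = int(topo.pos_in_strand[gi])
        levels = level_i if side == 0 else level_j
        if p in levels:
            pos[gi], a1[gi], a3[gi] = _helix_site(levels[p], side, 0.0, g)
            assigned[gi] = True

    link = 0.65  # backbone-neighbour COM spacing for unpaired segments
    for side, seq in enumerate(topo.strands):
        base = strand_start[side]
        n = len(seq)
        anchored = [p for p in range(n) if assigned[base + p]]
        # interior gaps: bulge outward between the flanking anchors
        runs = []
        for p in range(n):
            if not assigned[base + p]:
                if runs and runs[-1][-1] == p - 1:
                    runs[-1].append(p)
                else:
                    runs.append([p])
        for run in runs:
            lo, hi = run[0] - 1, run[-1] + 1
            if lo >= 0 and hi < n and assigned[base + lo] and assigned[base + hi]:
                p0, p1 = pos[base + lo], pos[base + hi]
                axis_out = (p0 + p1) / 2.0
                axis_out[2] = 0.0
                nrm = np.linalg.norm(axis_out)
                radial = axis_out / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
                m = len(run)
                for k, p in enumerate(run, start=1):
                    t = k / (m + 1)
                    bulge = 1.0 * math.sin(math.pi * t)
                    pt = p0 + (p1 - p0) * t + bulge * radial
                    pos[base + p] = pt
                    a1[base + p] = a1[base + lo]
                    a3[base + p] = a3[base + lo]
                    assigned[base + p] = True
        # tails: straight extrapolation past the outermost anchors
        if anchored:
            lo, hi = anchored[0], anchored[-1]
            d_lo = pos[base + lo] - pos[base + lo + 1] if lo + 1 < n and assigned[base + lo + 1] else np.array([0.0, 0.0, -link])
            d_hi = pos[base + hi] - pos[base + hi - 1] if hi - 1 >= 0 and assigned[base + hi - 1] else np.array([0.0, 0.0, link])
            for direction, edge, rng_ in (
                (d_lo, lo, range(lo - 1, -1, -1)),
                (d_hi, hi, range(hi + 1, n)),
            ):
                u = direction / max(np.linalg.norm(direction), 1e-9) * link
                for step, p in enumerate(rng_, start=1):
                    pos[base + p] = pos[base + edge] + u * step
                    a1[base + p] = a1[base + edge]
                    a3[base + p] = a3[base + edge]
                    assigned[base + p] = True
    cfg = make_configuration(topo, pos, a1, a3, spec.box, spec.temperature)
    cfg = _relax(cfg, params, spec.relax_steps)
    return cfg


def _build_pseudoknot(topo, spec, params):
    seq1, seq2 = topo.strands
    r1, r2 = spec.registers
    if r1 == r2:
        raise FeasibilityError("pseudoknot requires two distinct registers")
    n = len(seq1)
    split = spec.split if spec.split is not None else n // 2
    # block A: high-i strand-0 positions in register r1; block B: low-i in
    # r2; a 4-nucleotide strand-0 linker is left unpaired between the blocks
    # so the backbone can bridge the two stacked stems
    gap = 4
    block_a = [
        (i, j)
        for i, j in _feasible_pairs(seq1, seq2, r1)
        if i >= split + (gap - gap // 2)
    ]
    block_b = [
        (i, j) for i, j in _feasible_pairs(seq1, seq2, r2) if i < split - gap // 2
    ]
    # enforce disjoint strand-1 usage: drop conflicting pairs from block B
    used_j = {j for _, j in block_a}
    block_b = [(i, j) for i, j in block_b if j not in used_j]
    # keep blocks compact: drop block-B pairs overlapping block-A strand-0 range
    if len(block_a) < 2 or len(block_b) < 2:
        raise FeasibilityError(
            f"registers {spec.registers} with split {split} leave a block "
            f"with fewer than two pairs"
        )
    pairs = block_a + block_b
    js = sorted(j for _, j in pairs)
    if any(b - a != 1 for a, b in zip(js, js[1:])):
        # non-contiguous strand-1 occupancy: compress levels so stems stack
        level_of_j = {j: k for k, j in enumerate(js)}
    else:
        level_of_j = {j: j for j in js}
    cfg = _build_from_pairs(topo, pairs, spec, params, level_of_j=level_of_j)
    return cfg


# ---------------------------------------------------------------------------
# toy systems with known answers
# ---------------------------------------------------------------------------


@dataclass
class ToySystem:
    """A small stochastic system bundled with reference observables.

    ``reference()`` computes (and caches) independent oracle values:
    quadrature for equilibrium occupancies / free-energy differences and,
    for the walker, a long direct simulation for the crossing rate.
    """

    kind: str
    params: dict
    potential: Callable[[float], float]
    force: Callable[[float], float]
    _reference: dict = field(default_factory=dict)

    def reference(self, key: str, rng: Optional[np.random.Generator] = None):
        if key in self._reference:
            return self._reference[key]
        value = self._compute_reference(key, rng)
        self._reference[key] = value
        return value

    def _compute_reference(self, key, rng):
        p = self.params
        beta = 1.0 / p["kT"]
        if self.kind == "double_well_walker":
            if key == "occupancy_ratio":
                # right-well over left-well Boltzmann weight by quadrature
                z_r, _ = integrate.quad(
                    lambda x: math.exp(-beta * self.potential(x)), 0, p["x_max"]
                )
                z_l, _ = integrate.quad(
                    lambda x: math.exp(-beta * self.potential(x)), -p["x_max"], 0
                )
                return z_r / z_l
            if key == "delta_f_kT":
                return -math.log(self.reference("occupancy_ratio"))
            if key == "rate_brute_force":
                if rng is None:
                    rng = np.random.default_rng(p["seed"] + 12345)
                return brute_force_crossing_rate(self, rng)
            raise UsageError(f"unknown reference {key!r}")
        if self.kind == "two_state_dimer":
            if key == "p_bound":
                rb, rmax = p["r_bound"], p["r_max"]
                zb, _ = integrate.quad(
                    lambda r: 4 * math.pi * r**2 * math.exp(-beta * self.potential(r)),
                    1e-9, rb,
                )
                zt, _ = integrate.quad(
                    lambda r: 4 * math.pi * r**2 * math.exp(-beta * self.potential(r)),
                    1e-9, rmax,
                )
                return zb / zt
            if key == "K_eq":
                pb = self.reference("p_bound")
                return pb / (1.0 - pb)
            raise UsageError(f"unknown reference {key!r}")
        raise UsageError(f"unknown toy kind {self.kind!r}")


def make_toy(kind: str, parameters: Optional[dict] = None, seed: int = 0) -> ToySystem:
    """Build a toy system and attach its oracle machinery.

    ``double_well_walker``: overdamped 1D walker in
    U(x) = h (x^2 - 1)^2 + tilt * x, confined to |x| < x_max.
    ``two_state_dimer``: isotropic pair with a Gaussian well
    U(r) = -eps exp(-(r - r0)^2 / w^2), relative coordinate confined to a
    sphere of radius r_max; bound means r < r_bound.
    """
    parameters = dict(parameters or {})
    parameters.setdefault("seed", seed)
    if kind == "double_well_walker":
        parameters.setdefault("h", 5.0)
        parameters.setdefault("tilt", 0.0)
        parameters.setdefault("kT", 1.0)
        parameters.setdefault("D", 1.0)
        parameters.setdefault("dt", 1e-3)
        parameters.setdefault("x_max", 3.0)
        h, tilt = parameters["h"], parameters["tilt"]

        def U(x):
            return h * (x * x - 1.0) ** 2 + tilt * x

        def F(x):
            return -(4.0 * h * x * (x * x - 1.0) + tilt)

        return ToySystem(kind, parameters, U, F)
    if kind == "two_state_dimer":
        parameters.setdefault("eps", 4.0)
        parameters.setdefault("r0", 1.0)
        parameters.setdefault("w", 0.35)
        parameters.setdefault("kT", 1.0)
        parameters.setdefault("r_bound", 1.8)
        parameters.setdefault("r_max", 4.0)
        eps, r0, w = parameters["eps"], parameters["r0"], parameters["w"]

        def U(r):
            return -eps * math.exp(-((r - r0) ** 2) / w**2)

        def F(r):
            return -2.0 * eps * (r - r0) / w**2 * math.exp(-((r - r0) ** 2) / w**2)

        return ToySystem(kind, parameters, U, F)
    raise UsageError(f"unknown toy kind {kind!r}")


def walker_step(toy: ToySystem, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Euler-Maruyama step of the overdamped walker (vectorized)."""
    p = toy.params
    dt, D, kT = p["dt"], p["D"], p["kT"]
    drift = D / kT * np.vectorize(toy.force)(x) if np.ndim(x) else D / kT * toy.force(x)
    xn = x + drift * dt + np.sqrt(2 * D * dt) * rng.standard_normal(np.shape(x))
    return np.clip(xn, -p["x_max"], p["x_max"])


def brute_force_crossing_rate(
    toy: ToySystem,
    rng: np.random.Generator,
    n_walkers: int = 256,
    max_steps: int = 200_000,
    x_start: float = -1.0,
    x_target: float = 1.0,
) -> dict:
    """Mean first-passage rate left well -> right well by direct simulation.

    Runs an ensemble of independent walkers from the left minimum until each
    first reaches the right minimum; the rate is 1 / mean(first-passage time).
    """
    p = toy.params
    x = np.full(n_walkers, float(x_start))
    t_hit = np.full(n_walkers, np.nan)
    alive = np.ones(n_walkers, bool)
    rightward = x_target > x_start
    for step in range(1, max_steps + 1):
        x[alive] = walker_step(toy, x[alive], rng)
        hit = alive & ((x >= x_target) if rightward else (x <= x_target))
        t_hit[hit] = step * p["dt"]
        alive &= ~hit
        if not alive.any():
            break
    times = t_hit[~np.isnan(t_hit)]
    if len(times) < max(8, n_walkers // 4):
        raise RuntimeError("brute-force run did not accumulate enough crossings")
    mfpt = float(np.mean(times))
    se = float(np.std(times, ddof=1) / math.sqrt(len(times)))
    rate = 1.0 / mfpt
    return {
        "rate": rate,
        "rate_se": rate * se / mfpt,
        "mfpt": mfpt,
        "n_events": int(len(times)),
    }
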