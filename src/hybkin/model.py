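"""Rigid-nucleotide coarse-grained DNA model: energies, forces and torques.

Each nucleotide is a rigid body with a centre of mass and a right-handed
orthonormal frame (a1, a2, a3).  ``a1`` points from the backbone through the
base (the base-face direction), ``a3`` is the base-stacking normal and
``a2 = a3 x a1``.  Three interaction sites are rigid functions of the pose,
all displaced along ``a1``: one backbone site and two base sites (a stacking
site and a hydrogen-bonding site).

The potential is a sum of pairwise terms in the oxDNA model family:

* backbone connectivity (FENE spring between bonded backbone sites),
* hydrogen bonding (Watson-Crick specific, switched Morse well modulated by
  mutual orientation of the base faces and normals),
* stacking between bonded neighbours (switched Morse well between stacking
  sites, modulated by normal alignment; its depth grows linearly with kT and,
  in the sequence-dependent variant, carries nearest-neighbour factors),
* cross-stacking between non-bonded base sites on approaching strands,
* coaxial stacking (optional, off by default),
* excluded volume (WCA repulsion between non-bonded sites; electrostatics at
  the model's fixed high-salt condition is folded into this term).

Every term is an analytic function of the site separation and of dot products
between frame vectors, so forces and torques are exact gradients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class SchemaError(ValueError):
    """A packaged parameter table is missing or violates its schema."""


class UsageError(ValueError):
    """An operation was called with arguments outside its contract."""


class ValidationError(ValueError):
    """A Configuration violates a structural invariant."""


# ---------------------------------------------------------------------------
# sequences and topology
# ---------------------------------------------------------------------------


def complement(seq: str) -> str:
    """Watson-Crick complement of ``seq``, returned 5'->3'."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise UsageError(f"unknown base {exc.args[0]!r}") from exc


def is_watson_crick(a: str, b: str) -> bool:
    """True iff {a, b} is {A, T} or {C, G}."""
    a, b = a.upper(), b.upper()
    if a not in _BASE_INDEX or b not in _BASE_INDEX:
        raise UsageError(f"unknown base in pair ({a!r}, {b!r})")
    return COMPLEMENT[a] == b


class StrandTopology:
    """Strand sequences (each 5'->3') plus the bonded-neighbour relation.

    Nucleotides are indexed globally by concatenating the strands in order;
    within a strand indices run 5'->3'.
    """

    def __init__(self, strands: Iterable[str]):
        strands = tuple(s.upper() for s in strands)
        if not strands:
            raise UsageError("at least one strand required")
        for s in strands:
            if not s or any(b not in _BASE_INDEX for b in s):
                raise UsageError(f"invalid strand sequence {s!r}")
        self.strands = strands
        self.n_total = sum(len(s) for s in strands)
        self.strand_id = np.concatenate(
            [np.full(len(s), k, dtype=np.int64) for k, s in enumerate(strands)]
        )
        self.pos_in_strand = np.concatenate(
            [np.arange(len(s), dtype=np.int64) for s in strands]
        )
        self.base_codes = np.array(
            [_BASE_INDEX[b] for s in strands for b in s], dtype=np.int64
        )
        bonded = []
        offset = 0
        for s in strands:
            for i in range(len(s) - 1):
                bonded.append((offset + i, offset + i + 1))
            offset += len(s)
        self.bonded_pairs = (
            np.array(bonded, dtype=np.int64).reshape(-1, 2)
            if bonded
            else np.zeros((0, 2), dtype=np.int64)
        )
        self._bonded_set = frozenset(map(tuple, self.bonded_pairs.tolist()))
        n = self.n_total
        self.bonded_matrix = np.zeros((n, n), dtype=bool)
        if len(self.bonded_pairs):
            self.bonded_matrix[self.bonded_pairs[:, 0], self.bonded_pairs[:, 1]] = True
            self.bonded_matrix |= self.bonded_matrix.T
        # Watson-Crick complementarity of identities (A<->T, C<->G)
        comp_code = np.array([_BASE_INDEX[COMPLEMENT[b]] for b in BASES])
        self.wc_matrix = (
            comp_code[self.base_codes][:, None] == self.base_codes[None, :]
        )

    def base(self, i: int) -> str:
        return BASES[self.base_codes[i]]

    def are_bonded(self, i: int, j: int) -> bool:
        a, b = (i, j) if i < j else (j, i)
        return (a, b) in self._bonded_set

    def global_index(self, strand: int, pos: int) -> int:
        return int(np.flatnonzero(self.strand_id == strand)[0] + pos)

    def native_partner(self, i: int) -> int:
        """Global index of i's native partner for a two-strand duplex, or -1.

        The native partner of position p on one strand is position N-1-p on
        the other (antiparallel complements of equal length N).
        """
        if len(self.strands) != 2 or len(self.strands[0]) != len(self.strands[1]):
            return -1
        n = len(self.strands[0])
        s, p = int(self.strand_id[i]), int(self.pos_in_strand[i])
        other = 1 - s
        return int(np.flatnonzero(self.strand_id == other)[0]) + (n - 1 - p)

    def native_pair_set(self) -> frozenset:
        """All (i, j) native pairs (i < j) that are Watson-Crick complementary."""
        pairs = set()
        for i in range(self.n_total):
            j = self.native_partner(i)
            if j >= 0 and is_watson_crick(self.base(i), self.base(j)):
                pairs.add((min(i, j), max(i, j)))
        return frozenset(pairs)

    def __eq__(self, other):
        return isinstance(other, StrandTopology) and self.strands == other.strands

    def __repr__(self):
        return f"StrandTopology({self.strands!r})"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class Configuration:
    """Full microstate: per-nucleotide rigid-body pose and momenta.

    ``a1`` is the base-face direction, ``a3`` the stacking normal; both are
    (N, 3) arrays of unit vectors with ``a2 = a3 x a1`` completing a
    right-handed triad.  ``vel`` and ``angmom`` are lab-frame translational
    velocities and angular momenta (the inertia tensor is isotropic, so the
    lab-frame and body-frame components of the angular momentum coincide up
    to the frame rotation and carry the same physics).
    """

    topology: StrandTopology
    pos: np.ndarray
    a1: np.ndarray
    a3: np.ndarray
    vel: np.ndarray
    angmom: np.ndarray
    box: float
    temperature: float

    @property
    def n(self) -> int:
        return self.topology.n_total

    @property
    def kT(self) -> float:
        """Thermal energy in simulation units (kT = T[K] / 3000)."""
        return self.temperature / 3000.0

    @property
    def a2(self) -> np.ndarray:
        return np.cross(self.a3, self.a1)

    def copy(self) -> "Configuration":
        return Configuration(
            self.topology,
            self.pos.copy(),
            self.a1.copy(),
            self.a3.copy(),
            self.vel.copy(),
            self.angmom.copy(),
            self.box,
            self.temperature,
        )

    def validate(self, tol: float = 1e-8) -> None:
        n = self.n
        for name, arr in (
            ("pos", self.pos),
            ("a1", self.a1),
            ("a3", self.a3),
            ("vel", self.vel),
            ("angmom", self.angmom),
        ):
            if arr.shape != (n, 3):
                raise ValidationError(f"{name} has shape {arr.shape}, expected {(n, 3)}")
        if not self.box > 0:
            raise ValidationError("box edge must be positive")
        if not np.allclose(np.einsum("ij,ij->i", self.a1, self.a1), 1.0, atol=1e-6):
            raise ValidationError("a1 vectors are not unit length")
        if not np.allclose(np.einsum("ij,ij->i", self.a3, self.a3), 1.0, atol=1e-6):
            raise ValidationError("a3 vectors are not unit length")
        if np.max(np.abs(np.einsum("ij,ij->i", self.a1, self.a3))) > 1e-6:
            raise ValidationError("a1 and a3 are not orthogonal")

    def orthonormalize(self) -> None:
        """Project frames back onto the orthonormal manifold (Gram-Schmidt)."""
        a3 = self.a3 / np.linalg.norm(self.a3, axis=1, keepdims=True)
        a1 = self.a1 - np.einsum("ij,ij->i", self.a1, a3)[:, None] * a3
        a1 /= np.linalg.norm(a1, axis=1, keepdims=True)
        self.a3, self.a1 = a3, a1


def make_configuration(
    topology: StrandTopology,
    pos: np.ndarray,
    a1: np.ndarray,
    a3: np.ndarray,
    box: float,
    temperature: float,
) -> Configuration:
    """Configuration with zero momenta; frames are re-orthonormalized."""
    n = topology.n_total
    cfg = Configuration(
        topology,
        np.asarray(pos, float).reshape(n, 3),
        np.asarray(a1, float).reshape(n, 3),
        np.asarray(a3, float).reshape(n, 3),
        np.zeros((n, 3)),
        np.zeros((n, 3)),
        float(box),
        float(temperature),
    )
    cfg.orthonormalize()
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

_REQUIRED_SECTIONS = {
    "units": ("length_nm", "energy_kcal_mol", "kT_per_kelvin"),
    "geometry": (
        "helix_radius",
        "rise",
        "twist",
        "backbone_offset",
        "stack_offset",
        "base_offset",
    ),
    "backbone": ("eps", "r0", "delta"),
    "hydrogen_bonding": ("eps_AT", "eps_GC", "a", "r0", "r_switch", "r_cut", "angle_c0"),
    "stacking": ("eps0", "eps_kT", "a", "r0", "r_switch", "r_cut", "angle_c0", "factors"),
    "cross_stacking": ("eps", "a", "r0", "r_switch", "r_cut", "angle_c0"),
    "coaxial_stacking": ("enabled", "eps", "a", "r0", "r_switch", "r_cut", "angle_c0"),
    "excluded_volume": ("eps", "sigma_backbone", "sigma_base", "sigma_back_base"),
    "misc": ("mass", "inertia", "pairing_fraction"),
}

_ALL_NN = tuple(a + b for a in BASES for b in BASES)


@dataclass(frozen=True)
class ModelParameters:
    """All interaction constants for one parameterization variant.

    ``hb_allowed``, when set, restricts hydrogen bonding to the listed global
    index pairs (the native-only switch used to forbid misaligned bonds);
    identity-based Watson-Crick specificity always applies on top of it.
    """

    variant: str
    schema_version: int
    raw: dict = field(repr=False)
    hb_allowed: Optional[frozenset] = None
    coaxial_enabled: bool = False

    # -- unit conversions ---------------------------------------------------
    @property
    def length_nm(self) -> float:
        return self.raw["units"]["length_nm"]

    @property
    def energy_kcal_mol(self) -> float:
        return self.raw["units"]["energy_kcal_mol"]

    def kT_of(self, temperature_K: float) -> float:
        return temperature_K * self.raw["units"]["kT_per_kelvin"]

    # -- per-term accessors -------------------------------------------------
    @property
    def geometry(self) -> dict:
        return self.raw["geometry"]

    @property
    def backbone(self) -> dict:
        return self.raw["backbone"]

    @property
    def mass(self) -> float:
        return self.raw["misc"]["mass"]

    @property
    def inertia(self) -> float:
        return self.raw["misc"]["inertia"]

    @property
    def pairing_threshold(self) -> float:
        """Default base-pair detection threshold (simulation energy units).

        A fixed fraction of the mean full hydrogen-bond depth; negative.
        """
        hb = self.raw["hydrogen_bonding"]
        mean_eps = 0.5 * (hb["eps_AT"] + hb["eps_GC"])
        return -self.raw["misc"]["pairing_fraction"] * mean_eps

    def hb_strength(self, base_i: str, base_j: str) -> float:
        """Hydrogen-bond well depth; zero unless the identities are WC."""
        if not is_watson_crick(base_i, base_j):
            return 0.0
        hb = self.raw["hydrogen_bonding"]
        return hb["eps_AT"] if {base_i.upper(), base_j.upper()} == {"A", "T"} else hb["eps_GC"]

    def stack_strength(self, base_5p: str, base_3p: str, kT: float) -> float:
        st = self.raw["stacking"]
        return (st["eps0"] + st["eps_kT"] * kT) * st["factors"][base_5p + base_3p]

    def with_native_only(self, topology: StrandTopology) -> "ModelParameters":
        """Variant in which only native base pairs carry HB energy."""
        return replace(self, hb_allowed=topology.native_pair_set())

    def with_coaxial(self, enabled: bool = True) -> "ModelParameters":
        return replace(self, coaxial_enabled=enabled)


def load_parameters(variant: str = "average", source=None) -> ModelParameters:
    """Load and validate a packaged parameter table.

    Parameters
    ----------
    variant : {"average", "sequence_dependent"}
        ``average`` has base-independent bonding strengths; the
        sequence-dependent variant carries per-identity hydrogen-bonding
        depths and nearest-neighbour stacking factors.
    source : optional mapping or path
        Override the packaged table (used for schema testing).
    """
    if variant not in ("average", "sequence_dependent"):
        raise UsageError(f"unknown variant {variant!r}")
    if source is None:
        ref = resources.files("hybkin.data").joinpath(f"{variant}.json")
        raw = json.loads(ref.read_text())
    elif isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = json.load(fh)

    if raw.get("schema_version") != 1:
        raise SchemaError(f"unsupported schema_version {raw.get('schema_version')!r}")
    if raw.get("variant") != variant:
        raise SchemaError(
            f"table declares variant {raw.get('variant')!r}, requested {variant!r}"
        )
    for section, keys in _REQUIRED_SECTIONS.items():
        if section not in raw:
            raise SchemaError(f"missing section {section!r}")
        for key in keys:
            if key not in raw[section]:
                raise SchemaError(f"missing constant {section}.{key}")
    for nn in _ALL_NN:
        f = raw["stacking"]["factors"].get(nn)
        if not isinstance(f, (int, float)) or f <= 0:
            raise SchemaError(f"missing/invalid stacking factor stacking.factors.{nn}")
    for section, keys in _REQUIRED_SECTIONS.items():
        for key in keys:
            v = raw[section][key]
            if key in ("enabled", "factors"):
                continue
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise SchemaError(f"non-numeric constant {section}.{key}")
    for name in ("backbone", "hydrogen_bonding", "stacking", "cross_stacking"):
        sec = raw[name]
        if "r_cut" in sec and not sec["r_switch"] < sec["r_cut"]:
            raise SchemaError(f"{name}.r_switch must be < r_cut")
    if raw["backbone"]["delta"] <= 0 or raw["backbone"]["eps"] <= 0:
        raise SchemaError("backbone constants out of range")
    if raw["hydrogen_bonding"]["eps_AT"] <= 0 or raw["hydrogen_bonding"]["eps_GC"] <= 0:
        raise SchemaError("hydrogen-bonding depths out of range")
    if variant == "average" and raw["hydrogen_bonding"]["eps_AT"] != raw[
        "hydrogen_bonding"
    ]["eps_GC"]:
        raise SchemaError("average variant must have base-independent HB depth")

    return ModelParameters(
        variant=variant,
        schema_version=1,
        raw=raw,
        coaxial_enabled=bool(raw["coaxial_stacking"]["enabled"]),
    )


# ---------------------------------------------------------------------------
# energy report
# ---------------------------------------------------------------------------

TERMS = (
    "backbone",
    "hydrogen_bonding",
    "stacking",
    "cross_stacking",
    "coaxial_stacking",
    "excluded_volume",
)


@dataclass
class EnergyReport:
    backbone: float = 0.0
    hydrogen_bonding: float = 0.0
    stacking: float = 0.0
    cross_stacking: float = 0.0
    coaxial_stacking: float = 0.0
    excluded_volume: float = 0.0

    @property
    def total(self) -> float:
        return sum(getattr(self, t) for t in TERMS)

    def __add__(self, other: "EnergyReport") -> "EnergyReport":
        return EnergyReport(**{t: getattr(self, t) + getattr(other, t) for t in TERMS})


# ---------------------------------------------------------------------------
# radial potentials (value and d/dr)
# ---------------------------------------------------------------------------


def _fene(r, eps, r0, delta):
    # Diverges at |r - r0| = delta; extended linearly beyond 0.99 delta so the
    # energy stays C1 with a consistent gradient (the integrator's blow-up
    # guard handles configurations that stray out there).
    x = np.asarray(r, float) - r0
    xc = 0.99 * delta
    xi = np.clip(x, -xc, xc)
    denom = 1.0 - (xi / delta) ** 2
    v = -0.5 * eps * delta**2 * np.log(denom)
    dv = eps * xi / denom
    out = np.abs(x) > xc
    v = np.where(out, v + dv * (x - xi), v)
    return v, dv


def _switch(r, rs, rc):
    """C1 switching function: 1 below rs, 0 above rc."""
    r = np.asarray(r, float)
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > rs) & (r < rc)
    denom = (rc**2 - rs**2) ** 3
    rm = r[mid]
    s[mid] = (rc**2 - rm**2) ** 2 * (rc**2 + 2 * rm**2 - 3 * rs**2) / denom
    ds[mid] = 12.0 * rm * (rc**2 - rm**2) * (rs**2 - rm**2) / denom
    s[r >= rc] = 0.0
    return s, ds


def _morse_switched(r, eps, a, r0, rs, rc):
    """Morse well of depth eps at r0, smoothly truncated between rs and rc."""
    r = np.asarray(r, float)
    e = np.exp(-a * (r - r0))
    m = eps * ((1.0 - e) ** 2 - 1.0)
    dm = 2.0 * a * eps * (1.0 - e) * e
    s, ds = _switch(r, rs, rc)
    v = m * s
    dv = dm * s + m * ds
    v = np.where(r >= rc, 0.0, v)
    dv = np.where(r >= rc, 0.0, dv)
    return v, dv


def _wca(r, eps, sigma):
    rcut = 2.0 ** (1.0 / 6.0) * sigma
    r = np.asarray(r, float)
    inside = r < rcut
    rr = np.where(inside, r, rcut)
    sr6 = (sigma / rr) ** 6
    v = np.where(inside, 4.0 * eps * (sr6**2 - sr6) + eps, 0.0)
    dv = np.where(inside, 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / rr, 0.0)
    return v, dv


def _angular(c, c0):
    """Orientation factor: ((c - c0)/(1 - c0))^2 above the threshold c0, else 0.

    C1 at the threshold; reaches 1 at perfect alignment (c = 1).
    """
    x = (np.asarray(c, float) - c0) / (1.0 - c0)
    pos = x > 0.0
    m = np.where(pos, x**2, 0.0)
    dm = np.where(pos, 2.0 * x / (1.0 - c0), 0.0)
    return m, dm


# ---------------------------------------------------------------------------
# pairwise term evaluation with gradient assembly
# ---------------------------------------------------------------------------


def _min_image(d, box):
    return d - box * np.round(d / box)


def _cross_rows(a, b):
    """Row-wise cross product without np.cross's axis-juggling overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


class _Accumulator:
    def __init__(self, n):
        self.force = np.zeros((n, 3))
        self.torque = np.zeros((n, 3))
        # direct gradients with respect to frame vectors, per nucleotide
        self.grad_a1 = np.zeros((n, 3))
        self.grad_a3 = np.zeros((n, 3))

    def finalize_frame_torques(self, a1, a3):
        self.torque -= _cross_rows(a1, self.grad_a1) + _cross_rows(a3, self.grad_a3)


def _eval_term(
    cfg: Configuration,
    acc: Optional[_Accumulator],
    ii: np.ndarray,
    jj: np.ndarray,
    off_i: float,
    off_j: float,
    radial,
    eps_pair: np.ndarray,
    factors,
    rmax: float = 0.0,
) -> float:
    """Evaluate one pairwise term over pair lists (ii, jj).

    ``radial(r)`` returns the unit-depth potential and derivative; the actual
    well depth ``eps_pair`` multiplies the whole term.  ``factors`` is a list
    of (u_name, v_name, sign, c0) orientation modulations where the factor is
    ``_angular(sign * u.v, c0)``.  Gradients (forces, torques) accumulate into
    ``acc`` when given.  ``rmax``, when positive, drops pairs whose site
    separation is beyond the term's cutoff before any further work.
    """
    if len(ii) == 0:
        return 0.0
    a1, a3, pos, box = cfg.a1, cfg.a3, cfg.pos, cfg.box
    delta = _min_image(pos[jj] - pos[ii], box) + off_j * a1[jj] - off_i * a1[ii]
    r = np.sqrt(np.einsum("ij,ij->i", delta, delta))
    if rmax > 0.0:
        keep = r < rmax
        if not keep.any():
            return 0.0
        if not keep.all():
            ii, jj, delta, r = ii[keep], jj[keep], delta[keep], r[keep]
            if np.ndim(eps_pair):
                eps_pair = eps_pair[keep]
    rhat = delta / r[:, None]

    v, dv = radial(r)
    v = eps_pair * v
    dv = eps_pair * dv

    vecs = {"a1i": a1[ii], "a3i": a3[ii], "a1j": a1[jj], "a3j": a3[jj], "rhat": rhat}
    ms, dms, cs = [], [], []
    for (un, vn, sign, c0) in factors:
        c = np.einsum("ij,ij->i", vecs[un], vecs[vn])
        m, dm = _angular(sign * c, c0)
        ms.append(m)
        dms.append(dm * sign)  # derivative with respect to c itself
        cs.append(c)
    prod = np.ones_like(r)
    for m in ms:
        prod = prod * m
    energy = float(np.sum(v * prod))

    if acc is None:
        return energy

    # leave-one-out products for each factor
    k = len(ms)
    dE_ddelta = (dv * prod)[:, None] * rhat
    for idx in range(k):
        loo = np.ones_like(r)
        for l in range(k):
            if l != idx:
                loo = loo * ms[l]
        coef = v * dms[idx] * loo  # dE/dc for this factor
        un, vn, _, _ = factors[idx]
        u, w = vecs[un], vecs[vn]
        if vn == "rhat":
            # c = u . rhat ; d c/d delta = (u - c rhat)/r
            dE_ddelta += (coef / r)[:, None] * (u - cs[idx][:, None] * rhat)
            if un in ("a1i", "a3i"):
                tgt = acc.grad_a1 if un == "a1i" else acc.grad_a3
                np.add.at(tgt, ii, coef[:, None] * rhat)
            else:
                tgt = acc.grad_a1 if un == "a1j" else acc.grad_a3
                np.add.at(tgt, jj, coef[:, None] * rhat)
        else:
            # both body vectors
            ti = acc.grad_a1 if un == "a1i" else acc.grad_a3
            np.add.at(ti, ii, coef[:, None] * w)
            tj = acc.grad_a1 if vn == "a1j" else acc.grad_a3
            np.add.at(tj, jj, coef[:, None] * u)

    f_i = dE_ddelta  # force on site i
    f_j = -dE_ddelta
    np.add.at(acc.force, ii, f_i)
    np.add.at(acc.force, jj, f_j)
    # site lever arms (site - com = off * a1)
    np.add.at(acc.torque, ii, _cross_rows(off_i * a1[ii], f_i))
    np.add.at(acc.torque, jj, _cross_rows(off_j * a1[jj], f_j))
    return energy


# factor tables per term ----------------------------------------------------
# hydrogen bonding: base normals antiparallel, base faces pointing at each
# other along the separation vector
_HB_FACTORS = lambda c0: [
    ("a3i", "a3j", -1.0, c0),
    ("a1i", "rhat", +1.0, c0),
    ("a1j", "rhat", -1.0, c0),
]
_STACK_FACTORS = lambda c0: [("a3i", "a3j", +1.0, c0)]
_CROSS_FACTORS = lambda c0: [("a3i", "a3j", -1.0, c0)]
_COAX_FACTORS = lambda c0: [("a3i", "a3j", +1.0, c0)]


def _nonbonded_pairs(cfg: Configuration, cutoff: float = 2.2):
    """All non-bonded pairs (i < j) whose COM min-image distance < cutoff."""
    n = cfg.n
    if n < 2:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    iu, ju = np.triu_indices(n, k=1)
    d = _min_image(cfg.pos[ju] - cfg.pos[iu], cfg.box)
    near = np.einsum("ij,ij->i", d, d) < cutoff**2
    near &= ~cfg.topology.bonded_matrix[iu, ju]
    return iu[near], ju[near]


def _hb_eligible(cfg: Configuration, params: ModelParameters, ii, jj):
    """Filter non-bonded pairs down to HB-eligible ones, with depths."""
    if len(ii) == 0:
        return ii, jj, np.zeros(0)
    topo = cfg.topology
    wc = topo.wc_matrix[ii, jj]
    ii, jj = ii[wc], jj[wc]
    if params.hb_allowed is not None and len(ii):
        ok = np.array(
            [(min(a, b), max(a, b)) in params.hb_allowed for a, b in zip(ii, jj)]
        )
        ii, jj = ii[ok], jj[ok]
    hb = params.raw["hydrogen_bonding"]
    codes = topo.base_codes
    # pairs are already WC here, so one member being A or T marks an A-T pair
    is_at = (codes[ii] == _BASE_INDEX["A"]) | (codes[ii] == _BASE_INDEX["T"])
    eps = np.where(is_at, hb["eps_AT"], hb["eps_GC"])
    return ii, jj, eps


def _compute(cfg: Configuration, params: ModelParameters, want_gradients: bool):
    raw = params.raw
    g = raw["geometry"]
    off_back, off_stack, off_base = (
        g["backbone_offset"],
        g["stack_offset"],
        g["base_offset"],
    )
    acc = _Accumulator(cfg.n) if want_gradients else None
    rep = EnergyReport()
    kT = cfg.kT

    # backbone + stacking over bonded pairs (i is 5' of j)
    bp = cfg.topology.bonded_pairs
    bi, bj = bp[:, 0], bp[:, 1]
    bb = raw["backbone"]
    rep.backbone = _eval_term(
        cfg,
        acc,
        bi,
        bj,
        off_back,
        off_back,
        lambda r: _fene(r, bb["eps"], bb["r0"], bb["delta"]),
        np.ones(len(bi)),
        [],
    )
    st = raw["stacking"]
    codes = cfg.topology.base_codes
    fac = np.array(
        [[st["factors"][x + y] for y in BASES] for x in BASES]
    )
    eps_st = (st["eps0"] + st["eps_kT"] * kT) * fac[codes[bi], codes[bj]]
    rep.stacking = _eval_term(
        cfg,
        acc,
        bi,
        bj,
        off_stack,
        off_stack,
        lambda r: _morse_switched(r, 1.0, st["a"], st["r0"], st["r_switch"], st["r_cut"]),
        eps_st,
        _STACK_FACTORS(st["angle_c0"]),
        rmax=st["r_cut"],
    )

    # non-bonded terms
    ii, jj = _nonbonded_pairs(cfg)
    hb = raw["hydrogen_bonding"]
    hi, hj, heps = _hb_eligible(cfg, params, ii, jj)
    rep.hydrogen_bonding = _eval_term(
        cfg,
        acc,
        hi,
        hj,
        off_base,
        off_base,
        lambda r: _morse_switched(r, 1.0, hb["a"], hb["r0"], hb["r_switch"], hb["r_cut"]),
        heps,
        _HB_FACTORS(hb["angle_c0"]),
        rmax=hb["r_cut"],
    )
    cx = raw["cross_stacking"]
    rep.cross_stacking = _eval_term(
        cfg,
        acc,
        ii,
        jj,
        off_base,
        off_base,
        lambda r: _morse_switched(r, 1.0, cx["a"], cx["r0"], cx["r_switch"], cx["r_cut"]),
        np.full(len(ii), cx["eps"]),
        _CROSS_FACTORS(cx["angle_c0"]),
        rmax=cx["r_cut"],
    )
    if params.coaxial_enabled:
        co = raw["coaxial_stacking"]
        rep.coaxial_stacking = _eval_term(
            cfg,
            acc,
            ii,
            jj,
            off_stack,
            off_stack,
            lambda r: _morse_switched(
                r, 1.0, co["a"], co["r0"], co["r_switch"], co["r_cut"]
            ),
            np.full(len(ii), co["eps"]),
            _COAX_FACTORS(co["angle_c0"]),
            rmax=co["r_cut"],
        )
    ev = raw["excluded_volume"]
    ones = np.ones(len(ii))
    sixth = 2.0 ** (1.0 / 6.0)
    rep.excluded_volume = (
        _eval_term(
            cfg, acc, ii, jj, off_back, off_back,
            lambda r: _wca(r, ev["eps"], ev["sigma_backbone"]), ones, [],
            rmax=sixth * ev["sigma_backbone"],
        )
        + _eval_term(
            cfg, acc, ii, jj, off_base, off_base,
            lambda r: _wca(r, ev["eps"], ev["sigma_base"]), ones, [],
            rmax=sixth * ev["sigma_base"],
        )
        + _eval_term(
            cfg, acc, ii, jj, off_back, off_base,
            lambda r: _wca(r, ev["eps"], ev["sigma_back_base"]), ones, [],
            rmax=sixth * ev["sigma_back_base"],
        )
        + _eval_term(
            cfg, acc, ii, jj, off_base, off_back,
            lambda r: _wca(r, ev["eps"], ev["sigma_back_base"]), ones, [],
            rmax=sixth * ev["sigma_back_base"],
        )
    )
    if acc is not None:
        acc.finalize_frame_torques(cfg.a1, cfg.a3)
    return rep, acc


def total_energy(config: Configuration, params: ModelParameters) -> EnergyReport:
    rep, _ = _compute(config, params, want_gradients=False)
    return rep


def total_energy_forces_torques(
    config: Configuration, params: ModelParameters, validate: bool = True
):
    """Potential energy report plus per-nucleotide forces and torques.

    Forces and torques are the exact negative gradient of the potential with
    respect to the rigid-body pose (COM position and orientation); the
    accumulator folds the gradient signs in, so they are returned directly.
    """
    if validate:
        config.validate()
    rep, acc = _compute(config, params, want_gradients=True)
    return rep, acc.force, acc.torque


def pair_energy(
    i: int, j: int, config: Configuration, params: ModelParameters
) -> EnergyReport:
    """Interaction energy between nucleotides i and j alone.

    Symmetric in (i, j); the backbone term appears only for bonded
    neighbours, hydrogen bonding only for Watson-Crick identities.
    """
    n = config.n
    if not (0 <= i < n and 0 <= j < n):
        raise UsageError(f"index out of range: ({i}, {j}) for {n} nucleotides")
    if i == j:
        raise UsageError("pair_energy requires i != j")
    a, b = (i, j) if i < j else (j, i)
    raw = params.raw
    g = raw["geometry"]
    rep = EnergyReport()
    ii = np.array([a], np.int64)
    jj = np.array([b], np.int64)
    if config.topology.are_bonded(a, b):
        bb = raw["backbone"]
        rep.backbone = _eval_term(
            config, None, ii, jj, g["backbone_offset"], g["backbone_offset"],
            lambda r: _fene(r, bb["eps"], bb["r0"], bb["delta"]), np.ones(1), [],
        )
        st = raw["stacking"]
        codes = config.topology.base_codes
        eps = np.array(
            [params.stack_strength(BASES[codes[a]], BASES[codes[b]], config.kT)]
        )
        rep.stacking = _eval_term(
            config, None, ii, jj, g["stack_offset"], g["stack_offset"],
            lambda r: _morse_switched(r, 1.0, st["a"], st["r0"], st["r_switch"], st["r_cut"]),
            eps, _STACK_FACTORS(st["angle_c0"]),
        )
        return rep
    hi, hj, heps = _hb_eligible(config, params, ii, jj)
    hb = raw["hydrogen_bonding"]
    rep.hydrogen_bonding = _eval_term(
        config, None, hi, hj, g["base_offset"], g["base_offset"],
        lambda r: _morse_switched(r, 1.0, hb["a"], hb["r0"], hb["r_switch"], hb["r_cut"]),
        heps, _HB_FACTORS(hb["angle_c0"]),
    )
    cx = raw["cross_stacking"]
    rep.cross_stacking = _eval_term(
        config, None, ii, jj, g["base_offset"], g["base_offset"],
        lambda r: _morse_switched(r, 1.0, cx["a"], cx["r0"], cx["r_switch"], cx["r_cut"]),
        np.array([cx["eps"]]), _CROSS_FACTORS(cx["angle_c0"]),
    )
    if params.coaxial_enabled:
        co = raw["coaxial_stacking"]
        rep.coaxial_stacking = _eval_term(
            config, None, ii, jj, g["stack_offset"], g["stack_offset"],
            lambda r: _morse_switched(r, 1.0, co["a"], co["r0"], co["r_switch"], co["r_cut"]),
            np.array([co["eps"]]), _COAX_FACTORS(co["angle_c0"]),
        )
    ev = raw["excluded_volume"]
    one = np.ones(1)
    rep.excluded_volume = sum(
        _eval_term(config, None, ii, jj, oi, oj, lambda r, s=s: _wca(r, ev["eps"], s), one, [])
        for oi, oj, s in (
            (g["backbone_offset"], g["backbone_offset"], ev["sigma_backbone"]),
            (g["base_offset"], g["base_offset"], ev["sigma_base"]),
            (g["backbone_offset"], g["base_offset"], ev["sigma_back_base"]),
            (g["base_offset"], g["backbone_offset"], ev["sigma_back_base"]),
        )
    )
    return rep


def hb_energies(config: Configuration, params: ModelParameters):
    """Per-pair hydrogen-bond energies for all eligible non-bonded pairs.

    Returns a list of (i, j, energy) with i < j for pairs whose HB term is
    nonzero-capable (Watson-Crick identities within the global cutoff).
    """
    ii, jj = _nonbonded_pairs(config)
    hi, hj, heps = _hb_eligible(config, params, ii, jj)
    if len(hi) == 0:
        return []
    hb = params.raw["hydrogen_bonding"]
    g = params.raw["geometry"]
    out = []
    for a, b, e in zip(hi, hj, heps):
        val = _eval_term(
            config, None,
            np.array([a]), np.array([b]),
            g["base_offset"], g["base_offset"],
            lambda r: _morse_switched(r, 1.0, hb["a"], hb["r0"], hb["r_switch"], hb["r_cut"]),
            np.array([e]), _HB_FACTORS(hb["angle_c0"]),
        )
        out.append((int(a), int(b), float(val)))
    return out


def stacking_energies(config: Configuration, params: ModelParameters):
    """Per-bonded-pair stacking energies, as (i, j, energy)."""
    st = params.raw["stacking"]
    g = params.raw["geometry"]
    codes = config.topology.base_codes
    out = []
    for a, b in config.topology.bonded_pairs:
        eps = params.stack_strength(BASES[codes[a]], BASES[codes[b]], config.kT)
        val = _eval_term(
            config, None, np.array([a]), np.array([b]),
            g["stack_offset"], g["stack_offset"],
            lambda r: _morse_switched(r, 1.0, st["a"], st["r0"], st["r_switch"], st["r_cut"]),
            np.array([eps]), _STACK_FACTORS(st["angle_c0"]),
        )
        out.append((int(a), int(b), float(val)))
    return out


def min_interstrand_distance(config: Configuration) -> float:
    """Minimum min-image distance between base sites on different strands."""
    g_off = 0.4  # base site offset; geometry is fixed across packaged tables
    sid = config.topology.strand_id
    if len(set(sid.tolist())) < 2:
        return math.inf
    sites = config.pos + g_off * config.a1
    best = math.inf
    n = config.n
    iu, ju = np.triu_indices(n, k=1)
    inter = sid[iu] != sid[ju]
    iu, ju = iu[inter], ju[inter]
    d = _min_image(sites[ju] - sites[iu], config.box)
    if len(d):
        best = float(np.sqrt(np.min(np.einsum("ij,ij->i", d, d))))
    return best
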