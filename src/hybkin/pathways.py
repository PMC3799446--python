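"""Mechanism classification and kinetic analyses of hybridization pathways.

A misaligned duplex can reach the correctly aligned duplex without
dissociating ("internal displacement") in two ways: *inchworm* displacement,
in which base pairs of a new register form at the expense of the old one
across a bulge that migrates down the helix while the partner mapping stays
monotonic; and *pseudoknot* displacement, in which the two single-stranded
tails of a short misaligned duplex bind each other, producing a
non-monotonic (pseudoknotted) intermediate whose new register then strips
the old.  Trajectories are classified from their time-ordered secondary
structures alone; flickers shorter than a dwell threshold are ignored.

The module also houses the Arrhenius analysis (apparent activation
enthalpy from finite differences of ln k versus 1/T), kinetic-versus-
equilibrium ensemble comparisons at matched base-pair count, relative-rate
helpers and the detailed-balance identity k_off = k_on / K_eq.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import Configuration, ModelParameters, UsageError
from .structure import SecondaryStructure
from .ffs import FFSRateEstimate

R_GAS_KCAL = 1.987204258640832e-3  # kcal / mol / K

MECHANISMS = (
    "zippering",
    "inchworm",
    "pseudoknot_displacement",
    "detachment",
    "mixed",
)


class OpenRecordError(ValueError):
    """Trajectory record does not end in an absorbing state."""


class ComparabilityError(ValueError):
    """Rate estimates were produced under different run conditions."""


class ConditioningError(ValueError):
    """Ensemble states do not all have the required base-pair count."""


@dataclass
class TransitionRecord:
    """Time-ordered structures plus start/end labels and mechanism calls.

    ``mechanisms`` lists every displacement mechanism observed in order;
    ``mechanism`` is the headline label (the first displacement mechanism,
    or the overall call for simple records).
    """

    structures: tuple
    start_label: str
    end_label: str
    mechanism: str
    mechanisms: tuple

    @property
    def headline(self) -> str:
        """First displacement mechanism for mixed records, else mechanism."""
        return self.mechanisms[0] if self.mechanisms else self.mechanism


def _frame_label(ss: SecondaryStructure):
    """Coarse per-frame state: unbound, pseudoknot, or dominant register."""
    if ss.n_total == 0:
        return ("unbound",)
    if ss.pseudoknot is not None:
        return ("pseudoknot", ss.pseudoknot)
    return ("register", ss.dominant_register)


def _dwelled(labels: Sequence, dwell_min: int) -> list:
    """Collapse the label sequence, dropping runs shorter than dwell_min."""
    runs = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    kept = [lab for lab, n in runs if n >= dwell_min]
    merged = []
    for lab in kept:
        if not merged or merged[-1] != lab:
            merged.append(lab)
    return merged


def classify_transition(
    record: Sequence[SecondaryStructure],
    dwell_min: int = 10,
    n_full: Optional[int] = None,
) -> TransitionRecord:
    """Label the mechanism of a structure-sequence trajectory.

    * ``zippering``: a single register throughout, pair count growing up to
      fluctuation, ending in the full duplex of that register.
    * ``inchworm``: two registers coexist in dwelled frames with a monotonic
      (bulged, non-pseudoknotted) mapping and the new register replaces the
      old.
    * ``pseudoknot_displacement``: a dwelled pseudoknotted intermediate
      occurs between the start and end registers.
    * ``detachment``: the record ends unbound.
    * ``mixed``: both displacement mechanisms (headline label is the first).
    """
    if not record:
        raise OpenRecordError("empty record")
    structures = tuple(record)
    final = structures[-1]
    start_label = _fmt_label(_frame_label(structures[0]))

    end_lab = _frame_label(final)
    if end_lab[0] == "unbound":
        end_label = "unbound"
    elif end_lab[0] == "register" and (n_full is None or final.n_total >= n_full):
        end_label = "full_duplex"
    else:
        raise OpenRecordError(
            f"record ends in non-absorbing state {_fmt_label(end_lab)!r} "
            f"({final.n_total} pairs)"
        )

    if end_label == "unbound":
        return TransitionRecord(structures, start_label, end_label, "detachment", ())

    labels = [_frame_label(s) for s in structures]
    dwelled = _dwelled(labels, dwell_min)
    # mechanism events: dwelled pseudoknot intermediates and register changes
    events = []
    prev_reg = None
    prev_was_pk = False
    for lab in dwelled:
        if lab[0] == "pseudoknot":
            events.append("pseudoknot_displacement")
            prev_was_pk = True
        elif lab[0] == "register":
            if prev_reg is not None and lab[1] != prev_reg and not prev_was_pk:
                # register replaced with no mediating pseudoknot: a bulge
                # migrated through the duplex (inchworm displacement)
                events.append("inchworm")
            prev_reg = lab[1]
            prev_was_pk = False
    dedup = []
    for m in events:
        if not dedup or dedup[-1] != m:
            dedup.append(m)
    if not dedup:
        mechanism = "zippering"
    elif len(set(dedup)) == 1:
        mechanism = dedup[0]
    else:
        mechanism = "mixed"
    return TransitionRecord(structures, start_label, end_label, mechanism, tuple(dedup))


def _fmt_label(lab) -> str:
    if lab[0] == "unbound":
        return "unbound"
    if lab[0] == "pseudoknot":
        return f"pseudoknot{lab[1]}"
    return f"register {lab[1]}"


# ---------------------------------------------------------------------------
# Arrhenius analysis
# ---------------------------------------------------------------------------


@dataclass
class ArrheniusFit:
    """Pairwise apparent activation enthalpies from ln k versus 1/T.

    For adjacent temperature pairs, dH = -R * d(ln k) / d(1/T) in kcal/mol;
    a negative value means the rate falls as temperature rises.
    """

    temperatures: np.ndarray
    rates: np.ndarray
    rate_ses: np.ndarray
    pair_midpoints: np.ndarray
    activation_enthalpy_kcal: np.ndarray
    activation_enthalpy_se: np.ndarray


def arrhenius_apparent_enthalpy(
    temperatures: Sequence[float],
    rates: Sequence[float],
    rate_ses: Optional[Sequence[float]] = None,
) -> ArrheniusFit:
    """Finite-difference apparent activation enthalpy per temperature pair."""
    T = np.asarray(temperatures, float)
    k = np.asarray(rates, float)
    if len(T) < 2:
        raise UsageError("need at least two temperatures")
    if np.any(k <= 0):
        raise UsageError("rates must be positive")
    if rate_ses is None:
        se = np.zeros_like(k)
    else:
        se = np.asarray(rate_ses, float)
    order = np.argsort(T)
    T, k, se = T[order], k[order], se[order]
    if np.any(np.diff(T) == 0):
        raise UsageError("temperatures must be distinct")
    inv = 1.0 / T
    lnk = np.log(k)
    dH = -R_GAS_KCAL * np.diff(lnk) / np.diff(inv)
    rel = np.where(k > 0, se / k, 0.0)
    dH_se = np.abs(R_GAS_KCAL / np.diff(inv)) * np.sqrt(rel[1:] ** 2 + rel[:-1] ** 2)
    mid = 2.0 / (inv[:-1] + inv[1:])  # harmonic-mean midpoint on the 1/T axis
    return ArrheniusFit(T, k, se, mid, dH, dH_se)


# ---------------------------------------------------------------------------
# kinetic vs equilibrium ensembles
# ---------------------------------------------------------------------------


@dataclass
class EnsembleComparison:
    """Means (+-SE) of structural observables at matched base-pair count."""

    n: int
    kinetic_separation_nm: float
    kinetic_separation_se: float
    equilibrium_separation_nm: float
    equilibrium_separation_se: float
    kinetic_stacking: float
    kinetic_stacking_se: float
    equilibrium_stacking: float
    equilibrium_stacking_se: float
    n_kinetic: int
    n_equilibrium: int


def native_partner_separation_nm(
    config: Configuration, params: ModelParameters
) -> float:
    """Mean distance from each base site to its native partner's base site."""
    topo = config.topology
    off = params.geometry["base_offset"]
    sites = config.pos + off * config.a1
    dists = []
    for i in range(topo.n_total):
        j = topo.native_partner(i)
        if j > i:
            d = sites[j] - sites[i]
            d -= config.box * np.round(d / config.box)
            dists.append(np.linalg.norm(d))
    return float(np.mean(dists)) * params.length_nm


def intrastrand_stacking_count(
    config: Configuration, params: ModelParameters, fraction: float = 0.15
) -> int:
    """Number of stacked bonded neighbours.

    A neighbour pair counts as stacked when its stacking energy is below
    ``-fraction`` of the typical (average-identity) full stacking depth at
    the configuration's temperature.
    """
    from .model import stacking_energies

    st = params.raw["stacking"]
    depth = st["eps0"] + st["eps_kT"] * config.kT
    threshold = -fraction * depth
    return sum(1 for (_, _, e) in stacking_energies(config, params) if e <= threshold)


def ensemble_compare(
    kinetic_states: Sequence[Configuration],
    equilibrium_states: Sequence[Configuration],
    n: int,
    params: ModelParameters,
    n_boot: int = 200,
    seed: int = 0,
    check_n: bool = True,
) -> EnsembleComparison:
    """Compare kinetic and equilibrium ensembles conditioned on n pairs."""
    from .structure import detect_base_pairs

    if not kinetic_states or not equilibrium_states:
        raise UsageError("both ensembles must be non-empty")
    if check_n:
        for name, states in (("kinetic", kinetic_states), ("equilibrium", equilibrium_states)):
            for c in states:
                if detect_base_pairs(c, params).n_total != n:
                    raise ConditioningError(
                        f"{name} ensemble contains a state with "
                        f"{detect_base_pairs(c, params).n_total} pairs, expected {n}"
                    )
    rng = np.random.default_rng(seed)

    def stats(states):
        sep = np.array([native_partner_separation_nm(c, params) for c in states])
        stk = np.array(
            [intrastrand_stacking_count(c, params) for c in states], float
        )
        boots_sep, boots_stk = [], []
        for _ in range(n_boot):
            idx = rng.integers(len(states), size=len(states))
            boots_sep.append(sep[idx].mean())
            boots_stk.append(stk[idx].mean())
        return (
            float(sep.mean()),
            float(np.std(boots_sep, ddof=1)),
            float(stk.mean()),
            float(np.std(boots_stk, ddof=1)),
        )

    ks, ks_se, kk, kk_se = stats(kinetic_states)
    es, es_se, ek, ek_se = stats(equilibrium_states)
    return EnsembleComparison(
        n=n,
        kinetic_separation_nm=ks,
        kinetic_separation_se=ks_se,
        equilibrium_separation_nm=es,
        equilibrium_separation_se=es_se,
        kinetic_stacking=kk,
        kinetic_stacking_se=kk_se,
        equilibrium_stacking=ek,
        equilibrium_stacking_se=ek_se,
        n_kinetic=len(kinetic_states),
        n_equilibrium=len(equilibrium_states),
    )


# ---------------------------------------------------------------------------
# relative rates and detailed balance
# ---------------------------------------------------------------------------


def relative_rate(
    a: FFSRateEstimate,
    b: FFSRateEstimate,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Ratio a.k / b.k with a parametric-bootstrap confidence interval.

    Refuses to compare runs with different diffusion scales, boxes or
    temperatures: only rates measured under matched kinetics are comparable.
    """
    for attr in ("diffusion_scale", "box", "temperature"):
        va, vb = getattr(a, attr), getattr(b, attr)
        if va is not None and vb is not None and va != vb:
            raise ComparabilityError(f"{attr} differs: {va!r} vs {vb!r}")
    if b.k <= 0:
        raise UsageError("denominator rate must be positive")
    ratio = a.k / b.k
    rng = np.random.default_rng(seed)

    def resample(est):
        k = rng.normal(est.phi0, est.phi0_se)
        for s in est.stages:
            p = rng.binomial(s.n_shots, min(max(s.p, 0.0), 1.0)) / s.n_shots
            k *= p
        return k

    samples = []
    for _ in range(n_boot):
        num, den = resample(a), resample(b)
        if den > 0 and num > 0:
            samples.append(num / den)
    lo, hi = np.percentile(samples, [2.5, 97.5]) if samples else (np.nan, np.nan)
    return {"ratio": ratio, "ci95": (float(lo), float(hi)), "n_boot": len(samples)}


def dissociation_rate_from_equilibrium(
    k_on: float, K_eq: float, k_on_se: float = 0.0, K_eq_se: float = 0.0
) -> dict:
    """k_off = k_on / K_eq with first-order error propagation."""
    if k_on <= 0 or K_eq <= 0:
        raise UsageError("k_on and K_eq must be positive")
    k_off = k_on / K_eq
    rel = math.sqrt((k_on_se / k_on) ** 2 + (K_eq_se / K_eq) ** 2)
    return {"k_off": k_off, "k_off_se": k_off * rel}


# ---------------------------------------------------------------------------
# descriptive statistics of transition ensembles
# ---------------------------------------------------------------------------


def first_contact_positions(records: Sequence[Sequence[SecondaryStructure]]):
    """Strand-0 positions of the first base pair formed in each record."""
    out = []
    for rec in records:
        for ss in rec:
            if ss.n_total > 0:
                first = min(ss.pairs, key=lambda p: p.energy)
                out.append(first.pos_i if first.strand_i == 0 else first.pos_j)
                break
    return out


def mechanism_census(records: Sequence[TransitionRecord]):
    """Counts of (start label, end label, mechanism) over classified records."""
    census: dict = {}
    for r in records:
        key = (r.start_label, r.end_label, r.mechanism)
        census[key] = census.get(key, 0) + 1
    rows = [
        {"start": k[0], "end": k[1], "mechanism": k[2], "count": v}
        for k, v in sorted(census.items())
    ]
    return rows
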