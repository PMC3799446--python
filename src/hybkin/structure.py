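"""Secondary-structure descriptors: base pairs, registers, pseudoknots.

A detected base pair is an interstrand (or, in principle, intrastrand)
contact whose hydrogen-bond energy is below a negative threshold.  For a
two-strand system with both strands indexed 0..N-1 from the 5' end, the
native partner of position i is N-1-i, and the *register* of a pair (i, j)
is r = j - (N-1-i): r = 0 is correct alignment, and a structure whose
partner mapping is non-monotonic is a pseudoknot, described by the two
registers of its duplexed blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    Configuration,
    ModelParameters,
    UsageError,
    hb_energies,
    is_watson_crick,
    min_interstrand_distance,
)


@dataclass(frozen=True)
class BasePair:
    """One detected pair: global indices plus per-strand positions."""

    i: int
    j: int
    strand_i: int
    strand_j: int
    pos_i: int
    pos_j: int
    energy: float
    native: bool
    register: Optional[int]  # None for intrastrand pairs


@dataclass(frozen=True)
class SecondaryStructure:
    pairs: tuple
    n_total: int
    n_native: int
    register_hist: tuple  # sorted tuple of (register, count)
    pseudoknot: Optional[tuple]  # None or (r1, r2) with r1 > r2

    @property
    def dominant_register(self) -> Optional[int]:
        """Most-populated register; ties broken by the lowest-energy pair."""
        if not self.register_hist:
            return None
        top = max(c for _, c in self.register_hist)
        tied = [r for r, c in self.register_hist if c == top]
        if len(tied) == 1:
            return tied[0]
        best = min(
            (p for p in self.pairs if p.register in tied), key=lambda p: p.energy
        )
        return best.register

    def to_row(self, frame: int = 0) -> dict:
        """Tabular log row (one frame) for the per-frame structure log."""
        hist = ";".join(f"{r}:{c}" for r, c in self.register_hist)
        pk = "" if self.pseudoknot is None else f"{self.pseudoknot[0]},{self.pseudoknot[1]}"
        return {
            "frame": frame,
            "n_total": self.n_total,
            "n_native": self.n_native,
            "registers": hist,
            "pseudoknot": pk,
        }


def _monotonic(values: Sequence[int]) -> bool:
    v = list(values)
    inc = all(a < b for a, b in zip(v, v[1:]))
    dec = all(a > b for a, b in zip(v, v[1:]))
    return inc or dec or len(v) < 2


def structure_from_pairs(pairs: Sequence[BasePair]) -> SecondaryStructure:
    """Assemble the descriptor from an already-resolved pair set."""
    inter = sorted(
        (p for p in pairs if p.strand_i != p.strand_j), key=lambda p: (p.strand_i, p.pos_i)
    )
    registers = [p.register for p in inter if p.register is not None]
    hist: dict = {}
    for r in registers:
        hist[r] = hist.get(r, 0) + 1
    pk = None
    if not _monotonic([p.pos_j for p in inter]):
        # two most-populated registers, reported in descending order
        ranked = sorted(hist.items(), key=lambda rc: (-rc[1], rc[0]))
        rs = sorted((r for r, _ in ranked[:2]), reverse=True)
        pk = tuple(rs) if len(rs) == 2 else None
    return SecondaryStructure(
        pairs=tuple(sorted(pairs, key=lambda p: (p.i, p.j))),
        n_total=len(pairs),
        n_native=sum(p.native for p in pairs),
        register_hist=tuple(sorted(hist.items())),
        pseudoknot=pk,
    )


def detect_base_pairs(
    config: Configuration,
    params: ModelParameters,
    threshold: Optional[float] = None,
) -> SecondaryStructure:
    """Detect base pairs with HB energy at or below ``threshold``.

    If a base qualifies with two partners, the lower-energy pair is kept
    (ties broken toward the lower partner index).  Deterministic and
    independent of input pair ordering.
    """
    if threshold is None:
        threshold = params.pairing_threshold
    if not threshold < 0:
        raise UsageError("pairing threshold must be negative")
    topo = config.topology
    candidates = [
        (e, min(i, j), max(i, j))
        for (i, j, e) in hb_energies(config, params)
        if e <= threshold
    ]
    candidates.sort()  # ascending energy; ties fall back to index order
    used = set()
    pairs = []
    n = len(topo.strands[0]) if topo.strands else 0
    for e, i, j in candidates:
        if i in used or j in used:
            continue
        used.add(i)
        used.add(j)
        si, sj = int(topo.strand_id[i]), int(topo.strand_id[j])
        pi, pj = int(topo.pos_in_strand[i]), int(topo.pos_in_strand[j])
        native = topo.native_partner(i) == j
        register = None
        if si != sj:
            # orient so the register is computed from strand 0 toward strand 1
            p0, p1 = (pi, pj) if si < sj else (pj, pi)
            register = p1 - (n - 1 - p0)
        pairs.append(
            BasePair(i, j, si, sj, pi, pj, float(e), bool(native), register)
        )
    return structure_from_pairs(pairs)


def max_pairs_in_register(seq1: str, seq2: str, r: int) -> int:
    """Number of Watson-Crick pairings available at register offset ``r``.

    Position i of ``seq1`` is juxtaposed with position N-1-i+r of ``seq2``
    (both 5'->3', antiparallel); counts positions where that juxtaposition
    is complementary.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    n1, n2 = len(seq1), len(seq2)
    if abs(r) >= max(n1, n2):
        raise UsageError(f"|r| = {abs(r)} out of range for lengths {n1}, {n2}")
    count = 0
    for i in range(n1):
        j = n1 - 1 - i + r
        if 0 <= j < n2 and is_watson_crick(seq1[i], seq2[j]):
            count += 1
    return count


# ---------------------------------------------------------------------------
# staged order parameter for rare-event sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrderParameterSpec:
    """Staged progress coordinate: separation, then contact, then pairing.

    The scale is totally ordered and monotone in progress toward the duplex:

    * -1  unbound basin (minimum interstrand base-site distance > ``d_far``),
    *  0  approaching (below ``d_far`` but no contact),
    *  1  interstrand contact (minimum distance < ``d_contact``, no pair yet),
    *  1+n  with n >= 1 detected base pairs (native-only if requested).

    The full duplex of an N-mer sits at 1+N.
    """

    name: str
    pair_threshold: float
    d_far: float = 3.0
    d_contact: float = 0.85
    count_native_only: bool = False


def staged_order_parameter(
    params: ModelParameters,
    native_only: bool = False,
    d_far: float = 3.0,
    d_contact: float = 0.85,
) -> OrderParameterSpec:
    name = "distance_staged_native" if native_only else "distance_staged"
    return OrderParameterSpec(
        name=name,
        pair_threshold=params.pairing_threshold,
        d_far=d_far,
        d_contact=d_contact,
        count_native_only=native_only,
    )


_KNOWN_SPECS = ("distance_staged", "distance_staged_native")


def eval_order_parameter(
    config: Configuration, spec: OrderParameterSpec, params: ModelParameters
) -> float:
    if spec.name not in _KNOWN_SPECS:
        raise UsageError(f"unknown order-parameter spec {spec.name!r}")
    ss = detect_base_pairs(config, params, threshold=spec.pair_threshold)
    n = ss.n_native if spec.count_native_only else ss.n_total
    if n >= 1:
        return 1.0 + n
    d = min_interstrand_distance(config)
    if d < spec.d_contact:
        return 1.0
    if d < spec.d_far:
        return 0.0
    return -1.0


def duplex_target_lambda(n_bp: int) -> float:
    """Order-parameter value of the full duplex with ``n_bp`` base pairs."""
    return 1.0 + n_bp
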