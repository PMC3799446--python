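"""Constructed displacement-mechanism trajectories for the acceptance script."""

from hybkin.structure import BasePair, structure_from_pairs

N = 14


def _ss(*blocks):
    pairs = []
    for r, ipos in blocks:
        for i in ipos:
            j = N - 1 - i + r
            pairs.append(BasePair(i, N + j, 0, 1, i, j, -1.0, r == 0, r))
    return structure_from_pairs(pairs)


def build_fig5_style_records():
    """Five labelled trajectories: zippering, inchworm displacement,
    pseudoknot displacement, detachment, and a mixed route."""
    unbound = _ss()
    full = [_ss((0, range(0, N)))] * 15

    zipper = [unbound] * 12
    for k in range(1, 15):
        lo = 7 - k // 2
        zipper += [_ss((0, range(lo, lo + k)))] * 12

    inchworm = (
        [_ss((4, range(4, 14)))] * 15
        + [_ss((4, range(7, 14)), (0, range(0, 3)))] * 15
        + [_ss((4, range(10, 14)), (0, range(0, 6)))] * 15
        + full
    )
    pseudoknot = (
        [_ss((10, range(10, 14)))] * 15
        + [_ss((10, range(10, 14)), (0, range(0, 4)))] * 15
        + full
    )
    detach = [_ss((4, range(4, 14)))] * 15 + [unbound] * 12
    mixed = (
        [_ss((-10, range(0, 4)))] * 15
        + [_ss((-10, range(0, 4)), (2, range(8, 12)))] * 15
        + [_ss((2, range(2, 14)))] * 15
        + full
    )
    records = [zipper, inchworm, pseudoknot, detach, mixed]
    expected = ["zippering", "inchworm", "pseudoknot_displacement",
                "detachment", "mixed"]
    return records, expected
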