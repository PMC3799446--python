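"""Shared fixtures: parameter sets, random configurations, synthetic structures."""

import numpy as np
import pytest

from hybkin import (
    StrandTopology,
    load_parameters,
    make_configuration,
)
from hybkin.structure import BasePair, structure_from_pairs


@pytest.fixture(scope="session")
def params_avg():
    return load_parameters("average")


@pytest.fixture(scope="session")
def params_seq():
    return load_parameters("sequence_dependent")


def random_configuration(strands, seed=0, box=20.0, temperature=300.0, spacing=(0.55, 0.9)):
    """Random but backbone-plausible configuration for gradient/symmetry tests."""
    rng = np.random.default_rng(seed)
    topo = StrandTopology(strands)
    n = topo.n_total
    pos = np.zeros((n, 3))
    a1 = np.zeros((n, 3))
    a3 = np.zeros((n, 3))
    k = 0
    origin = rng.uniform(0, box, 3)
    for s in strands:
        p = origin + rng.uniform(-1, 1, 3)
        for _ in s:
            pos[k] = p
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            w = rng.normal(size=3)
            w -= (w @ v) * v
            w /= np.linalg.norm(w)
            a1[k], a3[k] = w, v
            step = rng.normal(size=3)
            step *= rng.uniform(*spacing) / np.linalg.norm(step)
            p = p + step
            k += 1
        origin = origin + rng.uniform(0.5, 1.5, 3)
    return make_configuration(topo, pos, a1, a3, box, temperature)


def synthetic_structure(n_strand, blocks):
    """SecondaryStructure from (register, strand0-positions) blocks.

    Partner position j = N-1-i+r; callers must keep j assignments disjoint.
    """
    pairs = []
    for r, ipos in blocks:
        for i in ipos:
            j = n_strand - 1 - i + r
            assert 0 <= j < n_strand, (r, i)
            pairs.append(
                BasePair(i, n_strand + j, 0, 1, i, j, -1.0, r == 0, r)
            )
    return structure_from_pairs(pairs)


@pytest.fixture
def make_structure():
    return synthetic_structure
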