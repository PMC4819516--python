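"""Shared fixtures: small synthetic datasets and hand-built toy matrices."""

import numpy as np
import pytest

from rhodate import phylo, rhodating, simdata
from rhodate.variants import GenotypeMatrix

CLADE_A = [f"AUS{i}" for i in range(1, 6)]
CLADE_B = [f"SAS{i}" for i in range(1, 6)]
OUTGROUP = ["OUT1"]
TRUE_SPLIT = 54_000.0


def toy_matrix(sample_ids, positions, calls, masks=None, universe_size=100):
    """Build a small GenotypeMatrix from explicit per-site masks.

    ``masks`` maps sample -> iterable of 1-based positions *excluded* from the
    callable universe (default: fully callable).
    """
    masks = masks or {}
    full = {}
    for s in sample_ids:
        m = np.ones(universe_size, dtype=bool)
        for p in masks.get(s, ()):
            m[p - 1] = False
        full[s] = m
    return GenotypeMatrix.from_explicit_masks(
        sample_ids, positions, np.asarray(calls, dtype=np.int8), full, universe_size
    )


def build_htree(data):
    """NJ tree from a simulated dataset, rooted by OUT1, mutations mapped."""
    m = data.matrix
    unrooted = phylo.neighbor_joining(phylo.distance_matrix(m), m.sample_ids)
    rooted = phylo.root_by_outgroup(unrooted, OUTGROUP)
    return phylo.map_mutations_parsimony(rooted, m)


def htree_on_truth(data):
    """Mutations mapped on the generating (fixed) topology."""
    return phylo.map_mutations_parsimony(data.truth.tree, data.matrix)


@pytest.fixture(scope="session")
def demo_data():
    """One mid-sized two-clade dataset (L=1e6, mixed coverage), reused widely."""
    return simdata.simulate_snv_dataset(simdata.demo_config(seed=42, L=1_000_000))


@pytest.fixture(scope="session")
def demo_full():
    """Full-scale dataset (L=1e7) for tests that need many mutations."""
    return simdata.simulate_snv_dataset(simdata.demo_config(seed=7, L=10_000_000))


@pytest.fixture(scope="session")
def default_rate():
    return rhodating.MutationRate()
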