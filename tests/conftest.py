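"""Shared fixtures: published annotations and synthetic datasets.

Everything is generated at test time from the package's own generator;
session scope keeps the heavier simulations to one run each.
"""

import pytest

from mitochar.annotation import published_annotation
from mitochar.phylo import concatenate_pcgs
from mitochar.simulate import SimulationSpec, evolve, generate_root, megophryidae_tree


@pytest.fixture(scope="session")
def bs_genome():
    return published_annotation("sangzhiensis")


@pytest.fixture(scope="session")
def bt_genome():
    return published_annotation("tuberogranulata")


@pytest.fixture(scope="session")
def synthetic_root():
    """Default-architecture synthetic genome (study layout, seed fixed)."""
    return generate_root(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def family_dataset():
    """29-taxon dataset evolved on the family-shaped reference topology."""
    spec = SimulationSpec(seed=2, tree=megophryidae_tree())
    root = generate_root(spec)
    leaves, true_tree = evolve(root, spec)
    return {"root": root, "leaves": leaves, "true_tree": true_tree}


@pytest.fixture(scope="session")
def family_supermatrix(family_dataset):
    return concatenate_pcgs({}, list(family_dataset["leaves"].values()))
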