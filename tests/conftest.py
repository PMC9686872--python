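import numpy as np
import pytest

from windtree import biomech, growth, harness, structure


@pytest.fixture(scope="session")
def cantilever():
    """Vertical homogeneous cantilever: 8 segments, L=2 m, r=2 cm, E=7 GPa."""
    return harness.make_fixtures("cantilever")


@pytest.fixture(scope="session")
def poplar_config():
    return harness.make_fixtures("poplar_preset")


@pytest.fixture(scope="session")
def grown_tree(poplar_config):
    """An 8-cycle wind-free poplar tree (shared, read-only)."""
    return harness.run_simulation(poplar_config)


def build_toy_tree(seed: int = 0, cycles: int = 3):
    """A small branched tree grown programmatically (deterministic)."""
    cfg = harness.make_fixtures("toy_tree")
    cfg.horizon = cycles
    return harness.run_simulation(cfg).tree


@pytest.fixture()
def toy_tree():
    return build_toy_tree()


def flat_stem_weight(tree):
    """Brute-force enumeration oracle: sum of internode weights."""
    total = 0.0
    for _, _, ph in structure.iter_phytomers(tree):
        total += ph.pith_biomass + sum(r.biomass for r in ph.rings)
    return total


def flat_total_weight(tree):
    """Brute-force stems + living leaves, grams."""
    total = flat_stem_weight(tree)
    for _, lf in structure.living_leaves(tree):
        total += lf.blade_biomass
    return total
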