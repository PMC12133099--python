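import numpy as np
import pytest

from regland import scenarios as sc
from regland import synthetic_data as syn
from regland.footprints import compute_footprint
from regland.library_design import MutagenesisConfig, mutate_promoter


@pytest.fixture
def window160():
    return sc.random_window(seed=11)


@pytest.fixture
def small_library(window160):
    return mutate_promoter(window160, MutagenesisConfig(n_variants=50, seed=3))


@pytest.fixture
def simulated_repressor():
    """One seeded single-repressor dataset: (window, arch, library, counts, footprint)."""
    seed = 1
    window = sc.random_window(seed)
    arch = sc.repressor_architecture(window)
    library = mutate_promoter(window, MutagenesisConfig(seed=seed))
    rates = syn.expression_rates(arch, library.codes, "active")
    table = syn.simulate_counts(
        library, rates, syn.SimulationConfig(), seed=seed, condition="active"
    )
    fp = compute_footprint(table, library)
    return window, arch, library, table, fp


def simulate_class_footprint(kind: str, seed: int, with_shift: bool = False):
    """Footprint of a class-pure simulation (SITES / SPIKE / INACTIVE)."""
    window = sc.random_window(seed + 300)
    if kind == "SITES":
        arch, cond = sc.repressor_architecture(window), "active"
    elif kind == "SPIKE":
        arch, cond = sc.spike_architecture(window), "c"
    elif kind == "INACTIVE":
        arch, cond = sc.inactive_architecture(window), "c"
    else:
        raise ValueError(kind)
    library = mutate_promoter(window, MutagenesisConfig(seed=seed))
    rates = syn.expression_rates(arch, library.codes, cond)
    table = syn.simulate_counts(
        library, rates, syn.SimulationConfig(), seed=seed, condition=cond
    )
    return compute_footprint(table, library, with_shift=with_shift)
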