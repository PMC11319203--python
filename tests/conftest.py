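import numpy as np
import pandas as pd
import pytest

import haplomethyl as hm


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort shared by read-level tests."""
    cfg = hm.SimulationConfig(
        n_individuals=20,
        chromosomes=(("chr1", 1_000_000), ("chr2", 1_000_000)),
        n_regions=12,
        seed=101,
    )
    return hm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_rates(small_cohort):
    return hm.aggregate_calls(small_cohort.calls)


def make_phenotypes(samples, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"age": rng.normal(50, 10, len(samples)), "sex": rng.integers(0, 2, len(samples))},
        index=pd.Index(samples, name="sample"),
    )
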