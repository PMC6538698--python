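import numpy as np
import pandas as pd
import pytest

import endbias as eb


@pytest.fixture(scope="session")
def toy_pool():
    """Four species with distinct first trinucleotides, shared 3' end."""
    return eb.ReferencePool(
        entries=[("m1", "AAAGGG"), ("m2", "CCAGGG"),
                 ("m3", "TTAGGG"), ("m4", "GCAGGG")],
        name="toy",
    )


@pytest.fixture(scope="session")
def sim_pool():
    """A mid-sized random pool shared by the simulation-backed unit tests."""
    return eb.simulate_pool(n=250, seed=11)


@pytest.fixture(scope="session")
def small_config():
    """Lighter forest for unit tests; acceptance uses the default config."""
    return eb.BiasModelConfig(n_estimators=150, seed=20190528)


@pytest.fixture(scope="session")
def minus1_sim(sim_pool):
    """Counts under a single 3'-terminal effect (G +0.5, U/T -0.5)."""
    spec = eb.BiasSpec(effects={(-1, "G"): 0.5, (-1, "T"): -0.5},
                       seed=3, depth=1_000_000)
    table, truth = eb.simulate_counts(sim_pool, spec)
    return spec, table, truth


def uniform_cpm_table(pool):
    df = pd.DataFrame({"s1": np.full(len(pool), 1.0)}, index=pool.ids)
    return eb.cpm(eb.CountTable(df))
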