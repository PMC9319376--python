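import numpy as np
import pandas as pd
import pytest

from netmr.gwas_io import SummaryStats, TraitMeta
from netmr.simulate import SimulationParams, simulate_system


def make_sumstats(rows, trait_id="trait", trait_type="continuous", n=10_000.0,
                  **meta_kw):
    """Build a SummaryStats from a list of row dicts with defaults filled."""
    defaults = {"chrom": "1", "eaf": 0.3, "se": 0.01, "pval": 1e-9}
    full = []
    for i, r in enumerate(rows):
        d = {"pos": (i + 1) * 100_000, **defaults, **r}
        full.append(d)
    meta = TraitMeta(trait_id, trait_type, n=n, **meta_kw)
    return SummaryStats(meta, pd.DataFrame(full))


@pytest.fixture(scope="session")
def valid_system():
    """One draw of the default mediation system (known truth)."""
    return simulate_system(SimulationParams(), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
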