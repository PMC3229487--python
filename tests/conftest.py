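import numpy as np
import pandas as pd
import pytest

from ssrpop.panel import MISSING, GeneticMap, SSRPanel
from ssrpop.simulate import SimConfig, simulate_panel


@pytest.fixture
def tiny_panel() -> SSRPanel:
    """Four varieties x three loci, one heterozygote and one missing call."""
    calls = np.array([
        [[120, 124], [200, 200], [88, 88]],
        [[120, 120], [202, 204], [88, 88]],
        [[124, 124], [200, 202], [MISSING, MISSING]],
        [[120, 124], [204, 204], [90, 90]],
    ], dtype=np.int32)
    return SSRPanel(["v1", "v2", "v3", "v4"], ["L1", "L2", "L3"], calls)


@pytest.fixture
def tiny_map() -> GeneticMap:
    table = pd.DataFrame(
        {"chromosome": [1, 1, 2], "position": [0.0, 7.5, 3.0]},
        index=pd.Index(["L1", "L2", "L3"], name="locus"))
    return GeneticMap(table)


@pytest.fixture(scope="session")
def small_sim():
    """A small but clearly structured two-subpopulation panel."""
    cfg = SimConfig(seed=42, n_subpop1=40, n_subpop2=20, n_admixed=6,
                    loci_per_chromosome=(6,) * 12,
                    mean_spacing_cm=(8.0,) * 12, divergence=0.4)
    return simulate_panel(cfg), cfg
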