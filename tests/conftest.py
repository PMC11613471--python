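import dataclasses
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from e2qtl.simulate import (
    SimulationConfig,
    plant_eqtl,
    simulate_expression,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_config():
    """Two-condition desk-scale study with planted attenuating eQTL."""
    cfg = SimulationConfig(
        n_donors=150,
        n_variants=60,
        n_genes=30,
        seed=11,
        conditions=("CTRL", "BPDE"),
    )
    return dataclasses.replace(
        cfg, planted_eqtl=plant_eqtl(cfg, 5, slope_ctrl=0.8, slope_stim=0.25)
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    genotypes = simulate_genotypes(small_config)
    expr, truth = simulate_expression(genotypes, small_config)
    return genotypes, expr, truth
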