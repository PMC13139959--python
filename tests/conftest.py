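import logging

import numpy as np
import pandas as pd
import pytest

import panelforge as pf
from panelforge.core import GenotypeMatrix, PopulationMap

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def three_pop_study():
    """Desk-scale three-population cohort with known structure (F ~ U(0.2, 0.7))."""
    cfg = pf.SimulationConfig(n_loci=400, sample_sizes=(20, 20, 10),
                              missing_rate=0.02, seed=101)
    return pf.simulate_study(cfg)


@pytest.fixture
def toy_two_group():
    """Six diploids at one locus: group A = {0,1,1}, group B = {2,2,1}.

    Hand-evaluated Weir-Cockerham components (direct scalar evaluation of the
    variance-component formulas): a = 7/72, b = -1/24, c = 1/4, theta = 7/22.
    """
    codes = np.array([[0], [1], [1], [2], [2], [1]])
    m = GenotypeMatrix([f"s{i}" for i in range(6)], ["l1"], codes)
    popmap = PopulationMap.from_items(
        {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    )
    return m, popmap


def make_matrix(codes, **kw):
    codes = np.asarray(codes)
    n, l = codes.shape
    return GenotypeMatrix([f"s{i}" for i in range(n)],
                          [f"loc{j}" for j in range(l)], codes, **kw)
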