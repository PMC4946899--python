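"""Shared fixtures: the hand-solvable two-substrate worlds D1-D3.

All three use N=2, R=(50, 50) and the species universe {A, B, AB}; only
the costs differ.  Equilibria were derived by hand from Delta=0 plus the
KKT conditions and are frozen in tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from metapart import CommunityState, CostTable, Environment, Genome

settings.register_profile("metapart", deadline=None, derandomize=True)
settings.load_profile("metapart")

A = Genome.from_label("A", 2)
B = Genome.from_label("B", 2)
AB = Genome.from_label("AB", 2)


@pytest.fixture(scope="session")
def env2():
    return Environment(R=[50.0, 50.0])


@pytest.fixture(scope="session")
def d1_costs():
    # AB outcompetes both specialists: n_AB = 100/1.9, F = ln(1/0.95)
    return CostTable.from_costs({A: 1.0, B: 1.0, AB: 1.9})


@pytest.fixture(scope="session")
def d2_costs():
    # cheap specialists win: n = 50/0.9 each, F = -ln 0.9
    return CostTable.from_costs({A: 0.9, B: 0.9, AB: 1.9})


@pytest.fixture(scope="session")
def d3_costs():
    # mixed outcome {A, AB}: H = (0.9, 1.0), n_A = 50/0.9 - 50, n_AB = 50
    return CostTable.from_costs({A: 0.9, B: 1.05, AB: 1.9})


@pytest.fixture(scope="session")
def universe2():
    return [A, B, AB]


@pytest.fixture
def d1_equilibrium_state():
    return CommunityState({AB: 100.0 / 1.9}, n_substrates=2)


D1_F = float(np.log(1 / 0.95))          # 0.051293...
D2_F = float(-np.log(0.9))              # 0.105361...
D3_F = float(-(np.log(0.9) + np.log(1.0)) / 2)  # 0.052680...
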