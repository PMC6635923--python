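"""Shared fixtures.

The expensive ABC fixtures (reference table at full desk scale and the
pseudo-observed datasets at the published posterior medians) are session
scoped so the scenario-recovery and parameter-recovery tests share one
simulation run.
"""

from __future__ import annotations

import numpy as np
import pytest

from peony import abc_inference, coalsim
from peony.coalsim import PriorConfig, ScenarioParams
from peony.datatypes import GenotypeDataset

# published posterior medians for the current sizes, split times and mutation
# rate; ancestral sizes from the companion text estimates (A2 = 9.52e3 and A1
# just below NR), which the median table omits
TRUTH_PARAMS = ScenarioParams(nj=1690, nq=4910, nr=5090, a1=5000, a2=9520,
                              t1=2430, t2=5030, mu=1.74e-4)
#: per-species nuclear sample sizes (sum of the 40 population samples)
FULL_SAMPLES = {"PJ": 255, "PQ": 118, "PR": 214}
SMALL_SAMPLES = {"PJ": 25, "PQ": 20, "PR": 25}

N_PER_SCENARIO = 5000
N_PODS = 20
ABC_SEED = 2025_0919


@pytest.fixture(scope="session")
def step2_scenarios():
    return dict(coalsim.STEP2_SCENARIOS)


@pytest.fixture(scope="session")
def prior():
    return PriorConfig()


@pytest.fixture(scope="session")
def reference_table(step2_scenarios, prior):
    """Full desk-scale ABC reference table (both step-2 scenarios)."""
    return abc_inference.build_reference(
        step2_scenarios, prior, N_PER_SCENARIO, FULL_SAMPLES, 22, seed=ABC_SEED,
    )


@pytest.fixture(scope="session")
def median_pods(step2_scenarios):
    """Summary vectors of pods simulated under scenario 1 at the published
    posterior medians."""
    rng = np.random.default_rng(ABC_SEED + 1)
    spec = step2_scenarios[1]
    return np.array([
        abc_inference.simulate_pod(spec, TRUTH_PARAMS, FULL_SAMPLES, 22,
                                   int(rng.integers(1, 2**31 - 1)))
        for _ in range(N_PODS)
    ])


@pytest.fixture()
def small_three_species() -> GenotypeDataset:
    """A small, strongly diverged three-species dataset."""
    spec = coalsim.get_scenario(1, step=2)
    params = ScenarioParams(nj=1000, nq=1000, nr=1000, a1=1000, a2=1000,
                            t1=4000, t2=8000, mu=5e-4)
    return coalsim.simulate_scenario(spec, params, SMALL_SAMPLES, 12, seed=99)
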