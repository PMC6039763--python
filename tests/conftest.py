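import numpy as np
import pytest

from membmode import synth
from membmode.synth import SyntheticParams, TetherParams

# ensemble seeds for the qualitative-contrast scenarios; five replicas
# per condition, matched seeds across paired conditions
ENSEMBLE_SEEDS = (1, 2, 3, 4, 5)
BOUND_START = 3.2  # nm: protein pre-positioned at the membrane surface
FREE_START = 8.0  # nm: protein starts in the aqueous phase


@pytest.fixture(scope="session")
def p1_ensemble():
    """Five replicas with strong P1-only attraction, pre-positioned."""
    return [synth.simulate_encounter(
        SyntheticParams.p1_only(seed=s, start_height=BOUND_START))
        for s in ENSEMBLE_SEEDS]


@pytest.fixture(scope="session")
def wt_ensemble():
    return [synth.simulate_encounter(
        SyntheticParams.wildtype(seed=s, start_height=BOUND_START))
        for s in ENSEMBLE_SEEDS]


@pytest.fixture(scope="session")
def mutant_ensemble():
    return [synth.simulate_encounter(
        SyntheticParams.mutant_p1p2(seed=s, start_height=BOUND_START))
        for s in ENSEMBLE_SEEDS]


@pytest.fixture(scope="session")
def tether_pairs():
    """Matched-seed pairs: tether off vs on, starting in solution."""
    pairs = []
    for s in ENSEMBLE_SEEDS:
        off = synth.simulate_encounter(SyntheticParams.wildtype(
            seed=s, start_height=FREE_START))
        on = synth.simulate_encounter(SyntheticParams.wildtype(
            seed=s, start_height=FREE_START,
            tether=TetherParams(enabled=True)))
        pairs.append((off, on))
    return pairs


@pytest.fixture(scope="session")
def small_bound_run():
    """One short run with planted patch engagement: a reliably
    membrane-bound fixture for integration tests."""
    return synth.simulate_encounter(
        SyntheticParams.p1_only(seed=2, n_steps=6000))
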