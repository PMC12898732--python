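import numpy as np
import pytest

import barhrm as b
from barhrm.simulate import market_cohort_spec


def run_market_cohort(seed: int):
    """Simulate and analyze one market cohort; returns (analysis, truth).

    The first three sequence-verified samples of each species serve as
    the genotype reference sets.
    """
    curves, truth = b.simulate_cohort(market_cohort_spec(seed))
    refs = {
        "PG": truth[truth.true_label == "PG"].sample_id[:3].tolist(),
        "PN": truth[truth.true_label == "PN"].sample_id[:3].tolist(),
    }
    analysis = b.analyze_cohort(curves, refs, reference_label="PG")
    return analysis, truth


@pytest.fixture(scope="session")
def grid():
    return b.simulate.temperature_grid()


@pytest.fixture(scope="session")
def market_run():
    return run_market_cohort(seed=101)
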