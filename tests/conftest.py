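import numpy as np
import pandas as pd
import pytest

from binomatch import tuning
from binomatch.protocol import make_stimulus_protocol
from binomatch.simulate import simulate_unit_population


@pytest.fixture(scope="session")
def protocol():
    return make_stimulus_protocol()


@pytest.fixture(scope="session")
def small_pop():
    """A 30-unit matched population under the standard protocol."""
    return simulate_unit_population(30, "matched", seed=7)


@pytest.fixture(scope="session")
def small_metrics(small_pop):
    return tuning.analyze_units(small_pop.spikes, small_pop.trials, small_pop.protocol)


def make_trials(protocol, rng=None):
    """Deterministic (unshuffled) trial table for handcrafted spike tests."""
    rows = []
    tid = 0
    for eye in protocol.eyes:
        for _ in range(protocol.repeats_per_eye):
            for ori in protocol.orientations_deg:
                for sf in protocol.spatial_frequencies_cpd:
                    rows.append((tid, eye, float(ori), sf, False, protocol.stim_duration_s))
                    tid += 1
            for _ in range(protocol.n_blank_conditions):
                rows.append((tid, eye, np.nan, np.nan, True, protocol.stim_duration_s))
                tid += 1
    return pd.DataFrame(
        rows,
        columns=["trial_id", "eye", "orientation_deg", "sf_cpd", "is_blank", "duration_s"],
    )
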