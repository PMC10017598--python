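import numpy as np
import pandas as pd
import pytest

from metresrtt.simulate import GenParams, simulate_cohort
from metresrtt.preprocess import filter_valid


@pytest.fixture(scope="session")
def cohort():
    """A medium simulated cohort shared across tests (default parameters)."""
    params = GenParams(n_participants=24)
    profiles, designs, trials = simulate_cohort(params, seed=2024)
    return params, profiles, designs, trials


@pytest.fixture(scope="session")
def clean(cohort):
    _, _, _, trials = cohort
    return filter_valid(trials)


def toy_trials(rows):
    """Build a minimal trial table from (participant, block, rt, correct[, accent, key]) rows."""
    recs = []
    for i, r in enumerate(rows):
        pid, block, rt, correct = r[:4]
        accent = r[4] if len(r) > 4 else 0
        key = r[5] if len(r) > 5 else "Z"
        recs.append(
            {
                "participant": pid,
                "block": block,
                "role": "learning",
                "trial": i + 1,
                "cycle": 1,
                "position_in_cycle": i % 12 + 1,
                "cue_location": 1,
                "response_key": key,
                "accent": accent,
                "rt_ms": float(rt),
                "correct": bool(correct),
            }
        )
    return pd.DataFrame(recs)
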