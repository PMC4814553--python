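"""Shared fixtures.

The heavyweight recovery study (12 synthetic subjects x 4 model inversions)
is computed once per session and shared by the acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from perceptdcm import design, synthetic
from perceptdcm.dcm import build_model_space
from perceptdcm.study import run_recovery_study, summarize_recovery

MASTER_SEED = 2026


@pytest.fixture(scope="session")
def model_space():
    return build_model_space()


@pytest.fixture(scope="session")
def model1(model_space):
    return model_space[0]


@pytest.fixture()
def small_events():
    """A miniature but complete event table covering all nine conditions."""
    rows = []
    skeleton = synthetic.generate_session_events()
    rows.append(skeleton)
    presses = {
        "press_block1": [(10.0, "face"), (30.0, "vase")],
        "press_block3": [(726.0, "face"), (750.0, "vase")],
        "press_block2": [(400.0, None)],
    }
    for cond, pts in presses.items():
        block = int(cond[-1])
        for t, percept in pts:
            rows.append(pd.DataFrame([{"onset": t, "duration": design.PRESS_DURATION,
                                       "trial_type": cond, "percept": percept,
                                       "trial_index": 0}]))
    df = pd.concat(rows, ignore_index=True)
    for block in (1, 2, 3):
        cond = f"press_block{block}"
        sub = df[df["trial_type"] == cond]
        df = pd.concat([df, design.derive_preswitch_events(
            sub, design.trial_windows(block),
            condition=f"preswitch_block{block}")], ignore_index=True)
    return design.validate_events(df.sort_values("onset", ignore_index=True))


@pytest.fixture(scope="session")
def recovery():
    """The 12-subject model/parameter recovery study (shared, ~minutes)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_recovery_study(n_young=6, n_older=6,
                                    master_seed=MASTER_SEED)
    return result


@pytest.fixture(scope="session")
def recovery_summary(recovery):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return summarize_recovery(recovery)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
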