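import numpy as np
import pandas as pd
import pytest

import retestkit as rk


def make_dataset(n_subjects=6, n_days=3, n_trials=2, test="stroop",
                 group="g1", scores=None, seed=0):
    """Small long-format dataset builder for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for d in range(1, n_days + 1):
            for t in range(1, n_trials + 1):
                if scores is not None:
                    score = scores[(s, d, t)]
                else:
                    score = 20.0 + s + rng.normal(0, 1.0)
                rows.append(
                    {
                        "subject": f"s{s + 1}",
                        "group": group,
                        "test": test,
                        "day": d,
                        "trial": t,
                        "score": score,
                    }
                )
    return rk.LongDataset(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def preset_cohort():
    """One realization of the emulated 65-subject, 5-test, 5x2 cohort."""
    return rk.simulate_cohort(rk.preset_paper_like(seed=123))


@pytest.fixture
def simple_pair():
    return rk.PairedComparison(
        label="toy 1", kind="intraday",
        x=np.array([10.0, 12.0, 14.0, 16.0]),
        y=np.array([9.0, 11.0, 12.0, 14.0]),
        n=4, subjects=("a", "b", "c", "d"),
    )
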