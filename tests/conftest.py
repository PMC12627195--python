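import numpy as np
import pytest

import serialbias as sb

PAPER_BINS = np.array([-144, -108, -72, -36, 0, 36, 72, 108, 144, 180], dtype=float)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated experiment (with trajectories)."""
    cfg = sb.SimConfig(
        n_participants=4, n_perceptual_trials=80, n_wm_trials=120, seed=11
    )
    return sb.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_summaries(small_dataset):
    return sb.prepare_condition_summaries(small_dataset.trials)


@pytest.fixture
def fast_spec3():
    return sb.HierarchicalSpec(levels=3, n_chains=2, n_warmup=400, n_samples=400, seed=3)


def make_trials(rows):
    """Minimal trial table from (participant, report, idx, target, prev, resp, random)."""
    import pandas as pd

    recs = []
    for participant, report, idx, target, prev, resp, rand in rows:
        recs.append({
            "participant": participant,
            "task": "perceptual" if report == "perceptual" else "wm",
            "report_type": report,
            "trial_index": idx,
            "target_deg": target,
            "prev_target_deg": prev,
            "response_deg": resp,
            "is_random": rand,
        })
    return pd.DataFrame(recs)
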