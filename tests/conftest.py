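import numpy as np
import pandas as pd
import pytest

import contextsim as cs


@pytest.fixture(scope="session")
def design():
    return cs.generate_design(1)


@pytest.fixture(scope="session")
def trials(design):
    return cs.simulate_behavior(design, seed=1)


@pytest.fixture(scope="session")
def meta(trials):
    return trials[["run", "trial", "onset", "item", "list", "room", "memory_status"]]


@pytest.fixture()
def tiny_neural():
    """One small ROI on a small grid; quiet noise for fast GLM tests."""

    return cs.NeuralParams(
        grid_shape=(4, 4, 2),
        roi_spec={"left_ant_hf": 20},
        recollection_gain={"left_ant_hf": {"immediate": 0.5, "delayed": 0.1}},
        context_gain={"left_ant_hf": {"immediate": 0.35, "delayed": 0.35}},
    )


def noiseless(params: cs.NeuralParams) -> cs.NeuralParams:
    from dataclasses import replace

    return replace(
        params,
        pattern_noise_sd=0.0,
        voxel_baseline_sd=0.0,
        noise_sd=0.0,
        ar1_phi=0.0,
        drift_amplitude=0.0,
        motion_coupling=0.0,
        motion_spike_rate=0.0,
        baseline_signal=0.0,
    )


def make_trial_frame(responses, lists, rooms=None, runs=None):
    """Minimal hand-built trial table for scoring tests."""

    n = len(responses)
    return pd.DataFrame(
        {
            "run": runs if runs is not None else np.zeros(n, dtype=int),
            "trial": np.arange(n),
            "onset": np.arange(n, dtype=float) * 6.0,
            "item": [f"w{i}" for i in range(n)],
            "list": lists,
            "room": rooms if rooms is not None else ["bedroom"] * n,
            "response": responses,
        }
    )
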