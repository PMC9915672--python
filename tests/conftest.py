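import numpy as np
import pandas as pd
import pytest

from popcode.synth import SynthConfig, generate_population, generate_traces

LEVELS = (0.0, 30.0, 50.0, 60.0, 70.0, 80.0, 90.0)


@pytest.fixture(scope="session")
def small_population():
    """Six-neuron mixed population with default (SST) laser effects."""
    cfg = SynthConfig(n_neurons=6, seed=1, noise_sd=0.1)
    truth, table = generate_population(cfg)
    return cfg, truth, table


@pytest.fixture(scope="session")
def small_traceset(small_population):
    cfg, truth, table = small_population
    return generate_traces(truth, cfg, table)


def make_table(responses: dict, n_trials: int = 1, noise: float = 0.0, seed: int = 0):
    """Tidy table from {(neuron, laser): level->response} mappings.

    `responses` maps (neuron_id, laser) to a sequence over LEVELS.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (nid, laser), vals in responses.items():
        for lv, v in zip(LEVELS, vals):
            for t in range(n_trials):
                rows.append(
                    (nid, lv, laser, t, float(v) + (rng.normal(0, noise) if noise else 0.0))
                )
    return pd.DataFrame(rows, columns=["neuron_id", "level_db", "laser", "trial", "response"])
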