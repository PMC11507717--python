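"""Shared fixtures: the packaged matrix and a reusable planted screen."""

import numpy as np
import pytest

import lawnscreen as ls


@pytest.fixture(scope="session")
def fixture_matrix():
    return ls.make_fixture_matrix()


@pytest.fixture(scope="session")
def planted_screen(fixture_matrix):
    """One planted k=4 screen with 5%-of-max replicate noise, 5 reps."""
    M = fixture_matrix
    truth = ls.plant_ground_truth(M, k=4, weight_low=20.0, weight_high=60.0,
                                  noise_sd=0.0, seed=1003)
    effect = M.values @ truth.w_reentry
    sd = 0.05 * float(np.max(np.abs(effect)))
    truth = ls.GroundTruthScreen(
        neuron_ids=truth.neuron_ids, w_exit=truth.w_exit,
        w_reentry=truth.w_reentry,
        noise_sd={"exit_rate": sd, "reentry_latency": sd}, seed=1003)
    table = ls.simulate_phenotypes(M, truth, n_reps=5, seed=77)
    P = ls.build_phenotype_vector(
        ls.phenotypes_from_table(table, "reentry_latency"),
        "reentry_latency", alpha=0.05, line_order=M.line_ids)
    return M, truth, table, P


@pytest.fixture
def rng():
    return np.random.default_rng(0)
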