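import numpy as np
import pytest

from predfr import PredationTrial, TrialSet, holling_expectation
from predfr.datasets import detection_survey, spider_holling_fits


@pytest.fixture(scope="session")
def survey_table():
    """The published 23-taxon gut-content screening table."""
    return detection_survey()


@pytest.fixture(scope="session")
def published_fits():
    """Published disc-equation estimates for the four spider species."""
    return spider_holling_fits()


def make_noise_free_trials(
    attack_rate,
    handling_time,
    densities=(10, 15, 20, 25, 30),
    replicates=4,
    exposure_T=1.0,
    model="II",
    predator="sim",
    stage="nymph_4_5",
):
    """Trials whose consumed values are the exact disc-equation expectation.

    Densities must lie in the region where the expectation does not exceed
    the prey offered, otherwise the trial invariant (consumed <= density)
    rejects the construction.
    """
    trials = []
    for d in densities:
        mu = holling_expectation(d, attack_rate, handling_time, exposure_T, model)
        for r in range(1, replicates + 1):
            trials.append(
                PredationTrial(predator, stage, int(d), float(mu), r)
            )
    return TrialSet(predator, stage, tuple(trials), exposure_T)


def grid_search_sse(trials, model, a_grid, th_grid):
    """Exhaustive minimum SSE of the disc equation over a parameter grid.

    Independent brute-force oracle for the nonlinear least-squares fit.
    """
    dens = trials.densities
    cons = trials.consumed
    best = np.inf
    for a in a_grid:
        mu = holling_expectation(dens[None, :], a, th_grid[:, None], trials.exposure_T, model)
        sse = ((mu - cons[None, :]) ** 2).sum(axis=1)
        m = sse.min()
        if m < best:
            best = float(m)
    return best
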