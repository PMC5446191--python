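"""Shared fixtures.

The expensive stable-phase simulations (full self-organization plus a
one-million-step measurement window, pooled over four independent
runs — a reduced replication of the study's 50-run pooling) are
computed once per session and shared by all acceptance checks that
analyze stable-phase statistics.
"""

import copy
from dataclasses import dataclass

import numpy as np
import pytest

from sorncrit.avalanche import alternative_sizes, detect_avalanches, half_mean_threshold
from sorncrit.core import (
    NetworkParams,
    NetworkState,
    NoiseModel,
    PlasticityFlags,
    RecordOptions,
    clone_state,
    init_network,
    make_streams,
    simulate,
)

PHASE_CUT = 2_000_000
MEASURE_STEPS = 1_000_000
N_POOL_RUNS = 6
STABLE_SEED = 1


@dataclass
class StableRun:
    """Pooled stable-phase data from independent self-organized runs."""

    params: NetworkParams
    noise: NoiseModel
    activity: np.ndarray          # pooled measurement-window a(t)
    durations: np.ndarray         # pooled avalanche durations
    sizes: np.ndarray             # pooled avalanche sizes
    alt_sizes: np.ndarray         # pooled sizes without theta subtraction
    thetas: list                  # per-run thresholds
    unit_counts: np.ndarray       # per-unit spike totals, first run
    n_steps_per_run: int
    checkpoint: NetworkState      # first run's state at window start
    checkpoint_streams: dict


@pytest.fixture(scope="session")
def stable_run() -> StableRun:
    params = NetworkParams()
    noise = NoiseModel()
    flags = PlasticityFlags.all_on()
    activities, durations, sizes, alts, thetas = [], [], [], [], []
    unit_counts = None
    checkpoint = checkpoint_streams = None
    for r in range(N_POOL_RUNS):
        streams = make_streams(STABLE_SEED + r)
        state = init_network(params, streams["init"])
        simulate(state, PHASE_CUT, params, noise, flags, streams)
        if r == 0:
            checkpoint = clone_state(state)
            checkpoint_streams = copy.deepcopy(streams)
        rec = simulate(
            state, MEASURE_STEPS, params, noise, flags, streams,
            record=RecordOptions(unit_counts=(r == 0)),
        )
        if r == 0:
            unit_counts = rec.unit_counts
        theta = half_mean_threshold(rec.activity)
        avs = detect_avalanches(rec.activity, theta)
        alt = alternative_sizes(rec.activity, avs)
        activities.append(rec.activity)
        durations.append(avs.durations)
        sizes.append(avs.sizes)
        alts.append(alt)
        thetas.append(theta)
    return StableRun(
        params=params,
        noise=noise,
        activity=np.concatenate(activities),
        durations=np.concatenate(durations),
        sizes=np.concatenate(sizes),
        alt_sizes=np.concatenate(alts),
        thetas=thetas,
        unit_counts=unit_counts,
        n_steps_per_run=MEASURE_STEPS,
        checkpoint=checkpoint,
        checkpoint_streams=checkpoint_streams,
    )


@pytest.fixture()
def small_params() -> NetworkParams:
    return NetworkParams(n_e=50)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2023)
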