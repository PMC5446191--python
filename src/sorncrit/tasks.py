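"""Sequence-learning tasks with a linear readout on the reservoir state.

Two tasks probe the network's spatio-temporal learning:

* Counting Task (CT): random alternation of the words "ABBB...BC" and
  "DEEE...EF" with n repeated middle letters; solving it requires
  counting how many B/E repetitions have passed.
* Random Sequence Task (RST): one random word of length L over an
  alphabet of A_S letters, fixed per simulation and cycled forever.

Each letter drives a fixed, randomly chosen, non-exclusive subset of
``U_E = 0.05 N_E`` excitatory units with a supra-threshold input.  The
network first adapts under full plasticity (T_plastic steps); a layer
of readout units is then trained by the Moore-Penrose pseudo-inverse
on T_train steps and scored on T_test further steps.  The readout
predicts the letter presented at step t from the internal state x'(t),
which is the threshold update computed without the external-input term
(membrane noise retained).  For the CT the first letter of each word
(A or D) is excluded from scoring, as the word alternation is random
and that letter is inherently unpredictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .avalanche import AvalancheSet, detect_avalanches, half_mean_threshold
from .core import (
    NetworkParams,
    NetworkState,
    NoiseModel,
    PlasticityFlags,
    RecordOptions,
    SUPRATHRESHOLD,
    init_network,
    make_streams,
    simulate,
)

__all__ = [
    "TaskStream",
    "ReadoutModel",
    "TaskResult",
    "make_letter_mapping",
    "counting_task_stream",
    "random_sequence_stream",
    "letters_to_input",
    "internal_state",
    "train_readout",
    "run_task",
    "ORIGINAL_SORN_FLAGS",
]

#: Fraction of excitatory units driven per letter in the learning tasks.
TASK_SUBSET_FRAC = 0.05

#: Default alphabet size of the Random Sequence Task.
DEFAULT_ALPHABET = 10

#: Flag set matching the original three-rule SORN (no iSTDP, no SP);
#: combine with NoiseModel(kind="none") for the classic comparison arm.
ORIGINAL_SORN_FLAGS = PlasticityFlags(istdp=False, sp=False)

CT_ALPHABET = "ABCDEF"


def make_letter_mapping(
    n_letters: int, n_e: int, rng: np.random.Generator,
    subset_frac: float = TASK_SUBSET_FRAC,
) -> np.ndarray:
    """Draw one fixed unit subset per letter (non-exclusive across letters)."""
    k = int(round(subset_frac * n_e))
    if k < 1:
        raise ValueError("subset size rounds to zero; increase n_e or subset_frac")
    return np.stack([rng.choice(n_e, size=k, replace=False) for _ in range(n_letters)])


@dataclass
class TaskStream:
    """A symbolic input stream bound to a letter -> unit-subset mapping.

    Implements the letter-source protocol of :func:`sorncrit.core.simulate`:
    ``next_ids`` yields the next letter ids, ``subsets``/``amplitude``
    define the external drive.  ``alphabet`` names the letters for
    reporting.
    """

    subsets: np.ndarray
    amplitude: float
    alphabet: str | list[str]
    _emit: "object" = field(repr=False, default=None)

    def next_ids(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._emit(n, rng)

    @property
    def n_letters(self) -> int:
        return len(self.subsets)


def counting_task_stream(
    n: int,
    mapping: np.ndarray,
    amplitude: float = SUPRATHRESHOLD,
) -> TaskStream:
    """Infinite CT stream: words A B^n C and D E^n F, equiprobable.

    ``mapping`` must have one subset per letter of "ABCDEF".
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(mapping) != 6:
        raise ValueError("the counting task needs subsets for exactly 6 letters")
    word1 = np.array([0] + [1] * n + [2], dtype=np.int64)   # A B..B C
    word2 = np.array([3] + [4] * n + [5], dtype=np.int64)   # D E..E F
    buf: list[np.ndarray] = [np.empty(0, dtype=np.int64)]

    def emit(count: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(count, dtype=np.int64)
        filled = 0
        pending = buf[0]
        while filled < count:
            if pending.size == 0:
                pending = word1 if rng.random() < 0.5 else word2
            take = min(pending.size, count - filled)
            out[filled:filled + take] = pending[:take]
            pending = pending[take:]
            filled += take
        buf[0] = pending
        return out

    return TaskStream(
        subsets=np.asarray(mapping, dtype=np.int64),
        amplitude=amplitude,
        alphabet=CT_ALPHABET,
        _emit=emit,
    )


def random_sequence_stream(
    length: int,
    mapping: np.ndarray,
    rng: np.random.Generator,
    amplitude: float = SUPRATHRESHOLD,
) -> TaskStream:
    """Infinite RST stream: one random word of ``length`` letters, cycled.

    The word is drawn once here (uniform over the alphabet given by
    ``mapping``); every repetition within a run is identical.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    a_s = len(mapping)
    if a_s < 2:
        raise ValueError("need an alphabet of at least 2 letters")
    word = rng.integers(0, a_s, size=length)
    pos = [0]

    def emit(count: int, _rng: np.random.Generator) -> np.ndarray:
        idx = (pos[0] + np.arange(count)) % length
        pos[0] = (pos[0] + count) % length
        return word[idx].astype(np.int64)

    stream = TaskStream(
        subsets=np.asarray(mapping, dtype=np.int64),
        amplitude=amplitude,
        alphabet=[str(i) for i in range(a_s)],
        _emit=emit,
    )
    stream.word = word  # type: ignore[attr-defined]
    return stream


def letters_to_input(
    letters: np.ndarray, mapping: np.ndarray, amplitude: float, n_e: int
) -> np.ndarray:
    """Dense external-input vectors for a letter sequence.

    Returns shape (len(letters), n_e) with ``amplitude`` on the current
    letter's subset and 0 elsewhere; -1 denotes a silent step.
    """
    letters = np.asarray(letters)
    if letters.size and letters.max() >= len(mapping):
        raise ValueError("letter id outside the mapping")
    u = np.zeros((letters.size, n_e))
    for t, lb in enumerate(letters):
        if lb >= 0:
            u[t, mapping[lb]] = amplitude
    return u


def internal_state(
    state: NetworkState, xi_e: Optional[np.ndarray] = None
) -> np.ndarray:
    """Prediction feature x'(t): threshold update without external input.

    Identical to the excitatory update except that the u(t) term is
    forced to zero; the membrane-noise term (``xi_e``) is retained when
    supplied.
    """
    drive = state.w_ee @ state.x - state.w_ei @ state.y - state.t_e
    if xi_e is not None:
        drive = drive + xi_e
    return (drive >= 0.0).astype(float)


@dataclass(frozen=True)
class ReadoutModel:
    """Linear readout trained by Moore-Penrose pseudo-inverse.

    ``weights`` maps an internal-state vector to one score per letter;
    prediction is the argmax with ties broken by lowest letter index.
    """

    weights: np.ndarray          # (n_e, n_letters)
    trained_on: tuple[int, int] = (0, 0)

    def predict(self, features: np.ndarray) -> np.ndarray:
        scores = np.asarray(features, dtype=float) @ self.weights
        return np.argmax(scores, axis=-1)


def train_readout(
    features: np.ndarray, target_letters: np.ndarray, n_letters: int
) -> ReadoutModel:
    """Least-squares readout: weights = pinv(features) @ one_hot(targets)."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(target_letters):
        raise ValueError("features and targets are misaligned")
    if x.shape[0] < n_letters:
        raise ValueError("need at least one training step per letter")
    if not np.any(x):
        raise ValueError("degenerate all-zero features cannot be fitted")
    onehot = np.zeros((len(target_letters), n_letters))
    onehot[np.arange(len(target_letters)), np.asarray(target_letters)] = 1.0
    weights = np.linalg.pinv(x) @ onehot
    return ReadoutModel(weights=weights, trained_on=(0, x.shape[0]))


@dataclass
class TaskResult:
    """Performance and (optionally) avalanche statistics of one task run."""

    performance: float
    n_scored: int
    readout: ReadoutModel
    avalanches: Optional[AvalancheSet] = None
    theta: Optional[int] = None
    seed: Optional[int] = None


def run_task(
    params: NetworkParams,
    task: TaskStream,
    noise: NoiseModel,
    seed: int,
    flags: PlasticityFlags = PlasticityFlags.all_on(),
    t_plastic: int = 50_000,
    t_train: int = 5_000,
    t_test: int = 5_000,
    measure_steps: int = 0,
    exclude_letters: tuple[int, ...] = (),
) -> TaskResult:
    """Full task protocol: plastic phase, readout training, scoring.

    Plasticity runs for ``t_plastic`` steps under the task input, then
    is frozen for the train/test windows so the readout sees a fixed
    reservoir.  ``measure_steps`` > 0 inserts an avalanche-measurement
    window (plasticity still on) between the plastic phase and
    training; theta is the standard half-mean threshold of that window.
    ``exclude_letters`` lists letter ids dropped from scoring (the CT
    word-initial letters).
    """
    streams = make_streams(seed)
    state = init_network(params, streams["init"])
    simulate(state, t_plastic, params, noise, flags, streams, input_source=task)

    avset = None
    theta = None
    if measure_steps:
        rec_m = simulate(
            state, measure_steps, params, noise, flags, streams, input_source=task
        )
        theta = half_mean_threshold(rec_m.activity)
        avset = detect_avalanches(rec_m.activity, theta)

    frozen = PlasticityFlags.all_off()
    rec_tr = simulate(
        state, t_train, params, noise, frozen, streams,
        input_source=task, record=RecordOptions(internal=True),
    )
    readout = train_readout(rec_tr.internal, rec_tr.letters, task.n_letters)

    rec_te = simulate(
        state, t_test, params, noise, frozen, streams,
        input_source=task, record=RecordOptions(internal=True),
    )
    pred = readout.predict(rec_te.internal)
    scored = ~np.isin(rec_te.letters, exclude_letters)
    n_scored = int(scored.sum())
    perf = float((pred[scored] == rec_te.letters[scored]).mean())
    return TaskResult(
        performance=perf,
        n_scored=n_scored,
        readout=readout,
        avalanches=avset,
        theta=theta,
        seed=seed,
    )
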