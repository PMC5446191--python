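"""Experiment protocols: development phases, frozen plasticity, noise
regimes, subset noise and external-input onset/readaptation.

Every protocol self-organizes one or more networks through the
transient (``phase_cut`` steps), measures avalanches in the stable
phase, and pools results across independent runs.  All protocols
accept reduced step counts and run counts for quick exploration; the
defaults follow the standard study conditions (phase cut 2e6 steps,
measurement 1e6 steps per run).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .avalanche import AvalancheSet, detect_avalanches, half_mean_threshold
from .core import (
    NetworkParams,
    NetworkState,
    NoiseModel,
    PlasticityFlags,
    RecordOptions,
    SUPRATHRESHOLD,
    clone_state,
    init_network,
    make_streams,
    simulate,
)
from .fitting import (
    fit_truncated_exponential,
    fit_truncated_powerlaw,
    loglik_ratio,
)

__all__ = [
    "ExperimentConfig",
    "InputEnsemble",
    "DevelopmentResult",
    "FrozenComparison",
    "NoiseSweepResult",
    "SubsetNoiseResult",
    "OnsetResult",
    "run_development",
    "run_frozen_comparison",
    "run_noise_sweep",
    "run_subset_noise",
    "run_input_onset",
    "powerlaw_vs_exponential",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared protocol knobs.

    ``phase_cut`` discards the self-organization transient;
    ``measure_steps`` is the analyzed stable-phase window per run;
    ``n_runs`` independent simulations are pooled, seeded
    ``base_seed + run_index``.  ``freeze_set`` names the plasticity
    rules disabled at the cut in the frozen protocol.
    """

    phase_cut: int = 2_000_000
    measure_steps: int = 1_000_000
    n_runs: int = 1
    base_seed: int = 0
    freeze_set: tuple[str, ...] = ("stdp", "istdp", "sn", "sp", "ip")

    def __post_init__(self) -> None:
        if self.phase_cut < 0 or self.n_runs < 1 or self.measure_steps < 1:
            raise ValueError("invalid experiment configuration")


@dataclass(frozen=True)
class InputEnsemble:
    """Random-letter external input for the onset experiment.

    Ten letters by default, each driving a fixed random subset of
    ``subset_frac * N_E`` excitatory units (subsets may overlap) with a
    supra-threshold amplitude; one uniformly drawn letter per step.
    """

    n_letters: int = 10
    subset_frac: float = 0.02
    amplitude: float = SUPRATHRESHOLD


class _UniformLetters:
    """Letter source drawing one uniform letter per step."""

    def __init__(self, subsets: np.ndarray, amplitude: float):
        self.subsets = subsets
        self.amplitude = amplitude

    def next_ids(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.integers(0, len(self.subsets), size=n)


def powerlaw_vs_exponential(
    samples: np.ndarray, x_min: int, x_max: Optional[int]
) -> float:
    """Goodness-of-fit R of a windowed power law against an exponential.

    R > 0: the data look power-law distributed; R < 0: exponential.
    """
    pl = fit_truncated_powerlaw(samples, x_min, x_max)
    ex = fit_truncated_exponential(samples, x_min, x_max)
    return loglik_ratio(pl, ex)


# ---------------------------------------------------------------------------
# development phases
# ---------------------------------------------------------------------------

@dataclass
class DevelopmentResult:
    """Connection-fraction traces and phase boundaries per run."""

    conn_steps: np.ndarray                # shared sampling steps
    conn_traces: list[np.ndarray]         # raw trace per run
    smooth_traces: list[np.ndarray]
    decay_end: list[Optional[int]]        # step of the smoothed minimum
    stable_start: list[Optional[int]]     # None when not reached


def run_development(
    config: ExperimentConfig,
    params: NetworkParams,
    noise: NoiseModel,
    conn_every: int = 1_000,
    smooth_window: int = 10_000,
    stable_band: float = 0.05,
    stable_span: int = 200_000,
) -> DevelopmentResult:
    """Track the E->E connection fraction through self-organization.

    The raw trace is smoothed with a moving average (``smooth_window``
    steps); the decay phase ends at the smoothed global minimum, and
    the stable phase starts at the first step from which the smoothed
    trace stays within ``+-stable_band`` (relative) of its value for
    ``stable_span`` steps.
    """
    n_steps = config.phase_cut + config.measure_steps
    traces, smooths, decay_end, stable_start = [], [], [], []
    conn_steps = None
    win = max(1, smooth_window // conn_every)
    span = max(1, stable_span // conn_every)
    for r in range(config.n_runs):
        streams = make_streams(config.base_seed + r)
        state = init_network(params, streams["init"])
        rec = simulate(
            state, n_steps, params, noise, PlasticityFlags.all_on(), streams,
            record=RecordOptions(conn_every=conn_every),
        )
        conn_steps = rec.conn_steps
        trace = rec.conn_fraction
        kernel = np.ones(win) / win
        smooth = np.convolve(trace, kernel, mode="same")
        # moving-average edges are biased; trim them from boundary search
        lo, hi = win // 2, len(smooth) - win // 2
        core_slice = smooth[lo:hi] if hi > lo else smooth
        i_min = int(np.argmin(core_slice)) + (lo if hi > lo else 0)
        decay_end.append(int(conn_steps[i_min]))
        start = None
        for i in range(len(smooth) - span):
            seg = smooth[i:i + span]
            ref = smooth[i]
            if ref > 0 and np.all(np.abs(seg - ref) <= stable_band * ref):
                start = int(conn_steps[i])
                break
        stable_start.append(start)
        traces.append(trace)
        smooths.append(smooth)
    return DevelopmentResult(
        conn_steps=conn_steps,
        conn_traces=traces,
        smooth_traces=smooths,
        decay_end=decay_end,
        stable_start=stable_start,
    )


# ---------------------------------------------------------------------------
# frozen plasticity
# ---------------------------------------------------------------------------

@dataclass
class FrozenComparison:
    """Stable-phase avalanches of plastic, frozen and never-plastic nets."""

    plastic: AvalancheSet
    frozen: AvalancheSet
    random_control: AvalancheSet
    plastic_activity: np.ndarray
    frozen_activity: np.ndarray
    random_activity: np.ndarray


def run_frozen_comparison(
    config: ExperimentConfig,
    params: NetworkParams,
    noise: NoiseModel,
) -> FrozenComparison:
    """Branch each self-organized run into a plastic and a frozen copy.

    Both branches continue from an identical checkpoint and share the
    same membrane-noise stream, so any difference is caused purely by
    the frozen rules (``config.freeze_set``).  A never-plastic network
    (random initialization, all rules off) serves as control.
    Thresholds are the half-mean of each branch's own trace.
    """
    if not config.freeze_set:
        raise ValueError("freeze_set must name at least one rule")
    plastic_avs, frozen_avs, control_avs = [], [], []
    plastic_act, frozen_act, control_act = [], [], []
    on = PlasticityFlags.all_on()
    frozen_flags = on.freeze(config.freeze_set)
    for r in range(config.n_runs):
        streams = make_streams(config.base_seed + r)
        state = init_network(params, streams["init"])
        if config.phase_cut:
            simulate(state, config.phase_cut, params, noise, on, streams)
        state_frozen = clone_state(state)
        streams_frozen = copy.deepcopy(streams)    # shared noise stream state
        rec_p = simulate(
            state, config.measure_steps, params, noise, on, streams
        )
        rec_f = simulate(
            state_frozen, config.measure_steps, params, noise, frozen_flags,
            streams_frozen,
        )
        # never-plastic control from an independent random initialization
        streams_c = make_streams(config.base_seed + 10_000 + r)
        state_c = init_network(params, streams_c["init"])
        rec_c = simulate(
            state_c, config.measure_steps, params, noise,
            PlasticityFlags.all_off(), streams_c,
        )
        for rec, avs, acts in (
            (rec_p, plastic_avs, plastic_act),
            (rec_f, frozen_avs, frozen_act),
            (rec_c, control_avs, control_act),
        ):
            theta = half_mean_threshold(rec.activity)
            avs.append(detect_avalanches(rec.activity, theta))
            acts.append(rec.activity)
    return FrozenComparison(
        plastic=_pool(plastic_avs),
        frozen=_pool(frozen_avs),
        random_control=_pool(control_avs),
        plastic_activity=np.concatenate(plastic_act),
        frozen_activity=np.concatenate(frozen_act),
        random_activity=np.concatenate(control_act),
    )


def _pool(sets: list[AvalancheSet]) -> AvalancheSet:
    if len(sets) == 1:
        return sets[0]
    thetas = [s.theta for s in sets]
    if len(set(thetas)) > 1:
        # per-run thresholds may differ by a count or two; pool at the median
        med = int(np.median(thetas))
        sets = [AvalancheSet(s.t0, s.durations, s.sizes, med, s.trace_length)
                for s in sets]
    return AvalancheSet.concatenate(sets)


# ---------------------------------------------------------------------------
# noise regimes
# ---------------------------------------------------------------------------

@dataclass
class NoiseSweepResult:
    """Per-noise-level stable-phase statistics."""

    levels: list[NoiseModel]
    avalanches: list[AvalancheSet]
    activity: list[np.ndarray]
    r_size: list[Optional[float]]         # power-law vs exponential, sizes
    binomial_reference: np.ndarray        # pmf of Binomial(n_e, mu_ip)


def run_noise_sweep(
    config: ExperimentConfig,
    params: NetworkParams,
    noise_levels: Sequence[NoiseModel],
    size_window: tuple[int, int] = (10, 1500),
) -> NoiseSweepResult:
    """Self-organize and measure once per membrane-noise level.

    Each level runs the full protocol (the network adapts to its own
    noise).  Reports pooled avalanche sets, raw activity traces, the
    size-distribution power-law-vs-exponential R, and the binomial
    activity pmf expected for fully independent units.
    """
    if len(noise_levels) < 2:
        raise ValueError("need at least 2 noise levels to sweep")
    avalanches, acts, r_vals = [], [], []
    for lv, noise in enumerate(noise_levels):
        run_avs, run_act = [], []
        for r in range(config.n_runs):
            streams = make_streams(config.base_seed + 100 * lv + r)
            state = init_network(params, streams["init"])
            if config.phase_cut:
                simulate(state, config.phase_cut, params, noise,
                         PlasticityFlags.all_on(), streams)
            rec = simulate(state, config.measure_steps, params, noise,
                           PlasticityFlags.all_on(), streams)
            theta = half_mean_threshold(rec.activity)
            run_avs.append(detect_avalanches(rec.activity, theta))
            run_act.append(rec.activity)
        pooled = _pool(run_avs)
        avalanches.append(pooled)
        acts.append(np.concatenate(run_act))
        try:
            r_vals.append(powerlaw_vs_exponential(pooled.sizes, *size_window))
        except ValueError:
            r_vals.append(None)           # too few in-window avalanches
    ks = np.arange(params.n_e + 1)
    reference = stats.binom.pmf(ks, params.n_e, params.mu_ip)
    return NoiseSweepResult(
        levels=list(noise_levels),
        avalanches=avalanches,
        activity=acts,
        r_size=r_vals,
        binomial_reference=reference,
    )


# ---------------------------------------------------------------------------
# subset noise
# ---------------------------------------------------------------------------

@dataclass
class SubsetNoiseResult:
    """Per-fraction statistics with noise limited to a unit subset."""

    fractions: list[float]
    avalanches: list[AvalancheSet]
    masked_activity: list[np.ndarray]     # activity excluding driven subset
    r_size: list[Optional[float]]


def run_subset_noise(
    config: ExperimentConfig,
    params: NetworkParams,
    subset_fractions: Sequence[float],
    p_s: float = 1.0,
    size_window: tuple[int, int] = (10, 1500),
) -> SubsetNoiseResult:
    """Restrict random-spike noise to a random subset of excitatory units.

    With the default ``p_s`` = 1 the subset is continuously active, so
    the threshold and the avalanche trace are computed from the
    activity of the remaining units only.  Fraction 0 means no noise at
    all; fraction 1 with ``p_s`` < 1 recovers the standard random-spike
    condition.
    """
    avalanches, masked, r_vals = [], [], []
    for fi, frac in enumerate(subset_fractions):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        run_avs, run_act = [], []
        for r in range(config.n_runs):
            streams = make_streams(config.base_seed + 100 * fi + r)
            n_sub = int(round(frac * params.n_e))
            subset = streams["init"].choice(params.n_e, size=n_sub, replace=False)
            noise = NoiseModel(kind="random_spike", p_s=p_s, active_subset=subset)
            state = init_network(params, streams["init"])
            exclude = subset if p_s >= 1.0 else np.empty(0, dtype=np.intp)
            record = RecordOptions(raster=False)
            if config.phase_cut:
                simulate(state, config.phase_cut, params, noise,
                         PlasticityFlags.all_on(), streams)
            rec = simulate(state, config.measure_steps, params, noise,
                           PlasticityFlags.all_on(), streams,
                           record=RecordOptions(raster=len(exclude) > 0))
            if len(exclude):
                keep = np.ones(params.n_e, dtype=bool)
                keep[exclude] = False
                act = np.array(
                    [int(keep[f].sum()) for f in rec.raster], dtype=np.int64
                )
            else:
                act = rec.activity
            theta = half_mean_threshold(act)
            run_avs.append(detect_avalanches(act, theta))
            run_act.append(act)
        pooled = _pool(run_avs)
        avalanches.append(pooled)
        masked.append(np.concatenate(run_act))
        try:
            r_vals.append(powerlaw_vs_exponential(pooled.sizes, *size_window))
        except ValueError:
            r_vals.append(None)
    return SubsetNoiseResult(
        fractions=list(subset_fractions),
        avalanches=avalanches,
        masked_activity=masked,
        r_size=r_vals,
    )


# ---------------------------------------------------------------------------
# external-input onset and readaptation
# ---------------------------------------------------------------------------

@dataclass
class OnsetResult:
    """Avalanches before input, right after onset, and after readaptation."""

    before: AvalancheSet
    transient: AvalancheSet
    readapted: AvalancheSet
    theta: int
    n_trials: int


def run_input_onset(
    config: ExperimentConfig,
    params: NetworkParams,
    noise: NoiseModel,
    ensemble: InputEnsemble = InputEnsemble(),
    n_trials: int = 250,
    transient_window: int = 10,
    readapt_runs: int = 0,
) -> OnsetResult:
    """Switch on random-letter input at the stable phase.

    Per trial an independently self-organized network receives the
    input; avalanches that *start* within ``transient_window`` steps of
    onset are pooled into the transient set, the rest of each trial's
    trace into the readapted set.  The threshold is the half-mean of
    the pre-onset activity and is reused for both input periods.
    ``readapt_runs`` > 0 limits how many trials contribute their long
    post-transient trace (the transient needs many trials, the
    readapted statistics only a few).
    """
    if n_trials < 1:
        raise ValueError("need at least one onset trial")
    before_avs, transient_parts, readapt_avs = [], [], []
    theta_pool = []
    readapt_runs = readapt_runs or config.n_runs
    for trial in range(n_trials):
        streams = make_streams(config.base_seed + trial)
        state = init_network(params, streams["init"])
        if config.phase_cut:
            simulate(state, config.phase_cut, params, noise,
                     PlasticityFlags.all_on(), streams)
        rec_before = simulate(state, config.measure_steps, params, noise,
                              PlasticityFlags.all_on(), streams)
        theta = half_mean_threshold(rec_before.activity)
        theta_pool.append(theta)
        if trial < readapt_runs:
            before_avs.append(detect_avalanches(rec_before.activity, theta))
        subsets = make_letter_subsets(params.n_e, ensemble, streams["init"])
        source = _UniformLetters(subsets, ensemble.amplitude)
        post_steps = config.measure_steps if trial < readapt_runs \
            else transient_window + 1
        rec_post = simulate(state, post_steps, params, noise,
                            PlasticityFlags.all_on(), streams,
                            input_source=source)
        avs = detect_avalanches(rec_post.activity, theta)
        in_transient = avs.t0 < transient_window
        transient_parts.append(AvalancheSet(
            avs.t0[in_transient], avs.durations[in_transient],
            avs.sizes[in_transient], theta, min(post_steps, transient_window),
        ))
        if trial < readapt_runs:
            readapt_avs.append(AvalancheSet(
                avs.t0[~in_transient], avs.durations[~in_transient],
                avs.sizes[~in_transient], theta,
                avs.trace_length - transient_window,
            ))
    return OnsetResult(
        before=_pool(before_avs),
        transient=_pool(transient_parts),
        readapted=_pool(readapt_avs),
        theta=int(np.median(theta_pool)),
        n_trials=n_trials,
    )


def make_letter_subsets(
    n_e: int, ensemble: InputEnsemble, rng: np.random.Generator
) -> np.ndarray:
    """Fixed random unit subsets for each letter (may overlap)."""
    k = max(1, int(round(ensemble.subset_frac * n_e)))
    return np.stack(
        [rng.choice(n_e, size=k, replace=False) for _ in range(ensemble.n_letters)]
    )
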